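"""Wingbeat kinematics: stroke plane, Euler-angle poses, cycles, AoA, Re.

Angle conventions (fixed package convention, following the standard
hovering-insect Euler-angle system):

* the stroke plane is fitted as the total-least-squares (major-axis)
  plane of the wing-tip cloud through the wing base;
* within the stroke-plane frame the wing rotation is composed as
  positional angle φ about the plane normal, then stroke deviation θ
  out of the plane, then pitch ψ about the spanwise (base–apex) axis:
  ``R = Rz(φ) · Ry(−θ) · Rx(ψ)``;
* angle of attack is the angle between the wing chord plane and the
  velocity of the radius-of-gyration point: 0° = edge-on (feathered),
  ±90° = flat-on, with the sign of the velocity component along the
  wing normal (so the upstroke carries negative AoA).

Angles are stored in degrees, times in ms, lengths in µm.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import CubicSpline
from statsmodels.nonparametric.smoothers_lowess import lowess

from .geometry import Frame, periodic_gradient, rot_x, rot_y, rot_z, angular_velocity_body
from .units import AIR_DENSITY, AIR_KINEMATIC_VISCOSITY

__all__ = [
    "EulerAngleSeries",
    "StrokePlaneFrame",
    "BodySeries",
    "CycleSet",
    "WingPlanform",
    "FluidProperties",
    "KinematicDerivatives",
    "fit_stroke_plane",
    "pose_from_angles",
    "angles_from_pose",
    "tip_positions",
    "resample_uniform",
    "detect_cycles",
    "phase_average",
    "derive_kinematics",
    "body_speed",
    "clap_distance",
    "planform_from_outline",
]

PART_IDS = ("left_wing", "right_wing", "left_elytron", "right_elytron")


@dataclass(frozen=True)
class EulerAngleSeries:
    """Euler angles of one moving part: t (ms), θ, φ, ψ (degrees)."""

    part_id: str
    t: np.ndarray
    theta: np.ndarray
    phi: np.ndarray
    psi: np.ndarray

    def __post_init__(self):
        for name in ("t", "theta", "phi", "psi"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.t.size
        if any(getattr(self, k).size != n for k in ("theta", "phi", "psi")):
            raise ValueError("angle columns must have equal length")
        if n >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValueError("time must be strictly increasing")
        if not all(np.all(np.isfinite(getattr(self, k))) for k in ("t", "theta", "phi", "psi")):
            raise ValueError("angle series must be finite")

    @property
    def angles(self) -> np.ndarray:
        """(n, 3) array of (θ, φ, ψ) in degrees."""
        return np.column_stack([self.theta, self.phi, self.psi])

    def mirrored(self) -> "EulerAngleSeries":
        """Map a right-side series into the left-side convention (θ, −φ, −ψ)."""
        return replace(self, phi=-self.phi, psi=-self.psi)


@dataclass(frozen=True)
class StrokePlaneFrame:
    """Stroke-plane frame at the wing base.

    ``frame`` axes rows are (e1 in-plane, e2 in-plane, normal); ``beta`` is
    the pitch of the plane to the horizon in degrees.
    """

    frame: Frame
    beta: float

    @property
    def origin(self):
        return self.frame.origin

    @property
    def normal(self):
        return self.frame.axes[2]


def fit_stroke_plane(tip_points: np.ndarray, base) -> StrokePlaneFrame:
    """Total-least-squares (major-axis) stroke plane of a wing-tip cloud.

    The plane passes through ``base``; its normal is the smallest-variance
    principal direction of the tip cloud.
    """
    pts = np.asarray(tip_points, dtype=float).reshape(-1, 3)
    base = np.asarray(base, dtype=float).reshape(3)
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 tip points")
    X = pts - pts.mean(axis=0)
    _, s, Vt = np.linalg.svd(X, full_matrices=False)
    if s[1] <= 1e-12 * max(s[0], 1.0):
        raise ValueError("tip cloud is collinear; stroke plane undefined")
    normal = Vt[2]
    e1 = Vt[0]
    # deterministic sign convention
    if normal[np.argmax(np.abs(normal))] < 0:
        normal = -normal
    if e1[np.argmax(np.abs(e1))] < 0:
        e1 = -e1
    e2 = np.cross(normal, e1)
    frame = Frame(base, np.vstack([e1, e2, normal]))
    beta = float(np.degrees(np.arccos(np.clip(abs(normal[2]), 0.0, 1.0))))
    return StrokePlaneFrame(frame, beta)


def pose_from_angles(theta_deg, phi_deg, psi_deg, frame: StrokePlaneFrame) -> np.ndarray:
    """Rotation matrices (…, 3, 3) mapping wing axes to the lab frame.

    Wing local axes: x spanwise (base→apex), y chordwise, z normal.
    """
    th, ph, ps = (np.radians(np.asarray(a, dtype=float)) for a in (theta_deg, phi_deg, psi_deg))
    R_s = rot_z(ph) @ rot_y(-th) @ rot_x(ps)
    return frame.frame.axes.T @ R_s


def angles_from_pose(R_lab: np.ndarray, frame: StrokePlaneFrame,
                     gimbal_tol: float = 1e-9):
    """Invert :func:`pose_from_angles`; returns (θ, φ, ψ) in degrees.

    At |θ| = 90° the spanwise axis coincides with the stroke-plane normal
    and φ is indeterminate; such samples raise unless they are flagged by
    the caller.
    """
    R_s = frame.frame.axes @ np.asarray(R_lab, dtype=float)
    sz = np.clip(R_s[..., 2, 0], -1.0, 1.0)
    theta = np.arcsin(sz)
    if np.any(np.abs(np.abs(sz) - 1.0) < gimbal_tol):
        raise ValueError("gimbal lock: |theta| = 90°, positional angle indeterminate")
    phi = np.arctan2(R_s[..., 1, 0], R_s[..., 0, 0])
    M = rot_y(theta) @ np.swapaxes(rot_z(phi), -1, -2) @ R_s
    psi = np.arctan2(M[..., 2, 1], M[..., 1, 1])
    return tuple(np.degrees(a) for a in (theta, phi, psi))


def tip_positions(series_or_angles, frame: StrokePlaneFrame, radius: float) -> np.ndarray:
    """Lab-frame positions of the spanwise point at ``radius`` µm from the base."""
    if isinstance(series_or_angles, EulerAngleSeries):
        th, ph, ps = series_or_angles.theta, series_or_angles.phi, series_or_angles.psi
    else:
        th, ph, ps = series_or_angles
    R = pose_from_angles(th, ph, ps, frame)
    return frame.origin + radius * R[..., :, 0]


def resample_uniform(series: EulerAngleSeries, dt: float) -> EulerAngleSeries:
    """Cubic-spline resampling onto a uniform grid of step ``dt`` (ms)."""
    if series.t.size < 4:
        raise ValueError("need at least 4 samples for cubic resampling")
    t0, t1 = series.t[0], series.t[-1]
    n = int(np.floor((t1 - t0) / dt + 1e-9)) + 1
    tu = t0 + dt * np.arange(n)
    cols = {}
    for name in ("theta", "phi", "psi"):
        spl = CubicSpline(series.t, getattr(series, name))
        cols[name] = spl(tu)
    return EulerAngleSeries(series.part_id, tu, cols["theta"], cols["phi"], cols["psi"])


@dataclass(frozen=True)
class CycleSet:
    """Wingbeat cycle boundaries (ms), mean period T (ms) and frequency f = 1/T (kHz)."""

    boundaries: np.ndarray
    period: float
    frequency: float

    def __post_init__(self):
        b = np.asarray(self.boundaries, dtype=float)
        if b.size < 2 or not np.all(np.diff(b) > 0):
            raise ValueError("cycle boundaries must be strictly increasing, at least 2")
        object.__setattr__(self, "boundaries", b)
        if not self.frequency > 0:
            raise ValueError("frequency must be positive")

    @property
    def n_cycles(self) -> int:
        return self.boundaries.size - 1


def detect_cycles(series: EulerAngleSeries, fit_window: float | None = None) -> CycleSet:
    """Cycle boundaries at rising zero crossings of the positional angle φ.

    Each crossing time solves φ(t) = 0 by a local straight-line fit over a
    window (default T/8, iterated once), which suppresses the effect of
    measurement noise on the crossing estimate.  The period is the slope of
    a least-squares fit of crossing time against crossing index.
    """
    t, phi = series.t, series.phi
    sign = np.sign(phi)
    rising = np.nonzero((sign[:-1] <= 0) & (sign[1:] > 0))[0]
    if rising.size < 2:
        raise ValueError("fewer than 2 rising zero crossings of phi; cannot define cycles")
    tc = t[rising] - phi[rising] * (t[rising + 1] - t[rising]) / (phi[rising + 1] - phi[rising])
    # dominant period from the spectrum: noise-proof scale for the local fits
    x = phi - phi.mean()
    spec = np.abs(np.fft.rfft(x * np.hanning(x.size)))
    k = int(np.argmax(spec[1:])) + 1
    T0 = (t[-1] - t[0]) / k
    if fit_window is None:
        fit_window = T0 / 8.0
    refined = []
    for tcross in tc:
        if tcross - fit_window / 2 < t[0] or tcross + fit_window / 2 > t[-1]:
            continue  # truncated window would bias the fit
        m = (t >= tcross - fit_window / 2) & (t <= tcross + fit_window / 2)
        if m.sum() < 3:
            continue
        a, b = np.polyfit(t[m], phi[m], 1)
        if a <= 0:  # noise wiggle on a falling flank, not a rising crossing
            continue
        refined.append(-b / a)
    if len(refined) < 2:
        raise ValueError("fewer than 2 rising zero crossings of phi; cannot define cycles")
    # merge noise-split duplicates of one crossing
    refined = np.sort(np.asarray(refined))
    groups = [[refined[0]]]
    for tcross in refined[1:]:
        if tcross - groups[-1][-1] < 0.5 * T0:
            groups[-1].append(tcross)
        else:
            groups.append([tcross])
    tc = np.array([np.mean(g) for g in groups])
    if tc.size < 2:
        raise ValueError("fewer than 2 rising zero crossings of phi; cannot define cycles")
    idx = np.arange(tc.size)
    T, _ = np.polyfit(idx, tc, 1)
    return CycleSet(tc, float(T), 1.0 / float(T))


def phase_average(left: EulerAngleSeries, right: EulerAngleSeries | None,
                  cycles: CycleSet, n_phase: int = 256,
                  mirror_right: bool = True,
                  smooth_harmonics: int | None = None) -> EulerAngleSeries:
    """Phase-averaged wingbeat: cycles splined onto a common phase grid,
    averaged across cycles, then across sides.

    The right wing is mirrored into the left-side convention before
    averaging (``mirror_right=False`` averages the raw angles).  The
    returned series is on the dimensionless grid t/T ∈ [0, 1), reported on
    a time axis of one mean period.

    ``smooth_harmonics`` optionally projects the average onto a truncated
    Fourier basis, making the cycle exactly periodic (no seam at t/T = 0)
    and suppressing residual measurement noise before differentiation;
    ``None`` returns the plain average.
    """
    u = np.arange(n_phase) / n_phase

    def side_mean(series: EulerAngleSeries) -> np.ndarray:
        out = np.zeros((n_phase, 3))
        count = 0
        for k in range(cycles.n_cycles):
            a, b = cycles.boundaries[k], cycles.boundaries[k + 1]
            m = (series.t >= a - 1e-9) & (series.t <= b + 1e-9)
            if m.sum() < 4:
                continue
            for j, name in enumerate(("theta", "phi", "psi")):
                spl = CubicSpline(series.t[m], getattr(series, name)[m])
                out[:, j] += spl(a + u * (b - a))
            count += 1
        if count == 0:
            raise ValueError("no cycle contained enough samples to average")
        return out / count

    mean = side_mean(left)
    n_sides = 1
    if right is not None:
        r = right.mirrored() if mirror_right else right
        mean = mean + side_mean(r)
        n_sides = 2
    mean /= n_sides
    if smooth_harmonics is not None:
        spec = np.fft.rfft(mean, axis=0)
        spec[smooth_harmonics + 1:] = 0.0
        mean = np.fft.irfft(spec, n=n_phase, axis=0)
    return EulerAngleSeries("phase_average", u * cycles.period,
                            mean[:, 0], mean[:, 1], mean[:, 2])


@dataclass(frozen=True)
class WingPlanform:
    """Aerodynamically effective planform: length R, area S, mean chord, radius of gyration (µm)."""

    length: float
    area: float
    mean_chord: float
    radius_of_gyration: float

    def __post_init__(self):
        if not (0 < self.radius_of_gyration < self.length):
            raise ValueError("radius of gyration must lie inside the wing span")
        if not self.mean_chord > 0:
            raise ValueError("mean chord must be positive")


def planform_from_outline(boundary: np.ndarray, step: float = 2.0) -> WingPlanform:
    """Planform metrics of an effective outline polygon with the base at the origin.

    The radius of gyration is area-based, R_g = sqrt(∫ r² dS / S), with r
    the in-plane distance from the wing base — the representative station
    for aerodynamic wing speed.
    """
    from .morphology import MembranePatch, membrane_mass_properties

    patch = MembranePatch(boundary, thickness=1.0, cuticle_density=1.0)
    props = membrane_mass_properties(patch, origin=(0, 0, 0), step=step)
    area = props.mass  # unit surface density -> mass == area
    izz = props.izz    # == ∫ r² dS
    b = np.asarray(boundary, dtype=float)
    length = float(np.max(np.linalg.norm(b, axis=1)))
    return WingPlanform(length, area, area / length, float(np.sqrt(izz / area)))


@dataclass(frozen=True)
class FluidProperties:
    """Ambient air: density (µg/µm³) and kinematic viscosity (µm²/ms)."""

    density: float = AIR_DENSITY
    kinematic_viscosity: float = AIR_KINEMATIC_VISCOSITY

    def __post_init__(self):
        if not (self.density > 0 and self.kinematic_viscosity > 0):
            raise ValueError("fluid properties must be positive")


@dataclass(frozen=True)
class KinematicDerivatives:
    """Per-phase kinematic observables of one wing over a single cycle.

    Velocities are µm/ms at the radius-of-gyration point; AoA in degrees
    signed by the normal velocity component; Re is dimensionless.
    ``gaps`` flags samples where the speed vanishes and AoA is undefined.
    """

    phase: np.ndarray
    rotations: np.ndarray
    tip_position: np.ndarray
    tip_velocity: np.ndarray
    speed: np.ndarray
    aoa_deg: np.ndarray
    re_instantaneous: np.ndarray
    re_mean: float
    gaps: np.ndarray
    omega_body: np.ndarray
    alpha_body: np.ndarray
    frame: StrokePlaneFrame
    period: float


def derive_kinematics(phase_series: EulerAngleSeries, frame: StrokePlaneFrame,
                      planform: WingPlanform, fluid: FluidProperties,
                      period: float | None = None,
                      speed_floor: float = 1e-9) -> KinematicDerivatives:
    """Kinematic observables from a phase-averaged cycle on a uniform grid.

    Differentiation is periodic (the grid covers [0, T) without the
    duplicated endpoint).  Samples with speed below ``speed_floor`` ×
    max speed are reported as gaps, never interpolated.
    """
    t = phase_series.t
    n = t.size
    dt = t[1] - t[0]
    if not np.allclose(np.diff(t), dt):
        raise ValueError("derive_kinematics requires a uniform phase grid")
    T = period if period is not None else t[-1] + dt
    R = pose_from_angles(phase_series.theta, phase_series.phi, phase_series.psi, frame)
    rg = planform.radius_of_gyration
    pos = frame.origin + rg * R[:, :, 0]
    vel = periodic_gradient(pos, dt, axis=0)
    speed = np.linalg.norm(vel, axis=1)
    gaps = speed <= speed_floor * max(speed.max(), 1e-300)
    normal = R[:, :, 2]
    vn = np.einsum("ij,ij->i", vel, normal)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.clip(np.abs(vn) / speed, 0.0, 1.0)
        aoa = np.degrees(np.arcsin(s)) * np.sign(vn)
    aoa[gaps] = np.nan
    chord = planform.mean_chord
    re_inst = speed * chord / fluid.kinematic_viscosity
    ok = ~gaps
    re_mean = float(speed[ok].mean() * chord / fluid.kinematic_viscosity) if ok.any() else 0.0
    omega = angular_velocity_body(R, dt, periodic=True)
    alpha = periodic_gradient(omega, dt, axis=0)
    return KinematicDerivatives(t / T, R, pos, vel, speed, aoa, re_inst, re_mean,
                                gaps, omega, alpha, frame, T)


@dataclass(frozen=True)
class BodySeries:
    """Body-centre track with raw and loess-filtered velocity (µm/ms)."""

    t: np.ndarray
    position: np.ndarray
    velocity_raw: np.ndarray
    velocity: np.ndarray
    chi_deg: np.ndarray | None = None

    @property
    def horizontal_speed(self) -> np.ndarray:
        return np.linalg.norm(self.velocity[:, :2], axis=1)

    @property
    def vertical_speed(self) -> np.ndarray:
        return self.velocity[:, 2]


def body_speed(t: np.ndarray, track: np.ndarray, loess_frac: float = 0.25,
               chi_deg: np.ndarray | None = None) -> BodySeries:
    """Finite-difference body velocity, loess-smoothed component-wise.

    ``loess_frac`` is the lowess span as a fraction of the series length
    (a smoothing parameter of this implementation; 0 disables smoothing).
    """
    t = np.asarray(t, dtype=float)
    track = np.asarray(track, dtype=float).reshape(-1, 3)
    if t.size < 10:
        raise ValueError("need at least 10 samples for body speed estimation")
    v_raw = np.gradient(track, t, axis=0)
    if loess_frac > 0:
        v = np.column_stack([
            lowess(v_raw[:, j], t, frac=loess_frac, return_sorted=False)
            for j in range(3)
        ])
    else:
        v = v_raw.copy()
    return BodySeries(t, track, v_raw, v, chi_deg)


def clap_distance(tips_left: np.ndarray, tips_right: np.ndarray,
                  phase: np.ndarray | None = None,
                  window: tuple[float, float] | None = None) -> float:
    """Minimum tip-to-tip separation (µm), optionally inside a phase window.

    ``window`` is a (lo, hi) interval of dimensionless phase t/T; it may
    wrap around 1 (lo > hi).  By default the whole series is searched.
    """
    d = np.linalg.norm(np.asarray(tips_left) - np.asarray(tips_right), axis=1)
    if window is not None:
        if phase is None:
            raise ValueError("a phase array is required with a phase window")
        lo, hi = window
        m = (phase >= lo) & (phase <= hi) if lo <= hi else (phase >= lo) | (phase <= hi)
        if not m.any():
            raise ValueError("phase window contains no samples")
        d = d[m]
    return float(d.min())
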