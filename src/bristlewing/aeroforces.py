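"""Aerodynamic force series, lift/drag decomposition and vertical-force budget.

The drag component of the instantaneous aerodynamic force on a wing is its
projection onto the direction of the wing velocity at the radius of
gyration; lift is the vector remainder, so drag + lift reconstructs the
total exactly and lift is orthogonal to the velocity by construction.
Where the speed vanishes (stroke reversals) the decomposition is undefined
and those samples are reported as gaps rather than silently filled.

Forces are internal units (µg·µm/ms² = nN); torques µg·µm²/ms², with the
reference point recorded explicitly.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np

from .kinematics import FluidProperties, KinematicDerivatives, WingPlanform
from .units import GRAVITY

__all__ = [
    "ForceSeries",
    "LiftDragDecomposition",
    "VerticalForceBreakdown",
    "CoefficientTable",
    "decompose",
    "quasisteady_surrogate",
    "vertical_breakdown",
    "shift_torque_reference",
]


@dataclass(frozen=True)
class ForceSeries:
    """Per-part aerodynamic force/torque series on the kinematic phase grid.

    ``torque_ref`` is the point (µm, lab frame) about which ``torque`` is
    taken; use :func:`shift_torque_reference` to move it.
    """

    part_id: str
    phase: np.ndarray
    force: np.ndarray
    torque: np.ndarray
    torque_ref: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        phase = np.asarray(self.phase, dtype=float)
        force = np.asarray(self.force, dtype=float).reshape(-1, 3)
        torque = np.asarray(self.torque, dtype=float).reshape(-1, 3)
        ref = np.asarray(self.torque_ref, dtype=float).reshape(3)
        if not (phase.size == force.shape[0] == torque.shape[0]):
            raise ValueError("phase, force and torque must share their length")
        if not (np.all(np.isfinite(force)) and np.all(np.isfinite(torque))):
            raise ValueError("force series must be finite")
        for name, val in (("phase", phase), ("force", force), ("torque", torque),
                          ("torque_ref", ref)):
            object.__setattr__(self, name, val)

    def __add__(self, other: "ForceSeries") -> "ForceSeries":
        if not (np.allclose(self.phase, other.phase)
                and np.allclose(self.torque_ref, other.torque_ref)):
            raise ValueError("can only add force series on one grid and torque reference")
        return ForceSeries(f"{self.part_id}+{other.part_id}", self.phase,
                           self.force + other.force, self.torque + other.torque,
                           self.torque_ref)

    def scaled(self, factor: float) -> "ForceSeries":
        return replace(self, force=self.force * factor, torque=self.torque * factor)


def shift_torque_reference(fs: ForceSeries, new_ref) -> ForceSeries:
    """Re-express torques about ``new_ref``: τ' = τ + (r_old − r_new) × F."""
    new_ref = np.asarray(new_ref, dtype=float).reshape(3)
    arm = fs.torque_ref - new_ref
    return replace(fs, torque=fs.torque + np.cross(arm, fs.force), torque_ref=new_ref)


@dataclass(frozen=True)
class LiftDragDecomposition:
    """Drag ∥ velocity, lift ⊥ velocity, their vertical components, and gaps."""

    phase: np.ndarray
    drag: np.ndarray
    lift: np.ndarray
    vertical_drag: np.ndarray
    vertical_lift: np.ndarray
    gaps: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.drag + self.lift


def decompose(fs: ForceSeries, velocity: np.ndarray,
              gaps: np.ndarray | None = None,
              speed_floor: float = 1e-9) -> LiftDragDecomposition:
    """Split a force series into drag (∥ v) and lift (⊥ v) components.

    ``velocity`` is the wing velocity at the radius of gyration on the same
    grid.  Gap samples (zero speed) carry NaN components.
    """
    v = np.asarray(velocity, dtype=float).reshape(-1, 3)
    if v.shape[0] != fs.phase.size:
        raise ValueError("velocity must be on the force grid")
    speed = np.linalg.norm(v, axis=1)
    if gaps is None:
        gaps = speed <= speed_floor * max(speed.max(), 1e-300)
    ok = ~gaps
    drag = np.full_like(fs.force, np.nan)
    vhat = v[ok] / speed[ok, None]
    drag[ok] = np.einsum("ij,ij->i", fs.force[ok], vhat)[:, None] * vhat
    lift = fs.force - drag
    return LiftDragDecomposition(fs.phase, drag, lift, drag[:, 2], lift[:, 2], gaps)


@dataclass(frozen=True)
class CoefficientTable:
    """Quasi-steady force coefficients versus AoA with a low-Re inflation.

    ``cd(aoa_deg)`` and ``cl(aoa_deg)`` take the unsigned AoA in degrees;
    both are multiplied by (1 + k_re / Re).  The defaults are a generic
    flat-plate-like shape (drag rising monotonically from edge-on to
    flat-on, lift peaking near 45°) — package defaults for the desk-scale
    surrogate, not measured values; replace them to calibrate.
    """

    cd: Callable[[np.ndarray], np.ndarray] = None
    cl: Callable[[np.ndarray], np.ndarray] = None
    k_re: float = 5.0

    def __post_init__(self):
        if self.cd is None:
            object.__setattr__(self, "cd", lambda a: 0.35 + 1.1 * np.sin(np.radians(a)) ** 2)
        if self.cl is None:
            object.__setattr__(self, "cl", lambda a: 1.3 * np.sin(2.0 * np.radians(a)))
        if self.k_re < 0:
            raise ValueError("k_re must be non-negative")

    def evaluate(self, aoa_deg: np.ndarray, re: np.ndarray):
        a = np.abs(np.asarray(aoa_deg, dtype=float))
        cd = np.asarray(self.cd(a), dtype=float)
        cl = np.asarray(self.cl(a), dtype=float)
        if np.any(cd < 0) or np.any(cl < 0):
            raise ValueError("force coefficients must be non-negative")
        infl = 1.0 + self.k_re / np.maximum(np.asarray(re, dtype=float), 1e-9)
        return cd * infl, cl * infl


def quasisteady_surrogate(kin: KinematicDerivatives, planform: WingPlanform,
                          fluid: FluidProperties,
                          coeffs: CoefficientTable | None = None,
                          part_id: str = "wing") -> ForceSeries:
    """Blade-element-style stand-in force series from kinematics alone.

    Drag opposes the velocity of the radius-of-gyration point with
    magnitude ½ ρ C_D S U²; lift is normal to the velocity in the
    chord–velocity plane with ½ ρ C_L S U².  The force acts at the
    radius-of-gyration point; torque is reported about the wing base.
    This is a phenomenological surrogate with the phase structure of the
    real flow (force peaks locked to the fast, flat-on phases), not a
    Navier–Stokes result.
    """
    coeffs = coeffs or CoefficientTable()
    v = kin.tip_velocity
    speed = kin.speed
    ok = ~kin.gaps
    q = np.zeros_like(speed)
    aoa = np.where(ok, np.nan_to_num(kin.aoa_deg), 0.0)
    cd, cl = coeffs.evaluate(aoa, np.maximum(kin.re_instantaneous, 1e-12))
    q[ok] = 0.5 * fluid.density * planform.area * speed[ok] ** 2
    F = np.zeros((speed.size, 3))
    vhat = np.zeros_like(F)
    vhat[ok] = v[ok] / speed[ok, None]
    F -= (q * cd)[:, None] * vhat  # drag, anti-aligned with velocity
    normal = kin.rotations[:, :, 2]
    vn = np.einsum("ij,ij->i", v, normal)
    # lift direction: ⊥ v in the plane of v and the wing normal, pointing
    # toward the side the flow comes from
    lperp = normal - np.einsum("ij,ij->i", normal, vhat)[:, None] * vhat
    lnorm = np.linalg.norm(lperp, axis=1)
    usable = ok & (lnorm > 1e-9)
    lhat = np.zeros_like(F)
    lhat[usable] = (-np.sign(vn[usable]))[:, None] * lperp[usable] / lnorm[usable, None]
    F += (q * cl)[:, None] * lhat
    arm = kin.tip_position - kin.frame.origin
    torque = np.cross(arm, F)
    return ForceSeries(part_id, kin.phase, F, torque, torque_ref=kin.frame.origin)


@dataclass(frozen=True)
class VerticalForceBreakdown:
    """Cycle-averaged vertical force budget.

    Per-part means are internal force units (nN); ``weight_equivalent_ug``
    divides by g so the support capacity reads directly in µg.  The
    drag/lift split refers to the wings' cycle-averaged vertical force.
    Vertical acceleration is µm/ms² (numerically m/s²).
    """

    per_part_mean: Mapping[str, float]
    total_mean: float
    weight_equivalent_ug: Mapping[str, float]
    drag_share_pct: float
    lift_share_pct: float
    vertical_acceleration: float


def vertical_breakdown(parts: Mapping[str, ForceSeries],
                       wing_decompositions: Mapping[str, LiftDragDecomposition],
                       body_mass: float, g: float = GRAVITY) -> VerticalForceBreakdown:
    """Cycle-mean vertical forces per part, drag/lift split, and net lift margin."""
    per_part = {name: float(fs.force[:, 2].mean()) for name, fs in parts.items()}
    total = float(sum(per_part.values()))
    weights = {name: v / g for name, v in per_part.items()}
    weights["total"] = total / g
    vd = vl = 0.0
    for dec in wing_decompositions.values():
        ok = ~dec.gaps
        vd += float(np.where(ok, dec.vertical_drag, 0.0).sum()) / dec.phase.size
        vl += float(np.where(ok, dec.vertical_lift, 0.0).sum()) / dec.phase.size
    wings_total = vd + vl
    if wings_total == 0:
        raise ValueError("wings produce zero mean vertical force; shares undefined")
    drag_share = 100.0 * vd / wings_total
    accel = (total - body_mass * g) / body_mass
    return VerticalForceBreakdown(per_part, total, weights, drag_share,
                                  100.0 - drag_share, accel)
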