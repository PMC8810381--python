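"""Mechanical power budget and single-axis body-pitch dynamics.

Inertial power is the rate of change of a rigid wing's rotational kinetic
energy about its base, P = ω·(I α + ω × (I ω)) with ω, α and I in the
wing frame (the gyroscopic term is orthogonal to ω and contributes no
power, but is kept for completeness).  Aerodynamic power is the rate of
work done by the wing on the air, P = −τ_base·ω.

Elastic-storage scenarios follow the classic muscle-work bookkeeping:
with no storage, negative total power cannot be recovered and the muscle
mean is the mean of max(P, 0); with perfect storage it is the plain mean.
A wing whose total power never goes negative makes storage irrelevant —
the two means coincide.

Body pitch is a single-degree-of-freedom torque balance
I_b χ̈ = τ_aero(t) + τ_recoil(t) integrated with fixed-step RK4; the elytra
enter as the recoil (reaction) torque −d/dt(I_e ω_e) projected onto the
pitch axis, the "inertial brake".
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import periodic_gradient
from .units import GRAVITY, SPECIFIC_POWER_TO_W_PER_KG

__all__ = [
    "BodyModel",
    "PowerBreakdown",
    "PitchDynamicsResult",
    "inertial_power",
    "aerodynamic_power",
    "power_scenarios",
    "recoil_pitch_torque",
    "pitch_simulation",
]


@dataclass(frozen=True)
class BodyModel:
    """Body mass (µg), pitch-axis moment of inertia (µg·µm²), centre of mass, g."""

    mass: float
    pitch_inertia: float
    com: np.ndarray = None
    g: float = GRAVITY

    def __post_init__(self):
        if not (self.mass > 0 and self.pitch_inertia > 0 and self.g > 0):
            raise ValueError("body mass, pitch inertia and g must be positive")
        com = np.zeros(3) if self.com is None else np.asarray(self.com, dtype=float).reshape(3)
        object.__setattr__(self, "com", com)


def inertial_power(inertia: np.ndarray, omega: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """P_inert(t) = ω·(I α + ω × (I ω)), internal power units (pW).

    ``inertia`` is the constant 3×3 wing tensor about the base in wing
    axes; ``omega``/``alpha`` are (n, 3) wing-frame angular velocity and
    acceleration in rad/ms and rad/ms².
    """
    I = np.asarray(inertia, dtype=float).reshape(3, 3)
    w = np.asarray(omega, dtype=float).reshape(-1, 3)
    a = np.asarray(alpha, dtype=float).reshape(-1, 3)
    torque = a @ I.T + np.cross(w, w @ I.T)
    return np.einsum("ij,ij->i", w, torque)


def rotational_kinetic_energy(inertia: np.ndarray, omega: np.ndarray) -> np.ndarray:
    """½ ωᵀ I ω per sample (µg·µm²/ms²)."""
    I = np.asarray(inertia, dtype=float).reshape(3, 3)
    w = np.asarray(omega, dtype=float).reshape(-1, 3)
    return 0.5 * np.einsum("ij,jk,ik->i", w, I, w)


def aerodynamic_power(torque_base: np.ndarray, omega: np.ndarray) -> np.ndarray:
    """P_aero(t) = −τ_base·ω: positive when the wing does work on the air.

    Both series must be expressed in one common frame (lab or wing).
    """
    tau = np.asarray(torque_base, dtype=float).reshape(-1, 3)
    w = np.asarray(omega, dtype=float).reshape(-1, 3)
    return -np.einsum("ij,ij->i", tau, w)


@dataclass(frozen=True)
class PowerBreakdown:
    """Body-mass-specific power series (W/kg) and cycle statistics.

    ``mean_no_storage`` rectifies negative total power before averaging;
    ``mean_perfect_storage`` is the plain mean.  ``always_positive`` marks
    the regime in which the two coincide and elastic storage is obsolete.
    """

    phase: np.ndarray
    aero: np.ndarray
    inertial: np.ndarray
    total: np.ndarray
    mean_aero: float
    mean_inertial: float
    mean_total: float
    peak_total: float
    mean_no_storage: float
    mean_perfect_storage: float
    always_positive: bool


def power_scenarios(p_aero: np.ndarray, p_inertial: np.ndarray,
                    body_mass: float) -> PowerBreakdown:
    """Assemble the body-mass-specific power budget with storage scenarios.

    Inputs are internal power series over one cycle on a uniform phase
    grid; the output is W per kg body mass.
    """
    pa = np.asarray(p_aero, dtype=float) / body_mass * SPECIFIC_POWER_TO_W_PER_KG
    pi = np.asarray(p_inertial, dtype=float) / body_mass * SPECIFIC_POWER_TO_W_PER_KG
    if pa.shape != pi.shape:
        raise ValueError("power series must share their grid")
    pt = pa + pi
    n = pt.size
    phase = np.arange(n) / n
    mean_perfect = float(pt.mean())
    mean_no_storage = float(np.maximum(pt, 0.0).mean())
    always_positive = bool(pt.min() >= 0.0)
    return PowerBreakdown(phase, pa, pi, pt, float(pa.mean()), float(pi.mean()),
                          mean_perfect, float(pt.max()), mean_no_storage,
                          mean_perfect, always_positive)


def recoil_pitch_torque(inertia: np.ndarray, rotations: np.ndarray,
                        omega_body: np.ndarray, dt: float,
                        pitch_axis=(0.0, 1.0, 0.0)) -> np.ndarray:
    """Reaction torque of an accelerating appendage on the body, pitch component.

    The appendage's angular momentum in the lab frame is L = R (I ω_body);
    the body feels −dL/dt.  Returns the component along ``pitch_axis``
    (lab y by default; positive = nose-down for an x-forward, z-up body).
    """
    I = np.asarray(inertia, dtype=float).reshape(3, 3)
    R = np.asarray(rotations, dtype=float)
    w = np.asarray(omega_body, dtype=float).reshape(-1, 3)
    L = np.einsum("nij,nj->ni", R, w @ I.T)
    tau = -periodic_gradient(L, dt, axis=0)
    return tau @ np.asarray(pitch_axis, dtype=float).reshape(3)


@dataclass(frozen=True)
class PitchDynamicsResult:
    """Body-pitch trajectories with and without elytra recoil.

    Amplitudes are peak-to-peak χ (degrees) measured after discarding the
    transient and removing a quadratic trend (net angular acceleration);
    ``amplitude_ratio_pct`` = 100 × with/without.
    """

    t: np.ndarray
    chi_with: np.ndarray
    chi_without: np.ndarray
    amplitude_with: float
    amplitude_without: float
    amplitude_ratio_pct: float
    torque_aero: np.ndarray
    torque_recoil: np.ndarray


def _rk4_double_integrator(tau_over_I, t0, t1, n_steps, chi0, chidot0):
    h = (t1 - t0) / n_steps
    t = t0
    chi, chidot = chi0, chidot0
    ts = np.empty(n_steps + 1)
    chis = np.empty(n_steps + 1)
    ts[0], chis[0] = t, chi
    for i in range(n_steps):
        k1v = tau_over_I(t)
        k1x = chidot
        k2v = tau_over_I(t + 0.5 * h)
        k2x = chidot + 0.5 * h * k1v
        k3v = k2v
        k3x = chidot + 0.5 * h * k2v
        k4v = tau_over_I(t + h)
        k4x = chidot + h * k3v
        chi += (h / 6.0) * (k1x + 2 * k2x + 2 * k3x + k4x)
        chidot += (h / 6.0) * (k1v + 2 * k2v + 2 * k3v + k4v)
        t = t0 + (i + 1) * h
        ts[i + 1], chis[i + 1] = t, chi
    return ts, chis


def _p2p_detrended(t, chi, period):
    """Peak-to-peak of the periodic part of χ.

    The secular drift (from initial conditions and any net mean torque) is
    a polynomial in t whose cycle means sample it exactly, while a periodic
    oscillation has constant cycle means — so fitting the drift through the
    cycle means removes it without eating into the oscillation.
    """
    k = np.floor((t - t[0]) / period + 1e-12).astype(int)
    n_cyc = k.max() + 1
    centers, means = [], []
    for i in range(n_cyc):
        m = k == i
        if m.sum() < 4:
            continue
        centers.append(t[m].mean())
        means.append(chi[m].mean())
    order = min(2, len(means) - 1)
    coef = np.polyfit(np.asarray(centers), np.asarray(means), order)
    resid = chi - np.polyval(coef, t)
    return float(resid.max() - resid.min())


def pitch_simulation(torque_aero: np.ndarray, torque_recoil: np.ndarray,
                     body: BodyModel, period: float, cycles: int = 6,
                     steps_per_cycle: int | None = None,
                     discard_cycles: int = 1,
                     chi0_deg: float = 0.0,
                     periodicity_tol: float = 0.05) -> PitchDynamicsResult:
    """Integrate I_b χ̈ = τ_aero(t) + τ_recoil(t) over several wingbeat cycles.

    Torque inputs are scalar pitch-axis series (nose-down positive,
    internal units) sampled on a uniform grid over one period and repeated
    periodically.  The same integration with the recoil zeroed gives the
    "without elytra" trajectory.  The first ``discard_cycles`` cycles are
    dropped as transient before measuring the peak-to-peak amplitudes
    about a quadratic trend.
    """
    tau_a = np.asarray(torque_aero, dtype=float)
    tau_r = np.asarray(torque_recoil, dtype=float)
    if tau_a.shape != tau_r.shape:
        raise ValueError("aero and recoil torque series must share their grid")
    if cycles <= discard_cycles:
        raise ValueError("need more cycles than the discarded transient")
    n = tau_a.size
    for name, tau in (("aero", tau_a), ("recoil", tau_r)):
        steps = np.abs(np.diff(tau))
        typical = max(np.percentile(steps, 95), 1e-300) if steps.size else 1e-300
        if abs(tau[0] - tau[-1]) > max(5.0 * typical, periodicity_tol * np.abs(tau).max()):
            warnings.warn(f"{name} torque series looks non-periodic at the cycle "
                          "boundary; it is wrapped periodically anyway")
    grid = np.arange(n) / n * period

    def make_interp(tau):
        def f(t):
            return float(np.interp(np.mod(t, period), grid, tau, period=period)) / body.pitch_inertia
        return f

    n_steps = (steps_per_cycle or n) * cycles
    t_with, chi_with = _rk4_double_integrator(
        make_interp(tau_a + tau_r), 0.0, cycles * period, n_steps, np.radians(chi0_deg), 0.0)
    _, chi_without = _rk4_double_integrator(
        make_interp(tau_a), 0.0, cycles * period, n_steps, np.radians(chi0_deg), 0.0)
    chi_with = np.degrees(chi_with)
    chi_without = np.degrees(chi_without)
    keep = t_with >= discard_cycles * period - 1e-12
    amp_with = _p2p_detrended(t_with[keep], chi_with[keep], period)
    amp_without = _p2p_detrended(t_with[keep], chi_without[keep], period)
    ratio = 100.0 * amp_with / amp_without if amp_without > 0 else float("nan")
    return PitchDynamicsResult(t_with, chi_with, chi_without, amp_with, amp_without,
                               ratio, tau_a, tau_r)
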