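"""End-to-end analysis runs and the structured report.

The pipeline chains the modules exactly the way the headline quantities
are defined: morphology → mass properties; Euler angles → cycles → phase
average → AoA/Re; forces (surrogate or file) → lift/drag split → vertical
budget; kinematics × inertia → power budget with storage scenarios;
torques → pitch dynamics with and without the elytra inertial brake.
Every report entry is produced by a module call; stage failures abort
with the failing stage named.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import seriesio
from .aeroforces import decompose, quasisteady_surrogate, shift_torque_reference, vertical_breakdown
from .kinematics import (FluidProperties, body_speed, clap_distance, detect_cycles,
                         derive_kinematics, fit_stroke_plane, phase_average,
                         resample_uniform, tip_positions)
from .morphology import assemble_wing, membrane_mass_properties
from .power import (aerodynamic_power, inertial_power, pitch_simulation,
                    power_scenarios, recoil_pitch_torque)
from .synthetic import (MorphFixtureSpec, ProtocolSpec, default_body_model,
                        make_morphology, make_protocol)

logger = logging.getLogger("bristlewing")

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

#: resampling step for the uniform kinematic grid, ms (2.6 µs)
DEFAULT_DT = 2.6e-3


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of an end-to-end run.

    With no file paths the run is fully synthetic from ``seed``.  Paths,
    when given, must exist; forces may come from a file dialect written by
    :mod:`bristlewing.seriesio` instead of the quasi-steady surrogate.
    """

    seed: int = 0
    morphology_path: str | None = None
    angles_dir: str | None = None
    forces_path: str | None = None
    force_source: str = "surrogate"  # or "file"
    dt: float = DEFAULT_DT
    n_phase: int = 256
    smooth_harmonics: int | None = 12
    body_pitch_inertia: float = 3.0e4
    pitch_cycles: int = 6
    drop_elytra_aero: bool = False  # "without elytra" variant: drop their wind torque too
    loess_frac: float = 0.25
    output_dir: str | None = None
    protocol: ProtocolSpec | None = None
    morph_spec: MorphFixtureSpec | None = None

    def __post_init__(self):
        for p in (self.morphology_path, self.forces_path, self.angles_dir):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured path does not exist: {p}")
        if self.force_source not in ("surrogate", "file"):
            raise ValueError("force_source must be 'surrogate' or 'file'")
        if self.force_source == "file" and self.forces_path is None:
            raise ValueError("force_source 'file' requires forces_path")


def _stage(name):
    def deco(fn):
        def wrapper(*a, **k):
            logger.info("stage %s", name)
            try:
                return fn(*a, **k)
            except PipelineError:
                raise
            except Exception as e:  # noqa: BLE001 - re-raised with stage context
                raise PipelineError(name, e) from e
        return wrapper
    return deco


@dataclass
class _State:
    config: RunConfig
    report: dict = field(default_factory=dict)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis chain and return the structured report."""
    st = _State(config)
    morph = _stage("morphology")(_run_morphology)(st)
    proto = _stage("protocol")(_run_protocol)(st, morph)
    kin = _stage("kinematics")(_run_kinematics)(st, proto, morph)
    forces = _stage("forces")(_run_forces)(st, proto, kin, morph)
    _stage("vertical_budget")(_run_vertical)(st, forces, kin)
    power = _stage("power")(_run_power)(st, kin, morph, forces)
    _stage("pitch_dynamics")(_run_pitch)(st, proto, kin, forces, morph)
    st.report["units"] = {
        "mass": "ug", "length": "um", "time": "ms", "force": "nN",
        "torque": "nN*um", "specific_power": "W/kg", "speed": "m/s",
        "angles": "deg",
    }
    st.report["seed"] = config.seed
    if config.output_dir:
        seriesio.write_json(st.report, Path(config.output_dir) / "report.json")
    return st.report


def _run_morphology(st: _State):
    cfg = st.config
    if cfg.morphology_path:
        wing = seriesio.read_morphology(cfg.morphology_path)
        morph = make_morphology(cfg.morph_spec or MorphFixtureSpec(seed=cfg.seed))
        morph = replace(morph, wing=wing)
    else:
        morph = make_morphology(cfg.morph_spec or MorphFixtureSpec(seed=cfg.seed))
    props = assemble_wing(morph.wing)
    body = default_body_model(cfg.body_pitch_inertia)
    sub_props = [membrane_mass_properties(s) for s in morph.substitutes]
    st.report["morphology"] = {
        "wing_mass_ug": props.mass,
        "wing_izz_ug_um2": props.izz,
        "wing_to_body_mass_pct": 100.0 * props.mass / body.mass,
        "setae_area_fraction_pct": 100.0 * morph.setae_area_fraction,
        "membrane_thicknesses_um": list(morph.labels["membrane_thicknesses_um"]),
        "substitute_masses_ug": [p.mass for p in sub_props],
        "substitute_izz_ug_um2": [p.izz for p in sub_props],
        "planform": {
            "length_um": morph.planform.length,
            "area_um2": morph.planform.area,
            "mean_chord_um": morph.planform.mean_chord,
            "radius_of_gyration_um": morph.planform.radius_of_gyration,
        },
    }
    st._wing_props = props
    st._sub_props = sub_props
    st._body = body
    return morph


def _run_protocol(st: _State, morph):
    cfg = st.config
    spec = cfg.protocol or ProtocolSpec(seed=cfg.seed)
    proto = make_protocol(spec, planform=morph.planform)
    if cfg.angles_dir:
        series = dict(proto.series)
        for part in series:
            p = Path(cfg.angles_dir) / f"{part}.csv"
            if p.exists():
                series[part] = seriesio.read_angles(p)
        proto = replace(proto, series=series)
    st.report["protocol"] = {
        "frequency_khz": proto.frequency,
        "period_ms": proto.period,
        "n_cycles": spec.n_cycles,
        "noise_sigma_deg": spec.noise_sigma_deg,
        "clap_distance_truth_um": proto.labels["clap_distance_um"],
    }
    return proto


def _run_kinematics(st: _State, proto, morph):
    cfg = st.config
    fluid = FluidProperties()
    uniform = {p: resample_uniform(s, cfg.dt) for p, s in proto.series.items()}
    cycles = detect_cycles(uniform["left_wing"])
    wing_avg = phase_average(uniform["left_wing"], uniform["right_wing"], cycles,
                             n_phase=cfg.n_phase, smooth_harmonics=cfg.smooth_harmonics)
    elytron_avg = phase_average(uniform["left_elytron"], uniform["right_elytron"],
                                cycles, n_phase=cfg.n_phase,
                                smooth_harmonics=cfg.smooth_harmonics)
    frame_l = proto.frames["left_wing"]
    tips = tip_positions(uniform["left_wing"], frame_l, morph.planform.length)
    stroke_plane = fit_stroke_plane(tips, frame_l.origin)
    kin_wing = derive_kinematics(wing_avg, frame_l, morph.planform, fluid,
                                 period=cycles.period)
    kin_elytron = derive_kinematics(
        elytron_avg, proto.frames["left_elytron"], morph.planform, fluid,
        period=cycles.period)
    # clap separation from the symmetrized cycle: left tips from the average,
    # right tips from its mirror mapped back into the right-side frame
    tips_l = tip_positions(wing_avg, frame_l, morph.planform.length)
    tips_r = tip_positions(wing_avg.mirrored(), proto.frames["right_wing"],
                           morph.planform.length)
    clap = clap_distance(tips_l, tips_r, phase=kin_wing.phase,
                         window=proto.labels["clap_windows"][0])
    body = body_speed(proto.body_t, proto.body_track, loess_frac=cfg.loess_frac,
                      chi_deg=proto.body_chi_deg)
    aoa = kin_wing.aoa_deg[~kin_wing.gaps]
    st.report["kinematics"] = {
        "frequency_khz": cycles.frequency,
        "period_ms": cycles.period,
        "n_cycles": cycles.n_cycles,
        "stroke_plane_beta_deg": stroke_plane.beta,
        "re_mean": kin_wing.re_mean,
        "re_peak": float(np.nanmax(kin_wing.re_instantaneous)),
        "aoa_downstroke_max_deg": float(aoa.max()),
        "aoa_upstroke_max_deg": float(aoa.min()),
        "clap_distance_um": clap,
        "body_speed_horizontal_m_s": float(body.horizontal_speed.mean() * 1e-3),
        "body_speed_vertical_m_s": float(body.vertical_speed.mean() * 1e-3),
    }
    st._cycles = cycles
    st._body_series = body
    return {"wing": kin_wing, "elytron": kin_elytron}


def _run_forces(st: _State, proto, kin, morph):
    cfg = st.config
    fluid = FluidProperties()
    if cfg.force_source == "file":
        grid = kin["wing"].phase
        fs_wing = seriesio.load_force_series(cfg.forces_path, phase_grid=grid)
        series = {"left_wing": fs_wing,
                  "right_wing": _mirror_force(fs_wing, "right_wing")}
    else:
        fs_wing = quasisteady_surrogate(kin["wing"], morph.planform, fluid,
                                        part_id="left_wing")
        series = {"left_wing": fs_wing,
                  "right_wing": _mirror_force(fs_wing, "right_wing")}
    # elytra via the same surrogate on their (slow) kinematics
    fs_el = quasisteady_surrogate(kin["elytron"], morph.planform, fluid,
                                  part_id="left_elytron")
    fs_el = fs_el.scaled(0.3)  # elytra are stubby: crude area correction
    series["left_elytron"] = fs_el
    series["right_elytron"] = _mirror_force(fs_el, "right_elytron")
    return series


def _mirror_force(fs, part_id):
    """Mirror a left-side force series through the sagittal (x–z) plane."""
    F = fs.force.copy()
    T = fs.torque.copy()
    F[:, 1] *= -1.0
    T[:, 0] *= -1.0
    T[:, 2] *= -1.0
    ref = fs.torque_ref.copy()
    ref[1] *= -1.0
    return type(fs)(part_id, fs.phase, F, T, ref)


def _run_vertical(st: _State, forces, kin):
    dec = {p: decompose(forces[p], kin["wing"].tip_velocity, gaps=kin["wing"].gaps)
           for p in ("left_wing", "right_wing")}
    breakdown = vertical_breakdown(forces, dec, st._body.mass, st._body.g)
    st.report["vertical_force"] = {
        "per_part_weight_ug": dict(breakdown.weight_equivalent_ug),
        "total_mean_weight_ug": breakdown.weight_equivalent_ug["total"],
        "drag_share_pct": breakdown.drag_share_pct,
        "lift_share_pct": breakdown.lift_share_pct,
        "vertical_acceleration_m_s2": breakdown.vertical_acceleration,
    }
    st._decomps = dec
    return breakdown


def _run_power(st: _State, kin, morph, forces):
    body = st._body
    kw = kin["wing"]
    ke = kin["elytron"]
    omega_lab_w = np.einsum("nij,nj->ni", kw.rotations, kw.omega_body)
    omega_lab_e = np.einsum("nij,nj->ni", ke.rotations, ke.omega_body)
    p_aero = 2.0 * aerodynamic_power(forces["left_wing"].torque, omega_lab_w)
    p_aero += 2.0 * aerodynamic_power(forces["left_elytron"].torque, omega_lab_e)
    I_wing = st._wing_props.inertia
    el_props = membrane_mass_properties(morph.elytron)
    p_inert = 2.0 * inertial_power(I_wing, kw.omega_body, kw.alpha_body)
    p_inert += 2.0 * inertial_power(el_props.inertia, ke.omega_body, ke.alpha_body)
    budget = power_scenarios(p_aero, p_inert, body.mass)
    report = {
        "bristled": _power_doc(budget),
    }
    for h, sp in zip(st.report["morphology"]["membrane_thicknesses_um"], st._sub_props):
        p_inert_m = 2.0 * inertial_power(sp.inertia, kw.omega_body, kw.alpha_body)
        p_inert_m += 2.0 * inertial_power(el_props.inertia, ke.omega_body, ke.alpha_body)
        report[f"membranous_{h}um"] = _power_doc(power_scenarios(p_aero, p_inert_m, body.mass))
    st.report["power"] = report
    st._el_props = el_props
    return budget


def _power_doc(b):
    return {
        "mean_aero_w_kg": b.mean_aero,
        "mean_inertial_w_kg": b.mean_inertial,
        "mean_total_w_kg": b.mean_total,
        "peak_total_w_kg": b.peak_total,
        "mean_no_storage_w_kg": b.mean_no_storage,
        "mean_perfect_storage_w_kg": b.mean_perfect_storage,
        "always_positive": b.always_positive,
    }


def _run_pitch(st: _State, proto, kin, forces, morph):
    cfg = st.config
    body = st._body
    kw, ke = kin["wing"], kin["elytron"]
    tau_aero = np.zeros(kw.phase.size)
    for part in ("left_wing", "right_wing"):
        tau_aero += shift_torque_reference(forces[part], body.com).torque[:, 1]
    if not cfg.drop_elytra_aero:
        for part in ("left_elytron", "right_elytron"):
            tau_aero += shift_torque_reference(forces[part], body.com).torque[:, 1]
    dt = kw.period / kw.phase.size
    tau_recoil = 2.0 * recoil_pitch_torque(st._el_props.inertia, ke.rotations,
                                           ke.omega_body, dt)
    result = pitch_simulation(tau_aero, tau_recoil, body, kw.period,
                              cycles=cfg.pitch_cycles)
    st.report["pitch_dynamics"] = {
        "amplitude_with_elytra_deg": result.amplitude_with,
        "amplitude_without_elytra_deg": result.amplitude_without,
        "amplitude_ratio_pct": result.amplitude_ratio_pct,
        "peak_pitch_torque_nN_um": float(np.abs(tau_aero).max()),
    }
    return result
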