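"""Delimited-text readers and writers for the pipeline's data dialects.

All files are plain CSV with `# key: value` metadata lines before the
header.  Units are explicit: angle series are ms/degrees, tracks ms/µm,
force files must declare their force, torque and time units and the
torque reference point.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.interpolate import CubicSpline

from .aeroforces import ForceSeries
from .kinematics import EulerAngleSeries
from .morphology import MembranePatch, SetaRod, WingMorphology

__all__ = [
    "write_angles", "read_angles",
    "write_track", "read_track",
    "write_force_series", "load_force_series",
    "write_morphology", "read_morphology",
    "write_json", "read_json",
]

_FORCE_UNITS = {"nN": 1.0, "N": 1e9, "uN": 1e3}
_TORQUE_UNITS = {"nN*um": 1.0, "N*m": 1e15, "nN*m": 1e6}
_TIME_UNITS = {"ms": 1.0, "s": 1e3, "phase": None}


def _read_meta(path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                k, v = line[1:].split(":", 1)
                meta[k.strip()] = v.strip()
    return meta


def _write_csv(path, meta: dict, frame: pd.DataFrame) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")
        frame.to_csv(fh, index=False)


def write_angles(series: EulerAngleSeries, path) -> None:
    frame = pd.DataFrame({"t": series.t, "theta": series.theta,
                          "phi": series.phi, "psi": series.psi})
    _write_csv(path, {"part_id": series.part_id, "units": "ms,deg"}, frame)


def read_angles(path) -> EulerAngleSeries:
    meta = _read_meta(path)
    df = pd.read_csv(path, comment="#")
    missing = {"t", "theta", "phi", "psi"} - set(df.columns)
    if missing:
        raise ValueError(f"angle file {path} missing columns {sorted(missing)}")
    return EulerAngleSeries(meta.get("part_id", "unknown"), df["t"].to_numpy(),
                            df["theta"].to_numpy(), df["phi"].to_numpy(),
                            df["psi"].to_numpy())


def write_track(t, track, path, chi_deg=None) -> None:
    track = np.asarray(track)
    data = {"t": t, "x": track[:, 0], "y": track[:, 1], "z": track[:, 2]}
    if chi_deg is not None:
        data["chi"] = chi_deg
    _write_csv(path, {"units": "ms,um,deg"}, pd.DataFrame(data))


def read_track(path):
    df = pd.read_csv(path, comment="#")
    missing = {"t", "x", "y", "z"} - set(df.columns)
    if missing:
        raise ValueError(f"track file {path} missing columns {sorted(missing)}")
    chi = df["chi"].to_numpy() if "chi" in df.columns else None
    return df["t"].to_numpy(), df[["x", "y", "z"]].to_numpy(), chi


def write_force_series(fs: ForceSeries, path) -> None:
    ref = " ".join(f"{x:.6g}" for x in fs.torque_ref)
    meta = {"part_id": fs.part_id, "time_unit": "phase", "force_unit": "nN",
            "torque_unit": "nN*um", "torque_ref_um": ref}
    frame = pd.DataFrame({
        "t": fs.phase,
        "Fx": fs.force[:, 0], "Fy": fs.force[:, 1], "Fz": fs.force[:, 2],
        "Tx": fs.torque[:, 0], "Ty": fs.torque[:, 1], "Tz": fs.torque[:, 2]})
    _write_csv(path, meta, frame)


def load_force_series(path, phase_grid: np.ndarray | None = None) -> ForceSeries:
    """Load a validated force/torque file, optionally splined onto a phase grid.

    The file must declare ``force_unit``, ``torque_unit``, ``time_unit``
    (``phase`` for a dimensionless grid) and ``torque_ref_um``; columns are
    ``t,Fx,Fy,Fz,Tx,Ty,Tz``.
    """
    meta = _read_meta(path)
    for key in ("force_unit", "torque_unit", "time_unit", "torque_ref_um"):
        if key not in meta:
            raise ValueError(f"force file {path} does not declare '{key}'")
    if meta["force_unit"] not in _FORCE_UNITS:
        raise ValueError(f"unsupported force unit {meta['force_unit']!r}")
    if meta["torque_unit"] not in _TORQUE_UNITS:
        raise ValueError(f"unsupported torque unit {meta['torque_unit']!r}")
    if meta["time_unit"] not in _TIME_UNITS:
        raise ValueError(f"unsupported time unit {meta['time_unit']!r}")
    df = pd.read_csv(path, comment="#")
    missing = {"t", "Fx", "Fy", "Fz", "Tx", "Ty", "Tz"} - set(df.columns)
    if missing:
        raise ValueError(f"force file {path} missing columns {sorted(missing)}")
    t = df["t"].to_numpy(dtype=float)
    if not np.all(np.diff(t) > 0):
        raise ValueError(f"force file {path} has non-monotone time")
    fscale = _FORCE_UNITS[meta["force_unit"]]
    tscale = _TORQUE_UNITS[meta["torque_unit"]]
    F = df[["Fx", "Fy", "Fz"]].to_numpy(dtype=float) * fscale
    T = df[["Tx", "Ty", "Tz"]].to_numpy(dtype=float) * tscale
    if _TIME_UNITS[meta["time_unit"]] is not None:
        t = t * _TIME_UNITS[meta["time_unit"]]
    ref = np.array([float(x) for x in meta["torque_ref_um"].split()])
    if phase_grid is not None and (t.size != phase_grid.size or not np.allclose(t, phase_grid)):
        F = CubicSpline(t, F, axis=0)(phase_grid)
        T = CubicSpline(t, T, axis=0)(phase_grid)
        t = np.asarray(phase_grid, dtype=float)
    return ForceSeries(meta.get("part_id", "unknown"), t, F, T, ref)


def write_morphology(wing: WingMorphology, path, extras: dict | None = None) -> None:
    doc = {
        "petiole": _patch_doc(wing.petiole),
        "blade": _patch_doc(wing.blade),
        "setae": [{"base": s.base.tolist(), "tip": s.tip.tolist(),
                   "linear_density": s.linear_density} for s in wing.setae],
    }
    if extras:
        doc.update(extras)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(doc, sort_keys=False))


def _patch_doc(patch: MembranePatch) -> dict:
    return {"boundary": np.asarray(patch.boundary).tolist(),
            "thickness": patch.thickness,
            "cuticle_density": patch.cuticle_density}


def _patch_from_doc(doc: dict) -> MembranePatch:
    return MembranePatch(np.asarray(doc["boundary"], dtype=float),
                         float(doc["thickness"]), float(doc["cuticle_density"]))


def read_morphology(path) -> WingMorphology:
    doc = yaml.safe_load(Path(path).read_text())
    setae = [SetaRod.from_tip(np.asarray(s["base"], dtype=float),
                              np.asarray(s["tip"], dtype=float),
                              float(s.get("linear_density", 9.6e-7)))
             for s in doc.get("setae", [])]
    return WingMorphology(_patch_from_doc(doc["petiole"]),
                          _patch_from_doc(doc["blade"]), setae)


def write_json(obj, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
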