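"""Configuration files, delimited-text measurement formats and exporters.

Conventions: CSV is comma-separated UTF-8 with a header row and '.' decimal
separator; temperatures are reported in degC to 3 decimals; all lengths are
SI meters unless the config file declares ``units: {length: mm}``.  Every
report starts with a ``# config_fingerprint:`` comment so outputs are
traceable to the exact configuration.  Files are written atomically
(temp-then-rename), so no partial output survives a failed stage.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from contextlib import contextmanager
from pathlib import Path

import numpy as np
import yaml

from .electrochem import CalibrationPoint, TraceRecord
from .geometry import DomainGrid, GridResolution
from .materials import BloodProps
from .piezo import ChargeForceSeries
from .pipeline import SimulationConfig
from .solver import TemperatureField

__all__ = [
    "atomic_write",
    "config_fingerprint",
    "load_config",
    "save_config",
    "read_charge_force",
    "write_charge_force",
    "read_trace",
    "write_trace",
    "read_calibration_points",
    "write_calibration_points",
    "write_field_csv",
    "write_field_vtk",
    "write_oracle_profile",
]


@contextmanager
def atomic_write(path, mode: str = "w"):
    """Write to a temp file in the target directory, rename on success."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, mode) as fh:
            yield fh
        os.replace(tmp, path)
    except BaseException:
        try:
            os.unlink(tmp)
        except OSError:
            pass
        raise


def config_fingerprint(config: dict) -> str:
    """Short sha256 of the canonical JSON form of a configuration dict."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# --- configuration files ------------------------------------------------------

_TOP_KEYS = {
    "units",
    "footprint",
    "contact_patch",
    "foot_length",
    "rubber_thickness",
    "resolution",
    "blood",
    "boundary",
    "sensors",
    "lesion",
    "sweep",
    "solver",
}
_BOUNDARY_KEYS = {"floor_h", "floor_T_env", "top", "top_T", "sock_resistance"}
_LESION_KEYS = {"height", "volume", "center", "types", "depths"}
_SENSOR_KEYS = {"detection_threshold", "positions"}
_SOLVER_KEYS = {"tol", "method"}
_RES_KEYS = {"dx", "dy", "dz_fine", "fine_band", "dz_coarse", "min_cells_per_layer"}


def _check_keys(section: dict, allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown config keys in {where}: {sorted(unknown)}")


def config_from_dict(raw: dict) -> SimulationConfig:
    """Build a SimulationConfig from a (parsed) config-file dict.

    Unknown keys are rejected.  ``units.length`` may be "m" (default) or
    "mm"; with mm every length-like entry is converted (volumes by mm^3).
    """
    _check_keys(raw, _TOP_KEYS, "top level")
    units = raw.get("units", {})
    _check_keys(units, {"length"}, "units")
    unit = units.get("length", "m")
    if unit not in ("m", "mm"):
        raise ValueError("units.length must be 'm' or 'mm'")
    s = 1e-3 if unit == "mm" else 1.0

    kw: dict = {}
    if "footprint" in raw:
        kw["footprint"] = tuple(np.asarray(raw["footprint"], dtype=float) * s)
    if "contact_patch" in raw:
        cp = raw["contact_patch"]
        kw["contact_patch"] = (
            None if cp is None else tuple(np.asarray(cp, dtype=float) * s)
        )
    if "foot_length" in raw:
        kw["foot_length"] = float(raw["foot_length"]) * s
    if "rubber_thickness" in raw:
        kw["rubber_thickness"] = float(raw["rubber_thickness"]) * s
    if "resolution" in raw:
        sec = dict(raw["resolution"])
        _check_keys(sec, _RES_KEYS, "resolution")
        for key in _RES_KEYS - {"min_cells_per_layer"}:
            if key in sec:
                sec[key] = float(sec[key]) * s
        kw["resolution"] = GridResolution(**sec)
    if "blood" in raw:
        _check_keys(raw["blood"], {"density", "specific_heat"}, "blood")
        kw["blood"] = BloodProps(**raw["blood"])
    if "boundary" in raw:
        sec = dict(raw["boundary"])
        _check_keys(sec, _BOUNDARY_KEYS, "boundary")
        kw.update(sec)
    if "sensors" in raw:
        sec = dict(raw["sensors"])
        _check_keys(sec, _SENSOR_KEYS, "sensors")
        if "detection_threshold" in sec:
            kw["detection_threshold"] = float(sec["detection_threshold"])
        if sec.get("positions") is not None:
            kw["sensor_positions"] = np.asarray(sec["positions"], dtype=float) * s
    if "lesion" in raw:
        sec = dict(raw["lesion"])
        _check_keys(sec, _LESION_KEYS, "lesion")
        if "height" in sec:
            kw["lesion_height"] = float(sec["height"]) * s
        if "volume" in sec:
            kw["lesion_volume"] = float(sec["volume"]) * s**3
        if sec.get("center") is not None:
            kw["lesion_center"] = tuple(np.asarray(sec["center"], dtype=float) * s)
        if "types" in sec:
            kw["lesion_types"] = tuple(sec["types"])
        if "depths" in sec:
            kw["depths"] = tuple(np.asarray(sec["depths"], dtype=float) * s)
    if "sweep" in raw:
        _check_keys(raw["sweep"], {"sock_settings"}, "sweep")
        kw["sock_settings"] = tuple(bool(b) for b in raw["sweep"]["sock_settings"])
    if "solver" in raw:
        sec = dict(raw["solver"])
        _check_keys(sec, _SOLVER_KEYS, "solver")
        if "tol" in sec:
            kw["tol"] = float(sec["tol"])
        if "method" in sec:
            kw["method"] = str(sec["method"])
    return SimulationConfig(**kw)


def load_config(path) -> SimulationConfig:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_to_schema(config: SimulationConfig) -> dict:
    """Sectioned config-file dict (SI units) that round-trips load_config."""
    from dataclasses import asdict

    out: dict = {
        "units": {"length": "m"},
        "footprint": [float(v) for v in config.footprint],
        "contact_patch": (
            None
            if config.contact_patch is None
            else [float(v) for v in config.contact_patch]
        ),
        "foot_length": config.foot_length,
        "rubber_thickness": config.rubber_thickness,
        "resolution": asdict(config.resolution),
        "blood": asdict(config.blood),
        "boundary": {
            "floor_h": config.floor_h,
            "floor_T_env": config.floor_T_env,
            "top": config.top,
            "top_T": config.top_T,
            "sock_resistance": config.sock_resistance,
        },
        "sensors": {
            "detection_threshold": config.detection_threshold,
            "positions": (
                None
                if config.sensor_positions is None
                else np.asarray(config.sensor_positions).tolist()
            ),
        },
        "lesion": {
            "height": config.lesion_height,
            "volume": config.lesion_volume,
            "center": (
                None if config.lesion_center is None else list(config.lesion_center)
            ),
            "types": list(config.lesion_types),
            "depths": [float(d) for d in config.depths],
        },
        "sweep": {"sock_settings": [bool(b) for b in config.sock_settings]},
        "solver": {"tol": config.tol, "method": config.method},
    }
    if out["boundary"]["top_T"] is None:
        del out["boundary"]["top_T"]
    return out


def save_config(config: SimulationConfig, path) -> None:
    with atomic_write(path) as fh:
        yaml.safe_dump(config_to_schema(config), fh, sort_keys=False)


# --- measurement series files -------------------------------------------------


def write_charge_force(series: ChargeForceSeries, path) -> None:
    with atomic_write(path) as fh:
        fh.write(f"# actuation_frequency_hz: {series.actuation_frequency}\n")
        fh.write(f"# electrode_diameter_m: {series.electrode_diameter}\n")
        fh.write("force_N,charge_pC\n")
        for f, q in zip(series.force, series.charge):
            fh.write(f"{float(f)!r},{float(q)!r}\n")


def read_charge_force(path) -> ChargeForceSeries:
    meta, data = _read_annotated_csv(path, 2)
    return ChargeForceSeries(
        force=data[:, 0],
        charge=data[:, 1],
        actuation_frequency=float(meta.get("actuation_frequency_hz", 5.0)),
        electrode_diameter=float(meta.get("electrode_diameter_m", 3.8e-3)),
    )


def write_trace(trace: TraceRecord, path) -> None:
    with atomic_write(path) as fh:
        fh.write(f"# kind: {trace.kind}\n")
        for key, val in trace.params.items():
            fh.write(f"# {key}: {val}\n")
        header = "potential_V" if trace.kind == "CV" else "time_s"
        fh.write(f"{header},current_A\n")
        for a, b in trace.samples:
            fh.write(f"{float(a)!r},{float(b)!r}\n")


def read_trace(path) -> TraceRecord:
    meta, data = _read_annotated_csv(path, 2)
    kind = meta.pop("kind", "CV")
    params = {}
    for key, val in meta.items():
        try:
            params[key] = float(val)
        except ValueError:
            params[key] = val
    return TraceRecord(kind=kind, samples=data, params=params)


def write_calibration_points(points: list[CalibrationPoint], path) -> None:
    with atomic_write(path) as fh:
        fh.write("concentration_mol_per_l,response\n")
        for p in points:
            fh.write(f"{float(p.concentration)!r},{float(p.response)!r}\n")


def read_calibration_points(path) -> list[CalibrationPoint]:
    _, data = _read_annotated_csv(path, 2)
    return [CalibrationPoint(float(c), float(r)) for c, r in data]


def _read_annotated_csv(path, ncols: int):
    """Parse '# key: value' metadata lines plus a header row and data."""
    meta: dict[str, str] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("# ")
                if ":" in body:
                    key, val = body.split(":", 1)
                    meta[key.strip()] = val.strip()
                continue
            parts = line.split(",")
            try:
                rows.append([float(p) for p in parts[:ncols]])
            except ValueError:
                continue  # header row
    if not rows:
        raise ValueError(f"no data rows found in {path}")
    return meta, np.array(rows, dtype=float)


# --- field exports ------------------------------------------------------------


def write_field_csv(field: TemperatureField, grid: DomainGrid, path) -> None:
    """Cell-center coordinates (m) and temperature (degC, 3 decimals)."""
    xc, yc, zc = grid.x_centers, grid.y_centers, grid.z_centers
    with atomic_write(path) as fh:
        fh.write("x_m,y_m,z_m,T_C\n")
        act = grid.active
        for i in range(len(xc)):
            for j in range(len(yc)):
                for k in np.flatnonzero(act[i, j, :]):
                    fh.write(
                        f"{xc[i]:.6f},{yc[j]:.6f},{zc[k]:.6f},"
                        f"{field.T[i, j, k]:.3f}\n"
                    )


def write_field_vtk(field: TemperatureField, grid: DomainGrid, path) -> None:
    """Legacy ASCII VTK rectilinear grid with cell-centered temperature.

    Void cells are written as -999 so visualization tools can threshold
    them out.
    """
    nx, ny, nz = grid.shape
    t = np.where(grid.active, field.T, -999.0)
    with atomic_write(path) as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("thermosole steady temperature field\n")
        fh.write("ASCII\nDATASET RECTILINEAR_GRID\n")
        fh.write(f"DIMENSIONS {nx + 1} {ny + 1} {nz + 1}\n")
        for name, edges in (
            ("X_COORDINATES", grid.x_edges),
            ("Y_COORDINATES", grid.y_edges),
            ("Z_COORDINATES", grid.z_edges),
        ):
            fh.write(f"{name} {len(edges)} double\n")
            fh.write(" ".join(f"{v:.8g}" for v in edges) + "\n")
        fh.write(f"CELL_DATA {nx * ny * nz}\n")
        fh.write("SCALARS temperature_C double 1\nLOOKUP_TABLE default\n")
        # VTK cell ordering: x fastest, then y, then z
        flat = np.transpose(t, (2, 1, 0)).ravel()
        for chunk in range(0, flat.size, 9):
            fh.write(" ".join(f"{v:.5f}" for v in flat[chunk : chunk + 9]) + "\n")


def write_oracle_profile(oracle, path, n: int = 400) -> None:
    """Two-column CSV (z m, T degC) of a 1-D analytic profile."""
    z = np.linspace(oracle.z_interfaces[0], oracle.z_interfaces[-1], n)
    t = oracle.temperature(z)
    with atomic_write(path) as fh:
        fh.write("z_m,T_C\n")
        for zi, ti in zip(z, t):
            fh.write(f"{zi:.6e},{ti:.6f}\n")
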