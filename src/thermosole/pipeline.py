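"""Full numerical experiment: healthy baselines plus lesion depth sweep.

Reproduces the study design of the insole simulation: for each sock setting
(worn / not worn) a healthy baseline is solved, then an inflammation and an
ischemia lesion are embedded at six published center depths (1.6, 2.6, 3.4,
5.9, 8.4, 9.7 mm below the plantar skin) laterally centered under sensor
S4, and per-sensor temperature changes against the matching baseline are
classified against the 0.1 degC detection threshold.  All cases share one
grid (lesions are embedded by cell reassignment, never remeshing), so the
reported ΔT values are free of discretization-difference noise and the
whole pipeline is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .geometry import (
    DomainGrid,
    GridResolution,
    LesionSpec,
    SensorLayout,
    build_domain,
    default_sensor_layout,
    embed_lesion,
)
from .materials import (
    DEFAULT_BLOOD,
    BloodProps,
    foot_tissue_layers,
    insole_shoe_layers,
)
from .sensors import SensorReading, sensor_deltas, read_sensors
from .solver import BoundarySpec, TemperatureField, solve_steady

__all__ = [
    "SimulationConfig",
    "DetectionReport",
    "CaseRecord",
    "default_config",
    "build_base_grid",
    "healthy_baseline",
    "run_depth_sweep",
    "summarize_field",
    "DEFAULT_DEPTHS",
]

#: Published lesion center depths below the plantar skin surface, m.
DEFAULT_DEPTHS: tuple[float, ...] = (1.6e-3, 2.6e-3, 3.4e-3, 5.9e-3, 8.4e-3, 9.7e-3)


@dataclass
class SimulationConfig:
    """Everything needed to rebuild the domain and run the sweep.

    Lengths are SI (m) here; the YAML loader in :mod:`thermosole.io` accepts
    a per-file ``units.length: mm`` declaration and converts on read.
    """

    footprint: tuple[float, float] = (0.26, 0.09)
    #: Foot-insole contact rectangle (x0, x1, y0, y1); None = full contact.
    #: Default is a 0.215 m x 0.052 m (~112 cm^2) patch, a typical adult
    #: static plantar contact area, centered on the insole.
    contact_patch: tuple[float, float, float, float] | None = (
        0.0225,
        0.2375,
        0.019,
        0.071,
    )
    foot_length: float = 0.26
    rubber_thickness: float = 15.0e-3
    resolution: GridResolution = field(
        default_factory=lambda: GridResolution(dx=4.0e-3, dy=4.0e-3)
    )
    blood: BloodProps = field(default_factory=BloodProps)
    floor_h: float = 5.0
    floor_T_env: float = 20.0
    top: str = "adiabatic"
    top_T: float | None = None
    sock_resistance: float = 0.02
    detection_threshold: float = 0.1
    sensor_positions: np.ndarray | None = None
    lesion_height: float = 2.5e-3
    lesion_volume: float = 1.5e-6
    lesion_center: tuple[float, float] | None = None  # default: under S4
    lesion_types: tuple[str, ...] = ("inflammation", "ischemia")
    depths: tuple[float, ...] = DEFAULT_DEPTHS
    sock_settings: tuple[bool, ...] = (True, False)
    tol: float = 1e-10
    method: str = "auto"

    def sensor_layout(self) -> SensorLayout:
        return default_sensor_layout(
            self.foot_length,
            detection_threshold=self.detection_threshold,
            positions=self.sensor_positions,
        )

    def boundary(self, sock: bool) -> BoundarySpec:
        return BoundarySpec(
            floor_h=self.floor_h,
            floor_T_env=self.floor_T_env,
            top=self.top,
            top_T=self.top_T,
            sock_resistance=self.sock_resistance if sock else 0.0,
        )

    def lesion_xy(self) -> tuple[float, float]:
        if self.lesion_center is not None:
            return self.lesion_center
        layout = self.sensor_layout()
        i = layout.labels.index("S4")
        return tuple(layout.positions[i])

    def lesion(self, lesion_type: str, depth: float) -> LesionSpec:
        return LesionSpec(
            lesion_type=lesion_type,
            center_depth=depth,
            lateral_center=self.lesion_xy(),
            height=self.lesion_height,
            volume=self.lesion_volume,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["resolution"] = asdict(self.resolution)
        d["blood"] = asdict(self.blood)
        if self.sensor_positions is not None:
            d["sensor_positions"] = np.asarray(self.sensor_positions).tolist()
        return d


def default_config(**overrides) -> SimulationConfig:
    """The packaged study-reproduction configuration."""
    return SimulationConfig(**overrides)


def build_base_grid(config: SimulationConfig) -> DomainGrid:
    return build_domain(
        tissue_layers=foot_tissue_layers(),
        insole_layers=insole_shoe_layers(config.rubber_thickness),
        footprint=config.footprint,
        resolution=config.resolution,
        contact_patch=config.contact_patch,
    )


def healthy_baseline(
    config: SimulationConfig,
    sock: bool = True,
    grid: DomainGrid | None = None,
) -> tuple[DomainGrid, TemperatureField]:
    """Solve the lesion-free reference case."""
    grid = grid if grid is not None else build_base_grid(config)
    fld = solve_steady(
        grid, config.blood, config.boundary(sock), tol=config.tol, method=config.method
    )
    return grid, fld


@dataclass
class CaseRecord:
    case_id: str
    lesion_type: str  # "healthy" for baselines
    depth: float | None  # m; None for baselines
    sock: bool
    readings: list[SensorReading]
    field: TemperatureField | None = None  # kept only with keep_fields
    grid: DomainGrid | None = None  # the (possibly lesioned) grid solved on

    def deltas(self) -> np.ndarray:
        return np.array([r.delta for r in self.readings])

    def detectable(self) -> np.ndarray:
        return np.array([r.detectable for r in self.readings])


@dataclass
class DetectionReport:
    """Sweep output: 2 baselines + len(types) x len(depths) x len(socks) cases."""

    fingerprint: str
    config: SimulationConfig
    records: list[CaseRecord]
    labels: tuple[str, ...]
    grid: DomainGrid | None = None

    def lesion_records(self) -> list[CaseRecord]:
        return [r for r in self.records if r.lesion_type != "healthy"]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            row = {
                "case_id": rec.case_id,
                "lesion_type": rec.lesion_type,
                "depth_mm": np.nan if rec.depth is None else rec.depth * 1e3,
                "sock": rec.sock,
            }
            for lab, r in zip(self.labels, rec.readings):
                row[f"dT_{lab}"] = r.delta
            for lab, r in zip(self.labels, rec.readings):
                row[f"det_{lab}"] = r.detectable
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> pd.DataFrame:
        """Deepest detectable lesion depth per (lesion type, sock setting)."""
        rows = []
        for lesion_type in self.config.lesion_types:
            for sock in self.config.sock_settings:
                depths = [
                    rec.depth
                    for rec in self.lesion_records()
                    if rec.lesion_type == lesion_type
                    and rec.sock == sock
                    and rec.detectable().any()
                ]
                rows.append(
                    {
                        "lesion_type": lesion_type,
                        "sock": sock,
                        "deepest_detectable_mm": (
                            max(depths) * 1e3 if depths else np.nan
                        ),
                    }
                )
        return pd.DataFrame(rows)

    def write_csv(self, path) -> None:
        from .io import atomic_write

        df = self.to_dataframe().copy()
        for c in df.columns:
            if c.startswith("dT_") or c == "depth_mm":
                df[c] = df[c].map(lambda v: "" if pd.isna(v) else f"{v:.3f}")
        with atomic_write(path) as fh:
            fh.write(f"# config_fingerprint: {self.fingerprint}\n")
            df.to_csv(fh, index=False)


def run_depth_sweep(
    config: SimulationConfig | None = None, keep_fields: bool = False
) -> DetectionReport:
    """Run the full healthy + lesion-depth numerical experiment.

    Deterministic given the configuration; any solver failure aborts with
    the failing case id.
    """
    from .io import config_fingerprint

    config = config or default_config()
    grid = build_base_grid(config)
    layout = config.sensor_layout()
    records: list[CaseRecord] = []

    baselines: dict[bool, TemperatureField] = {}
    for sock in config.sock_settings:
        case_id = f"healthy_sock={int(sock)}"
        try:
            _, fld = healthy_baseline(config, sock=sock, grid=grid)
        except Exception as exc:
            raise RuntimeError(f"solver failed for case {case_id}: {exc}") from exc
        baselines[sock] = fld
        t = read_sensors(fld, grid, layout)
        records.append(
            CaseRecord(
                case_id=case_id,
                lesion_type="healthy",
                depth=None,
                sock=sock,
                readings=[
                    SensorReading(lab, float(ti), float(ti), 0.0, False)
                    for lab, ti in zip(layout.labels, t)
                ],
                field=fld if keep_fields else None,
                grid=grid if keep_fields else None,
            )
        )

    for lesion_type in config.lesion_types:
        for depth in config.depths:
            lesion_grid = embed_lesion(grid, config.lesion(lesion_type, depth))
            for sock in config.sock_settings:
                case_id = f"{lesion_type}_d={depth * 1e3:g}mm_sock={int(sock)}"
                try:
                    fld = solve_steady(
                        lesion_grid,
                        config.blood,
                        config.boundary(sock),
                        tol=config.tol,
                        method=config.method,
                    )
                except Exception as exc:
                    raise RuntimeError(
                        f"solver failed for case {case_id}: {exc}"
                    ) from exc
                records.append(
                    CaseRecord(
                        case_id=case_id,
                        lesion_type=lesion_type,
                        depth=depth,
                        sock=sock,
                        readings=sensor_deltas(fld, baselines[sock], grid, layout),
                        field=fld if keep_fields else None,
                        grid=lesion_grid if keep_fields else None,
                    )
                )

    return DetectionReport(
        fingerprint=config_fingerprint(config.to_dict()),
        config=config,
        records=records,
        labels=layout.labels,
        grid=grid,
    )


def summarize_field(field: TemperatureField, grid: DomainGrid) -> pd.DataFrame:
    """Volume-weighted temperature statistics per material region.

    One row per material present in the grid plus an ``insole_top_surface``
    row with the area-weighted statistics over the top face of the insole
    (covered and exposed columns alike).
    """
    vol = grid.cell_volumes()
    rows = []
    for name in dict.fromkeys(grid.layer_names()):
        mask = grid.layer_mask(name)
        if not mask.any():
            continue
        t = field.T[mask]
        w = vol[mask]
        rows.append(
            {
                "region": name,
                "mean_T": float(np.average(t, weights=w)),
                "min_T": float(t.min()),
                "max_T": float(t.max()),
            }
        )
    if grid.has_insole:
        iz = grid.insole_top_cell_index
        t = field.T[:, :, iz]
        w = grid.dx[:, None] * grid.dy[None, :]
        ok = ~np.isnan(t)
        if ok.any():
            rows.append(
                {
                    "region": "insole_top_surface",
                    "mean_T": float(np.average(t[ok], weights=w[ok])),
                    "min_T": float(t[ok].min()),
                    "max_T": float(t[ok].max()),
                }
            )
    return pd.DataFrame(rows)
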