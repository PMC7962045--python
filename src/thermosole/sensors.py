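"""Virtual temperature-sensor readout and detectability classification.

Sensors sit on the insole top surface; the via under each sensing pad is
filled with conductive paste, thermally shorting the pad to the contact
surface, so readings are taken in the first insole cell below the
skin-insole interface at the cell center nearest each sensor (x, y).
A lesion is counted detectable at a sensor when the absolute temperature
change against the matched healthy baseline reaches the readout
resolution (0.1 degC for the MAX30205 used on the insole), boundary
inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import DomainGrid, SensorLayout
from .solver import TemperatureField

__all__ = ["SensorReading", "read_sensors", "sensor_deltas", "classify_detectable"]


@dataclass(frozen=True)
class SensorReading:
    """Per-sensor lesion-vs-healthy comparison."""

    label: str
    T_lesion: float
    T_healthy: float
    delta: float  # T_lesion - T_healthy, degC
    detectable: bool


def _sensor_cell_indices(grid: DomainGrid, layout: SensorLayout):
    """Nearest insole-top cell for each sensor; ties break to lower index."""
    length, width = grid.footprint
    pos = layout.positions
    if (
        (pos[:, 0] < 0).any()
        or (pos[:, 0] > length).any()
        or (pos[:, 1] < 0).any()
        or (pos[:, 1] > width).any()
    ):
        raise ValueError("sensor position outside the grid footprint")
    # np.argmin returns the first (lowest-index) minimizer, the tie rule.
    ix = np.array([np.argmin(np.abs(grid.x_centers - x)) for x in pos[:, 0]])
    iy = np.array([np.argmin(np.abs(grid.y_centers - y)) for y in pos[:, 1]])
    iz = grid.insole_top_cell_index
    return ix, iy, iz


def read_sensors(
    field: TemperatureField, grid: DomainGrid, layout: SensorLayout
) -> np.ndarray:
    """Temperatures (degC) at the 8 sensor positions, deterministic."""
    ix, iy, iz = _sensor_cell_indices(grid, layout)
    t = field.T[ix, iy, iz]
    if np.isnan(t).any():
        raise ValueError("a sensor maps to a void cell (outside solved domain)")
    return t


def classify_detectable(delta: float, threshold: float) -> bool:
    """|delta| >= threshold, boundary inclusive (limit of detection rule)."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    return bool(abs(delta) >= threshold)


def sensor_deltas(
    lesion_field: TemperatureField,
    healthy_field: TemperatureField,
    grid: DomainGrid,
    layout: SensorLayout,
) -> list[SensorReading]:
    """Per-sensor ΔT = T_lesion - T_healthy with detectability flags.

    Both fields must come from the same grid and boundary settings (only the
    lesion differs), so discretization error cancels in the difference.
    """
    t_les = read_sensors(lesion_field, grid, layout)
    t_hea = read_sensors(healthy_field, grid, layout)
    out = []
    for label, tl, th in zip(layout.labels, t_les, t_hea):
        d = float(tl - th)
        out.append(
            SensorReading(
                label=label,
                T_lesion=float(tl),
                T_healthy=float(th),
                delta=d,
                detectable=classify_detectable(d, layout.detection_threshold),
            )
        )
    return out
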