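"""Piezoelectric pressure-sensor characterization.

Quasi-static charge-force calibration of an AlN-on-kapton pressure sensor:
the longitudinal piezoelectric coefficient d33 (pC/N) is the slope of an
ordinary least-squares fit of generated charge on applied normal force.
Also provides the transverse figure of merit d31^2/(eps0 * eps_r) and the
force-to-contact-pressure conversion used to map the 0-4 N load range onto
plantar pressures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ChargeForceSeries",
    "FitResult",
    "fit_charge_force",
    "figure_of_merit",
    "force_to_pressure",
    "EPS0",
]

#: Vacuum permittivity, F/m.
EPS0 = 8.8541878128e-12


@dataclass(frozen=True)
class ChargeForceSeries:
    """Paired (force N, charge pC) samples from the quasi-static setup."""

    force: np.ndarray
    charge: np.ndarray
    actuation_frequency: float = 5.0  # Hz
    electrode_diameter: float = 3.8e-3  # m
    force_range: tuple[float, float] = (0.0, 4.0)

    def __post_init__(self) -> None:
        f = np.asarray(self.force, dtype=float)
        q = np.asarray(self.charge, dtype=float)
        if f.shape != q.shape or f.ndim != 1:
            raise ValueError("force and charge must be 1-D arrays of equal length")
        object.__setattr__(self, "force", f)
        object.__setattr__(self, "charge", q)
        lo, hi = self.force_range
        if (f < lo - 1e-9).any() or (f > hi + 1e-9).any():
            raise ValueError(f"forces outside the declared range {self.force_range}")
        if np.unique(f).size < 2:
            raise ValueError("need at least two distinct force values")


@dataclass(frozen=True)
class FitResult:
    """Ordinary least-squares line fit with uncertainty."""

    slope: float
    intercept: float
    slope_stderr: float
    r_squared: float
    n: int
    slope_units: str = ""

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.r_squared <= 1 + 1e-12):
            raise ValueError("r_squared outside [0, 1]")
        if self.slope_stderr < 0:
            raise ValueError("slope_stderr must be >= 0")


def ols_fit(x: np.ndarray, y: np.ndarray, slope_units: str = "") -> FitResult:
    """OLS of y on x (intercept estimated, not forced through zero)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or np.unique(x).size < 2:
        raise ValueError("need at least two distinct x values for a line fit")
    res = stats.linregress(x, y)
    # guard against round-off pushing r^2 infinitesimally past 1
    r2 = min(float(res.rvalue**2), 1.0)
    stderr = float(res.stderr) if np.isfinite(res.stderr) else 0.0
    return FitResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_stderr=stderr,
        r_squared=r2,
        n=int(x.size),
        slope_units=slope_units,
    )


def fit_charge_force(series: ChargeForceSeries) -> FitResult:
    """d33 estimate: slope (pC/N) of charge on force with stderr and r^2."""
    return ols_fit(series.force, series.charge, slope_units="pC/N")


def figure_of_merit(d31: float, eps_r: float) -> float:
    """Piezoelectric figure of merit d31^2 / (eps0 * eps_r), Pa.

    d31 is the transverse piezoelectric constant in C/m^2 and eps_r the
    film's relative permittivity.  Quadratic in d31, so the sign of d31 is
    irrelevant.
    """
    if eps_r <= 0:
        raise ValueError("eps_r must be > 0")
    return d31**2 / (EPS0 * eps_r)


def force_to_pressure(force: float, contact_diameter: float) -> float:
    """Normal force (N) over a circular contact of given diameter (m) -> Pa."""
    if contact_diameter <= 0:
        raise ValueError("contact diameter must be > 0")
    return force / (math.pi * (contact_diameter / 2.0) ** 2)
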