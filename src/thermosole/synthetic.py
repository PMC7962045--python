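"""Synthetic measurement generators for calibration QA.

The bench raw data behind the published sensor characterizations are not
deposited, so every calibration routine in this package is exercised on
synthetic inputs whose statistical structure mirrors the reported behavior:

* charge-force series: linear with slope d33 plus Gaussian noise over the
  0-4 N quasi-static load range;
* CV traces: triangular potential sweep (start +0.5 V, high +1.0 V, low
  -1.2 V, 4 scans at 0.1 V/s) carrying a Gaussian-shaped anodic oxidation
  peak at +0.72 V on a sloping linear baseline, with peak height following
  a saturating response -- linear up to 6 mM, a plateau from 6 to 10 mM,
  then linear again from 10 to 24 mM (the published linear-range
  structure);
* blank replicates for the limit-of-detection estimate;
* multiplicatively perturbed tissue-property sets for solver robustness
  sweeps.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .electrochem import TraceRecord
from .materials import MaterialProps
from .piezo import ChargeForceSeries

__all__ = [
    "GeneratorSpec",
    "gen_charge_force",
    "saturating_response",
    "gen_cv_trace",
    "gen_blank_traces",
    "perturb_tissue_params",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """Knobs of the synthetic generators (units noted per field).

    The voltammetric gain is the peak current per unit concentration in the
    linear regime (A per mol/L); breakpoints of the saturating response are
    fixed at 6 and 10 mM to mirror the published calibration structure.
    """

    seed: int = 0
    # charge-force channel
    d33: float = 4.5  # pC/N
    charge_noise: float = 0.5  # pC
    charge_offset: float = 0.0  # pC
    force_range: tuple[float, float] = (0.0, 4.0)  # N
    # voltammetry channel
    cv_gain: float = 2.5e-3  # A per mol/L  (2.5 uA/mM)
    peak_center: float = 0.72  # V
    peak_width: float = 0.03  # V (Gaussian sigma)
    current_noise: float = 0.02e-6  # A
    baseline_slope: float = 5e-6  # A/V
    baseline_offset: float = 1e-6  # A
    sample_dv: float = 2e-3  # V between CV samples
    cv_start: float = 0.5
    cv_high: float = 1.0
    cv_low: float = -1.2
    cv_scans: int = 4
    cv_scan_rate: float = 0.1  # V/s
    # tissue perturbation channel
    perturbation_fraction: float = 0.1

    def __post_init__(self) -> None:
        for name in ("charge_noise", "current_noise", "peak_width"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.perturbation_fraction <= 0.5:
            raise ValueError("perturbation_fraction must be in [0, 0.5]")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, stream))


def gen_charge_force(spec: GeneratorSpec, n: int = 50) -> ChargeForceSeries:
    """Noisy linear charge-force series: Q = d33 * F + offset + N(0, sigma)."""
    if n < 2:
        raise ValueError("need n >= 2 samples")
    rng = spec.rng(stream=1)
    lo, hi = spec.force_range
    force = np.linspace(lo, hi, n)
    charge = spec.d33 * force + spec.charge_offset
    if spec.charge_noise > 0:
        charge = charge + rng.normal(0.0, spec.charge_noise, size=n)
    return ChargeForceSeries(force=force, charge=charge, force_range=spec.force_range)


def saturating_response(concentration_mol_l: float) -> float:
    """Normalized response shape: linear to 6 mM, flat 6-10 mM, linear 10-24 mM.

    Returns the effective concentration (mol/L) the peak height is
    proportional to; the generator multiplies it by ``cv_gain``.
    """
    c_mm = concentration_mol_l * 1e3
    if c_mm <= 6.0:
        eff = c_mm
    elif c_mm <= 10.0:
        eff = 6.0
    else:
        eff = 6.0 + (c_mm - 10.0)
    return eff * 1e-3


def _triangular_sweep(spec: GeneratorSpec) -> np.ndarray:
    """Potential samples of the CV protocol: start -> high -> low, repeated."""
    up0 = np.arange(spec.cv_start, spec.cv_high, spec.sample_dv)
    down = np.arange(spec.cv_high, spec.cv_low, -spec.sample_dv)
    up = np.arange(spec.cv_low, spec.cv_high, spec.sample_dv)
    segs = [up0]
    for s in range(spec.cv_scans):
        segs.append(down)
        if s < spec.cv_scans - 1:
            segs.append(up)
        else:
            # final scan ends with a full anodic sweep back to the high limit
            segs.append(np.append(up, spec.cv_high))
    return np.concatenate(segs)


def gen_cv_trace(
    concentration_mol_l: float, spec: GeneratorSpec, stream: int = 2
) -> TraceRecord:
    """Synthetic CV trace with a concentration-dependent anodic peak.

    current = linear baseline + gain * saturating_response(c) * Gaussian
    peak at ``peak_center`` (applied on anodic sweeps only) + noise.
    """
    if concentration_mol_l < 0:
        raise ValueError("concentration must be >= 0")
    rng = spec.rng(stream=stream)
    v = _triangular_sweep(spec)
    rising = np.append(np.diff(v) > 0, False)
    peak_height = spec.cv_gain * saturating_response(concentration_mol_l)
    current = spec.baseline_offset + spec.baseline_slope * v
    current = current + np.where(
        rising,
        peak_height * np.exp(-0.5 * ((v - spec.peak_center) / spec.peak_width) ** 2),
        0.0,
    )
    if spec.current_noise > 0:
        current = current + rng.normal(0.0, spec.current_noise, size=v.size)
    return TraceRecord(
        kind="CV",
        samples=np.column_stack([v, current]),
        params={
            "start_E": spec.cv_start,
            "high_E": spec.cv_high,
            "low_E": spec.cv_low,
            "scans": spec.cv_scans,
            "scan_rate": spec.cv_scan_rate,
            "concentration_mol_l": concentration_mol_l,
        },
    )


def gen_blank_traces(
    spec: GeneratorSpec, n_blanks: int = 10
) -> list[TraceRecord]:
    """Replicate blank (zero-concentration) traces for the LOD estimate."""
    if n_blanks < 2:
        raise ValueError("need at least 2 blank replicates")
    return [
        gen_cv_trace(0.0, spec, stream=100 + i) for i in range(n_blanks)
    ]


def perturb_tissue_params(
    base: dict[str, MaterialProps],
    fraction: float,
    seed: int,
) -> dict[str, MaterialProps]:
    """Multiplicatively perturb tissue properties for robustness sweeps.

    Each positive parameter is multiplied by an independent factor uniform
    in [1 - fraction, 1 + fraction]; exact zeros (e.g. epidermis perfusion)
    are preserved.  Blood temperature is left untouched: it is an anchor,
    not a tissue property.
    """
    if not 0 <= fraction <= 0.5:
        raise ValueError("fraction must be in [0, 0.5]")
    rng = np.random.default_rng(seed)
    out: dict[str, MaterialProps] = {}
    for name, mat in base.items():
        def jitter(value: float) -> float:
            if value == 0:
                return 0.0
            return value * rng.uniform(1 - fraction, 1 + fraction)

        out[name] = replace(
            mat,
            density=jitter(mat.density),
            thermal_conductivity=jitter(mat.thermal_conductivity),
            specific_heat=jitter(mat.specific_heat),
            metabolic_heat=jitter(mat.metabolic_heat),
            perfusion_rate=jitter(mat.perfusion_rate),
        )
    return out
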