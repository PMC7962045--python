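"""CV peak extraction, calibration, linear ranges, LOD."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thermosole import (
    CalibrationPoint,
    GeneratorSpec,
    TraceRecord,
    build_calibration,
    detect_linear_range,
    extract_peak_current,
    gen_cv_trace,
    limit_of_detection,
    sensitivity_per_area,
)
from thermosole.electrochem import mg_dl_to_mm, mm_to_mg_dl
from thermosole.synthetic import saturating_response


def synthetic_trace(peak_height, baseline=(0.0, 0.0), noise=0.0, seed=0,
                    width=0.03):
    """Single triangular CV sweep with a Gaussian anodic peak at +0.72 V."""
    # gain chosen so that saturating_response(1 mM) * gain = peak_height
    spec = GeneratorSpec(
        seed=seed, current_noise=noise, peak_width=width,
        baseline_offset=baseline[0], baseline_slope=baseline[1],
        cv_gain=peak_height / 1e-3,
    )
    return gen_cv_trace(1e-3, spec)


class TestPeakExtraction:
    def test_flat_zero_trace(self):
        v = np.concatenate([np.linspace(-1.2, 1.0, 221), np.linspace(1.0, -1.2, 221)])
        v = np.concatenate([v, np.linspace(-1.2, 1.0, 221)])
        trace = TraceRecord("CV", np.column_stack([v, np.zeros_like(v)]))
        peak = extract_peak_current(trace)
        assert peak.current == 0.0

    def test_gaussian_peak_height_recovered_within_2pct(self):
        """Known generator peak height recovered for a window >= 6 widths."""
        h = 5e-6
        trace = synthetic_trace(h, baseline=(1e-6, 4e-6))
        peak = extract_peak_current(trace, 0.72, window=0.2)
        assert peak.current == pytest.approx(h, rel=0.02)
        assert abs(peak.potential - 0.72) < 0.01
        assert not peak.edge_peak

    def test_linear_baseline_invariance(self):
        """Adding any global linear baseline leaves the extracted peak
        unchanged (exact for the linear-interpolation baseline)."""
        h = 5e-6
        t1 = synthetic_trace(h, baseline=(0.0, 0.0))
        t2_samples = t1.samples.copy()
        t2_samples[:, 1] += 3e-6 + 8e-6 * t2_samples[:, 0]
        t2 = TraceRecord("CV", t2_samples, params=dict(t1.params))
        p1 = extract_peak_current(t1)
        p2 = extract_peak_current(t2)
        assert p1.current == pytest.approx(p2.current, rel=1e-9)

    def test_peaks_increase_with_concentration(self):
        spec = GeneratorSpec(seed=3)
        p = [
            extract_peak_current(gen_cv_trace(c, spec, stream=i)).current
            for i, c in enumerate((1e-3, 2e-3, 4e-3))
        ]
        assert p[0] < p[1] < p[2]

    def test_window_outside_sweep_rejected(self):
        trace = synthetic_trace(1e-6)
        with pytest.raises(ValueError):
            extract_peak_current(trace, peak_potential=0.9, window=0.5)

    def test_ca_trace_rejected(self):
        t = np.linspace(0, 3, 31)
        trace = TraceRecord("CA", np.column_stack([t, np.ones_like(t)]))
        with pytest.raises(ValueError):
            extract_peak_current(trace)


class TestCalibration:
    def linear_points(self, gain=2.0, n=8, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        c = np.linspace(0, 6e-3, n)
        r = gain * c + rng.normal(0, noise, size=n)
        return [CalibrationPoint(ci, ri) for ci, ri in zip(c, r)]

    def test_perfectly_linear_points(self):
        fit = build_calibration(self.linear_points())
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.slope == pytest.approx(2.0, rel=1e-12)

    def test_plateau_degrades_wide_fit(self):
        """Linear to 6 mM then flat to 10 mM: fitting only 0-6 mM recovers
        the gain; fitting 0-10 mM lowers r^2."""
        c = np.array([0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10]) * 1e-3
        r = np.array([saturating_response(ci) for ci in c]) * 2.0
        pts = [CalibrationPoint(ci, ri) for ci, ri in zip(c, r)]
        fit_6 = build_calibration(pts, fit_range=(0, 6e-3))
        fit_10 = build_calibration(pts, fit_range=(0, 10e-3))
        assert fit_6.slope == pytest.approx(2.0, rel=1e-9)
        assert fit_6.r_squared == pytest.approx(1.0)
        assert fit_10.r_squared < fit_6.r_squared

    def test_all_zero_responses(self):
        pts = [CalibrationPoint(c, 0.0) for c in (0, 1e-3, 2e-3, 3e-3)]
        fit = build_calibration(pts)
        assert fit.slope == 0.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            build_calibration(self.linear_points(n=8), fit_range=(0, 0.5e-3))


class TestLinearRange:
    def structured_points(self, gain=2.0, noise=0.0, seed=0):
        """Mirrors the published structure: linear to 6 mM, plateau to
        10 mM, linear 10-24 mM."""
        rng = np.random.default_rng(seed)
        c_mm = np.array([0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20, 22, 24])
        c = c_mm * 1e-3
        r = np.array([saturating_response(ci) for ci in c]) * gain
        r = r + rng.normal(0, noise, size=len(c))
        return [CalibrationPoint(ci, ri) for ci, ri in zip(c, r)]

    def test_fully_linear_single_window(self):
        c = np.linspace(0, 24e-3, 13)
        pts = [CalibrationPoint(ci, 3.0 * ci) for ci in c]
        assert detect_linear_range(pts) == [(0.0, 24e-3)]

    def test_structured_response_two_windows(self):
        """First window ends at 6 mM; second spans 10-24 mM."""
        wins = detect_linear_range(self.structured_points())
        assert len(wins) == 2
        assert wins[0][1] == pytest.approx(6e-3)
        assert wins[1][0] == pytest.approx(10e-3)
        assert wins[1][1] == pytest.approx(24e-3)

    def test_pure_noise_yields_nothing(self):
        rng = np.random.default_rng(11)
        c = np.linspace(0, 24e-3, 18)
        pts = [CalibrationPoint(ci, ri) for ci, ri in zip(c, rng.normal(size=18))]
        assert detect_linear_range(pts, r2_min=0.99) == []

    def test_unsorted_points_rejected(self):
        pts = [CalibrationPoint(2e-3, 1.0), CalibrationPoint(1e-3, 0.5),
               CalibrationPoint(3e-3, 1.5), CalibrationPoint(4e-3, 2.0)]
        with pytest.raises(ValueError):
            detect_linear_range(pts)


class TestLod:
    def test_zero_blank_sd(self):
        assert limit_of_detection(0.0, 2.0) == 0.0

    def test_doubling_blank_sd_doubles_lod(self):
        assert limit_of_detection(0.2, 2.0) == pytest.approx(
            2 * limit_of_detection(0.1, 2.0)
        )

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(sd=st.floats(1e-9, 1.0), slope=st.floats(1e-6, 1e3),
           scale=st.floats(0.01, 100))
    def test_unit_rescaling_invariance(self, sd, slope, scale):
        """Rescaling the response units co-scales sigma and slope, leaving
        the LOD (a concentration) unchanged."""
        lod1 = limit_of_detection(sd, slope)
        lod2 = limit_of_detection(sd * scale, slope * scale)
        assert lod2 == pytest.approx(lod1, rel=1e-9)

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(ValueError):
            limit_of_detection(0.1, 0.0)


class TestUnitsAndSensitivity:
    def test_sensitivity_identity_area(self):
        assert sensitivity_per_area(21.0, 1.0) == 21.0

    def test_halving_area_doubles_sensitivity(self):
        assert sensitivity_per_area(21.0, 0.5) == 42.0

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            sensitivity_per_area(21.0, 0.0)

    def test_mm_mgdl_round_trip(self):
        """1 mM = 18.016 mg/dL; the 0-6 mM range maps to ~0-108 mg/dL and
        round-trips to 4 significant figures."""
        assert mm_to_mg_dl(6.0) == pytest.approx(108.1, abs=0.05)
        for c in (0.5, 1.0, 6.0, 24.0):
            assert mg_dl_to_mm(mm_to_mg_dl(c)) == pytest.approx(c, rel=1e-4)
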