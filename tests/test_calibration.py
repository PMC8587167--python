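"""Beer-Lambert calibration, peak picking and quantification."""

import numpy as np
import pytest

from setschenow.calibration import (
    ABSORBANCE_RESOLUTION,
    Spectrum,
    aggregate_replicates,
    fit_calibration,
    pick_peak,
    quantify,
)
from setschenow.exceptions import DegenerateFitError, InsufficientDataError

GRID = np.arange(200.0, 301.0)


def gaussian_band(center, height=1.0, width=12.0):
    return Spectrum(GRID, height * np.exp(-((GRID - center) ** 2) / (2 * width**2)))


class TestPickPeak:
    def test_gaussian_band_argmax(self):
        lam, a = pick_peak(gaussian_band(251.0), (200.0, 300.0))
        assert lam == 251.0
        assert a == pytest.approx(1.0)

    def test_flat_spectrum_ties_to_lower_bound(self):
        flat = Spectrum(GRID, np.full_like(GRID, 0.42))
        lam, a = pick_peak(flat, (240.0, 260.0))
        assert lam == 240.0 and a == 0.42

    def test_monotonic_spectrum_boundary_maximum(self):
        rising = Spectrum(GRID, np.linspace(0.0, 1.0, GRID.size))
        lam, _ = pick_peak(rising, (200.0, 300.0))
        assert lam == 300.0

    def test_empty_window_raises(self):
        with pytest.raises(ValueError):
            pick_peak(gaussian_band(251.0), (250.2, 250.8))

    def test_decreasing_grid_rejected(self):
        with pytest.raises(ValueError):
            Spectrum(GRID[::-1], np.zeros_like(GRID))


class TestFitCalibration:
    def test_exact_line_recovered(self):
        standards = [(m, 40.0 * m) for m in np.linspace(2e-3, 25e-3, 6)]
        curve = fit_calibration(standards)
        assert curve.slope == pytest.approx(40.0, rel=1e-10)
        assert curve.intercept == pytest.approx(0.0, abs=1e-12)
        assert curve.r_squared == pytest.approx(1.0)
        assert curve.lod == pytest.approx(0.0, abs=1e-12)

    def test_paper_standard_range_accepted(self):
        # hydroxybenzoic-like standards spanning 2.0e-3 .. 25.0e-3 molal
        ms = np.linspace(2.0e-3, 25.0e-3, 8)
        curve = fit_calibration([(m, 40.0 * m + 0.002) for m in ms])
        assert curve.range == (pytest.approx(2.0e-3), pytest.approx(25.0e-3))

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            fit_calibration([(0.001, 0.04), (0.002, 0.08)])

    def test_negative_slope_degenerate(self):
        with pytest.raises(DegenerateFitError):
            fit_calibration([(0.001, 0.9), (0.002, 0.5), (0.003, 0.1)])

    def test_through_origin_mode(self):
        standards = [(m, 40.0 * m + 0.01) for m in np.linspace(1e-3, 1e-2, 5)]
        free = fit_calibration(standards)
        origin = fit_calibration(standards, through_origin=True)
        assert free.intercept == pytest.approx(0.01, rel=1e-9)
        assert origin.intercept == 0.0
        assert origin.through_origin


class TestQuantify:
    @pytest.fixture()
    def curve(self):
        standards = [(m, 40.0 * m + 0.005) for m in np.linspace(2e-3, 25e-3, 6)]
        return fit_calibration(standards)

    def test_blank_reads_zero(self, curve):
        assert quantify(curve.intercept, curve, 100.0).value == pytest.approx(
            0.0, abs=1e-15
        )

    def test_hand_inversion_with_dilution(self, curve):
        a = curve.slope * 0.005 + curve.intercept
        q = quantify(a, curve, dilution_factor=100.0)
        assert q.value == pytest.approx(0.5, rel=1e-12)
        assert not q.extrapolated and not q.below_lod

    def test_below_blank_flag_not_exception(self, curve):
        q = quantify(0.0, curve, 10.0)
        assert q.value < 0 and q.below_blank and q.below_lod

    def test_below_lod_flag(self):
        rng = np.random.default_rng(0)
        ms = np.linspace(2e-3, 25e-3, 8)
        curve = fit_calibration(
            [(m, 40.0 * m + rng.normal(0, 0.01)) for m in ms]
        )
        assert curve.lod > 0
        q = quantify(curve.intercept + curve.slope * curve.lod / 2, curve)
        assert q.below_lod

    def test_roundtrip_identity_zero_noise(self, curve):
        # quantify after the forward Beer-Lambert map is the identity
        for c in np.linspace(1e-3, 3e-2, 7):
            a = curve.slope * c + curve.intercept
            assert quantify(a, curve).value == pytest.approx(c, rel=1e-10)

    def test_quantization_perturbs_by_at_most_half_step(self, curve):
        dilution = 100.0
        bound = dilution * (ABSORBANCE_RESOLUTION / 2) / curve.slope
        for a in np.linspace(0.05, 1.0, 23):
            aq = np.round(a / ABSORBANCE_RESOLUTION) * ABSORBANCE_RESOLUTION
            delta = abs(
                quantify(aq, curve, dilution).value
                - quantify(a, curve, dilution).value
            )
            assert delta <= bound + 1e-12


class TestAggregateReplicates:
    def test_single_replicate(self):
        assert aggregate_replicates([5.0]) == (5.0, 0.0, 1)

    def test_hand_sample_sd(self):
        mean, sd, n = aggregate_replicates([1.0, 2.0, 3.0])
        assert (mean, n) == (2.0, 3)
        assert sd == pytest.approx(1.0)

    def test_permutation_invariance(self):
        assert aggregate_replicates([3.0, 1.0, 2.0]) == aggregate_replicates(
            [1.0, 2.0, 3.0]
        )

    def test_empty_raises(self):
        with pytest.raises(InsufficientDataError):
            aggregate_replicates([])


def test_slope_estimator_unbiased_under_gaussian_noise(rng):
    """Mean of 1000 noisy slope estimates stays within 2 SE of truth."""
    ms = np.linspace(2e-3, 25e-3, 8)
    truth = 40.0
    slopes = []
    for _ in range(1000):
        noise = rng.normal(0.0, 0.005, size=ms.size)
        curve = fit_calibration(list(zip(ms, truth * ms + noise)))
        slopes.append(curve.slope)
    slopes = np.asarray(slopes)
    se_of_mean = slopes.std(ddof=1) / np.sqrt(slopes.size)
    assert abs(slopes.mean() - truth) < 2 * se_of_mean
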