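"""Activity coefficients of the neutral species and Setschenow fits."""

import numpy as np
import pytest

from setschenow.activity import (
    ActivityPoint,
    SetschenowFit,
    effective_k,
    fit_setschenow,
    fit_setschenow_solubility,
    log_gamma,
    predict_log_gamma,
)
from setschenow.exceptions import DegenerateFitError, InsufficientDataError

M_GRID = np.array([0.16, 0.5, 1.0, 2.0, 3.0])


def fit_obj(k0, kinf, model="extended"):
    return SetschenowFit(model, k0, kinf, np.zeros((2, 2)))


def curve(m, k0, kinf):
    return (kinf + (k0 - kinf) / (1.0 + m)) * m


class TestLogGamma:
    def test_pure_water_reference(self):
        assert log_gamma(0.01, 0.01) == 0.0

    def test_decade_ratio(self):
        assert log_gamma(0.02, 0.002) == pytest.approx(1.0)

    def test_salting_in_sign(self):
        assert log_gamma(0.002, 0.02) == pytest.approx(-1.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            log_gamma(0.0, 0.01)


class TestPredict:
    def test_zero_at_reference_state(self):
        assert predict_log_gamma(fit_obj(0.5, 0.1), 0.0) == 0.0
        assert predict_log_gamma(fit_obj(0.2, 0.2, "constant"), 0.0) == 0.0

    def test_degenerate_extended_reduces_to_constant(self):
        m = np.linspace(0.0, 4.0, 101)
        assert np.allclose(
            predict_log_gamma(fit_obj(0.2, 0.2), m), 0.2 * m, atol=1e-14
        )

    def test_hand_value(self):
        # (0.1 + 0.4/2) * 1 = 0.30
        assert predict_log_gamma(fit_obj(0.5, 0.1), 1.0) == pytest.approx(0.30)

    def test_printed_form_fails_reference_state(self):
        # the historical variant offsets the curve by k_inf at m=0
        assert predict_log_gamma(
            fit_obj(0.5, 0.1), 0.0, printed_form=True
        ) == pytest.approx(0.1)

    def test_effective_k_limits(self):
        f = fit_obj(0.5, 0.1)
        assert effective_k(f, 0.0) == pytest.approx(0.5)
        assert effective_k(f, 1e9) == pytest.approx(0.1, abs=1e-8)


class TestFit:
    def test_noiseless_linear_recovery_both_models(self):
        pts = [ActivityPoint(float(m), 0.2 * float(m)) for m in M_GRID]
        con = fit_setschenow(pts, model="constant")
        ext = fit_setschenow(pts, model="extended")
        assert con.k == pytest.approx(0.2, rel=1e-12)
        assert ext.k_0 == pytest.approx(0.2, rel=1e-9)
        assert ext.k_inf == pytest.approx(0.2, rel=1e-9)

    def test_noiseless_extended_recovery(self):
        pts = [ActivityPoint(float(m), curve(float(m), 0.5, 0.1)) for m in M_GRID]
        ext = fit_setschenow(pts, model="extended")
        assert ext.k_0 == pytest.approx(0.5, rel=1e-9)
        assert ext.k_inf == pytest.approx(0.1, rel=1e-9)

    def test_auto_prefers_constant_on_linear_data(self):
        pts = [ActivityPoint(float(m), 0.2 * float(m)) for m in M_GRID]
        assert fit_setschenow(pts, model="auto").model == "constant"

    def test_all_points_at_origin_degenerate(self):
        with pytest.raises(DegenerateFitError):
            fit_setschenow([ActivityPoint(0.0, 0.0)] * 4)

    def test_too_few_for_extended(self):
        pts = [ActivityPoint(0.5, 0.1), ActivityPoint(1.0, 0.2)]
        with pytest.raises(InsufficientDataError):
            fit_setschenow(pts, model="extended")

    def test_joint_solubility_fit_matches_gamma_fit(self):
        # when the water solubility is exact, both routes agree
        log_s0w = -2.0
        m = np.concatenate([[0.0], M_GRID])
        y = log_s0w - curve(m, 0.4, 0.15)
        joint = fit_setschenow_solubility(m, y, model="extended")
        pts = [
            ActivityPoint(float(mm), float(log_s0w - yy))
            for mm, yy in zip(m[1:], y[1:])
        ]
        direct = fit_setschenow(pts, model="extended")
        assert joint.k_0 == pytest.approx(direct.k_0, rel=1e-9)
        assert joint.k_inf == pytest.approx(direct.k_inf, rel=1e-9)
        assert joint.intercept_log_s0 == pytest.approx(log_s0w, rel=1e-9)


def test_local_slope_plateaus_at_high_molality():
    """d(log gamma)/dm changes by <5% between m=2.5 and m=3.5."""
    f = fit_obj(0.2, 0.1)

    def slope(m):
        return f.k_inf + (f.k_0 - f.k_inf) / (1.0 + m) ** 2

    change = abs(slope(3.5) - slope(2.5)) / slope(2.5)
    assert change < 0.05
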