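"""SIT ionization model, speciation and the coupled correction loop."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from setschenow.ionization import (
    SITParams,
    correct_total_solubility,
    debye_term,
    extrapolate_pK0,
    pK_at_I,
    solve_saturation,
)
from setschenow.units import AcidSpec, NACL, SolubilityPoint, WATER

SIT = SITParams(b_plus=0.12, b_minus=0.06, k=0.1)


class TestDebyeTerm:
    def test_zero_ionic_strength(self):
        assert debye_term(0.0) == 0.0

    def test_hand_value_at_unit_ionic_strength(self):
        assert debye_term(1.0) == pytest.approx(0.4565 / 2.11, rel=1e-12)

    def test_asymptote(self):
        assert debye_term(1e12) == pytest.approx(0.4565 / 1.11, rel=1e-5)

    def test_strictly_increasing(self):
        I = np.linspace(0.0, 5.0, 200)
        assert np.all(np.diff(debye_term(I)) > 0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            debye_term(-0.1)


class TestPKModel:
    def test_infinite_dilution_identity(self):
        assert pK_at_I(4.5, 0.0, SIT) == 4.5

    def test_cancellation_case(self):
        sit = SITParams(b_plus=0.1, b_minus=0.05, k=0.15)  # b+ + b- - k = 0
        for I in (0.16, 0.51, 2.0):
            assert pK_at_I(4.5, I, sit) == pytest.approx(
                4.5 - 2 * debye_term(I), rel=1e-12
            )

    def test_hand_chained_value(self):
        # pK0=4.50, I=0.51, b+=0.12, b-=0.06, k=0.1
        d = 0.4565 * np.sqrt(0.51) / (1 + 1.11 * np.sqrt(0.51))
        expected = 4.50 - 2 * d + 0.08 * 0.51
        assert pK_at_I(4.50, 0.51, SIT) == pytest.approx(expected, rel=1e-14)

    @given(
        pk0=st.floats(2.0, 7.0),
        I=st.floats(0.0, 4.0),
        k=st.floats(-0.3, 0.5),
    )
    @settings(derandomize=True, max_examples=200)
    def test_extrapolation_inverts_exactly(self, pk0, I, k):
        sit = SITParams(b_plus=0.12, b_minus=0.06, k=k)
        pk_i = pK_at_I(pk0, I, sit)
        assert extrapolate_pK0(pk_i, I, sit) == pytest.approx(pk0, abs=1e-12)

    def test_extrapolation_at_zero_is_identity(self):
        assert extrapolate_pK0(4.31, 0.0, SIT) == 4.31

    def test_decreasing_near_zero_when_debye_dominates(self):
        # b+ + b- - k < 2 dD/dI at I=0 (the Debye slope diverges there)
        I = np.array([1e-4, 1e-3, 1e-2])
        pk = pK_at_I(4.5, I, SIT)
        assert np.all(np.diff(pk) < 0)


class TestSolveSaturation:
    def test_no_dissociation_limit(self):
        spec = solve_saturation(0.01, 0.0)
        assert spec.s0 == 0.01 and spec.h == 0.0

    def test_frozen_quadratic_root(self):
        spec = solve_saturation(0.01, 1e-4)
        assert spec.h == pytest.approx(9.5125e-4, rel=1e-4)
        assert spec.s0 == pytest.approx(9.049e-3, rel=1e-3)

    def test_mass_balance_conservation(self):
        for S_T in np.logspace(-4, 0, 9):
            for K in np.logspace(-8, -2, 9):
                spec = solve_saturation(float(S_T), float(K))
                assert spec.s0 + spec.a_minus == pytest.approx(S_T, rel=1e-12)

    def test_neutral_fraction_monotone_in_K(self):
        fractions = [
            solve_saturation(0.01, K).s0 / 0.01
            for K in np.logspace(-3, -9, 13)
        ]
        assert all(b >= a for a, b in zip(fractions, fractions[1:]))
        assert fractions[-1] == pytest.approx(1.0, rel=1e-3)

    def test_user_supplied_hydrogen(self):
        spec = solve_saturation(0.01, 1e-4, h=2e-3)
        assert spec.h == 2e-3
        assert spec.s0 == pytest.approx(0.01 * 2e-3 / (2e-3 + 1e-4))

    def test_autoprotolysis_warning(self):
        with pytest.warns(UserWarning):
            solve_saturation(1e-4, 1e-11)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            solve_saturation(0.0, 1e-4)
        with pytest.raises(ValueError):
            solve_saturation(0.01, -1e-4)


class TestCorrectionLoop:
    def test_non_ionizing_passthrough(self):
        acid = AcidSpec("x", 180.0, 287.0)  # no measured pK
        pts = [
            SolubilityPoint(WATER, 0.0, 0.01),
            SolubilityPoint(NACL, 0.5, 0.008),
            SolubilityPoint(NACL, 1.0, 0.006),
            SolubilityPoint(NACL, 2.0, 0.004),
            SolubilityPoint(NACL, 3.0, 0.003),
        ]
        res = correct_total_solubility(pts, acid, NACL)
        for (m, spec), p in zip(res.speciation, pts):
            assert spec.s0 == p.S_T
        assert res.converged and np.isnan(res.pK0)

    def test_ionizing_reduces_neutral_below_total(self):
        acid = AcidSpec("x", 180.0, 287.0, pK_measured=((0.16, 4.2), (0.51, 4.15)))
        pts = [
            SolubilityPoint(WATER, 0.0, 0.01),
            SolubilityPoint(NACL, 0.16, 0.009),
            SolubilityPoint(NACL, 0.5, 0.008),
            SolubilityPoint(NACL, 1.0, 0.006),
            SolubilityPoint(NACL, 2.0, 0.004),
            SolubilityPoint(NACL, 3.0, 0.003),
        ]
        res = correct_total_solubility(pts, acid, NACL)
        assert res.converged
        for m, spec in res.speciation:
            assert 0 < spec.s0 < spec.S_T
        assert res.pK0_spread is not None

    def test_requires_single_water_point(self):
        acid = AcidSpec("x", 180.0, 287.0)
        with pytest.raises(ValueError):
            correct_total_solubility(
                [SolubilityPoint(NACL, 0.5, 0.01)], acid, NACL
            )
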