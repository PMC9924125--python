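import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from primescatter.device import irf_nominal
from primescatter.reference import INSCATTER_FRACTIONS, calibrated_sigma_x, dmod_fit_points
from primescatter.scatter import (
    DmodCoefficients,
    ScatterParams,
    calibrate_sigma_x,
    d_in_scatter,
    d_modified,
    equivalent_square_side,
    fit_dmod_surface,
    inscatter_fraction,
    irf_in_scatter,
    sigma_x_foam,
)


class TestEquivalentSquare:
    @pytest.mark.parametrize(
        "d, s", [(0.158, 0.14002), (0.0, 0.0), (0.352, 0.31195)]
    )
    def test_area_equality(self, d, s):
        assert equivalent_square_side(d) == pytest.approx(s, abs=5e-6)
        assert equivalent_square_side(d) ** 2 == pytest.approx(math.pi * d**2 / 4, abs=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            equivalent_square_side(-0.1)


class TestSigmaXFoam:
    def test_angular_term_only(self):
        p = ScatterParams(0.03, 0.0, 0.096, 1.27)
        assert sigma_x_foam(p) == pytest.approx(0.03 * 1.27, abs=1e-12)

    def test_foam_term_only(self):
        t_rho, rho, t = 0.5, 0.096, 1.27
        p = ScatterParams(0.0, t_rho, rho, t)
        assert sigma_x_foam(p) == pytest.approx(t * math.sqrt(t_rho * rho * t / 6.0), abs=1e-12)

    def test_zero_scatter(self):
        assert sigma_x_foam(ScatterParams(0.0, 0.0, 0.096, 1.27)) == 0.0


class TestInscatterFraction:
    def test_zero_spread_is_exactly_zero(self):
        assert inscatter_fraction(0.2, 0.0) == 0.0

    def test_tabulated_midsize_block(self):
        # spread calibrated to the smallest block at the lowest energy
        sigma = calibrate_sigma_x(equivalent_square_side(0.158), 0.420)
        assert sigma == pytest.approx(0.0419, abs=1e-4)
        f = inscatter_fraction(equivalent_square_side(0.273), sigma)
        assert round(f, 3) == 0.257

    def test_large_spread_limit(self):
        assert inscatter_fraction(0.1, 50.0) > 0.999

    @pytest.mark.parametrize("s", [0.0, -0.1])
    def test_nonpositive_side_rejected(self, s):
        with pytest.raises(ValueError):
            inscatter_fraction(s, 0.05)

    @given(
        s=st.floats(0.05, 0.5),
        sig=st.lists(st.floats(1e-3, 0.5), min_size=2, max_size=2, unique=True),
    )
    def test_strictly_increasing_in_spread(self, s, sig):
        lo, hi = sorted(sig)
        assert inscatter_fraction(s, lo) < inscatter_fraction(s, hi)

    @given(
        sigma=st.floats(1e-3, 0.3),
        sides=st.lists(st.floats(0.05, 0.5), min_size=2, max_size=2, unique=True),
    )
    def test_strictly_decreasing_in_side(self, sigma, sides):
        lo, hi = sorted(sides)
        assert inscatter_fraction(hi, sigma) < inscatter_fraction(lo, sigma)


class TestCalibrateSigmaX:
    @pytest.mark.parametrize(
        "f_target, expected", [(0.420, 0.0419), (0.172, 0.0158)]
    )
    def test_study_calibrations(self, f_target, expected):
        s = equivalent_square_side(0.158)
        assert calibrate_sigma_x(s, f_target) == pytest.approx(expected, abs=1e-4)

    @given(s=st.floats(0.05, 0.5), f=st.floats(0.01, 0.95))
    def test_round_trip(self, s, f):
        assert inscatter_fraction(s, calibrate_sigma_x(s, f)) == pytest.approx(f, abs=1e-10)

    @pytest.mark.parametrize("f", [0.0, 1.0, -0.2, 1.5])
    def test_target_outside_unit_interval_rejected(self, f):
        with pytest.raises(ValueError):
            calibrate_sigma_x(0.14, f)


class TestSingleSpreadConsistency:
    """One lateral spread per energy, calibrated on the smallest block,
    reproduces the tabulated in-scatter fractions of the other two blocks."""

    @pytest.mark.parametrize("e_p0", sorted(INSCATTER_FRACTIONS))
    def test_predicts_other_diameters(self, e_p0):
        sigma = calibrated_sigma_x(e_p0)
        for d, f_tab in INSCATTER_FRACTIONS[e_p0].items():
            f = inscatter_fraction(equivalent_square_side(d), sigma)
            assert f == pytest.approx(f_tab, abs=1e-3)


class TestInScatterAdjustments:
    @pytest.mark.parametrize(
        "d, f, expected", [(0.158, 0.420, 0.188), (0.352, 0.125, 0.373)]
    )
    def test_effective_diameter(self, d, f, expected):
        assert round(d_in_scatter(d, f), 3) == expected

    def test_no_inscatter_identity(self):
        assert d_in_scatter(0.3, 0.0) == 0.3
        assert irf_in_scatter(0.8, 0.0) == 0.8

    @pytest.mark.parametrize(
        "irf, f, expected", [(0.937, 0.420, 0.911), (0.688, 0.202, 0.625)]
    )
    def test_adjusted_irf(self, irf, f, expected):
        assert round(irf_in_scatter(irf, f), 3) == expected

    @pytest.mark.parametrize("args", [(0.3, 1.0), (0.3, -0.1), (-0.1, 0.2)])
    def test_diameter_domain_errors(self, args):
        with pytest.raises(ValueError):
            d_in_scatter(*args)

    @pytest.mark.parametrize("args", [(0.0, 0.2), (1.2, 0.2), (0.8, 1.0)])
    def test_irf_domain_errors(self, args):
        with pytest.raises(ValueError):
            irf_in_scatter(*args)

    @given(
        d_frac=st.floats(0.05, 0.70),
        r=st.floats(0.3, 1.0),
        f=st.floats(0.0, 0.9),
    )
    def test_diameter_and_irf_adjustments_agree(self, d_frac, r, f):
        # both express removal of the same extra fractional fluence
        d = d_frac * r
        d_is = d_in_scatter(d, f)
        if d_is >= r:
            return
        lhs = irf_nominal(d_is, r)
        rhs = irf_in_scatter(irf_nominal(d, r), f)
        assert lhs == pytest.approx(rhs, abs=1e-12)


class TestModifiedDiameter:
    @pytest.mark.parametrize(
        "d, e, expected_surface, expected_table",
        [(0.158, 20.47, 0.1557, 0.155), (0.352, 13.12, 0.3535, 0.352)],
    )
    def test_surface_evaluation(self, d, e, expected_surface, expected_table):
        v = d_modified(d, e)
        assert v == pytest.approx(expected_surface, abs=2e-4)
        assert abs(v - expected_table) <= 0.002

    def test_identity_surface(self):
        c = DmodCoefficients(a0=0, a1=1, a2=0, a3=0, a4=0, a5=0)
        assert d_modified(0.273, 13.12, c) == 0.273

    def test_extrapolation_warns(self):
        with pytest.warns(UserWarning, match="extrapolat"):
            d_modified(0.273, 25.0)

    def test_nonpositive_diameter_rejected(self):
        with pytest.raises(ValueError):
            d_modified(0.0, 13.12)


class TestFitDmodSurface:
    def test_commissioning_triplets_fit_tightly(self):
        pts = dmod_fit_points()
        co = fit_dmod_surface(pts)
        for d, e, dm in pts:
            assert d_modified(d, e, co) == pytest.approx(dm, abs=0.002)

    def test_exact_quadratic_recovered(self):
        truth = DmodCoefficients(0.01, 1.05, -0.002, -0.1, -0.001, 5e-5)
        pts = [
            (d, e, d_modified(d, e, truth))
            for d in (0.15, 0.25, 0.35)
            for e in (7.0, 13.0, 20.0)
        ]
        fit = fit_dmod_surface(pts)
        np.testing.assert_allclose(fit.as_array(), truth.as_array(), atol=1e-10)

    def test_underdetermined_rejected(self):
        pts = [(0.1 * i, 7.0 + i, 0.1) for i in range(5)]
        with pytest.raises(ValueError, match="6 point"):
            fit_dmod_surface(pts)

    def test_rank_deficient_rejected(self):
        pts = [(0.2, 7.0 + i, 0.2) for i in range(7)]
        with pytest.raises(ValueError):
            fit_dmod_surface(pts)
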