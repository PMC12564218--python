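"""Visual-curve fitting and AoC integration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from numpy.polynomial import polynomial as npoly

from vicurve.curves import (
    AoCResult,
    VisualCurve,
    aoc_indices,
    aoc_table,
    aoc_wide,
    curve_area,
    dct_aoc,
    evaluate,
    fit_vic,
    select_degree,
)
from vicurve.errors import DomainError, InsufficientDataError, MissingDistanceError, PipelineError
from vicurve.profiles import DISTANCES_9, SUBSETS, VAProfile

from conftest import make_random_profiles


def profile_from(distances, va):
    return VAProfile("t", tuple(float(d) for d in distances), tuple(float(v) for v in va))


FLAT80 = profile_from(DISTANCES_9, [80.0] * 9)


# -------------------------------------------------------------- degree choice

class TestSelectDegree:
    def test_small_point_counts_force_exact_interpolation(self):
        pts4 = list(zip((25, 33, 66, 300), (70, 74, 80, 86)))
        pts5 = list(zip((25, 33, 50, 100, 300), (70, 74, 77, 82, 86)))
        assert select_degree(pts4) == 3
        assert select_degree(pts5) == 4

    def test_exact_cubic_data_selects_degree_three(self):
        # brute-force check: data on a cubic gives zero LOOCV error at
        # degree 3, so the parsimony rule must stop there
        x = np.asarray(DISTANCES_9)
        t = (x - 162.5) / 137.5
        y = 70 + 10 * t + 4 * t**2 - 3 * t**3
        assert y.min() > 0 and y.max() < 100
        assert select_degree(list(zip(x, y))) == 3

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            select_degree([(25, 70), (300, 86)])

    def test_loocv_agrees_with_brute_force_refit(self, rng):
        # oracle: refit with numpy.polyfit on raw coordinates per fold
        from vicurve.curves import _loocv_rmse

        x = np.asarray(DISTANCES_9)
        y = np.clip(75 + rng.normal(0, 5, 9), 0, 100)
        for deg in (3, 4):
            errs = []
            for i in range(9):
                xr, yr = np.delete(x, i), np.delete(y, i)
                c = np.polyfit(xr, yr, deg)
                errs.append(y[i] - np.polyval(c, x[i]))
            oracle = float(np.sqrt(np.mean(np.square(errs))))
            ours = _loocv_rmse(x, y, deg, 25.0, 300.0)
            assert ours == pytest.approx(oracle, rel=1e-6)


# -------------------------------------------------------------------- fitting

class TestFitVic:
    def test_flat_profile_gives_constant_curve(self):
        c = fit_vic(FLAT80, "S4")
        assert evaluate(c, 120.0) == pytest.approx(80.0, abs=1e-9)
        assert max(abs(r) for r in c.residuals) < 1e-9

    def test_four_point_fit_interpolates_exactly(self):
        p = profile_from((25, 33, 66, 300), (70, 74, 80, 86))
        c = fit_vic(p, "S4")
        assert c.degree == 3
        for d, v in p.points:
            assert evaluate(c, d) == pytest.approx(v, abs=1e-6)

    def test_least_squares_matches_normal_equations_oracle(self, rng):
        # independent oracle: solve the normal equations on the scaled
        # coordinate directly
        y = np.clip(75 + rng.normal(0, 4, 9), 0, 100)
        p = profile_from(DISTANCES_9, y)
        c = fit_vic(p, "S9", warn_range=False)
        x = np.asarray(DISTANCES_9)
        t = (2 * x - 325.0) / 275.0
        V = np.vander(t, c.degree + 1, increasing=True)
        beta = np.linalg.solve(V.T @ V, V.T @ y)
        pred_oracle = V @ beta
        for d, exp in zip(DISTANCES_9, pred_oracle):
            assert evaluate(c, float(d)) == pytest.approx(exp, abs=1e-7)

    def test_missing_subset_distance_named_in_error(self):
        p = profile_from((25, 33, 66, 200), (70, 74, 80, 86))
        with pytest.raises(MissingDistanceError, match="300"):
            fit_vic(p, "S4")

    def test_dct_subset_rejected(self):
        with pytest.raises(ValueError, match="piecewise"):
            fit_vic(FLAT80, "DCT")


class TestEvaluate:
    def test_linear_coefficients(self):
        c = VisualCurve(coefficients=(0.0, 1.0), domain=(0.0, 100.0), degree=1,
                        subset_id="S4", residuals=())
        assert evaluate(c, 50.0) == 50.0

    def test_extrapolation_refused_unless_allowed(self):
        c = fit_vic(FLAT80, "S4")
        with pytest.raises(DomainError):
            evaluate(c, 400.0)
        assert evaluate(c, 400.0, allow_extrapolation=True) == pytest.approx(80.0, abs=1e-6)

    def test_matches_naive_power_sum(self, rng):
        p = profile_from((25, 33, 66, 300), (70, 74, 80, 86))
        c = fit_vic(p, "S4")
        naive = sum(coef * 45.0**k for k, coef in enumerate(c.coefficients))
        assert evaluate(c, 45.0) == pytest.approx(naive, rel=1e-12)


# ---------------------------------------------------------------- aoc areas

class TestAoCIndices:
    def test_constant_curve_closed_form(self):
        c = fit_vic(FLAT80, "S4")
        r = aoc_indices(c)
        assert r.total == pytest.approx(80 * 275, rel=1e-12)
        assert r.near == pytest.approx(80 * 25, rel=1e-12)
        assert r.distance == pytest.approx(80 * 250, rel=1e-12)

    def test_identity_curve_closed_form(self):
        c = VisualCurve(coefficients=(0.0, 1.0), domain=(0.0, 2.0), degree=1,
                        subset_id="S4", residuals=())
        r = aoc_indices(c, split_cm=1.0)
        assert r.total == pytest.approx(2.0, rel=1e-12)
        assert r.near == pytest.approx(0.5, rel=1e-12)
        assert r.distance == pytest.approx(1.5, rel=1e-12)

    def test_split_outside_domain_rejected(self):
        c = fit_vic(FLAT80, "S4")
        with pytest.raises(DomainError):
            aoc_indices(c, split_cm=300.0)

    def test_matches_quadrature(self, random_profiles):
        from scipy.integrate import quad

        for p in random_profiles[:10]:
            c = fit_vic(p, "S9", warn_range=False)
            coef = np.asarray(c.coefficients)
            val, _ = quad(lambda x: npoly.polyval(x, coef), *c.domain, limit=200)
            assert aoc_indices(c).total == pytest.approx(val, rel=1e-9)


class TestDctAoc:
    def test_rectangle(self):
        p = profile_from((25, 300), (80, 80))
        assert dct_aoc(p).total == pytest.approx(22000.0, rel=1e-12)

    def test_two_point_hand_trapezoid(self):
        # straight line 60 -> 100 over [25, 300]; value at the 50 cm split
        # is 60 + 40 * 25/275, and areas follow the trapezoid formula
        p = profile_from((25, 300), (60, 100))
        v50 = 60 + 40 * 25 / 275
        near = (60 + v50) / 2 * 25
        r = dct_aoc(p)
        assert r.total == pytest.approx((60 + 100) / 2 * 275, rel=1e-12)
        assert r.near == pytest.approx(near, rel=1e-12)
        assert r.distance == pytest.approx(r.total - near, rel=1e-9)

    def test_linear_profile_equals_polynomial_fit(self):
        d = np.asarray(DISTANCES_9)
        va = 60 + 0.1 * d  # straight line in distance
        p = profile_from(d, va)
        poly_total = aoc_indices(fit_vic(p, "S9")).total
        assert dct_aoc(p).total == pytest.approx(poly_total, rel=1e-9)

    def test_matches_dense_trapezoid_oracle(self, random_profiles):
        for p in random_profiles[:10]:
            x, y = p.as_arrays()
            grid = np.linspace(x[0], x[-1], 30001)
            dense = np.trapezoid(np.interp(grid, x, y), grid)
            assert dct_aoc(p).total == pytest.approx(dense, rel=1e-6)


# ----------------------------------------------------------------- invariants

@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.lists(st.floats(20, 80), min_size=9, max_size=9), st.integers(0, 4))
def test_conservation_near_plus_distance_is_total(vas, subset_idx):
    subset = ("S4", "S5", "S6", "S9", "DCT")[subset_idx]
    p = profile_from(DISTANCES_9, vas)
    if subset == "DCT":
        r = dct_aoc(p)
    else:
        r = aoc_indices(fit_vic(p, subset, warn_range=False))
    assert r.near + r.distance == pytest.approx(r.total, rel=1e-9)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.lists(st.floats(25, 75), min_size=9, max_size=9), st.floats(-20, 20))
def test_shift_covariance(vas, c):
    """Adding c Letters everywhere adds c * (xmax - xmin) to the total."""
    p0 = profile_from(DISTANCES_9, vas)
    p1 = profile_from(DISTANCES_9, [v + c for v in vas])
    for subset in ("S4", "S9"):
        a0 = aoc_indices(fit_vic(p0, subset, warn_range=False)).total
        a1 = aoc_indices(fit_vic(p1, subset, warn_range=False)).total
        assert a1 - a0 == pytest.approx(c * 275.0, abs=1e-6 * max(1.0, abs(c) * 275))
    d0 = dct_aoc(p0).total
    d1 = dct_aoc(p1).total
    assert d1 - d0 == pytest.approx(c * 275.0, abs=1e-6 * max(1.0, abs(c) * 275))


def test_constant_profile_identical_across_subsets_and_methods():
    results = [aoc_indices(fit_vic(FLAT80, s)).total for s in ("S4", "S5", "S6", "S9")]
    results.append(dct_aoc(FLAT80).total)
    assert all(r == pytest.approx(22000.0, rel=1e-9) for r in results)


def test_range_exit_flag_on_oscillating_fit():
    # exact interpolation through alternating extremes must overshoot
    p = profile_from((25, 33, 66, 300), (5, 95, 5, 95))
    with pytest.warns(Warning):
        c = fit_vic(p, "S4")
    assert c.exits_va_range


# --------------------------------------------------------------- cohort table

class TestAoCTable:
    def test_counts_and_wide_shape(self, rng):
        profiles = make_random_profiles(rng, 10)
        table = aoc_table(profiles)
        assert len(table) == 50  # 10 patients x 5 subsets
        wide = aoc_wide(table)
        assert wide.shape == (10, 15)

    def test_constant_cohort_zero_variance(self):
        profiles = [VAProfile(f"p{i}", DISTANCES_9, (80.0,) * 9) for i in range(5)]
        wide = aoc_wide(aoc_table(profiles))
        totals = wide[[c for c in wide.columns if c.startswith("total_")]]
        assert np.allclose(totals, 22000.0)

    def test_fit_error_carries_patient_id(self):
        bad = VAProfile("BADPAT", (25.0, 33.0, 300.0), (70.0, 75.0, 85.0))
        with pytest.raises(PipelineError, match="BADPAT"):
            aoc_table([bad])


class TestDiopterAxis:
    def test_constant_profile_diopter_areas(self):
        # x = 100/d spans [1/3, 4] D; near vision (d <= 50) is x >= 2 D
        c = fit_vic(FLAT80, "S4", x_axis="diopters")
        r = aoc_indices(c)
        assert r.total == pytest.approx(80 * (4 - 1 / 3), rel=1e-9)
        assert r.near == pytest.approx(80 * 2.0, rel=1e-9)
        assert r.distance == pytest.approx(80 * (2 - 1 / 3), rel=1e-9)
        rd = dct_aoc(FLAT80, x_axis="diopters")
        assert rd.near + rd.distance == pytest.approx(rd.total, rel=1e-12)
        assert rd.near == pytest.approx(80 * 2.0, rel=1e-9)
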