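import numpy as np
import pytest

from fragdd.density_dependence import (
    BevertonHoltFit,
    bh_curvature,
    bh_slope,
    bh_value,
    fit_bh,
    inflection_density,
    strength_b,
    summarize,
    tipping_point,
)
from fragdd.exceptions import DataError, ValidationError
from fragdd.landscape import Landscape, PatchSizeClass, PatchSizeDistribution
from fragdd.site_dependence import FecundityDensityPoint, FecundityDensitySeries


def make_series(fit, densities, noise=None):
    f = bh_value(np.asarray(densities), fit)
    if noise is not None:
        f = np.clip(f + noise, 1e-6, 1.0)
    pts = tuple(
        FecundityDensityPoint(threshold_class_size=float(i + 1), density=float(d),
                              fecundity=float(v))
        for i, (d, v) in enumerate(zip(densities, f))
    )
    return FecundityDensitySeries(landscape_id="t", points=pts)


STANDARD = BevertonHoltFit(F_max=0.6, K=0.1, gamma=2.0)


class TestValueAndDerivatives:
    @pytest.mark.parametrize(
        "d,expected",
        [(0.0, 0.6), (0.1, 0.3), (0.2, 0.12)],
    )
    def test_values(self, d, expected):
        assert bh_value(d, STANDARD) == pytest.approx(expected, rel=1e-12)

    def test_slope_closed_forms(self):
        assert bh_slope(0.0, STANDARD) == 0.0
        assert bh_slope(0.1, STANDARD) == pytest.approx(-0.6 * 2 / (4 * 0.1), rel=1e-12)
        assert strength_b(0.1, STANDARD) == pytest.approx(3.0, rel=1e-12)

    @pytest.mark.parametrize("gamma", [0.5, 1.0, 1.5, 2.0, 3.0, 5.0])
    def test_derivatives_match_finite_differences(self, gamma):
        # 4th-order central stencils: the only way float64 finite differences
        # reach 1e-6 relative agreement for the second derivative
        fit = BevertonHoltFit(F_max=0.6, K=0.1, gamma=gamma)
        grid = np.geomspace(0.01 * fit.K, 10 * fit.K, 60)
        f = lambda x: bh_value(x, fit)
        h1 = grid * 1e-4
        fd1 = (
            f(grid - 2 * h1) - 8 * f(grid - h1) + 8 * f(grid + h1) - f(grid + 2 * h1)
        ) / (12 * h1)
        h2 = grid * 5e-3
        fd2 = (
            -f(grid - 2 * h2) + 16 * f(grid - h2) - 30 * f(grid)
            + 16 * f(grid + h2) - f(grid + 2 * h2)
        ) / (12 * h2**2)
        # F' vanishes like x^(gamma-1) at low density and F'' crosses zero
        # at the inflection; where the derivative is orders of magnitude
        # below the function scale a pure relative comparison only measures
        # float64 cancellation, so anchor the tolerance to the grid maximum
        np.testing.assert_allclose(
            bh_slope(grid, fit), fd1, rtol=1e-6, atol=1e-6 * np.abs(fd1).max()
        )
        curv = bh_curvature(grid, fit)
        np.testing.assert_allclose(
            curv, fd2, rtol=1e-6, atol=1e-6 * np.abs(fd2).max()
        )

    def test_negative_density_rejected(self):
        with pytest.raises(ValidationError):
            bh_value(-0.1, STANDARD)


class TestInflectionAndTipping:
    def test_no_inflection_for_gamma_at_most_one(self):
        assert inflection_density(BevertonHoltFit(0.6, 0.1, 1.0)) is None
        assert tipping_point(BevertonHoltFit(0.6, 0.1, 0.7)) is None

    def test_inflection_closed_form(self):
        d = inflection_density(STANDARD)
        assert d == pytest.approx(0.1 * (1 / 3) ** 0.5, rel=1e-12)

    def test_curvature_changes_sign_at_inflection(self):
        fit = BevertonHoltFit(0.6, 0.1, 3.0)
        d = inflection_density(fit)
        assert bh_curvature(d * 0.999, fit) < 0 < bh_curvature(d * 1.001, fit)

    def test_tipping_matches_dense_grid(self):
        fit = STANDARD
        d_infl = inflection_density(fit)
        grid = np.linspace(d_infl / 1e6, d_infl, 10**6, endpoint=False)
        ref = grid[np.argmax(np.abs(bh_curvature(grid, fit)))]
        tip = tipping_point(fit)
        assert tip == pytest.approx(ref, abs=1e-5)
        assert tip < d_infl

    def test_tipping_scales_with_k(self):
        t1 = tipping_point(BevertonHoltFit(0.6, 0.1, 3.0))
        t10 = tipping_point(BevertonHoltFit(0.6, 1.0, 3.0))
        assert t10 == pytest.approx(10 * t1, rel=1e-6)

    def test_b_prime_unimodal_below_inflection_for_convex_curves(self):
        for gamma in (2.5, 3.0, 5.0):
            fit = BevertonHoltFit(0.6, 0.1, gamma)
            grid = np.linspace(1e-5, 5 * fit.K, 4000)
            b = strength_b(grid, fit)
            k = int(np.argmax(b))
            assert 0 < k < grid.size - 1
            assert np.all(np.diff(b[: k + 1]) > 0)
            assert np.all(np.diff(b[k:]) < 0)


class TestFitBH:
    def test_noiseless_recovery(self):
        truth = BevertonHoltFit(0.6, 0.1, 3.0)
        series = make_series(truth, np.linspace(0.02, 0.4, 8))
        fit = fit_bh(series)
        assert fit.F_max == pytest.approx(0.6, rel=1e-4)
        assert fit.K == pytest.approx(0.1, rel=1e-4)
        assert fit.gamma == pytest.approx(3.0, rel=1e-4)
        assert not fit.poor_fit

    def test_pure_beverton_holt_special_case(self):
        truth = BevertonHoltFit(0.6, 0.1, 1.0)
        series = make_series(truth, np.linspace(0.02, 0.4, 8))
        fit = fit_bh(series)
        assert fit.gamma == pytest.approx(1.0, rel=1e-4)

    def test_two_points_rejected(self):
        truth = BevertonHoltFit(0.6, 0.1, 2.0)
        series = make_series(truth, [0.05, 0.2])
        with pytest.raises(DataError):
            fit_bh(series)

    def test_noisy_gamma_recovery_median_error(self):
        # 8 points, Gaussian noise sd 0.01 on F, 200 seeded replicates
        truth = BevertonHoltFit(0.6, 0.1, 3.0)
        densities = np.linspace(0.02, 0.4, 8)
        rng = np.random.default_rng(123)
        errors = []
        for _ in range(200):
            series = make_series(truth, densities, noise=rng.normal(0, 0.01, 8))
            fit = fit_bh(series)
            errors.append(abs(fit.gamma - truth.gamma) / truth.gamma)
        assert np.median(errors) < 0.15


def _toy_landscape(q=0.8):
    dist = PatchSizeDistribution(classes=(PatchSizeClass("c", 10.0, 2, 20.0),))
    return Landscape(id="T", forest=dist, core=None, quality=q)


class TestSummarize:
    def test_zero_density(self):
        s = summarize(_toy_landscape(), STANDARD, 0.0)
        assert s.realized_survival == pytest.approx(0.6)
        assert s.b_prime == 0.0

    def test_at_half_saturation_density(self):
        s = summarize(_toy_landscape(), STANDARD, 0.1)
        assert s.realized_survival == pytest.approx(0.3, rel=1e-12)
        assert s.b_prime == pytest.approx(0.6 * 2 / (4 * 0.1), rel=1e-12)
        assert s.tipping_density < s.inflection_density
        assert s.quality_class == "good"

    def test_negative_density_rejected(self):
        with pytest.raises(ValidationError):
            summarize(_toy_landscape(), STANDARD, -0.1)
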