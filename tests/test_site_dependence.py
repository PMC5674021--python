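"""Site-dependence occupancy model vs an independent per-patch oracle."""

import numpy as np
import pytest

from fragdd.exceptions import DataError, ValidationError
from fragdd.landscape import PatchSizeClass, PatchSizeDistribution
from fragdd.site_dependence import occupancy_curve, occupancy_point
from fragdd.vital_rates import (
    SaturatingSurvivalCurve,
    SigmoidDensityCurve,
    nest_survival,
    saturation_density,
)

from conftest import random_small_distribution


def brute_force_fill(dist, survival, sat_density, a):
    """Independent oracle: expand classes to individual patches and fill.

    Every class becomes n_patches equal patches; patches are occupied
    largest-first at saturation density, and F, D are accumulated patch by
    patch until all patches of mean size >= a are full.
    """
    patches = []
    for c in dist.classes:
        patches += [(c.mean_size_ha, c.total_area_ha / c.n_patches)] * int(c.n_patches)
    patches.sort(key=lambda p: -p[0])
    total_area = sum(area for _, area in patches)
    num_f = den = 0.0
    for size, area in patches:
        if size < a:
            break
        f = nest_survival(size, survival)
        d = saturation_density(size, sat_density)
        num_f += f * d * area
        den += d * area
    return num_f / den, den / total_area


class TestToyOracle:
    """Hand-computed two-class landscape values."""

    def test_threshold_at_large_class(self, toy_dist, default_survival, default_density):
        pt = occupancy_point(toy_dist, default_survival, default_density, 100.0)
        assert pt.fecundity == pytest.approx(0.5986, abs=5e-5)
        assert pt.density == pytest.approx(0.104, abs=5e-4)

    def test_threshold_at_small_class(self, toy_dist, default_survival, default_density):
        pt = occupancy_point(toy_dist, default_survival, default_density, 10.0)
        assert pt.fecundity == pytest.approx(0.3498, abs=5e-5)
        assert pt.density == pytest.approx(0.2428, abs=5e-5)

    def test_series_is_ascending_in_density(self, toy_dist, default_survival,
                                            default_density):
        series = occupancy_curve(toy_dist, default_survival, default_density)
        assert len(series.points) == 2
        assert series.densities == pytest.approx([0.104, 0.2428], abs=5e-4)


class TestContracts:
    def test_threshold_must_be_class_size(self, toy_dist, default_survival,
                                          default_density):
        with pytest.raises(ValidationError):
            occupancy_point(toy_dist, default_survival, default_density, 55.0)

    def test_single_class_degenerates_to_curve_values(self, default_survival,
                                                      default_density):
        dist = PatchSizeDistribution(
            classes=(PatchSizeClass("only", 30.0, 4, 120.0),)
        )
        pt = occupancy_point(dist, default_survival, default_density, 30.0)
        assert pt.fecundity == pytest.approx(nest_survival(30.0), rel=1e-12)
        assert pt.density == pytest.approx(saturation_density(30.0), rel=1e-12)

    def test_empty_middle_class_contributes_no_point(self, default_survival,
                                                     default_density):
        dist = PatchSizeDistribution(
            classes=(
                PatchSizeClass("a", 10.0, 5, 50.0),
                PatchSizeClass("b", 50.0, 0, 0.0),
                PatchSizeClass("c", 100.0, 2, 200.0),
            )
        )
        series = occupancy_curve(dist, default_survival, default_density)
        assert len(series.points) == 2

    def test_empty_distribution_rejected(self, default_survival, default_density):
        with pytest.raises(ValidationError):
            PatchSizeDistribution(classes=(PatchSizeClass("z", 5.0, 0, 0.0),))


class TestBruteForceEquivalence:
    def test_random_small_landscapes_match_per_patch_fill(
        self, default_survival, default_density
    ):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            dist = random_small_distribution(rng)
            series = occupancy_curve(dist, default_survival, default_density)
            for pt in series.points:
                f_ref, d_ref = brute_force_fill(
                    dist, default_survival, default_density, pt.threshold_class_size
                )
                assert pt.fecundity == pytest.approx(f_ref, rel=1e-10)
                assert pt.density == pytest.approx(d_ref, rel=1e-10)

    def test_monotonicity_of_every_series(self, default_survival, default_density):
        rng = np.random.default_rng(7)
        for _ in range(50):
            dist = random_small_distribution(rng)
            series = occupancy_curve(dist, default_survival, default_density)
            d = series.densities
            f = series.fecundities
            assert np.all(np.diff(d) > 0)  # density strictly increasing
            assert np.all(np.diff(f) <= 1e-12)  # fecundity non-increasing

    def test_bounds(self, default_survival, default_density):
        rng = np.random.default_rng(11)
        for _ in range(20):
            dist = random_small_distribution(rng)
            series = occupancy_curve(dist, default_survival, default_density)
            sizes = [c.mean_size_ha for c in dist.nonempty()]
            d_max = max(saturation_density(s, default_density) for s in sizes)
            f_vals = [nest_survival(s, default_survival) for s in sizes]
            assert series.densities[-1] <= d_max + 1e-12
            assert min(f_vals) - 1e-12 <= series.fecundities.min()
            assert series.fecundities.max() <= max(f_vals) + 1e-12


def test_interpolated_curve_densifies_monotonically(toy_dist, default_survival,
                                                    default_density):
    series = occupancy_curve(
        toy_dist, default_survival, default_density, interpolate=3
    )
    assert len(series.points) == 2 + 3
    assert np.all(np.diff(series.densities) > 0)
    assert np.all(np.diff(series.fecundities) <= 1e-12)
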