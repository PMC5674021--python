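import numpy as np
import pytest

from fragdd.density_dependence import fit_bh, strength_b
from fragdd.landscape import PatchSizeClass, PatchSizeDistribution
from fragdd.site_dependence import occupancy_curve
from fragdd.synthetic_data import LandscapeGeneratorConfig, generate_fragmentation_gradient
from fragdd.vital_rates import SaturatingSurvivalCurve, SigmoidDensityCurve


@pytest.fixture(scope="session")
def default_survival():
    return SaturatingSurvivalCurve()


@pytest.fixture(scope="session")
def default_density():
    return SigmoidDensityCurve()


@pytest.fixture(scope="session")
def toy_dist():
    """Two-class landscape used for the hand-computed occupancy oracle."""
    return PatchSizeDistribution(
        classes=(
            PatchSizeClass("small", 10.0, 5, 50.0),
            PatchSizeClass("large", 100.0, 2, 200.0),
        )
    )


@pytest.fixture(scope="session")
def gradient_landscapes():
    """The demo fragmentation gradient (11 landscapes, fixed seed)."""
    cfg = LandscapeGeneratorConfig(seed=0)
    return generate_fragmentation_gradient(cfg)


@pytest.fixture(scope="session")
def gradient_summaries(gradient_landscapes, default_survival, default_density):
    """(Q, gamma, K, b') per gradient landscape at density 0.25*K."""
    rows = {}
    for ls in gradient_landscapes:
        series = occupancy_curve(
            ls.forest, default_survival, default_density, landscape_id=ls.id
        )
        fit = fit_bh(series)
        rows[ls.id] = {
            "Q": ls.quality,
            "gamma": fit.gamma,
            "K": fit.K,
            "b_prime": strength_b(0.25 * fit.K, fit),
            "fit": fit,
        }
    return rows


def random_small_distribution(rng: np.random.Generator) -> PatchSizeDistribution:
    """A random <=5-class distribution with integer patch counts."""
    n_classes = rng.integers(2, 6)
    sizes = np.sort(rng.uniform(1.0, 400.0, n_classes))
    while np.any(np.diff(sizes) < 1e-3):
        sizes = np.sort(rng.uniform(1.0, 400.0, n_classes))
    classes = []
    for i, s in enumerate(sizes):
        n = int(rng.integers(1, 8))
        classes.append(
            PatchSizeClass(
                class_label=f"K{i}", mean_size_ha=float(s), n_patches=n,
                total_area_ha=float(n * s),
            )
        )
    return PatchSizeDistribution(classes=tuple(classes))
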