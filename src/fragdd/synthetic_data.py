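"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators cover the three input classes of the pipeline:

* landscapes along a fragmentation gradient — patch areas drawn log-normal,
  core area from a square-patch geometry with a 30 m edge buffer, binned
  into the standard size classes;
* noisy vital-rate field observations around the survival and
  saturation-density curves;
* abundance-index series whose trends follow the two-season shift
  decomposition (|dn| from b' and the scenario's d'), so non-breeding- and
  breeding-limited worlds can be simulated at will.

Every generator is deterministic under its seed, and writers emit the same
delimited-text formats the pipeline readers consume, so synthetic runs
exercise the real I/O path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .landscape import (
    DEFAULT_CLASS_EDGES,
    Landscape,
    PatchSizeClass,
    PatchSizeDistribution,
    landscape_quality,
)
from .trend_stats import AbundanceIndexSeries
from .two_season import SeasonScenario, predicted_change
from .vital_rates import (
    SaturatingSurvivalCurve,
    SigmoidDensityCurve,
    VitalRateObservation,
    nest_survival,
    saturation_density,
)


@dataclass(frozen=True)
class LandscapeGeneratorConfig:
    """Study conditions for the synthetic fragmentation gradient.

    Eleven landscapes match the study region's landscape count; the mu
    gradient (log-ha location of the patch-size distribution) spans enough
    range that landscape quality covers the poor, moderate and good classes.
    Total forest area is normalized across landscapes so fragmentation and
    forest amount are not confounded.  The patch count is census-scale
    (inventory tables enumerate every patch in a state), which keeps the
    heavy-tailed upper size classes' area weights stable.
    """

    n_patches: int = 20000
    sigma: float = 1.2
    mu_gradient: tuple[float, ...] = tuple(np.linspace(0.0, 4.0, 11))
    edge_depth_m: float = 30.0
    total_forest_ha: float = 5.0e5
    class_edges: tuple[float, ...] = DEFAULT_CLASS_EDGES
    seed: int = 0

    def __post_init__(self):
        if self.n_patches <= 0:
            raise ValidationError("n_patches must be > 0")
        if self.edge_depth_m <= 0:
            raise ValidationError("edge_depth_m must be > 0")


@dataclass(frozen=True)
class TrendScenarioConfig:
    """A two-season world: which season's curves shifted, and how noisily.

    The default non-breeding scenario shifts only the mortality curve,
    calibrated so the steepest synthetic decline (in the least-regulated,
    best-quality landscape, b' ~ 0.6) is ~8 %/yr, the steepest decline
    reported for the study region: |dM| = 0.11 with d' = 2.0, plus
    0.5 %/yr Gaussian noise on the trend.
    """

    scenario: str = "nonbreeding"
    delta_F: float | None = None
    delta_M: float | None = None
    d_prime: float = 2.0
    noise_sd: float = 0.005
    y0: int = 1987
    y1: int = 1997
    base_index: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in ("nonbreeding", "breeding", "mixed"):
            raise ValidationError(f"unknown scenario {self.scenario!r}")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")

    def season_scenario(self) -> SeasonScenario:
        presets = {
            "nonbreeding": (0.0, 0.11),
            "breeding": (0.11, 0.0),
            "mixed": (0.055, 0.055),
        }
        df, dm = presets[self.scenario]
        return SeasonScenario(
            delta_F=self.delta_F if self.delta_F is not None else df,
            delta_M=self.delta_M if self.delta_M is not None else dm,
            d_prime=self.d_prime,
        )


def core_area_ha(patch_area_ha, edge_depth_m: float = 30.0):
    """Core area of a square patch: side L = 100*sqrt(A) m, buffer inset.

    core = max(0, L - 2*edge_depth)^2 / 1e4 ha; patches smaller than
    (2*edge_depth/100)^2 ha have no core.
    """
    a = np.asarray(patch_area_ha, dtype=float)
    side = 100.0 * np.sqrt(a)
    core_side = np.maximum(side - 2.0 * edge_depth_m, 0.0)
    out = core_side**2 / 1.0e4
    return float(out) if out.ndim == 0 else out


def _bin_patches(
    areas: np.ndarray, edges: tuple[float, ...]
) -> tuple[PatchSizeClass, ...]:
    """Bin patch areas into size classes; empty classes keep zero weight."""
    # classes: (0, e1), [e1, e2), ..., [e_last, inf); labels C1..Cn
    upper = np.array(edges[1:])
    idx = np.searchsorted(upper, areas, side="right")
    classes = []
    n_classes = len(edges)
    for k in range(n_classes):
        mask = idx == k
        n = int(mask.sum())
        total = float(areas[mask].sum())
        if n > 0:
            mean = total / n
        else:
            # nominal midpoint keeps the class ordered within its bin
            mean = (
                (edges[k] + edges[k + 1]) / 2.0
                if k + 1 < n_classes
                else 1.5 * edges[-1]
            )
            total = 0.0
        classes.append(
            PatchSizeClass(
                class_label=f"C{k + 1}", mean_size_ha=mean, n_patches=n,
                total_area_ha=total,
            )
        )
    return tuple(classes)


def _scale_classes(
    classes: tuple[PatchSizeClass, ...], factor: float
) -> tuple[PatchSizeClass, ...]:
    return tuple(
        PatchSizeClass(
            class_label=c.class_label,
            mean_size_ha=c.mean_size_ha,
            n_patches=c.n_patches * factor,
            total_area_ha=c.total_area_ha * factor,
        )
        for c in classes
    )


def generate_landscape(
    config: LandscapeGeneratorConfig, mu: float, landscape_id: str = "L"
) -> Landscape:
    """One synthetic landscape at log-ha location mu of the gradient."""
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed & 0x7FFFFFFF, int(round(mu * 1e6)) & 0x7FFFFFFF])
    )
    areas = rng.lognormal(mean=mu, sigma=config.sigma, size=config.n_patches)
    cores = core_area_ha(areas, config.edge_depth_m)

    forest_classes = _bin_patches(areas, config.class_edges)
    core_classes = _bin_patches(cores[cores > 0], config.class_edges)

    # normalize total forest area: fragmentation varies, forest amount does not
    drawn_total = float(areas.sum())
    factor = config.total_forest_ha / drawn_total
    forest_classes = _scale_classes(forest_classes, factor)
    core_classes = _scale_classes(core_classes, factor)

    forest = PatchSizeDistribution(classes=forest_classes)
    core = PatchSizeDistribution(classes=core_classes)
    q = landscape_quality(core.total_area_ha, forest.total_area_ha)
    return Landscape(id=landscape_id, forest=forest, core=core, quality=q)


def generate_fragmentation_gradient(
    config: LandscapeGeneratorConfig,
) -> list[Landscape]:
    """One landscape per mu in the gradient, ids L01, L02, ... ascending mu."""
    return [
        generate_landscape(config, mu, landscape_id=f"L{i + 1:02d}")
        for i, mu in enumerate(config.mu_gradient)
    ]


def generate_vital_observations(
    survival: SaturatingSurvivalCurve,
    density: SigmoidDensityCurve,
    sizes,
    noise_sd_survival: float = 0.05,
    noise_sd_density: float = 0.05,
    seed: int = 0,
) -> list[VitalRateObservation]:
    """Noisy field observations of both vital rates at the given patch sizes."""
    sizes = np.asarray(sizes, dtype=float)
    rng = np.random.default_rng(seed)
    surv = np.clip(
        nest_survival(sizes, survival) + rng.normal(0, noise_sd_survival, sizes.size),
        0.0, 1.0,
    )
    dens = np.maximum(
        saturation_density(sizes, density) + rng.normal(0, noise_sd_density, sizes.size),
        0.0,
    )
    obs = [
        VitalRateObservation(patch_size_ha=float(s), value=float(v), kind="survival")
        for s, v in zip(sizes, surv)
    ]
    obs += [
        VitalRateObservation(patch_size_ha=float(s), value=float(v), kind="density")
        for s, v in zip(sizes, dens)
    ]
    return obs


def generate_trend_scenario(
    b_primes: dict[str, float], config: TrendScenarioConfig
) -> list[AbundanceIndexSeries]:
    """Abundance-index series whose trends follow the two-season model.

    Per landscape the decline magnitude is predicted_change(b', scenario)
    plus truncated Gaussian noise; the index compounds (1 - |dn|) from
    base_index at y0 through y1.  Declines are the scenario convention:
    seasonal shifts are losses.
    """
    scenario = config.season_scenario()
    rng = np.random.default_rng(config.seed)
    out = []
    years = tuple(range(config.y0, config.y1 + 1))
    for lid in sorted(b_primes):
        dn = predicted_change(b_primes[lid], scenario)
        dn = max(dn + rng.normal(0.0, config.noise_sd), 0.0)
        ratio = 1.0 - dn
        if ratio <= 0:
            raise ValidationError(f"decline {dn} >= 100%/yr for landscape {lid!r}")
        index = tuple(config.base_index * ratio**k for k in range(len(years)))
        out.append(AbundanceIndexSeries(landscape_id=lid, years=years, index=index))
    return out


def write_patch_table(landscapes: list[Landscape], path) -> None:
    """Write landscapes as a county-level class table the reader accepts."""
    rows = []
    for ls in landscapes:
        for ftype, dist in (("total", ls.forest), ("core", ls.core)):
            if dist is None:
                continue
            for c in dist.classes:
                rows.append(
                    {
                        "landscape_id": ls.id,
                        "county": "synthetic",
                        "class_label": c.class_label,
                        "mean_size_ha": c.mean_size_ha,
                        "n_patches": c.n_patches,
                        "total_area_ha": c.total_area_ha,
                        "forest_type": ftype,
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_observations(obs: list[VitalRateObservation], path) -> None:
    pd.DataFrame(
        {
            "patch_size_ha": [o.patch_size_ha for o in obs],
            "value": [o.value for o in obs],
            "kind": [o.kind for o in obs],
        }
    ).to_csv(path, index=False)


def write_index_series(series: list[AbundanceIndexSeries], path) -> None:
    rows = [
        {"landscape_id": s.landscape_id, "year": y, "index": v}
        for s in series
        for y, v in zip(s.years, s.index)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
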