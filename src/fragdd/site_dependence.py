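"""Site-dependent habitat selection: fecundity-density curve generation.

Territorial breeders occupy forest patches in order of decreasing size, each
patch filling to its saturation density d(s).  When every class of mean size
a and larger is saturated, the population's mean nest survival and the
landscape-scale density are discrete weighted sums over occupied classes:

    F(a) = sum_{s >= a} f(s) d(s) A(s) / sum_{s >= a} d(s) A(s)
    D(a) = sum_{s >= a} d(s) A(s) / sum_{all s} A(s)

with A(s) the total area in the class of mean size s.  Sweeping the
threshold a from the largest class down to the smallest traces the
fecundity-density curve of the landscape: density rises and mean survival
falls as progressively smaller (lower-survival) patches fill.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DataError, ValidationError
from .landscape import PatchSizeDistribution
from .vital_rates import (
    SaturatingSurvivalCurve,
    SigmoidDensityCurve,
    nest_survival,
    saturation_density,
)


@dataclass(frozen=True)
class FecundityDensityPoint:
    """One (D(a), F(a)) point at occupancy threshold class size a."""

    threshold_class_size: float
    density: float
    fecundity: float

    def __post_init__(self):
        if not 0.0 <= self.fecundity <= 1.0:
            raise ValidationError(f"fecundity {self.fecundity} outside [0, 1]")
        if self.density < 0:
            raise ValidationError("density must be >= 0")


@dataclass(frozen=True)
class FecundityDensitySeries:
    """Fecundity-density points of one landscape, ascending in density."""

    landscape_id: str
    points: tuple[FecundityDensityPoint, ...]

    def __post_init__(self):
        d = [p.density for p in self.points]
        if any(b <= a for a, b in zip(d, d[1:])):
            raise ValidationError("densities must be strictly increasing")

    @property
    def densities(self) -> np.ndarray:
        return np.array([p.density for p in self.points])

    @property
    def fecundities(self) -> np.ndarray:
        return np.array([p.fecundity for p in self.points])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "landscape_id": self.landscape_id,
                "threshold_class_size": [p.threshold_class_size for p in self.points],
                "density": self.densities,
                "fecundity": self.fecundities,
            }
        )


def occupancy_point(
    dist: PatchSizeDistribution,
    survival: SaturatingSurvivalCurve,
    sat_density: SigmoidDensityCurve,
    a: float,
) -> FecundityDensityPoint:
    """F(a) and D(a) when all classes of mean size >= a are saturated.

    ``a`` must equal the mean size of one of the distribution's classes
    (within floating-point tolerance); classes with zero area contribute
    nothing to either sum.
    """
    sizes = np.array([c.mean_size_ha for c in dist.classes])
    areas = np.array([c.total_area_ha for c in dist.classes])
    if not np.any(np.isclose(sizes, a, rtol=1e-9)):
        raise ValidationError(f"threshold a={a} is not a class mean size")
    occupied = (sizes >= a * (1 - 1e-12)) & (areas > 0)
    if not occupied.any():
        raise DataError("all occupied classes have zero area; point undefined")

    f = nest_survival(sizes[occupied], survival)
    d = saturation_density(sizes[occupied], sat_density)
    w = d * areas[occupied]
    fecundity = float(np.sum(f * w) / np.sum(w))
    density = float(np.sum(w) / np.sum(areas))
    return FecundityDensityPoint(
        threshold_class_size=float(a), density=density, fecundity=fecundity
    )


def occupancy_curve(
    dist: PatchSizeDistribution,
    survival: SaturatingSurvivalCurve | None = None,
    sat_density: SigmoidDensityCurve | None = None,
    landscape_id: str = "",
    interpolate: int = 0,
) -> FecundityDensitySeries:
    """Fecundity-density series over all non-empty classes, sU down to sL.

    With ``interpolate`` = m > 0, each marginal class is additionally filled
    in m fractional steps (both occupancy sums scale linearly in the occupied
    fraction of the marginal class), densifying the curve for fitting.  The
    default is class-threshold points only.
    """
    survival = survival or SaturatingSurvivalCurve()
    sat_density = sat_density or SigmoidDensityCurve()
    nonempty = dist.nonempty()
    if not nonempty:
        raise DataError("empty patch-size distribution")

    sizes = np.array([c.mean_size_ha for c in nonempty])
    areas = np.array([c.total_area_ha for c in nonempty])
    total_area = sum(c.total_area_ha for c in dist.classes)
    f = nest_survival(sizes, survival)
    d = saturation_density(sizes, sat_density)

    points = []
    # iterate thresholds from the largest class downward
    for k in range(len(nonempty) - 1, -1, -1):
        if interpolate and k < len(nonempty) - 1:
            # fractional fill of class k before it saturates
            for j in range(1, interpolate + 1):
                frac = j / (interpolate + 1)
                w_full = d[k + 1 :] * areas[k + 1 :]
                w_part = frac * d[k] * areas[k]
                num = np.sum(f[k + 1 :] * w_full) + f[k] * w_part
                den = np.sum(w_full) + w_part
                points.append(
                    FecundityDensityPoint(
                        threshold_class_size=float(sizes[k]),
                        density=float(den / total_area),
                        fecundity=float(num / den),
                    )
                )
        w = d[k:] * areas[k:]
        points.append(
            FecundityDensityPoint(
                threshold_class_size=float(sizes[k]),
                density=float(np.sum(w) / total_area),
                fecundity=float(np.sum(f[k:] * w) / np.sum(w)),
            )
        )
    return FecundityDensitySeries(landscape_id=landscape_id, points=tuple(points))
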