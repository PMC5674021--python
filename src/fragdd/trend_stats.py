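"""Population trends, breeding density and buffer-effect statistics.

Trends are the average annual proportional change of an abundance index
between two endpoint years (geometric mean annual change by default).
Breeding density is population size / 2 / total forest area — pairs per
hectare of forest.  The buffer-effect test correlates trend magnitude with
landscape quality: significantly *larger* changes in *poorer* landscapes is
the classical buffer effect, larger changes in better landscapes the
inverse buffer effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .exceptions import DataError, ValidationError


@dataclass(frozen=True)
class AbundanceIndexSeries:
    landscape_id: str
    years: tuple[int, ...]
    index: tuple[float, ...]

    def __post_init__(self):
        if len(self.years) != len(self.index):
            raise ValidationError("years and index must have equal length")
        if any(b <= a for a, b in zip(self.years, self.years[1:])):
            raise ValidationError("years must be strictly increasing")
        if any(v <= 0 for v in self.index):
            raise ValidationError("abundance index must be > 0")

    def at(self, year: int) -> float:
        try:
            return self.index[self.years.index(year)]
        except ValueError:
            raise DataError(
                f"landscape {self.landscape_id!r}: year {year} not in series"
            ) from None


@dataclass(frozen=True)
class TrendEstimate:
    landscape_id: str
    trend: float  # signed proportional change per year

    @property
    def magnitude(self) -> float:
        return abs(self.trend)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    df: int
    p: float
    n: int


def annual_trend(
    series: AbundanceIndexSeries,
    y0: int = 1987,
    y1: int = 1997,
    method: str = "geometric",
) -> TrendEstimate:
    """Average annual proportional change of the index between y0 and y1.

    ``geometric`` (default) uses the endpoint ratio,
    trend = (index(y1)/index(y0))^(1/(y1-y0)) - 1, which inverts
    compounding exactly; ``arithmetic`` averages the year-over-year
    proportional changes across the window.
    """
    if y0 >= y1:
        raise ValidationError("window years must satisfy y0 < y1")
    if method == "geometric":
        ratio = series.at(y1) / series.at(y0)
        trend = ratio ** (1.0 / (y1 - y0)) - 1.0
    elif method == "arithmetic":
        years = [y for y in series.years if y0 <= y <= y1]
        if years[0] != y0 or years[-1] != y1 or len(years) < 2:
            raise DataError("arithmetic trend needs the full year window")
        vals = np.array([series.at(y) for y in years])
        steps = np.diff(np.array(years))
        changes = (vals[1:] / vals[:-1]) ** (1.0 / steps) - 1.0
        trend = float(np.mean(changes))
    else:
        raise ValidationError(f"unknown trend method {method!r}")
    return TrendEstimate(landscape_id=series.landscape_id, trend=float(trend))


def breeding_density(population_size: float, forest_area_ha: float) -> float:
    """Breeding pairs per hectare: population / 2 / total forest area."""
    if forest_area_ha <= 0:
        raise ValidationError("forest area must be > 0")
    if population_size < 0:
        raise ValidationError("population size must be >= 0")
    return population_size / 2.0 / forest_area_ha


def pearson_test(x, y) -> CorrelationResult:
    """Pearson r with two-sided t-test p-value on n-2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise DataError("x and y must have equal length")
    if x.size < 3:
        raise DataError("need n >= 3 for a correlation test")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DataError("degenerate correlation: an input has zero variance")
    res = pearsonr(x, y)
    return CorrelationResult(
        r=float(res.statistic), df=x.size - 2, p=float(res.pvalue), n=x.size
    )


def buffer_effect_test(
    trends: list[TrendEstimate],
    qualities: dict[str, float],
    alpha: float = 0.05,
) -> dict:
    """Classify buffer vs inverse buffer from |trend|-vs-Q correlation.

    Landscapes are matched by id.  The classification comes from the sign of
    the correlation between trend *magnitude* and quality at two-sided
    p < alpha; the signed trend-vs-Q correlation is reported alongside.
    """
    matched = [t for t in trends if t.landscape_id in qualities]
    if len(matched) < 4:
        raise DataError("need >= 4 matched landscapes for the buffer-effect test")
    q = np.array([qualities[t.landscape_id] for t in matched])
    signed = np.array([t.trend for t in matched])
    mag = np.array([t.magnitude for t in matched])
    signed_corr = pearson_test(signed, q)
    mag_corr = pearson_test(mag, q)
    if mag_corr.p < alpha:
        classification = "inverse_buffer" if mag_corr.r > 0 else "buffer"
    else:
        classification = "none"
    return {
        "classification": classification,
        "trend_vs_quality": signed_corr,
        "magnitude_vs_quality": mag_corr,
        "n": len(matched),
    }


def load_index_series(path) -> list[AbundanceIndexSeries]:
    """Read index series from CSV with columns landscape_id, year, index."""
    df = pd.read_csv(path)
    for col in ("landscape_id", "year", "index"):
        if col not in df.columns:
            raise DataError(f"index table is missing column {col!r}")
    out = []
    for lid, group in df.groupby("landscape_id", sort=True):
        group = group.sort_values("year")
        out.append(
            AbundanceIndexSeries(
                landscape_id=str(lid),
                years=tuple(int(y) for y in group["year"]),
                index=tuple(float(v) for v in group["index"]),
            )
        )
    return out


def trends_frame(trends: list[TrendEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "landscape_id": [t.landscape_id for t in trends],
            "trend": [t.trend for t in trends],
            "magnitude": [t.magnitude for t in trends],
        }
    )
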