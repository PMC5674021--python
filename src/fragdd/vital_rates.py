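"""Patch-size-dependent vital rates: nest survival and saturation density.

Nest survival rises with patch size following a saturating (Michaelis-Menten
style) curve

    f(s) = f_max * s / (s_half + s),

while the density at which a patch saturates with territorial breeders falls
with patch size following a reverse sigmoid.  Field data for the wood thrush
give the defaults f_max = 0.85, s_half = 42 ha, and (l, alpha, t) =
(0.13, 0.18, 13.4).

The sigmoid has two orientations.  The "decreasing" default

    d(s) = l + (1 - l) / (1 + exp(alpha * (s - t)))

declines from ~1 pair/ha in the smallest patches to the asymptote l in
contiguous forest, matching the observed pattern of higher density in
smaller patches.  The "literal" form d(s) = 1 + (l - 1)/(1 + exp(alpha*(s-t)))
is the same expression with the sign convention flipped — it *increases*
with s and is retained only so the discrepancy between the two published
forms can be inspected; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .exceptions import DataError, FitError, ValidationError

DEFAULT_SURVIVAL = None  # set below once the class exists
DEFAULT_DENSITY = None

_MAX_RESTARTS = 10


@dataclass(frozen=True)
class SaturatingSurvivalCurve:
    """f(s) = f_max * s / (s_half + s)."""

    f_max: float = 0.85
    s_half: float = 42.0

    def __post_init__(self):
        if not 0 < self.f_max <= 1:
            raise ValidationError(f"f_max={self.f_max} outside (0, 1]")
        if self.s_half <= 0:
            raise ValidationError(f"s_half={self.s_half} must be > 0")


@dataclass(frozen=True)
class SigmoidDensityCurve:
    """Saturation density d(s); see module docstring for the two orientations."""

    l: float = 0.13
    alpha: float = 0.18
    t: float = 13.4
    orientation: str = "decreasing"

    def __post_init__(self):
        if not 0 < self.l < 1:
            raise ValidationError(f"l={self.l} outside (0, 1)")
        if self.alpha <= 0 or self.t <= 0:
            raise ValidationError("alpha and t must be > 0")
        if self.orientation not in ("decreasing", "literal"):
            raise ValidationError(f"unknown orientation {self.orientation!r}")


@dataclass(frozen=True)
class VitalRateObservation:
    """A field observation of survival or density at one patch size."""

    patch_size_ha: float
    value: float
    kind: str  # "survival" | "density"

    def __post_init__(self):
        if self.patch_size_ha <= 0:
            raise ValidationError("patch_size_ha must be > 0")
        if self.kind == "survival" and not 0 <= self.value <= 1:
            raise ValidationError(f"survival value {self.value} outside [0, 1]")
        if self.kind == "density" and self.value < 0:
            raise ValidationError("density value must be >= 0")
        if self.kind not in ("survival", "density"):
            raise ValidationError(f"unknown observation kind {self.kind!r}")


def nest_survival(s, curve: SaturatingSurvivalCurve | None = None):
    """Nest survival f(s) for patch size s (ha); vectorized over s."""
    curve = curve or SaturatingSurvivalCurve()
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValidationError("patch size must be >= 0")
    out = curve.f_max * s / (curve.s_half + s)
    return float(out) if out.ndim == 0 else out


def saturation_density(s, curve: SigmoidDensityCurve | None = None):
    """Saturation density d(s) in pairs/ha for patch size s; vectorized."""
    curve = curve or SigmoidDensityCurve()
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValidationError("patch size must be >= 0")
    with np.errstate(over="ignore"):  # exp overflow -> logistic underflows to 0
        logistic = 1.0 / (1.0 + np.exp(curve.alpha * (s - curve.t)))
    if curve.orientation == "decreasing":
        out = curve.l + (1.0 - curve.l) * logistic
    else:  # literal published form, increasing in s for l < 1
        out = 1.0 + (curve.l - 1.0) * logistic
    return float(out) if out.ndim == 0 else out


def _restart_fit(model, sizes, values, p0, bounds, rng):
    """curve_fit with jittered restarts; returns params or raises FitError."""
    best = None
    best_res = np.inf
    p0 = np.asarray(p0, dtype=float)
    for attempt in range(_MAX_RESTARTS):
        start = p0 if attempt == 0 else p0 * rng.lognormal(0.0, 0.3, size=p0.size)
        start = np.clip(start, bounds[0], bounds[1])
        try:
            popt, _ = curve_fit(
                model, sizes, values, p0=start, bounds=bounds, maxfev=20000
            )
        except (RuntimeError, ValueError):
            continue
        res = float(np.sum((values - model(sizes, *popt)) ** 2))
        if res < best_res:
            best, best_res = popt, res
        if res <= 1e-12 or attempt >= 2 and best is not None:
            break
    if best is None:
        raise FitError("nonlinear fit failed to converge", best_residual=best_res)
    return best, best_res


def fit_survival_curve(
    obs: list[VitalRateObservation], seed: int = 0
) -> SaturatingSurvivalCurve:
    """Least-squares (f_max, s_half) from survival-vs-patch-size observations."""
    pts = [o for o in obs if o.kind == "survival"]
    if len(pts) < 3:
        raise DataError("need >= 3 survival observations")
    sizes = np.array([o.patch_size_ha for o in pts])
    values = np.array([o.value for o in pts])
    if np.unique(sizes).size < 2:
        raise DataError("survival observations at a single patch size are unidentifiable")

    def model(s, f_max, s_half):
        return f_max * s / (s_half + s)

    vmax = max(values.max(), 1e-3)
    above = sizes[values >= vmax / 2]
    s_half0 = float(above.min()) if above.size else float(np.median(sizes))
    rng = np.random.default_rng(seed)
    (f_max, s_half), _ = _restart_fit(
        model, sizes, values, [vmax, max(s_half0, 1e-3)],
        ([1e-9, 1e-9], [1.0, np.inf]), rng,
    )
    return SaturatingSurvivalCurve(f_max=f_max, s_half=s_half)


def fit_density_curve(
    obs: list[VitalRateObservation],
    orientation: str = "decreasing",
    seed: int = 0,
) -> SigmoidDensityCurve:
    """Least-squares (l, alpha, t) for the saturation-density sigmoid."""
    pts = [o for o in obs if o.kind == "density"]
    if len(pts) < 4:
        raise DataError("need >= 4 density observations")
    order = np.argsort([o.patch_size_ha for o in pts])
    sizes = np.array([pts[i].patch_size_ha for i in order])
    values = np.array([pts[i].value for i in order])
    if np.unique(sizes).size < 3:
        raise DataError("density observations span too few distinct patch sizes")

    def model(s, l, alpha, t):
        return saturation_density(
            s, SigmoidDensityCurve(l=l, alpha=alpha, t=t, orientation=orientation)
        )

    l0 = float(np.clip(values.min(), 1e-3, 0.99))
    drops = np.diff(values) / np.maximum(np.diff(sizes), 1e-12)
    t0 = float(sizes[np.argmin(drops)]) if drops.size else float(np.median(sizes))
    alpha0 = 4.0 / max(sizes.max() - sizes.min(), 1e-6)
    rng = np.random.default_rng(seed)
    (l, alpha, t), _ = _restart_fit(
        model, sizes, values, [l0, alpha0, max(t0, 1e-3)],
        ([1e-9, 1e-9, 1e-9], [1 - 1e-9, np.inf, np.inf]), rng,
    )
    return SigmoidDensityCurve(l=l, alpha=alpha, t=t, orientation=orientation)


def load_observations(path) -> list[VitalRateObservation]:
    """Read observations from CSV with columns patch_size_ha, value, kind."""
    df = pd.read_csv(path)
    for col in ("patch_size_ha", "value", "kind"):
        if col not in df.columns:
            raise DataError(f"observation table is missing column {col!r}")
    return [
        VitalRateObservation(float(r.patch_size_ha), float(r.value), str(r.kind))
        for r in df.itertuples(index=False)
    ]


DEFAULT_SURVIVAL = SaturatingSurvivalCurve()
DEFAULT_DENSITY = SigmoidDensityCurve()
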