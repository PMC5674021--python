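"""Patch-size distributions, landscapes and landscape quality.

A *landscape* is described by two patch-size distributions derived from
county-level forest inventory class tables: all forest, and *core* forest
(forest more than ~30 m from an edge).  Landscape quality Q is the ratio of
core to total forest area and classifies landscapes as good (Q > 0.7),
moderate (0.6 <= Q <= 0.7) or poor (Q < 0.6).

County tables give, per patch-size class, the number of patches and total
area; patches within a county/class are assumed equal in area, so the
landscape-level class mean is the patch-count-weighted mean
sum(area)/sum(count) over counties.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .exceptions import FormatError, SchemaError, ValidationError

#: Default size-class lower edges in hectares; the last class is open-ended.
DEFAULT_CLASS_EDGES = (1.0, 5.0, 10.0, 25.0, 50.0, 100.0, 250.0, 500.0)

#: Nominal midpoints used for classes that end up with zero patches.
DEFAULT_CLASS_MIDPOINTS = (3.0, 7.5, 17.5, 37.5, 75.0, 175.0, 375.0, 750.0)

REQUIRED_COLUMNS = (
    "landscape_id",
    "county",
    "class_label",
    "n_patches",
    "total_area_ha",
    "forest_type",
)

QUALITY_GOOD_THRESHOLD = 0.7
QUALITY_POOR_THRESHOLD = 0.6


@dataclass(frozen=True)
class PatchSizeClass:
    """One forest patch size class: mean size s, count and total area A(s)."""

    class_label: str
    mean_size_ha: float
    n_patches: float
    total_area_ha: float

    def __post_init__(self):
        if self.mean_size_ha <= 0:
            raise ValidationError(
                f"class {self.class_label!r}: mean_size_ha must be > 0, "
                f"got {self.mean_size_ha}"
            )
        if self.n_patches < 0 or self.total_area_ha < 0:
            raise ValidationError(
                f"class {self.class_label!r}: negative count or area"
            )

    @property
    def empty(self) -> bool:
        return self.total_area_ha == 0


@dataclass(frozen=True)
class PatchSizeDistribution:
    """Ordered size classes of one landscape; A(s) with bounds sL, sU."""

    classes: tuple[PatchSizeClass, ...]

    def __post_init__(self):
        sizes = [c.mean_size_ha for c in self.classes]
        if any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise ValidationError("class mean sizes must be strictly increasing")
        if not any(c.total_area_ha > 0 for c in self.classes):
            raise ValidationError("distribution needs at least one non-empty class")

    @property
    def s_lower(self) -> float:
        """Smallest class mean size sL."""
        return self.classes[0].mean_size_ha

    @property
    def s_upper(self) -> float:
        """Largest class mean size sU."""
        return self.classes[-1].mean_size_ha

    @property
    def total_area_ha(self) -> float:
        return sum(c.total_area_ha for c in self.classes)

    def nonempty(self) -> tuple[PatchSizeClass, ...]:
        return tuple(c for c in self.classes if c.total_area_ha > 0)


@dataclass(frozen=True)
class Landscape:
    """A landscape: forest and core-forest distributions plus quality Q."""

    id: str
    forest: PatchSizeDistribution
    core: PatchSizeDistribution | None
    quality: float

    def __post_init__(self):
        if not 0.0 <= self.quality <= 1.0:
            raise ValidationError(f"quality Q={self.quality} outside [0, 1]")
        if self.core is not None:
            if self.core.total_area_ha > self.forest.total_area_ha * (1 + 1e-9):
                raise ValidationError("core area exceeds total forest area")

    @property
    def quality_class(self) -> str:
        return classify_quality(self.quality)


@dataclass(frozen=True)
class CountyClassRecord:
    """One row of a county-level inventory class table."""

    landscape_id: str
    county: str
    class_label: str
    n_patches: float
    total_area_ha: float
    forest_type: str
    mean_size_ha: float | None = None
    empty: bool = field(default=False)


def load_patch_table(path) -> list[CountyClassRecord]:
    """Read a county-level class table (CSV with header) into records.

    Required columns: landscape_id, county, class_label, n_patches,
    total_area_ha, forest_type (``total`` or ``core``); ``mean_size_ha`` is
    optional.  Rows with zero patches and zero area are retained but flagged
    empty.
    """
    df = pd.read_csv(path)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"patch table is missing required column {col!r}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is row 1
        n = float(row.n_patches)
        area = float(row.total_area_ha)
        if n < 0:
            raise ValidationError(f"row {i}: negative n_patches ({n:g})")
        if area < 0:
            raise ValidationError(f"row {i}: negative total_area_ha ({area:g})")
        ftype = str(row.forest_type)
        if ftype not in ("total", "core"):
            raise ValidationError(
                f"row {i}: forest_type must be 'total' or 'core', got {ftype!r}"
            )
        mean = getattr(row, "mean_size_ha", None)
        mean = None if mean is None or pd.isna(mean) else float(mean)
        records.append(
            CountyClassRecord(
                landscape_id=str(row.landscape_id),
                county=str(row.county),
                class_label=str(row.class_label),
                n_patches=n,
                total_area_ha=area,
                forest_type=ftype,
                mean_size_ha=mean,
                empty=(n == 0 and area == 0),
            )
        )
    return records


def aggregate_counties(
    records: list[CountyClassRecord],
    landscape_id: str,
    class_midpoints: dict[str, float] | None = None,
) -> PatchSizeDistribution:
    """Pool county class records of one landscape into its distribution.

    Per class: counts and areas are summed over counties and the landscape
    mean patch size is sum(area)/sum(count).  Classes with zero patches keep
    zero area and get their nominal midpoint (from the input mean_size_ha or
    ``class_midpoints``) so downstream curve point counts stay stable.
    """
    recs = [r for r in records if r.landscape_id == landscape_id]
    if not recs:
        raise SchemaError(f"no records for landscape {landscape_id!r}")

    schemes = {
        county: frozenset(r.class_label for r in recs if r.county == county)
        for county in {r.county for r in recs}
    }
    if len(set(schemes.values())) > 1:
        raise SchemaError(
            f"conflicting class-label schemes across counties of {landscape_id!r}: "
            + ", ".join(f"{c}={sorted(s)}" for c, s in sorted(schemes.items()))
        )

    labels = sorted({r.class_label for r in recs})
    classes = []
    for label in labels:
        group = [r for r in recs if r.class_label == label]
        n = sum(r.n_patches for r in group)
        area = sum(r.total_area_ha for r in group)
        if n > 0:
            mean = area / n
        else:
            provided = [r.mean_size_ha for r in group if r.mean_size_ha is not None]
            if provided:
                mean = provided[0]
            elif class_midpoints and label in class_midpoints:
                mean = class_midpoints[label]
            else:
                mean = _positional_midpoint(label, labels)
            area = 0.0
        classes.append(
            PatchSizeClass(
                class_label=label, mean_size_ha=mean, n_patches=n, total_area_ha=area
            )
        )
    classes.sort(key=lambda c: c.mean_size_ha)
    return PatchSizeDistribution(classes=tuple(classes))


def _positional_midpoint(label: str, labels: list[str]) -> float:
    idx = labels.index(label)
    if idx < len(DEFAULT_CLASS_MIDPOINTS):
        return DEFAULT_CLASS_MIDPOINTS[idx]
    return DEFAULT_CLASS_MIDPOINTS[-1] * 2 ** (idx - len(DEFAULT_CLASS_MIDPOINTS) + 1)


def landscape_quality(core_total_ha: float, forest_total_ha: float) -> float:
    """Q = core forest area / total forest area, in [0, 1]."""
    if forest_total_ha <= 0:
        raise ValidationError("landscape quality undefined: total forest area is 0")
    if core_total_ha < 0 or core_total_ha > forest_total_ha:
        raise ValidationError(
            f"core area {core_total_ha} outside [0, total={forest_total_ha}]"
        )
    return core_total_ha / forest_total_ha


def classify_quality(q: float) -> str:
    """Classify Q: good (Q > 0.7), moderate (0.6 <= Q <= 0.7), poor (Q < 0.6)."""
    if not 0.0 <= q <= 1.0:
        raise ValidationError(f"Q={q} outside [0, 1]")
    if q > QUALITY_GOOD_THRESHOLD:
        return "good"
    if q >= QUALITY_POOR_THRESHOLD:
        return "moderate"
    return "poor"


def build_landscapes(
    records: list[CountyClassRecord],
    class_midpoints: dict[str, float] | None = None,
) -> list[Landscape]:
    """Assemble all landscapes present in a record list.

    Each landscape needs ``total`` rows; ``core`` rows are optional but
    required to compute Q (landscapes without core rows get Q from an
    all-core assumption refused — a ValidationError — so missing core data
    never passes silently).
    """
    ids = sorted({r.landscape_id for r in records})
    landscapes = []
    for lid in ids:
        total_recs = [r for r in records if r.landscape_id == lid and r.forest_type == "total"]
        core_recs = [r for r in records if r.landscape_id == lid and r.forest_type == "core"]
        if not total_recs:
            raise SchemaError(f"landscape {lid!r} has no 'total' forest rows")
        forest = aggregate_counties(total_recs, lid, class_midpoints)
        if not core_recs:
            raise ValidationError(
                f"landscape {lid!r} has no 'core' rows; quality Q is undefined"
            )
        core = aggregate_counties(core_recs, lid, class_midpoints)
        q = landscape_quality(core.total_area_ha, forest.total_area_ha)
        landscapes.append(Landscape(id=lid, forest=forest, core=core, quality=q))
    return landscapes


def summarize_landscapes(landscapes: list[Landscape]) -> pd.DataFrame:
    """Per-landscape summary table: areas, Q and quality class."""
    rows = [
        {
            "landscape_id": ls.id,
            "n_classes": len(ls.forest.classes),
            "forest_total_ha": ls.forest.total_area_ha,
            "core_total_ha": ls.core.total_area_ha if ls.core else float("nan"),
            "Q": ls.quality,
            "quality_class": ls.quality_class,
        }
        for ls in landscapes
    ]
    return pd.DataFrame(rows)
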