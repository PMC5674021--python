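import textwrap

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fragdd.exceptions import FormatError, SchemaError, ValidationError
from fragdd.landscape import (
    CountyClassRecord,
    aggregate_counties,
    build_landscapes,
    classify_quality,
    landscape_quality,
    load_patch_table,
    summarize_landscapes,
)


def _write(tmp_path, text):
    p = tmp_path / "patches.csv"
    p.write_text(textwrap.dedent(text))
    return p


WELL_FORMED = """\
    landscape_id,county,class_label,mean_size_ha,n_patches,total_area_ha,forest_type
    A,c1,C1,3,10,50,total
    A,c1,C2,7.5,4,30,total
    A,c1,C1,3,8,40,core
"""


class TestLoadPatchTable:
    def test_reads_all_rows(self, tmp_path):
        records = load_patch_table(_write(tmp_path, WELL_FORMED))
        assert len(records) == 3
        assert records[0].landscape_id == "A"
        assert records[0].n_patches == 10
        assert records[2].forest_type == "core"

    def test_missing_column_is_format_error(self, tmp_path):
        path = _write(
            tmp_path,
            """\
            landscape_id,county,class_label,n_patches,forest_type
            A,c1,C1,10,total
            """,
        )
        with pytest.raises(FormatError, match="total_area_ha"):
            load_patch_table(path)

    def test_negative_count_cites_row(self, tmp_path):
        path = _write(
            tmp_path,
            """\
            landscape_id,county,class_label,n_patches,total_area_ha,forest_type
            A,c1,C1,10,50,total
            A,c1,C2,-1,30,total
            """,
        )
        with pytest.raises(ValidationError, match="row 3"):
            load_patch_table(path)

    def test_empty_row_flagged(self, tmp_path):
        path = _write(
            tmp_path,
            """\
            landscape_id,county,class_label,n_patches,total_area_ha,forest_type
            A,c1,C8,0,0,total
            """,
        )
        (rec,) = load_patch_table(path)
        assert rec.empty


def _rec(county, label, n, area, mean=None):
    return CountyClassRecord(
        landscape_id="A", county=county, class_label=label, n_patches=n,
        total_area_ha=area, forest_type="total", mean_size_ha=mean,
    )


class TestAggregateCounties:
    def test_single_county_mean(self):
        dist = aggregate_counties([_rec("c1", "C1", 10, 50)], "A")
        assert dist.classes[0].mean_size_ha == pytest.approx(5.0)
        assert dist.classes[0].total_area_ha == 50

    def test_two_counties_pooled_mean(self):
        # patch-count-weighted mean: (50 + 250) / (10 + 30) = 7.5
        dist = aggregate_counties(
            [_rec("c1", "C1", 10, 50), _rec("c2", "C1", 30, 250)], "A"
        )
        cls = dist.classes[0]
        assert cls.n_patches == 40
        assert cls.total_area_ha == 300
        assert cls.mean_size_ha == pytest.approx(7.5)

    def test_totals_conserved(self):
        recs = [
            _rec("c1", "C1", 3, 10), _rec("c2", "C1", 5, 22),
            _rec("c1", "C2", 2, 15), _rec("c2", "C2", 1, 9),
        ]
        dist = aggregate_counties(recs, "A")
        assert sum(c.total_area_ha for c in dist.classes) == pytest.approx(56)
        assert sum(c.n_patches for c in dist.classes) == pytest.approx(11)

    def test_zero_patch_class_keeps_nominal_midpoint_and_zero_area(self):
        recs = [_rec("c1", "C1", 10, 50), _rec("c1", "C8", 0, 0, mean=750.0)]
        dist = aggregate_counties(recs, "A")
        c8 = [c for c in dist.classes if c.class_label == "C8"][0]
        assert c8.total_area_ha == 0
        assert c8.mean_size_ha == 750.0
        assert c8 not in dist.nonempty()

    def test_conflicting_schemes_rejected(self):
        recs = [_rec("c1", "C1", 10, 50), _rec("c2", "X1", 5, 20)]
        with pytest.raises(SchemaError):
            aggregate_counties(recs, "A")


class TestQuality:
    @pytest.mark.parametrize(
        "core,total,expected", [(70, 100, 0.7), (0, 100, 0.0), (100, 100, 1.0)]
    )
    def test_ratio(self, core, total, expected):
        assert landscape_quality(core, total) == pytest.approx(expected)

    def test_zero_total_undefined(self):
        with pytest.raises(ValidationError):
            landscape_quality(10, 0)

    def test_core_exceeding_total_rejected(self):
        with pytest.raises(ValidationError):
            landscape_quality(101, 100)

    @pytest.mark.parametrize(
        "q,expected",
        [(0.75, "good"), (0.7, "moderate"), (0.6, "moderate"), (0.59, "poor"),
         (0.0, "poor"), (1.0, "good")],
    )
    def test_classify_boundaries(self, q, expected):
        assert classify_quality(q) == expected

    def test_classify_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            classify_quality(1.2)

    @given(st.floats(0, 1), st.floats(1e-6, 1e6))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, frac, scale):
        base = landscape_quality(frac * 100, 100)
        scaled = landscape_quality(frac * 100 * scale, 100 * scale)
        assert scaled == pytest.approx(base, rel=1e-12)

    @given(st.floats(0, 1))
    @settings(max_examples=100, deadline=None)
    def test_classification_total_on_unit_interval(self, q):
        assert classify_quality(q) in {"good", "moderate", "poor"}


def test_build_landscapes_and_summary(tmp_path):
    path = _write(
        tmp_path,
        """\
        landscape_id,county,class_label,mean_size_ha,n_patches,total_area_ha,forest_type
        A,c1,C1,,10,50,total
        A,c1,C2,,4,150,total
        A,c1,C1,,8,40,core
        A,c1,C2,,3,100,core
        """,
    )
    (ls,) = build_landscapes(load_patch_table(path))
    assert ls.quality == pytest.approx(140 / 200)
    assert ls.quality_class == "moderate"
    table = summarize_landscapes([ls])
    assert table.loc[0, "Q"] == pytest.approx(0.7)
    assert table.loc[0, "forest_total_ha"] == pytest.approx(200)
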