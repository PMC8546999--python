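"""Tree-table-metadata joins: presence, barplot stats, aggregation,
quantile subsetting, propagation and clade collapsing."""

import numpy as np
import pandas as pd
import pytest

from treescape import (
    FeatureTable, MetadataTable, build_presence, collapse_uniform_clades,
    feature_numeric_aggregate, generate_fixture, propagate_uniform_metadata,
    read_newick, subset_samples_middle_fraction, tip_category_proportions,
)
from treescape.community import MISSING_CATEGORY


def md_from(mapping, index_name="#SampleID"):
    df = pd.DataFrame(mapping)
    df.index = pd.Index(df.index.astype(str), name=index_name)
    return MetadataTable(df)


@pytest.fixture
def toy():
    tree = read_newick("((f1:1,f2:1)x:1,f3:1)r;")
    table = FeatureTable(
        ["s1", "s2", "s3"], ["f1", "f2"],
        [[3.0, 0.0], [0.0, 1.0], [2.0, 0.0]])
    md = md_from({"cat": {"s1": "A", "s2": "B", "s3": "B"},
                  "ph": {"s1": "6", "s2": "8", "s3": ""}})
    return tree, table, md


class TestPresence:
    def test_membership_and_transpose(self, toy):
        _, table, _ = toy
        pres = build_presence(table)
        assert pres.samples_of("f1") == {"s1", "s3"}
        assert pres.samples_of("f2") == {"s2"}
        for f, ss in pres.feature_to_samples.items():
            for s in ss:
                assert f in pres.features_of(s)

    def test_empty_table(self):
        pres = build_presence(FeatureTable(["s1"], ["f1"], [[0.0]]))
        assert pres.n_pairs == 0

    def test_pair_count_equals_stored_entries(self):
        _, table, _, _ = generate_fixture(30, 15, 0.3, seed=7)
        assert build_presence(table).n_pairs == table.nnz


class TestTipCategoryProportions:
    def test_stratified_proportions(self, toy):
        tree, table, md = toy
        layer = tip_category_proportions(tree, build_presence(table), md,
                                         "cat")
        assert layer.payload["f1"] == {"A": 0.5, "B": 0.5}
        assert layer.payload["f2"] == {"B": 1.0}
        assert layer.payload["f3"] == {}  # tip absent from table: no bar

    def test_missing_pooled(self, toy):
        tree, table, _ = toy
        md = md_from({"cat": {"s1": "A", "s2": "", "s3": ""}})
        layer = tip_category_proportions(tree, build_presence(table), md,
                                         "cat")
        assert layer.payload["f1"] == {"A": 0.5, MISSING_CATEGORY: 0.5}

    def test_numeric_field_rejected(self, toy):
        tree, table, md = toy
        with pytest.raises(ValueError, match="numeric"):
            tip_category_proportions(tree, build_presence(table), md, "ph")

    def test_reserved_label_collision_rejected(self, toy):
        tree, table, _ = toy
        md = md_from({"cat": {"s1": MISSING_CATEGORY, "s2": "B", "s3": "B"}})
        with pytest.raises(ValueError, match="reserved"):
            tip_category_proportions(tree, build_presence(table), md, "cat")

    def test_orphan_features_warn_or_error(self, toy):
        _, table, md = toy
        tree = read_newick("(f1:1,zz:1)r;")  # f2 not in tree
        pres = build_presence(table)
        with pytest.warns(UserWarning, match="absent from the tree"):
            tip_category_proportions(tree, pres, md, "cat")
        with pytest.raises(ValueError, match="absent from the tree"):
            tip_category_proportions(tree, pres, md, "cat", strict=True)

    def test_proportions_sum_to_one_on_fixture(self):
        nw, table, sample_md, _ = generate_fixture(60, 40, 0.2, seed=11)
        tree = read_newick(nw)
        layer = tip_category_proportions(tree, build_presence(table),
                                         sample_md, "group")
        for tip, pay in layer.payload.items():
            if pay:
                assert sum(pay.values()) == pytest.approx(1.0, abs=1e-9)

    def test_shear_then_compute_equals_restriction(self):
        """Computing layers after shearing matches the full-tree layer
        restricted to shared tips."""
        nw, table, sample_md, _ = generate_fixture(40, 20, 0.3, seed=13,
                                                   feature_coverage=0.6)
        tree = read_newick(nw)
        pres = build_presence(table)
        full = tip_category_proportions(tree, pres, sample_md, "group")
        sheared_tree = tree.shear(set(table.feature_ids))
        sheared = tip_category_proportions(sheared_tree, pres, sample_md,
                                           "group")
        for tip in sheared_tree.tip_names():
            assert sheared.payload[tip] == full.payload[tip]


class TestNumericAggregate:
    def test_mean_median_and_missing_exclusion(self, toy):
        tree, table, md = toy
        pres = build_presence(table)
        mean = feature_numeric_aggregate(pres, md, "ph", "mean")
        # f1 occurs in s1 (ph 6) and s3 (ph missing): mean over {6}
        assert mean["f1"] == 6.0
        assert mean["f2"] == 8.0
        med = feature_numeric_aggregate(pres, md, "ph", "median")
        assert med["f1"] == 6.0

    def test_count_log10(self):
        table = FeatureTable([f"s{i}" for i in range(10)], ["f1"],
                             np.ones((10, 1)))
        md = md_from({"ph": {f"s{i}": "7" for i in range(10)}})
        counts = feature_numeric_aggregate(build_presence(table), md, "ph",
                                           "count_log10")
        assert counts["f1"] == pytest.approx(1.0)

    def test_categorical_field_rejected(self, toy):
        _, table, md = toy
        with pytest.raises(ValueError, match="categorical"):
            feature_numeric_aggregate(build_presence(table), md, "cat",
                                      "mean")

    def test_mean_bounded_by_observed_range(self):
        _, table, sample_md, _ = generate_fixture(50, 30, 0.25, seed=17)
        agg = feature_numeric_aggregate(build_presence(table), sample_md,
                                        "ph", "mean").dropna()
        ph = sample_md.numeric("ph").dropna()
        assert agg.min() >= ph.min() and agg.max() <= ph.max()


class TestMiddleFraction:
    def test_quantile_oracle_on_1_to_100(self):
        md = md_from({"v": {f"s{i}": str(i) for i in range(1, 101)}})
        kept = subset_samples_middle_fraction(md, "v", 0.9)
        # brute force with the linear-interpolation quantile definition
        vals = np.arange(1, 101, dtype=float)
        lo, hi = np.quantile(vals, [0.05, 0.95], method="linear")
        expect = {f"s{i}" for i in range(1, 101) if lo <= i <= hi}
        assert kept == expect
        assert len(kept) == 90 and lo == pytest.approx(5.95)

    def test_keep_all_and_single_sample(self):
        md = md_from({"v": {"s1": "3.5"}})
        assert subset_samples_middle_fraction(md, "v", 1.0) == {"s1"}
        assert subset_samples_middle_fraction(md, "v", 0.5) == {"s1"}

    def test_missing_dropped_and_all_missing_errors(self):
        md = md_from({"v": {"s1": "1", "s2": "", "s3": "3"}})
        assert "s2" not in subset_samples_middle_fraction(md, "v", 1.0)
        # a column with no values at all cannot be subset on
        empty = md_from({"v": {"s1": "", "s2": ""}})
        with pytest.raises(ValueError):
            subset_samples_middle_fraction(empty, "v", 0.9)

    def test_span_mode_differs_from_quantile(self):
        md = md_from({"v": {**{f"s{i}": "1" for i in range(50)},
                            "big": "101"}})
        by_q = subset_samples_middle_fraction(md, "v", 0.5)
        by_span = subset_samples_middle_fraction(md, "v", 0.5, mode="span")
        assert "big" not in by_span and by_q != by_span


class TestPropagateAndCollapse:
    def md(self, mapping):
        return md_from({"grp": mapping}, index_name="#FeatureID")

    def test_uniform_mixed_and_missing_tolerance(self):
        tree = read_newick("((a,b)x,(c,d)y)r;")
        cases = [
            ({"a": "P", "b": "P", "c": "Q", "d": "Q"}, "P", "Q", None),
            ({"a": "P", "b": "Q", "c": "Q", "d": "Q"}, None, "Q", None),
            ({"a": "P", "b": "", "c": "P", "d": "P"}, "P", "P", "P"),
        ]
        for mapping, at_x, at_y, at_r in cases:
            vals = propagate_uniform_metadata(tree, self.md(mapping), "grp")
            assert vals[tree.find_name("x")] == at_x
            assert vals[tree.find_name("y")] == at_y
            assert vals[0] == at_r

    def test_collapse_maximality(self):
        tree = read_newick("((a,b)x,(c)y)r;")
        vals = propagate_uniform_metadata(
            tree, self.md({"a": "P", "b": "P", "c": "Q"}), "grp")
        names = {c.name for c in collapse_uniform_clades(tree, vals)}
        assert names == {"x", "y"}

    def test_all_uniform_collapses_at_root_only(self):
        tree = read_newick("((a,b)x,(c,d)y)r;")
        vals = propagate_uniform_metadata(
            tree, self.md({t: "P" for t in "abcd"}), "grp")
        collapsed = collapse_uniform_clades(tree, vals)
        assert [c.name for c in collapsed] == ["r"]
        assert collapsed[0].tip_count == 4

    def test_exclusion_exposes_inner_uniform_clades(self):
        tree = read_newick("(((a,b)w,c)x,(d,e)y)r;")
        vals = propagate_uniform_metadata(
            tree, self.md({"a": "P", "b": "P", "c": "P",
                           "d": "Q", "e": "Q"}), "grp")
        assert {c.name for c in collapse_uniform_clades(tree, vals)} == \
            {"x", "y"}
        masked = collapse_uniform_clades(tree, vals, exclude={"x"})
        assert {c.name for c in masked} == {"w", "y"}

    def test_collapsed_tip_sets_disjoint_and_value_consistent(self):
        nw, _, _, feature_md = generate_fixture(40, 4, 0.5, seed=23)
        tree = read_newick(nw)
        vals = propagate_uniform_metadata(tree, feature_md, "phylum")
        collapsed = collapse_uniform_clades(tree, vals)
        seen = set()
        col = feature_md.categorical("phylum")
        for cc in collapsed:
            tips = set(tree.descendant_tip_names(cc.position))
            assert not (tips & seen)
            seen |= tips
            for t in tips:
                v = col.get(t, "")
                assert v in ("", cc.value)
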