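"""Sample <-> node linking, biplot arrows, frames, sliding windows."""

import numpy as np
import pandas as pd
import pytest

from conftest import oracle_sliding_windows

from treescape import (
    FeatureTable, MetadataTable, build_frames, build_presence,
    generate_fixture, generate_ordination, generate_record_fixture,
    node_to_samples, read_newick, resolve_biplot_arrow, samples_to_nodes,
    sliding_window_communities, summarize_selection,
)


def md_from(mapping, index_name="#SampleID"):
    df = pd.DataFrame(mapping)
    df.index = pd.Index(df.index.astype(str), name=index_name)
    return MetadataTable(df)


@pytest.fixture
def linked():
    tree = read_newick("((a:1,b:1)x:1,c:1)r;")
    table = FeatureTable(["s1", "s2"], ["a", "b", "c"],
                         [[1.0, 2.0, 0.0], [0.0, 0.0, 3.0]])
    return tree, table, build_presence(table)


class TestSamplesToNodes:
    def test_fully_covered_clade_highlights(self, linked):
        tree, _, pres = linked
        sel = samples_to_nodes({"s1"}, pres, tree)
        names = {tree.name(tree.postorder_select(k)) for k in sel.node_ids}
        assert names == {"a", "b", "x"}

    def test_tips_only_mode(self, linked):
        tree, _, pres = linked
        sel = samples_to_nodes({"s1"}, pres, tree, tips_only=True)
        names = {tree.name(tree.postorder_select(k)) for k in sel.node_ids}
        assert names == {"a", "b"}

    def test_unknown_sample_errors(self, linked):
        tree, _, pres = linked
        with pytest.raises(KeyError):
            samples_to_nodes({"nope"}, pres, tree)

    def test_all_samples_covers_root(self, linked):
        tree, _, pres = linked
        sel = samples_to_nodes({"s1", "s2"}, pres, tree)
        assert tree.postorder_rank(0) in sel.node_ids

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_over_descendant_sets(self, seed):
        nw, table, _, _ = generate_fixture(25, 12, 0.3, seed=seed)
        tree = read_newick(nw)
        pres = build_presence(table)
        rng = np.random.default_rng(seed)
        chosen = set(rng.choice(table.sample_ids, size=3, replace=False))
        sel = samples_to_nodes(chosen, pres, tree)
        covered = set()
        for s in chosen:
            covered |= pres.features_of(s)
        expected = set()
        for p in tree.preorder_positions():
            p = int(p)
            tips = set(tree.descendant_tip_names(p))
            if tips and tips <= covered:
                expected.add(tree.postorder_rank(p))
        assert sel.node_ids == expected


class TestNodeToSamples:
    def test_internal_node_unions_descendants(self, linked):
        tree, _, pres = linked
        k = tree.postorder_rank(tree.find_name("x"))
        assert node_to_samples(k, tree, pres).sample_ids == {"s1"}
        root_k = tree.postorder_rank(0)
        assert node_to_samples(root_k, tree, pres).sample_ids == {"s1", "s2"}

    def test_tip_with_empty_presence(self):
        tree = read_newick("(a,b)r;")
        pres = build_presence(FeatureTable(["s1"], ["a"], [[1.0]]))
        k = tree.postorder_rank(tree.find_name("b"))
        assert node_to_samples(k, tree, pres).sample_ids == set()

    @pytest.mark.parametrize("seed", range(10))
    def test_adjoint_with_samples_to_nodes(self, seed):
        """Every tip is recovered by selecting the samples that contain it."""
        nw, table, _, _ = generate_fixture(20, 10, 0.3, seed=seed)
        tree = read_newick(nw)
        pres = build_presence(table)
        for p in tree.tip_positions():
            p = int(p)
            k = tree.postorder_rank(p)
            samples = node_to_samples(k, tree, pres).sample_ids
            if not samples:
                continue
            back = samples_to_nodes(samples, pres, tree)
            assert k in back.node_ids


class TestSummarize:
    def test_counts_and_missing_pooling(self, linked):
        tree, _, pres = linked
        md = md_from({"cat": {"s1": "A", "s2": ""}})
        sel = node_to_samples(tree.postorder_rank(0), tree, pres)
        assert summarize_selection(sel, md, "cat") == \
            {"A": 1, "__missing__": 1}
        assert sum(summarize_selection(sel, md, "cat").values()) == \
            len(sel.sample_ids)

    def test_empty_selection(self, linked):
        tree, _, pres = linked
        md = md_from({"cat": {"s1": "A", "s2": "B"}})
        from treescape import Selection
        assert summarize_selection(Selection("samples"), md, "cat") == {}


class TestBiplotArrows:
    def test_resolution_to_tip_and_internal(self, linked):
        tree, table, _ = linked
        ordn = generate_ordination(table.sample_ids, seed=1,
                                   feature_ids=["a", "x"])
        ka = resolve_biplot_arrow("a", ordn, tree)
        assert tree.name(tree.postorder_select(ka)) == "a"
        kx = resolve_biplot_arrow("x", ordn, tree)
        assert not tree.is_leaf(tree.postorder_select(kx))

    def test_absent_id_errors(self, linked):
        tree, table, _ = linked
        ordn = generate_ordination(table.sample_ids, seed=1,
                                   feature_ids=["zz"])
        with pytest.raises(KeyError, match="zz"):
            resolve_biplot_arrow("zz", ordn, tree)
        no_biplot = generate_ordination(table.sample_ids, seed=1)
        with pytest.raises(ValueError, match="biplot"):
            resolve_biplot_arrow("a", no_biplot, tree)


class TestFrames:
    def test_unique_features_set_algebra(self):
        table = FeatureTable(
            ["s1", "s2"], ["f1", "f2", "f3"],
            [[1.0, 1.0, 0.0], [0.0, 1.0, 1.0]])
        md = md_from({"t": {"s1": "t1", "s2": "t1"},
                      "traj": {"s1": "X", "s2": "Y"}})
        fs = build_frames(md, "t", "traj", build_presence(table))
        assert fs.frame_keys == ["t1"]
        assert fs.frame_unique["t1"] == {"X": {"f1"}, "Y": {"f3"}}

    def test_single_trajectory_keeps_everything(self):
        table = FeatureTable(["s1"], ["f1", "f2"], [[1.0, 1.0]])
        md = md_from({"t": {"s1": "d1"}, "traj": {"s1": "X"}})
        fs = build_frames(md, "t", "traj", build_presence(table))
        assert fs.frame_unique["d1"]["X"] == {"f1", "f2"}

    def test_identical_sets_cancel(self):
        table = FeatureTable(["s1", "s2"], ["f1"], [[1.0], [1.0]])
        md = md_from({"t": {"s1": "d", "s2": "d"},
                      "traj": {"s1": "X", "s2": "Y"}})
        fs = build_frames(md, "t", "traj", build_presence(table))
        assert fs.frame_unique["d"] == {"X": set(), "Y": set()}

    def test_numeric_gradient_sorts_numerically(self):
        table = FeatureTable([f"s{i}" for i in range(3)], ["f1"],
                             np.ones((3, 1)))
        md = md_from({"day": {"s0": "2", "s1": "10", "s2": "1"},
                      "traj": {f"s{i}": "X" for i in range(3)}})
        fs = build_frames(md, "day", "traj", build_presence(table))
        assert [float(k) for k in fs.frame_keys] == [1.0, 2.0, 10.0]

    @pytest.mark.parametrize("seed", range(5))
    def test_per_frame_disjointness_on_fixtures(self, seed):
        _, table, sample_md, _ = generate_fixture(30, 20, 0.3, seed=seed)
        fs = build_frames(sample_md, "timepoint", "location",
                          build_presence(table))
        for fk in fs.frame_keys:
            trajs = list(fs.frame_unique[fk])
            for i, a in enumerate(trajs):
                for b in trajs[i + 1:]:
                    assert not (fs.frame_unique[fk][a]
                                & fs.frame_unique[fk][b])
                    assert not (fs.frame_samples[fk][a]
                                & fs.frame_samples[fk][b])


class TestSlidingWindows:
    def records(self, md):
        dates = md.categorical("date")
        locs = md.categorical("location")
        return [(r, dates[r], locs[r]) for r in md.ids]

    def test_single_day_burst_yields_one_window(self):
        md = md_from({"date": {f"r{i}": "2020-03-05" for i in range(5)},
                      "location": {f"r{i}": "L" for i in range(5)}},
                     index_name="#RecordID")
        out = sliding_window_communities(md, "date", "location", 7, 5)
        assert out.sample_ids == ["L@2020-03-05"]
        assert out.nnz == 5  # each record once, presence

    def test_below_threshold_empty(self):
        md = md_from({"date": {f"r{i}": "2020-03-05" for i in range(4)},
                      "location": {f"r{i}": "L" for i in range(4)}},
                     index_name="#RecordID")
        out = sliding_window_communities(md, "date", "location", 7, 5)
        assert out.sample_ids == [] and out.nnz == 0

    def test_min_records_one_single_record(self):
        md = md_from({"date": {"r1": "2020-01-01"},
                      "location": {"r1": "L"}}, index_name="#RecordID")
        out = sliding_window_communities(md, "date", "location", 7, 1)
        assert out.sample_ids == ["L@2020-01-01"]
        assert out.value("L@2020-01-01", "r1") == 1.0

    def test_rename_map_merges_locations(self):
        md = md_from({"date": {"r1": "2020-01-01", "r2": "2020-01-02"},
                      "location": {"r1": "Brooklyn", "r2": "Queens"}},
                     index_name="#RecordID")
        out = sliding_window_communities(
            md, "date", "location", 7, 2,
            rename_map={"Brooklyn": "New York", "Queens": "New York"})
        assert all(s.startswith("New York@") for s in out.sample_ids)
        # only the 01-01 window holds both records; the 01-02 window has one
        assert out.sample_ids == ["New York@2020-01-01"]

    def test_unparseable_date_errors(self):
        md = md_from({"date": {"r1": "03/05/2020"},
                      "location": {"r1": "L"}}, index_name="#RecordID")
        with pytest.raises(ValueError, match="r1"):
            sliding_window_communities(md, "date", "location", 7, 1)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        md = generate_record_fixture(40, seed=seed, span_days=20)
        window_days, min_records = 7, 5
        out = sliding_window_communities(md, "date", "location",
                                         window_days, min_records)
        expect = oracle_sliding_windows(self.records(md), window_days,
                                        min_records)
        assert set(out.sample_ids) == set(expect)
        pres = build_presence(out)
        for sid, members in expect.items():
            assert pres.features_of(sid) == set(members)
            assert len(members) >= min_records
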