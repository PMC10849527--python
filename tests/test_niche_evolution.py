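"""Tree surgery, binned niche characters, and Fitch ancestral reconstruction."""

import numpy as np
import pandas as pd
import pytest

from progniche.niche_evolution import (
    ABSENT,
    PRESENT,
    UNCERTAIN,
    NicheCharacterTable,
    build_characters,
    classify_changes,
    insert_tip,
    parsimony_score_bruteforce,
    prune_tip,
    reconstruct,
    tip_depths,
)
from progniche.synthetic_data import DEFAULT_TREE, read_tree

NINE_TIP = DEFAULT_TREE
TIPS = [f"sp{i}" for i in range(1, 10)]


class TestInsertTip:
    def test_halfway_split_places_node_at_half(self):
        tree = read_tree("(a:1.0,b:1.0)r;")
        out = insert_tip(tree, "c", sister="b", fraction=0.5)
        leaf_b = [n for n in out.leaf_node_iter() if n.taxon.label == "b"][0]
        assert leaf_b.parent_node.edge.length == pytest.approx(0.5)
        assert leaf_b.edge.length == pytest.approx(0.5)

    def test_tip_count_increments_and_ultrametric_preserved(self):
        tree = read_tree(NINE_TIP)
        out = insert_tip(tree, "new", sister="sp5", fraction=0.5)
        assert len(out.leaf_nodes()) == 10
        depths = tip_depths(out)
        assert max(depths.values()) - min(depths.values()) < 1e-9

    def test_prune_inverts_insertion(self):
        tree = read_tree(NINE_TIP)
        out = prune_tip(insert_tip(tree, "new", sister="sp5", fraction=0.5), "new")
        orig = tip_depths(tree)
        back = tip_depths(out)
        assert set(back) == set(orig)
        for t in orig:
            assert back[t] == pytest.approx(orig[t], abs=1e-12)
        a, b = clade_depths(out), clade_depths(tree)
        assert set(a) == set(b)
        for clade in a:
            assert a[clade] == pytest.approx(b[clade], abs=1e-12)

    def test_boundary_fractions_rejected(self):
        tree = read_tree("(a:1.0,b:1.0)r;")
        for frac in (0.0, 1.0, -0.2):
            with pytest.raises(ValueError, match="fraction"):
                insert_tip(tree, "c", "b", frac)

    def test_unknown_sister_errors(self):
        tree = read_tree("(a:1.0,b:1.0)r;")
        with pytest.raises(KeyError, match="zz"):
            insert_tip(tree, "c", "zz")

    def test_input_tree_unmodified(self):
        tree = read_tree("(a:1.0,b:1.0)r;")
        before = tree.as_string(schema="newick")
        insert_tip(tree, "c", "b", 0.5)
        assert tree.as_string(schema="newick") == before


def states_table(columns, n_bins=4, lo=0.0, hi=4.0, anchor=False):
    """Hand-built character table; ``anchor`` appends an all-present bin so
    every column satisfies the >=1-present invariant."""
    if anchor:
        columns = {t: list(v) + [PRESENT] for t, v in columns.items()}
        n_bins += 1
    edges = np.linspace(lo, hi, n_bins + 1)
    return NicheCharacterTable("v", edges, pd.DataFrame(columns))


def clade_depths(tree):
    """Map frozenset-of-tip-labels -> node depth, a string-order-free tree key."""
    out = {}
    for node in tree.preorder_node_iter():
        tips = frozenset(l.taxon.label for l in node.leaf_iter())
        d, n = 0.0, node
        while n.parent_node is not None:
            d += n.edge.length or 0.0
            n = n.parent_node
        out[tips] = d
    return out


class TestBuildCharacters:
    def make_inputs(self, occ_vals, bg_vals):
        occ = {t: pd.DataFrame({"v": np.asarray(v, float)}) for t, v in occ_vals.items()}
        bg = {t: pd.DataFrame({"v": np.asarray(v, float)}) for t, v in bg_vals.items()}
        return occ, bg

    def test_full_span_taxon_all_present(self):
        occ, bg = self.make_inputs(
            {"a": np.linspace(0, 10, 50)}, {"a": np.linspace(0, 10, 50)})
        tables = build_characters(occ, bg, n_bins=5)
        assert (tables[0].states["a"] == PRESENT).all()

    def test_bins_outside_m_range_uncertain(self):
        # taxon a's background only reaches 5; the pooled range goes to 10
        occ, bg = self.make_inputs(
            {"a": [1.0, 2.0], "b": [8.0, 9.0]},
            {"a": np.linspace(0, 5, 50), "b": np.linspace(0, 10, 50)})
        tables = build_characters(occ, bg, n_bins=10)
        states = tables[0].states["a"]
        assert (states.iloc[6:] == UNCERTAIN).all()  # bins above 6 inaccessible to a
        assert (states.iloc[:2] == PRESENT).any()

    def test_lower_half_occupancy_matches_membership_oracle(self, rng):
        bg_a = rng.uniform(0, 10, 500)
        occ_a = rng.uniform(0, 5, 200)
        occ, bg = self.make_inputs({"a": occ_a, "b": [9.0]},
                                   {"a": bg_a, "b": rng.uniform(0, 10, 500)})
        tables = build_characters(occ, bg, n_bins=10, trim_percent=0.0)
        t = tables[0]
        for b in range(t.n_bins):
            lo, hi = t.bin_edges[b], t.bin_edges[b + 1]
            last = b == t.n_bins - 1
            in_bin = lambda x: (x >= lo) & ((x <= hi) if last else (x < hi))
            expect = (PRESENT if in_bin(occ_a).any()
                      else ABSENT if in_bin(bg_a).any() else UNCERTAIN)
            assert t.states.loc[b, "a"] == expect

    def test_tail_trimming_suppresses_lone_outlier_presence(self, rng):
        # one stray record far above the bulk should not code the top bin present
        occ_a = np.concatenate([rng.uniform(0, 3, 199), [9.9]])
        occ, bg = self.make_inputs({"a": occ_a, "b": [9.0]},
                                   {"a": np.linspace(0, 10, 500), "b": np.linspace(0, 10, 500)})
        trimmed = build_characters(occ, bg, n_bins=10)[0]
        raw = build_characters(occ, bg, n_bins=10, trim_percent=0.0)[0]
        assert raw.states.loc[9, "a"] == PRESENT
        assert trimmed.states.loc[9, "a"] == ABSENT

    def test_zero_occurrence_taxon_errors(self):
        occ, bg = self.make_inputs({"a": []}, {"a": [1.0]})
        with pytest.raises(ValueError, match="zero occurrences"):
            build_characters(occ, bg)


class TestReconstruct:
    def test_uniform_present_tips_give_present_ancestors(self):
        cols = {t: [PRESENT] * 4 for t in TIPS}
        anc = reconstruct(NINE_TIP, states_table(cols))
        assert (anc.states == PRESENT).all().all()
        assert (anc.score == 0).all()

    def test_two_tip_conflict_gives_ambiguous_root(self):
        table = states_table({"a": [PRESENT], "b": [ABSENT]}, n_bins=1, hi=1.0,
                             anchor=True)
        anc = reconstruct("(a:1.0,b:1.0)root;", table)
        assert anc.states.loc[0, "root"] == UNCERTAIN
        assert anc.score[0] == 1

    def test_tip_states_preserved(self):
        cols = {t: [PRESENT if i % 2 else ABSENT] for i, t in enumerate(TIPS)}
        anc = reconstruct(NINE_TIP, states_table(cols, n_bins=1, hi=1.0, anchor=True))
        for t in TIPS:
            assert anc.states.loc[0, t] == cols[t][0]

    def test_all_uncertain_bin_warns_and_stays_uncertain(self):
        cols = {t: [UNCERTAIN, PRESENT] for t in TIPS}
        with pytest.warns(UserWarning, match="uncertain"):
            anc = reconstruct(NINE_TIP, states_table(cols, n_bins=2, hi=2.0))
        assert anc.states.loc[0, "root"] == UNCERTAIN

    def test_matches_bruteforce_on_random_tables(self, rng):
        for trial in range(20):
            tip_states = {
                t: rng.choice([PRESENT, ABSENT, UNCERTAIN], p=[0.45, 0.45, 0.1])
                for t in TIPS}
            if all(s == UNCERTAIN for s in tip_states.values()):
                continue
            table = states_table({t: [s] for t, s in tip_states.items()},
                                 n_bins=1, hi=1.0, anchor=True)
            anc = reconstruct(NINE_TIP, table)
            best, roots = parsimony_score_bruteforce(NINE_TIP, tip_states)
            assert anc.score[0] == best
            expect = roots.pop() if len(roots) == 1 else UNCERTAIN
            assert anc.states.loc[0, "root"] == expect

    def test_invariant_to_tip_order_permutation(self, rng):
        cols = {t: list(rng.choice([PRESENT, ABSENT], size=3)) for t in TIPS}
        t1 = states_table(cols, n_bins=3, hi=3.0, anchor=True)
        shuffled = {t: cols[t] for t in rng.permutation(TIPS)}
        t2 = states_table(shuffled, n_bins=3, hi=3.0, anchor=True)
        a1 = reconstruct(NINE_TIP, t1)
        a2 = reconstruct(NINE_TIP, t2)
        pd.testing.assert_frame_equal(
            a1.states.sort_index(axis=1), a2.states.sort_index(axis=1))

    def test_missing_tip_column_errors(self):
        table = states_table({"sp1": [PRESENT]}, n_bins=1, hi=1.0)
        with pytest.raises(ValueError, match="lacks"):
            reconstruct(NINE_TIP, table)


class TestClassifyChanges:
    def test_identical_parent_child_no_changes(self):
        cols = {t: [PRESENT, ABSENT] for t in TIPS}
        anc = reconstruct(NINE_TIP, states_table(cols, n_bins=2, hi=2.0))
        summary = classify_changes(anc, NINE_TIP)
        assert (summary["expansion"] == 0).all()
        assert (summary["contraction"] == 0).all()

    def test_gain_and_loss_counts(self):
        # two-tip tree: root resolves ambiguous on conflicting bins
        cols = {"a": [PRESENT, PRESENT, ABSENT], "b": [PRESENT, ABSENT, ABSENT]}
        anc = reconstruct("(a:1.0,b:1.0)root;", states_table(cols, n_bins=3, hi=3.0))
        summary = classify_changes(anc, "(a:1.0,b:1.0)root;").set_index("child")
        # bin 0 agrees (present), bin 2 agrees (absent), bin 1 root is ambiguous
        assert summary.loc["a", "ambiguous"] == 1
        assert summary.loc["a", "expansion"] == 0
        assert summary.loc["b", "contraction"] == 0

    def test_derived_absence_counted_as_contraction(self):
        cols = {t: [PRESENT] for t in TIPS}
        cols["sp9"] = [ABSENT]
        anc = reconstruct(NINE_TIP, states_table(cols, n_bins=1, hi=1.0, anchor=True))
        summary = classify_changes(anc, NINE_TIP).set_index("child")
        assert summary.loc["sp9", "contraction"] == 1
        assert summary["expansion"].sum() == 0
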