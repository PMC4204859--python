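"""Dollo parsimony reconstruction, dating and summaries."""

import itertools

import dendropy
import pandas as pd
import pytest

from conftest import (
    OracleTree,
    enumerate_rooted_topologies,
    oracle_is_feasible,
    oracle_min_losses,
    topology_to_tree,
)
from intronarch import fixtures as fx
from intronarch.dollo import (
    annotate_ages,
    dollo_reconstruct,
    event_summary,
    reconstruct_ledger,
)


def rooted(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=newick, schema="newick", rooting="force-rooted", preserve_underscores=True
    )


SIX_LEAF = rooted("((a,b)ab,((c,d)cd,(e,f)ef)cdef)root;")


class TestReconstruct:
    def test_all_present_single_root_gain(self):
        gain, losses = dollo_reconstruct(
            {t: "present" for t in "abcdef"}, SIX_LEAF
        )
        assert gain == "root" and losses == []

    def test_single_absent_leaf_terminal_loss(self):
        states = {t: "present" for t in "abcdef"}
        states["c"] = "absent"
        gain, losses = dollo_reconstruct(states, SIX_LEAF)
        assert gain == "root" and losses == ["c"]

    def test_clade_absence_one_internal_loss(self):
        states = dict(a="present", b="present", c="absent", d="absent", e="present", f="present")
        gain, losses = dollo_reconstruct(states, SIX_LEAF)
        assert gain == "root" and losses == ["cd"]

    def test_two_losses_pattern(self):
        """Absent in a 2-leaf clade plus one extra leaf: two losses, matching
        the exhaustive minimum."""
        states = dict(a="present", b="absent", c="absent", d="absent", e="present", f="present")
        gain, losses = dollo_reconstruct(states, SIX_LEAF)
        assert gain == "root"
        assert sorted(losses) == ["b", "cd"]
        ot = OracleTree(SIX_LEAF)
        assert oracle_min_losses(ot, states) == 2

    def test_gain_at_mrca_of_carriers(self):
        states = dict(a="absent", b="absent", c="present", d="present", e="present", f="absent")
        gain, losses = dollo_reconstruct(states, SIX_LEAF)
        assert gain == "cdef" and losses == ["f"]

    def test_unknown_never_forces_loss(self):
        states = dict(a="present", b="present", c="unknown", d="unknown", e="present", f="present")
        gain, losses = dollo_reconstruct(states, SIX_LEAF)
        assert gain == "root" and losses == []

    def test_adding_unknown_taxon_changes_nothing(self):
        base = dict(a="present", b="absent", c="present", d="present", e="present", f="present")
        with_unknown = dict(base)
        del base["f"]
        with_unknown["f"] = "unknown"
        assert dollo_reconstruct(base, SIX_LEAF) == dollo_reconstruct(with_unknown, SIX_LEAF)

    def test_absent_everywhere(self):
        assert dollo_reconstruct({t: "absent" for t in "abcdef"}, SIX_LEAF) == (None, [])

    def test_unrooted_rejected(self):
        tree = dendropy.Tree.get(data="((a,b),(c,d));", schema="newick")
        tree.is_rooted = False
        with pytest.raises(ValueError, match="rooted"):
            dollo_reconstruct({t: "present" for t in "abcd"}, tree)

    def test_non_leaf_taxon_rejected(self):
        with pytest.raises(ValueError):
            dollo_reconstruct({"zz": "present"}, SIX_LEAF)

    def test_zero_losses_iff_carriers_form_clade(self):
        """On all 4-leaf topologies x all patterns: losses vanish exactly when
        the carrier set is a clade."""
        leaves = ("a", "b", "c", "d")
        for topo in enumerate_rooted_topologies(leaves):
            tree = topology_to_tree(topo)
            clades = {
                frozenset(lf.taxon.label for lf in n.leaf_iter())
                for n in tree.preorder_node_iter()
            }
            for bits in itertools.product([0, 1], repeat=4):
                if not any(bits):
                    continue
                states = {t: "present" if b else "absent" for t, b in zip(leaves, bits)}
                present = frozenset(t for t, b in zip(leaves, bits) if b)
                _, losses = dollo_reconstruct(states, tree)
                assert (losses == []) == (present in clades)

    def test_matches_exhaustive_oracle_small_trees(self):
        """Spot equivalence with the brute-force single-gain/minimal-loss
        search on every 4-leaf topology, including unknown states."""
        leaves = ("a", "b", "c", "d")
        for topo in enumerate_rooted_topologies(leaves):
            tree = topology_to_tree(topo)
            ot = OracleTree(tree)
            for combo in itertools.product(["present", "absent", "unknown"], repeat=4):
                states = dict(zip(leaves, combo))
                gain, losses = dollo_reconstruct(states, tree)
                expected = oracle_min_losses(ot, states)
                if expected is None:
                    assert gain is None and losses == []
                else:
                    assert len(losses) == expected
                    assert oracle_is_feasible(ot, states, gain, losses)


class TestAgesAndSummary:
    def test_dated_fixture_events(self):
        tree = fx.dated_tree()
        ledger = reconstruct_ledger(fx.dated_presence().T, tree)
        dated = annotate_ages(ledger, fx.node_ages(), tree)
        assert dated["i7l"].gain_age == 855
        assert dated["i3l"].loss_ages == [372]
        assert dated["i3l"].gain_age == 783
        assert 300 in dated["i7c"].loss_ages

    def test_missing_age_lists_nodes(self):
        tree = fx.dated_tree()
        ledger = reconstruct_ledger(fx.dated_presence().T, tree)
        ages = fx.node_ages()
        del ages["N3"]
        with pytest.raises(ValueError, match="N3"):
            annotate_ages(ledger, ages, tree)

    def test_empty_ledger(self):
        tree = fx.dated_tree()
        empty = reconstruct_ledger(pd.DataFrame(index=fx.dated_presence().columns), tree)
        dated = annotate_ages(empty, fx.node_ages(), tree)
        assert list(dated) == []

    def test_hymenoptera_site_sharing(self, table_matrix):
        formicids = {"A_cephalotes", "S_invicta", "C_floridanus", "H_saltator"}
        hymenoptera = formicids | {"A_mellifera", "B_impatiens", "M_rotundata"}
        carriers = lambda lab: {
            sp for sp in table_matrix.index if table_matrix.at[sp, lab] == "present"
        }
        assert carriers("i2h") == hymenoptera
        assert carriers("i4h") == hymenoptera
        assert carriers("i3h") == formicids  # family-specific site

    def test_event_summary_counts(self, table_matrix):
        hym = fx.hymenoptera_table()
        group = {row["species"]: row["family"] for _, row in hym.iterrows()}
        group.update({sp: "other" for sp in table_matrix.index if sp not in group})
        tree = fx.dated_tree()
        ledger = reconstruct_ledger(fx.dated_presence().T, tree)
        summary = event_summary(ledger, table_matrix, group)
        counts = summary["taxon_counts"]
        assert counts.at["S_frugiperda", "n_sites"] == 11
        # i3h is carried only by formicids -> private to that family
        assert counts.at["S_invicta", "n_private_sites"] >= 1
        assert counts.at["A_mellifera", "n_private_sites"] == 0
        totals = summary["branch_totals"]
        assert totals["gains"].sum() == len(list(ledger))

    def test_no_events_all_zero(self):
        tree = fx.dated_tree()
        matrix = pd.DataFrame(
            {"sX": {lf.taxon.label: "absent" for lf in tree.leaf_node_iter()}}
        )
        ledger = reconstruct_ledger(matrix, tree)
        assert ledger["sX"].gain_branch is None
        assert ledger.branch_totals().empty
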