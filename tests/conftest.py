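"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
from typing import Iterable, Iterator

import dendropy
import pytest

from intronarch import fixtures as fx
from intronarch.dollo import ensure_node_ids
from intronarch.projection import (
    auto_label_remaining,
    cluster_sites,
    label_clusters,
    presence_absence,
)

# ---------------------------------------------------------------------------
# published-table clusters


def build_table_clusters():
    """Cluster + label the packaged table sites with the three lineage passes."""
    sites = fx.aligned_sites_from_tables()
    clusters = cluster_sites(sites)
    clusters = label_clusters(clusters, "S_frugiperda", "l")
    clusters = label_clusters(clusters, ["A_mellifera", "S_invicta"], "h")
    clusters = label_clusters(clusters, "H_sapiens", "c")
    return auto_label_remaining(clusters)


@pytest.fixture(scope="session")
def table_clusters():
    return build_table_clusters()


@pytest.fixture(scope="session")
def table_matrix(table_clusters):
    return presence_absence(
        table_clusters,
        fx.all_table_species(),
        truncated_before=fx.truncated_before_columns(),
    )


# ---------------------------------------------------------------------------
# exhaustive Dollo oracle: enumerate every gain placement, search loss-branch
# subsets by increasing size, entirely independent of the implementation


def enumerate_rooted_topologies(leaves: tuple[str, ...]) -> Iterator[object]:
    """All rooted binary labeled topologies on ``leaves`` as nested tuples."""
    if len(leaves) == 1:
        yield leaves[0]
        return
    first, rest = leaves[0], leaves[1:]
    for r in range(len(rest)):
        for combo in itertools.combinations(rest, r):
            side_a = (first,) + combo
            side_b = tuple(x for x in rest if x not in combo)
            if not side_b:
                continue
            for ta in enumerate_rooted_topologies(side_a):
                for tb in enumerate_rooted_topologies(side_b):
                    yield (ta, tb)


def topology_to_tree(topology: object) -> dendropy.Tree:
    def to_newick(node: object) -> str:
        if isinstance(node, str):
            return node
        a, b = node
        return f"({to_newick(a)},{to_newick(b)})"

    tree = dendropy.Tree.get(
        data=to_newick(topology) + ";",
        schema="newick",
        rooting="force-rooted",
        preserve_underscores=True,
    )
    ensure_node_ids(tree)
    return tree


class OracleTree:
    """Precomputed node/ancestry tables for brute-force Dollo search."""

    def __init__(self, tree: dendropy.Tree) -> None:
        ensure_node_ids(tree)
        self.nodes = list(tree.preorder_node_iter())
        self.leaves_below = {
            n.node_id: frozenset(lf.taxon.label for lf in n.leaf_iter())
            for n in self.nodes
        }
        self.descendant_ids = {
            n.node_id: [d.node_id for d in n.preorder_iter() if d is not n]
            for n in self.nodes
        }
        # per leaf: ids of itself and all ancestors
        self.ancestry: dict[str, frozenset[str]] = {}
        for n in self.nodes:
            if n.is_leaf():
                ids = []
                cur = n
                while cur is not None:
                    ids.append(cur.node_id)
                    cur = cur.parent_node
                self.ancestry[n.taxon.label] = frozenset(ids)


def oracle_min_losses(ot: OracleTree, states: dict[str, str]) -> int | None:
    """Minimal loss count over every single-gain scenario; None if no taxon
    is present."""
    present = {t for t, s in states.items() if s == "present"}
    absent = {t for t, s in states.items() if s == "absent"}
    if not present:
        return None
    best: int | None = None
    for gain in ot.nodes:
        gid = gain.node_id
        if not present <= ot.leaves_below[gid]:
            continue
        edges = ot.descendant_ids[gid]
        clade_leaves = ot.leaves_below[gid]
        absent_in = [t for t in absent if t in clade_leaves]
        cap = len(absent_in) if best is None else min(len(absent_in), best - 1)
        for size in range(0, cap + 1):
            found = False
            for losses in itertools.combinations(edges, size):
                loss_set = set(losses)
                ok = True
                for t in clade_leaves:
                    covered = bool(ot.ancestry[t] & loss_set)
                    if t in present and covered:
                        ok = False
                        break
                    if t in absent_in and not covered:
                        ok = False
                        break
                if ok:
                    found = True
                    break
            if found:
                best = size if best is None else min(best, size)
                break
    return best


def oracle_is_feasible(
    ot: OracleTree, states: dict[str, str], gain: str | None, losses: Iterable[str]
) -> bool:
    """Does (gain, losses) explain the pattern under the Dollo model?"""
    present = {t for t, s in states.items() if s == "present"}
    absent = {t for t, s in states.items() if s == "absent"}
    if gain is None:
        return not present
    if not present <= ot.leaves_below[gain]:
        return False
    loss_set = set(losses)
    if not loss_set <= set(ot.descendant_ids[gain]):
        return False
    for t in ot.leaves_below[gain]:
        covered = bool(ot.ancestry[t] & loss_set)
        if t in present and covered:
            return False
        if t in absent and not covered:
            return False
    for t in present:
        if t not in ot.leaves_below[gain]:
            return False
    return True
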