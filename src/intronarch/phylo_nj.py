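"""Distance-based phylogeny: p-distances, neighbor-joining, bootstrap.

Implements the classical pipeline used for quick protein phylogenies:
pairwise p-distances (fraction of differing residues over retained columns,
with complete or pairwise gap deletion), Saitou & Nei neighbor-joining with
the standard Q criterion, and nonparametric bootstrap support mapped onto
the bipartitions of the full-data tree.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "p_distance",
    "nj_tree",
    "tree_splits",
    "bootstrap_support",
]

_GAPS = frozenset("-.?Xx*")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of pairwise distances over an ordered taxon list."""

    taxa: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxon count")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("diagonal must be zero")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        object.__setattr__(self, "values", v)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.taxa.index(pair[0])
        j = self.taxa.index(pair[1])
        return float(self.values[i, j])


def _columns_mask(rows: list[str], mode: str) -> np.ndarray:
    arr = np.array([list(r) for r in rows])
    gap = np.isin(arr, list(_GAPS))
    if mode == "complete":
        return ~gap.any(axis=0)
    if mode == "pairwise":
        return np.ones(arr.shape[1], dtype=bool)
    raise ValueError(f"unknown deletion mode {mode!r}")


def p_distance(msa: Mapping[str, str], deletion_mode: str = "complete") -> DistanceMatrix:
    """Pairwise p-distances on an aligned protein (or nucleotide) set.

    ``complete`` deletion (default) drops every column that has a gap or
    missing character in *any* sequence before counting differences;
    ``pairwise`` deletion drops gapped columns per pair.
    """
    taxa = tuple(msa)
    if len(taxa) < 2:
        raise ValueError("need at least two sequences")
    lengths = {len(msa[t]) for t in taxa}
    if len(lengths) != 1:
        raise ValueError("sequences must have equal aligned length")
    rows = [msa[t].upper() for t in taxa]
    arr = np.array([list(r) for r in rows])
    gap = np.isin(arr, list(_GAPS))
    n = len(taxa)
    d = np.zeros((n, n))
    if deletion_mode == "complete":
        keep = ~gap.any(axis=0)
        if not keep.any():
            raise ValueError("no columns retained under complete deletion")
        sub = arr[:, keep]
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = np.mean(sub[i] != sub[j])
    elif deletion_mode == "pairwise":
        for i in range(n):
            for j in range(i + 1, n):
                keep = ~(gap[i] | gap[j])
                if not keep.any():
                    raise ValueError(
                        f"no columns retained under pairwise deletion for "
                        f"({taxa[i]}, {taxa[j]})"
                    )
                d[i, j] = d[j, i] = np.mean(arr[i, keep] != arr[j, keep])
    else:
        raise ValueError(f"unknown deletion mode {deletion_mode!r}")
    return DistanceMatrix(taxa, d)


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree from a distance matrix.

    Standard Q-criterion agglomeration; when several pairs tie for the
    minimal Q the pair with the lowest taxon indices is joined, which makes
    the output deterministic.  Negative branch-length estimates are clamped
    to zero (with a warning), following the convention of mainstream
    phylogenetics software.  The returned tree is unrooted (trifurcating
    seed node); ``tree.length()`` gives the total branch length.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor-joining needs at least 3 taxa")

    taxon_ns = dendropy.TaxonNamespace([str(t) for t in dm.taxa])
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    nodes: list[dendropy.Node] = []
    for t in dm.taxa:
        node = dendropy.Node(taxon=taxon_ns.get_taxon(str(t)))
        nodes.append(node)
    d = dm.values.copy()
    active = list(range(n))
    clamped = False

    def join(i_pos: int, j_pos: int) -> None:
        nonlocal d, active, clamped
        i, j = active[i_pos], active[j_pos]
        r = len(active)
        ri = d[i, [k for k in active]].sum()
        rj = d[j, [k for k in active]].sum()
        vi = 0.5 * d[i, j] + (ri - rj) / (2 * (r - 2))
        vj = d[i, j] - vi
        if vi < 0 or vj < 0:
            clamped = True
            vi, vj = max(vi, 0.0), max(vj, 0.0)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = vi
        parent.add_child(nodes[j])
        nodes[j].edge.length = vj
        # distances from the new node u to every other active node k
        new_row = np.zeros(d.shape[0] + 1)
        d = np.pad(d, ((0, 1), (0, 1)))
        u = d.shape[0] - 1
        for k in active:
            if k in (i, j):
                continue
            d[u, k] = d[k, u] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        nodes.append(parent)
        active.remove(i)
        active.remove(j)
        active.append(u)

    while len(active) > 3:
        r = len(active)
        sub = d[np.ix_(active, active)]
        rowsums = sub.sum(axis=1)
        q = (r - 2) * sub - rowsums[:, None] - rowsums[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index tie-break: scan in index order
        best = None
        best_q = np.inf
        for a in range(r):
            for b in range(a + 1, r):
                if q[a, b] < best_q - 1e-12:
                    best_q = q[a, b]
                    best = (a, b)
        join(*best)

    # resolve the final three lineages around the central node
    i, j, k = active
    vi = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    vj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    vk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    lengths = [vi, vj, vk]
    if any(v < 0 for v in lengths):
        clamped = True
        lengths = [max(v, 0.0) for v in lengths]
    center = dendropy.Node()
    for idx, v in zip((i, j, k), lengths):
        center.add_child(nodes[idx])
        nodes[idx].edge.length = v
    tree.seed_node = center
    tree.is_rooted = False
    if clamped:
        warnings.warn("negative NJ branch length(s) clamped to 0", stacklevel=2)
    tree.update_bipartitions(suppress_unifurcations=False)
    return tree


def tree_splits(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an (un)rooted tree.

    Each split is represented by the leaf-label set on the side *not*
    containing the lexicographically first taxon, so representations are
    comparable across trees on the same taxa.
    """
    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    anchor = labels[0]
    all_set = set(labels)
    splits: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = {lf.taxon.label for lf in node.leaf_iter()}
        side = below if anchor not in below else all_set - below
        if 1 < len(side) < len(labels) - 1:
            splits.add(frozenset(side))
    return splits


def bootstrap_support(
    msa: Mapping[str, str],
    replicates: int,
    seed: int,
    deletion_mode: str = "complete",
) -> tuple[dendropy.Tree, dict[frozenset[str], float]]:
    """Bootstrap support for the bipartitions of the full-data NJ tree.

    Columns are resampled with replacement ``replicates`` times; support for
    each original bipartition is the percentage of replicate NJ trees that
    contain it.  Reproducible for a given ``seed``.  Returns the full-data
    tree with ``support`` annotations on internal edges plus the raw
    split -> percent mapping.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    taxa = list(msa)
    rows = [msa[t] for t in taxa]
    ncols = len(rows[0])
    original = nj_tree(p_distance(msa, deletion_mode))
    target_splits = tree_splits(original)
    counts = {s: 0 for s in target_splits}
    rng = np.random.default_rng(seed)
    for _ in range(replicates):
        idx = rng.integers(0, ncols, size=ncols)
        resampled = {t: "".join(r[c] for c in idx) for t, r in zip(taxa, rows)}
        try:
            rep_tree = nj_tree(p_distance(resampled, deletion_mode))
        except ValueError:
            logger.warning("bootstrap replicate dropped (no retained columns)")
            continue
        rep_splits = tree_splits(rep_tree)
        for s in target_splits:
            if s in rep_splits:
                counts[s] += 1
    support = {s: 100.0 * c / replicates for s, c in counts.items()}
    labels = sorted(lf.taxon.label for lf in original.leaf_node_iter())
    anchor = labels[0]
    all_set = set(labels)
    for node in original.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = {lf.taxon.label for lf in node.leaf_iter()}
        side = frozenset(below if anchor not in below else all_set - below)
        if side in support:
            node.label = f"{support[side]:.0f}"
    return original, support
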