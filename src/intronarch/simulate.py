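"""Synthetic intron gain/loss histories with full ground truth.

Generates the complete input bundle the pipeline consumes — a rooted species
tree, per-taxon gene models, a protein alignment carrying the intron sites,
and start-codon context windows — from a single seeded configuration, while
recording the true history (which branch gained each site, which branches
lost it, where every site sits in the alignment).  This makes every stage of
the analysis testable end to end: reconstruction output can be compared
against the simulated truth instead of against itself.

The generator emulates the data regime of deep-time single-copy gene
comparisons: a conserved protein with a stable length, intron sites gained
once on a branch (Dollo-consistent, no convergent gain) and lost
independently in descendant lineages, clade-dependent intron length scales
(log-normal; some clades carry kilobase introns, others sub-100-bp ones),
and a low substitution rate so the alignment stays trivially correct.  By
default proteins evolve without indels, so residue index equals alignment
column and the site-to-column map is exact; an optional deletion mode
introduces gaps to stress gap-aware projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .dollo import ensure_node_ids
from .gene_models import GeneModel

__all__ = [
    "SimulationConfig",
    "TrueSite",
    "GroundTruth",
    "SimulatedData",
    "random_tree",
    "simulate_history",
    "simulate_contexts",
]

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_RNA = np.array(list("AUGC"))


@dataclass
class SimulationConfig:
    """Knobs of the history simulator.

    ``loss_rate`` and ``gain_rate`` are expected events per branch (losses
    are realised as "at least one Poisson event", i.e. probability
    ``1 - exp(-loss_rate)`` per branch).  ``n_sites`` fixes the total number
    of simulated sites: ``n_ancestral_sites`` of them start at the root, the
    rest gain on branches drawn uniformly at random.  Intron lengths are
    log-normal with a per-clade mean-log (``clade_log_scale`` maps an
    internal-node id to the mean-log used by every leaf below it).
    """

    seed: int = 0
    n_leaves: int = 8
    tree_newick: str | None = None
    n_sites: int = 20
    n_ancestral_sites: int = 11
    loss_rate: float = 0.3
    gain_rate: float = 0.2
    protein_length: int = 561
    substitution_rate: float = 0.05
    intron_log_mean: float = 6.7  # ~800 bp median
    intron_log_sd: float = 1.0
    clade_log_scale: dict[str, float] = field(default_factory=dict)
    deletion_rate: float = 0.0  # per-residue, per-leaf; >0 stresses gap handling


@dataclass(frozen=True)
class TrueSite:
    """Ground truth for one simulated site."""

    label: str
    residue_index: int
    phase: int
    column: int
    gain_branch: str
    loss_branches: tuple[str, ...]
    identifiable: bool  # true history is the unique minimal Dollo explanation


@dataclass
class GroundTruth:
    sites: dict[str, TrueSite]
    presence: pd.DataFrame  # leaves x site labels, 1/0


@dataclass
class SimulatedData:
    tree: dendropy.Tree
    gene_models: dict[str, GeneModel]
    msa: dict[str, str]
    truth: GroundTruth


def random_tree(n_leaves: int, rng: np.random.Generator) -> dendropy.Tree:
    """Random rooted binary tree over leaves t1..tn (random joins,
    exponential branch lengths)."""
    if n_leaves < 2:
        raise ValueError("need at least two leaves")
    ns = dendropy.TaxonNamespace([f"t{i+1}" for i in range(n_leaves)])
    nodes = [dendropy.Node(taxon=ns.get_taxon(f"t{i+1}")) for i in range(n_leaves)]
    for node in nodes:
        node.edge.length = float(rng.exponential(1.0))
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.edge.length = float(rng.exponential(1.0))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = nodes[0]
    tree.seed_node.edge.length = None
    tree.is_rooted = True
    return tree


def _branches(tree: dendropy.Tree) -> list[dendropy.Node]:
    """All non-root nodes (each identifies the branch above it)."""
    return [n for n in tree.preorder_node_iter() if n.parent_node is not None]


def simulate_history(config: SimulationConfig) -> SimulatedData:
    """Simulate sites, sequences and gene models along a species tree.

    Deterministic for a given config: identical seeds give identical output.
    """
    rng = np.random.default_rng(config.seed)
    if config.tree_newick is not None:
        tree = dendropy.Tree.get(
            data=config.tree_newick, schema="newick", rooting="force-rooted",
            preserve_underscores=True,
        )
    else:
        tree = random_tree(config.n_leaves, rng)
    ensure_node_ids(tree)
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    node_by_id = {n.node_id: n for n in tree.preorder_node_iter()}
    branches = _branches(tree)

    if config.n_sites < config.n_ancestral_sites:
        raise ValueError("n_sites must be >= n_ancestral_sites")
    if config.n_sites > config.protein_length - 1:
        raise ValueError("more sites than distinct residue positions")

    # distinct residue positions, sorted 5'->3'; random phases
    positions = np.sort(
        rng.choice(np.arange(1, config.protein_length), size=config.n_sites, replace=False)
    )
    phases = rng.integers(0, 3, size=config.n_sites)

    p_loss = 1.0 - float(np.exp(-config.loss_rate))
    sites: dict[str, TrueSite] = {}
    presence_rows: dict[str, dict[str, int]] = {lf: {} for lf in leaves}

    for k in range(config.n_sites):
        label = f"s{k+1}"
        if k < config.n_ancestral_sites:
            gain_node = tree.seed_node
        else:
            gain_node = branches[int(rng.integers(0, len(branches)))]
        # losses: each branch strictly below the gain node may lose the site;
        # a subtree below a loss is never revisited (no regain under Dollo)
        losses: list[str] = []
        present_leaves: set[str] = set()

        def descend(node: dendropy.Node) -> None:
            if node.is_leaf():
                present_leaves.add(node.taxon.label)
                return
            for child in node.child_nodes():
                if rng.random() < p_loss:
                    losses.append(child.node_id)
                else:
                    descend(child)

        descend(gain_node)
        for lf in leaves:
            presence_rows[lf][label] = 1 if lf in present_leaves else 0
        identifiable = _is_identifiable(tree, gain_node, losses, present_leaves)
        sites[label] = TrueSite(
            label=label,
            residue_index=int(positions[k]),
            phase=int(phases[k]),
            column=int(positions[k]),
            gain_branch=gain_node.node_id,
            loss_branches=tuple(losses),
            identifiable=identifiable,
        )

    presence = pd.DataFrame.from_dict(presence_rows, orient="index").reindex(
        columns=[f"s{k+1}" for k in range(config.n_sites)]
    )

    msa = _evolve_proteins(tree, config, rng)
    gene_models = _leaf_gene_models(tree, config, rng, sites, presence, msa)
    return SimulatedData(
        tree=tree,
        gene_models=gene_models,
        msa=msa,
        truth=GroundTruth(sites=sites, presence=presence),
    )


def _is_identifiable(
    tree: dendropy.Tree,
    gain_node: dendropy.Node,
    losses: Sequence[str],
    present_leaves: set[str],
) -> bool:
    """True when the simulated events are the unique minimal explanation.

    Requires (a) surviving carriers on >= 2 child lineages of the gain node
    (or a leaf gain), so the carriers' MRCA is the gain node itself, and
    (b) every loss branch to have a surviving carrier somewhere outside it
    under its parent, so sibling losses cannot be merged into one cheaper
    loss higher up.  Both are structural properties of the true history;
    no reconstruction is run here.
    """
    if not present_leaves:
        return False
    if not gain_node.is_leaf():
        children_with_carriers = sum(
            1
            for child in gain_node.child_nodes()
            if present_leaves & {lf.taxon.label for lf in child.leaf_iter()}
        )
        if children_with_carriers < 2:
            return False
    loss_set = set(losses)
    node_by_id = {n.node_id: n for n in tree.preorder_node_iter()}
    for branch in losses:
        parent = node_by_id[branch].parent_node
        carriers_elsewhere = False
        for sib in parent.child_nodes():
            if sib.node_id == branch:
                continue
            if present_leaves & {lf.taxon.label for lf in sib.leaf_iter()}:
                carriers_elsewhere = True
        if not carriers_elsewhere:
            return False
    return True


def _evolve_proteins(
    tree: dendropy.Tree, config: SimulationConfig, rng: np.random.Generator
) -> dict[str, str]:
    L = config.protein_length
    root_seq = rng.choice(len(AMINO_ACIDS), size=L)
    seqs: dict[dendropy.Node, np.ndarray] = {tree.seed_node: root_seq}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_seq = seqs[node.parent_node].copy()
        hits = rng.random(L) < config.substitution_rate
        if hits.any():
            shift = rng.integers(1, len(AMINO_ACIDS), size=int(hits.sum()))
            parent_seq[hits] = (parent_seq[hits] + shift) % len(AMINO_ACIDS)
        seqs[node] = parent_seq
    msa: dict[str, str] = {}
    for lf in tree.leaf_node_iter():
        chars = AMINO_ACIDS[seqs[lf]].copy()
        if config.deletion_rate > 0:
            gaps = rng.random(L) < config.deletion_rate
            chars = np.where(gaps, "-", chars)
        msa[lf.taxon.label] = "".join(chars)
    return msa


def _leaf_gene_models(
    tree: dendropy.Tree,
    config: SimulationConfig,
    rng: np.random.Generator,
    sites: Mapping[str, TrueSite],
    presence: pd.DataFrame,
    msa: Mapping[str, str],
) -> dict[str, GeneModel]:
    log_mean_by_leaf: dict[str, float] = {}
    for lf in tree.leaf_node_iter():
        mean = config.intron_log_mean
        node = lf
        while node is not None:
            if node.node_id in config.clade_log_scale:
                mean = config.clade_log_scale[node.node_id]
                break
            node = node.parent_node
        log_mean_by_leaf[lf.taxon.label] = mean
    models: dict[str, GeneModel] = {}
    for leaf in presence.index:
        row = msa[leaf]
        # residue numbering of this leaf's own (possibly deletion-shortened) CDS
        leaf_res = []
        seen = 0
        for ch in row:
            leaf_res.append(seen)
            if ch != "-":
                seen += 1
        cds_length = 3 * (seen + 1)  # stop codon included
        carried = [
            sites[lab]
            for lab in presence.columns
            if presence.at[leaf, lab] == 1
            and (config.deletion_rate == 0 or row[sites[lab].column] != "-")
        ]
        carried.sort(key=lambda s: (s.residue_index, s.phase))
        offsets = [3 * leaf_res[s.column] + s.phase for s in carried]
        lengths = [
            max(30, int(rng.lognormal(log_mean_by_leaf[leaf], config.intron_log_sd)))
            for _ in carried
        ]
        exon_lengths = []
        prev = 0
        for off in offsets:
            exon_lengths.append(off - prev)
            prev = off
        exon_lengths.append(cds_length - prev)
        models[leaf] = GeneModel.from_exon_lengths(leaf, exon_lengths, lengths)
    return models


def simulate_contexts(pfm: pd.DataFrame, n: int, seed: int) -> list[str]:
    """Draw ``n`` 10-nt start-context windows position-independently from a
    percentage PFM (rows = positions -10..-1, columns A/U/G/C)."""
    rng = np.random.default_rng(seed)
    cols = [c for c in ("A", "U", "G", "C") if c in pfm.columns]
    windows = np.empty((n, len(pfm.index)), dtype="<U1")
    for j, pos in enumerate(pfm.index):
        probs = pfm.loc[pos, cols].to_numpy(dtype=float)
        probs = probs / probs.sum()
        windows[:, j] = rng.choice(np.array(cols), size=n, p=probs)
    return ["".join(w) for w in windows]
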