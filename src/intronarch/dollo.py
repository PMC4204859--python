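"""Dollo parsimony reconstruction of intron gain/loss histories.

Each intron insertion site is treated as a binary character evolving on a
rooted species tree under the Dollo constraint: the site is gained exactly
once (complex characters do not arise twice independently) and may then be
lost any number of times.  The reconstruction places the single gain on the
branch above the most recent common ancestor of all taxa carrying the site
and explains every absence inside that clade with the smallest possible set
of loss branches — the maximal subtrees containing no carrier.

Taxa with unknown state (e.g. 5'-truncated gene models) are treated as
missing data: they never force a loss and never pull the gain deeper.

Events live on branches and are identified by the branch's child node; they
are dated with the age of the branch's *parent* node, i.e. the divergence
that opens the branch.  A gain at the root carries the root's own age.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd

__all__ = [
    "SiteEvents",
    "EventLedger",
    "ensure_node_ids",
    "dollo_reconstruct",
    "reconstruct_ledger",
    "annotate_ages",
    "event_summary",
]

PRESENT = "present"
ABSENT = "absent"
UNKNOWN = "unknown"

_STATE_ALIASES = {
    "present": PRESENT, "1": PRESENT, "x": PRESENT, "+": PRESENT, "p": PRESENT,
    "absent": ABSENT, "0": ABSENT, "": ABSENT, "a": ABSENT,
    "unknown": UNKNOWN, "?": UNKNOWN, "na": UNKNOWN, "nan": UNKNOWN, "u": UNKNOWN,
}


def _norm_state(value: object) -> str:
    if value is None:
        return UNKNOWN
    if isinstance(value, bool):
        return PRESENT if value else ABSENT
    if isinstance(value, (int, float)):
        if value != value:  # NaN
            return UNKNOWN
        return PRESENT if value else ABSENT
    key = str(value).strip().lower()
    if key in _STATE_ALIASES:
        return _STATE_ALIASES[key]
    raise ValueError(f"unrecognised presence state {value!r}")


def ensure_node_ids(tree: dendropy.Tree) -> dendropy.Tree:
    """Give every node a stable id: taxon label for leaves, label or ``n<k>``
    (preorder) for internal nodes.  Ids are stored on ``node.node_id``."""
    k = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            node.node_id = node.taxon.label if node.taxon else node.label
        else:
            node.node_id = node.label if node.label else f"n{k}"
        k += 1
    ids = [n.node_id for n in tree.preorder_node_iter()]
    if len(ids) != len(set(ids)):
        raise ValueError("node ids are not unique on this tree")
    return tree


def dollo_reconstruct(
    presence: Mapping[str, object], tree: dendropy.Tree
) -> tuple[str | None, list[str]]:
    """Single-gain / minimal-loss explanation of one presence column.

    Returns ``(gain_branch, loss_branches)`` where branches are named by
    their child node id.  A site absent everywhere yields ``(None, [])``.
    Requires a rooted tree; unknown states are ignored when placing events.
    """
    if not tree.is_rooted:
        raise ValueError("Dollo reconstruction requires a rooted tree")
    ensure_node_ids(tree)
    states: dict[str, str] = {}
    leaf_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    for taxon, value in presence.items():
        if taxon not in leaf_labels:
            raise ValueError(f"taxon {taxon!r} is not a leaf of the tree")
        states[taxon] = _norm_state(value)
    present_taxa = [t for t, s in states.items() if s == PRESENT]
    if not present_taxa:
        return None, []

    taxa = [tree.taxon_namespace.get_taxon(t) for t in present_taxa]
    if len(taxa) == 1:
        gain_node = tree.find_node_with_taxon_label(present_taxa[0])
    else:
        gain_node = tree.mrca(taxa=taxa)

    # post-order tallies of present/absent leaves per subtree
    n_present: dict[dendropy.Node, int] = {}
    n_absent: dict[dendropy.Node, int] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            s = states.get(node.taxon.label, UNKNOWN)
            n_present[node] = 1 if s == PRESENT else 0
            n_absent[node] = 1 if s == ABSENT else 0
        else:
            n_present[node] = sum(n_present[c] for c in node.child_nodes())
            n_absent[node] = sum(n_absent[c] for c in node.child_nodes())

    losses: list[str] = []

    def walk(node: dendropy.Node) -> None:
        for child in node.child_nodes():
            if n_present[child] > 0:
                walk(child)
            elif n_absent[child] > 0:
                losses.append(child.node_id)
            # all-unknown subtrees force nothing

    walk(gain_node)
    return gain_node.node_id, losses


@dataclass
class SiteEvents:
    """Gain/loss events for one site, optionally dated in MYA."""

    site: str
    gain_branch: str | None
    loss_branches: list[str] = field(default_factory=list)
    gain_age: float | None = None
    loss_ages: list[float] = field(default_factory=list)


@dataclass
class EventLedger:
    """Dollo events for a set of sites on one tree."""

    events: dict[str, SiteEvents] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.events.values())

    def __getitem__(self, site: str) -> SiteEvents:
        return self.events[site]

    def branch_totals(self) -> pd.DataFrame:
        """Gain and loss counts per branch (child-node id)."""
        gains: dict[str, int] = {}
        losses: dict[str, int] = {}
        for ev in self:
            if ev.gain_branch is not None:
                gains[ev.gain_branch] = gains.get(ev.gain_branch, 0) + 1
            for b in ev.loss_branches:
                losses[b] = losses.get(b, 0) + 1
        branches = sorted(set(gains) | set(losses))
        return pd.DataFrame(
            {
                "gains": [gains.get(b, 0) for b in branches],
                "losses": [losses.get(b, 0) for b in branches],
            },
            index=pd.Index(branches, name="branch"),
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ev in self:
            rows.append(
                {
                    "site": ev.site,
                    "event": "gain",
                    "branch": ev.gain_branch,
                    "age_mya": ev.gain_age,
                }
            )
            for b, a in zip(
                ev.loss_branches,
                ev.loss_ages if ev.loss_ages else [None] * len(ev.loss_branches),
            ):
                rows.append({"site": ev.site, "event": "loss", "branch": b, "age_mya": a})
        return pd.DataFrame(rows, columns=["site", "event", "branch", "age_mya"])


def reconstruct_ledger(matrix: pd.DataFrame, tree: dendropy.Tree) -> EventLedger:
    """Run :func:`dollo_reconstruct` for every column of a presence matrix.

    ``matrix`` has species as rows and site labels as columns (the layout
    produced by :func:`intronarch.projection.presence_absence`).
    """
    ledger = EventLedger()
    for site in matrix.columns:
        gain, losses = dollo_reconstruct(matrix[site].to_dict(), tree)
        ledger.events[site] = SiteEvents(site=site, gain_branch=gain, loss_branches=losses)
    return ledger


def annotate_ages(
    ledger: EventLedger, node_ages: Mapping[str, float], tree: dendropy.Tree
) -> EventLedger:
    """Date every event with the age (MYA) of its branch's parent node.

    A gain sitting at the root is dated with the root's own age.  Raises if
    any referenced node is missing from ``node_ages``, listing the missing
    node ids.
    """
    ensure_node_ids(tree)
    parent_of: dict[str, str | None] = {}
    for node in tree.preorder_node_iter():
        parent_of[node.node_id] = (
            node.parent_node.node_id if node.parent_node is not None else None
        )
    needed: set[str] = set()
    for ev in ledger:
        for branch in ([ev.gain_branch] if ev.gain_branch else []) + list(ev.loss_branches):
            if branch not in parent_of:
                raise ValueError(f"branch {branch!r} not found on tree")
            needed.add(parent_of[branch] if parent_of[branch] is not None else branch)
    missing = sorted(n for n in needed if n not in node_ages)
    if missing:
        raise ValueError(f"missing node ages for: {', '.join(missing)}")

    def age_of(branch: str) -> float:
        parent = parent_of[branch]
        return float(node_ages[parent if parent is not None else branch])

    out = EventLedger()
    for ev in ledger:
        out.events[ev.site] = SiteEvents(
            site=ev.site,
            gain_branch=ev.gain_branch,
            loss_branches=list(ev.loss_branches),
            gain_age=age_of(ev.gain_branch) if ev.gain_branch is not None else None,
            loss_ages=[age_of(b) for b in ev.loss_branches],
        )
    return out


def event_summary(
    ledger: EventLedger,
    matrix: pd.DataFrame,
    group_map: Mapping[str, str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Branch totals plus per-taxon site counts.

    ``group_map`` assigns each species to an order/family; a site counts as
    *private* to a group when every species carrying it belongs to that
    group.  Returns ``{"branch_totals": ..., "taxon_counts": ...}``.
    """
    per_site_present: dict[str, list[str]] = {
        site: [sp for sp in matrix.index if _norm_state(matrix.at[sp, site]) == PRESENT]
        for site in matrix.columns
    }
    rows = []
    for sp in matrix.index:
        n_sites = sum(sp in carriers for carriers in per_site_present.values())
        n_private = 0
        if group_map is not None and sp in group_map:
            group = group_map[sp]
            for carriers in per_site_present.values():
                if sp in carriers and all(group_map.get(c) == group for c in carriers):
                    n_private += 1
        rows.append({"species": sp, "n_sites": n_sites, "n_private_sites": n_private})
    taxon_counts = pd.DataFrame(rows).set_index("species")
    return {"branch_totals": ledger.branch_totals(), "taxon_counts": taxon_counts}
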