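"""Projecting intron insertion sites onto a protein multiple alignment.

An intron site is homologous across species when it maps to the same
alignment column with the same phase.  Sites are first converted from CDS
coordinates to a residue index (the residue containing the insertion point,
or the residue immediately following a phase-0 boundary), then to the column
holding that residue in the species' aligned row.  Sites sharing a column
(within a configurable tolerance) and an identical phase are clustered, the
clusters are labelled from reference lineages (e.g. ``i7l`` for the 7th
lepidopteran site), and presence/absence matrices and near-intron pairs are
derived from the clusters.

Insertion-point convention: a phase-0 site at residue ``r`` lies between
residues ``r-1`` and ``r``; phase 1/2 sites lie inside residue ``r``'s codon.
With this convention the CDS distance between two projected sites is exactly
``(3*col_a + phase_a) - (3*col_b + phase_b)`` on a gapless scaffold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .gene_models import IntronSite

__all__ = [
    "AlignedSite",
    "SiteCluster",
    "cds_to_residue",
    "project_site",
    "cluster_sites",
    "label_clusters",
    "auto_label_remaining",
    "near_intron_pairs",
    "presence_absence",
    "column_profile",
]

GAP_CHARS = frozenset("-.")


def cds_to_residue(cds_offset: int) -> tuple[int, int]:
    """Map a CDS nucleotide offset to (residue_index, phase)."""
    if cds_offset < 0:
        raise ValueError(f"cds_offset must be non-negative, got {cds_offset}")
    return cds_offset // 3, cds_offset % 3


@dataclass(frozen=True)
class AlignedSite:
    """An intron insertion site expressed in alignment coordinates."""

    species_id: str
    residue_index: int
    alignment_column: int
    phase: int
    intron_length: int | None = None


def _residue_to_column(row: str, residue_index: int) -> int:
    seen = 0
    for col, ch in enumerate(row):
        if ch not in GAP_CHARS:
            if seen == residue_index:
                return col
            seen += 1
    raise IndexError(residue_index)


def project_site(site: IntronSite, msa: Mapping[str, str]) -> AlignedSite:
    """Project one CDS-coordinate intron site onto the protein alignment.

    ``msa`` maps species id to its aligned (gapped) protein row.  The column
    is the one holding the residue returned by :func:`cds_to_residue`,
    obtained by skipping that species' gap columns.
    """
    if site.species_id not in msa:
        raise KeyError(f"species {site.species_id!r} not present in alignment")
    residue_index, phase = cds_to_residue(site.cds_offset)
    row = msa[site.species_id]
    try:
        col = _residue_to_column(row, residue_index)
    except IndexError:
        raise ValueError(
            f"residue {residue_index} (cds_offset {site.cds_offset}) beyond the "
            f"aligned sequence of {site.species_id!r}"
        ) from None
    return AlignedSite(
        species_id=site.species_id,
        residue_index=residue_index,
        alignment_column=col,
        phase=phase,
        intron_length=site.intron_length,
    )


@dataclass(frozen=True)
class SiteCluster:
    """A homologous insertion site shared across taxa.

    All member sites have an identical phase and sit within the configured
    column tolerance of each other; ``alignment_column`` is the smallest
    member column.
    """

    alignment_column: int
    phase: int
    sites: tuple[AlignedSite, ...]
    label: str | None = None

    @property
    def members(self) -> frozenset[str]:
        return frozenset(s.species_id for s in self.sites)

    def insertion_point_nt(self) -> int:
        """CDS-scale coordinate of the insertion point on the alignment."""
        return 3 * self.alignment_column + self.phase


def cluster_sites(
    sites: Iterable[AlignedSite], column_tolerance: int = 0
) -> list[SiteCluster]:
    """Single-linkage grouping of projected sites into homologous clusters.

    Two sites join the same cluster when their columns differ by at most
    ``column_tolerance`` (chained transitively) AND their phases are equal —
    a conserved position with a different phase is treated as a distinct,
    non-homologous site.  Clusters are returned ordered by column, then phase.
    """
    if column_tolerance < 0:
        raise ValueError("column_tolerance must be >= 0")
    by_phase: dict[int, list[AlignedSite]] = {}
    for s in sites:
        by_phase.setdefault(s.phase, []).append(s)
    clusters: list[SiteCluster] = []
    for phase, group in by_phase.items():
        group.sort(key=lambda s: (s.alignment_column, s.species_id))
        current: list[AlignedSite] = []
        for s in group:
            if current and s.alignment_column - current[-1].alignment_column > column_tolerance:
                clusters.append(_make_cluster(current, phase))
                current = []
            current.append(s)
        if current:
            clusters.append(_make_cluster(current, phase))
    clusters.sort(key=lambda c: (c.alignment_column, c.phase))
    return clusters


def _make_cluster(members: list[AlignedSite], phase: int) -> SiteCluster:
    return SiteCluster(
        alignment_column=min(s.alignment_column for s in members),
        phase=phase,
        sites=tuple(members),
    )


def label_clusters(
    clusters: Sequence[SiteCluster],
    reference_species: str | Sequence[str],
    suffix: str,
) -> list[SiteCluster]:
    """Number clusters 1..n along the alignment from a reference lineage.

    ``reference_species`` may be a single species or several (e.g. one
    species per family so that family-specific sites are still numbered in
    their positional order).  Every cluster containing at least one reference
    species enters the numbering, in 5'->3' column order; clusters that
    already carry a label keep it, so running successive passes with
    different references/suffixes layers lineage-specific label systems
    without collisions.
    """
    refs = {reference_species} if isinstance(reference_species, str) else set(reference_species)
    known = {s.species_id for c in clusters for s in c.sites}
    if not refs & known:
        raise ValueError(f"reference species {sorted(refs)} have no sites")
    out = sorted(clusters, key=lambda c: (c.alignment_column, c.phase))
    n = 0
    for i, c in enumerate(out):
        if refs & c.members:
            n += 1
            if c.label is None:
                out[i] = replace(c, label=f"i{n}{suffix}")
    return out


def auto_label_remaining(clusters: Sequence[SiteCluster]) -> list[SiteCluster]:
    """Give any still-unlabelled cluster a positional fallback label."""
    return [
        c if c.label is not None else replace(c, label=f"u{c.alignment_column}.{c.phase}")
        for c in clusters
    ]


def near_intron_pairs(
    clusters: Sequence[SiteCluster],
    max_nt_distance: int = 32,
    msa: Mapping[str, str] | None = None,
    scaffold_species: str | None = None,
) -> list[tuple[str, str, int]]:
    """Pairs of distinct clusters whose insertion points nearly coincide.

    The distance between two clusters is measured in CDS nucleotides as the
    difference of their insertion-point coordinates ``3*column + phase``.
    When a scaffold species with an aligned row is supplied, columns are
    first converted to that species' ungapped residue indices so the
    distance is gap-aware; otherwise the raw alignment columns are used.
    Pairs of identical position and phase (distance 0) that share a member
    species are the same site and are excluded.
    """
    results: list[tuple[str, str, int]] = []
    scaffold_row = None
    if msa is not None and scaffold_species is not None:
        scaffold_row = msa[scaffold_species]

    def point(c: SiteCluster) -> int:
        if scaffold_row is not None:
            col = c.alignment_column
            if col < len(scaffold_row) and scaffold_row[col] not in GAP_CHARS:
                res = sum(1 for ch in scaffold_row[:col] if ch not in GAP_CHARS)
                return 3 * res + c.phase
        return c.insertion_point_nt()

    for i, a in enumerate(clusters):
        for b in clusters[i + 1:]:
            d = abs(point(a) - point(b))
            if d == 0 and (a.members & b.members or (a.alignment_column, a.phase) == (b.alignment_column, b.phase)):
                continue
            if d <= max_nt_distance:
                la = a.label or f"u{a.alignment_column}.{a.phase}"
                lb = b.label or f"u{b.alignment_column}.{b.phase}"
                results.append((la, lb, d))
    results.sort(key=lambda t: (t[2], t[0], t[1]))
    return results


PRESENT = "present"
ABSENT = "absent"
UNKNOWN = "unknown"


def presence_absence(
    clusters: Sequence[SiteCluster],
    species: Sequence[str],
    truncated_before: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Species x site-label presence/absence matrix.

    ``truncated_before`` maps a species with a 5'-truncated gene to the first
    alignment column covered by its sequence; sites 5' of that column are
    scored ``unknown`` rather than absent.
    """
    truncated_before = truncated_before or {}
    labelled = auto_label_remaining(clusters)
    labels = [c.label for c in labelled]
    data: dict[str, list[str]] = {}
    for sp in species:
        row: list[str] = []
        for c in labelled:
            if sp in c.members:
                row.append(PRESENT)
            elif sp in truncated_before and c.alignment_column < truncated_before[sp]:
                row.append(UNKNOWN)
            else:
                row.append(ABSENT)
        data[sp] = row
    return pd.DataFrame.from_dict(data, orient="index", columns=labels)


def column_profile(msa: Mapping[str, str], columns: Iterable[int]) -> pd.DataFrame:
    """Per-column residue frequencies and information content.

    Frequencies are computed over non-gap characters and sum to 1; the gap
    fraction is reported separately.  Information content (bits) is
    ``log2(20) + sum(f * log2 f)``, i.e. the small-sample-uncorrected stack
    height of a protein sequence logo: log2(20) for an invariant column,
    0 for a uniform one.  All-gap columns get NaN information.
    """
    rows = list(msa.values())
    if not rows:
        raise ValueError("empty alignment")
    records = []
    for col in columns:
        chars = [r[col] for r in rows if col < len(r)]
        residues = [c.upper() for c in chars if c not in GAP_CHARS]
        gap_fraction = 1 - len(residues) / len(chars) if chars else math.nan
        counts: dict[str, int] = {}
        for c in residues:
            counts[c] = counts.get(c, 0) + 1
        total = len(residues)
        freqs = {c: n / total for c, n in counts.items()} if total else {}
        if total:
            entropy = -sum(f * math.log2(f) for f in freqs.values())
            info = math.log2(20) - entropy
        else:
            info = math.nan
        records.append(
            {
                "column": col,
                "n_residues": total,
                "gap_fraction": gap_fraction,
                "information_bits": info,
                "frequencies": freqs,
            }
        )
    return pd.DataFrame.from_records(records).set_index("column")
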