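"""Coding-gene architecture: exons, introns, phases and exon notation.

A coding gene is modelled as an ordered run of coding exons on the coding
strand.  Each exon/exon junction hosts one intron whose *phase* records where
it interrupts the reading frame: phase 0 introns fall between two codons,
phase 1 introns after the first nucleotide of a codon, and phase 2 introns
between the second and third nucleotide.  Because homologous insertion sites
conserve both position and phase across deep evolutionary time, phase
arithmetic is the foundation for every downstream comparison in this package.

The exon-notation algebra (`ExonNotation`, :func:`merge_exons`,
:func:`split_exon`) describes an exon by the phases of its flanking introns
and its codon count (every codon with at least one nucleotide in the exon is
counted).  Intron loss fuses two exons into one; the algebra makes that
operation, and its inverse, exact and testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "GeneModel",
    "IntronSite",
    "ExonNotation",
    "GeneSummary",
    "SpliceSiteReport",
    "intron_phase",
    "infer_intron_sites",
    "notation_to_length",
    "merge_exons",
    "split_exon",
    "validate_splice_sites",
    "summarize_gene",
]


def intron_phase(cds_offset: int) -> int:
    """Phase of an intron inserted after ``cds_offset`` coding nucleotides.

    Parameters
    ----------
    cds_offset:
        Number of CDS nucleotides 5' of the insertion point.  Must be >= 0.

    Returns
    -------
    int
        ``cds_offset mod 3`` — 0 (between codons), 1 (after the first
        nucleotide of a codon) or 2 (between the second and third).
    """
    if cds_offset < 0:
        raise ValueError(f"cds_offset must be non-negative, got {cds_offset}")
    return cds_offset % 3


@dataclass(frozen=True)
class IntronSite:
    """One intron insertion point within a coding sequence.

    ``cds_offset`` counts the CDS nucleotides preceding the intron;
    the phase is always ``cds_offset mod 3``.
    """

    species_id: str
    cds_offset: int
    phase: int
    intron_length: int

    def __post_init__(self) -> None:
        if self.cds_offset <= 0:
            raise ValueError(
                f"{self.species_id}: cds_offset must be positive, got {self.cds_offset}"
            )
        if self.phase != self.cds_offset % 3:
            raise ValueError(
                f"{self.species_id}: phase {self.phase} inconsistent with "
                f"cds_offset {self.cds_offset} (expected {self.cds_offset % 3})"
            )
        if self.intron_length < 0:
            raise ValueError(f"{self.species_id}: negative intron length")


@dataclass(frozen=True)
class GeneModel:
    """Ordered coding exons of one gene in one species.

    Exons are 0-based half-open intervals on the coding strand, strictly
    increasing and non-overlapping.  ``intron_lengths`` holds one entry per
    junction; ``cds_length`` (stop codon included) must equal the summed exon
    lengths.
    """

    species_id: str
    exons: tuple[tuple[int, int], ...]
    intron_lengths: tuple[int, ...]
    cds_length: int

    def __init__(
        self,
        species_id: str,
        exons: Sequence[tuple[int, int]],
        intron_lengths: Sequence[int],
        cds_length: int | None = None,
    ) -> None:
        exons_t = tuple((int(a), int(b)) for a, b in exons)
        introns_t = tuple(int(x) for x in intron_lengths)
        if not exons_t:
            raise ValueError(f"{species_id}: gene model needs at least one exon")
        for a, b in exons_t:
            if b - a < 1:
                raise ValueError(f"{species_id}: exon ({a},{b}) shorter than 1 nt")
        for (a0, b0), (a1, b1) in zip(exons_t, exons_t[1:]):
            if a1 < b0:
                raise ValueError(
                    f"{species_id}: exons ({a0},{b0}) and ({a1},{b1}) overlap or "
                    "are out of order"
                )
        if len(introns_t) != len(exons_t) - 1:
            raise ValueError(
                f"{species_id}: {len(introns_t)} intron lengths for "
                f"{len(exons_t)} exons (need n_exons - 1)"
            )
        if any(x < 0 for x in introns_t):
            raise ValueError(f"{species_id}: negative intron length")
        total = sum(b - a for a, b in exons_t)
        if cds_length is None:
            cds_length = total
        elif cds_length != total:
            raise ValueError(
                f"{species_id}: cds_length {cds_length} != summed exon length {total}"
            )
        object.__setattr__(self, "species_id", species_id)
        object.__setattr__(self, "exons", exons_t)
        object.__setattr__(self, "intron_lengths", introns_t)
        object.__setattr__(self, "cds_length", int(cds_length))

    @classmethod
    def from_exon_lengths(
        cls,
        species_id: str,
        exon_lengths: Sequence[int],
        intron_lengths: Sequence[int],
    ) -> "GeneModel":
        """Build a model from exon/intron lengths, laying exons end to end.

        Genomic coordinates are synthesised on the coding strand with each
        intron occupying its stated length between consecutive exons; all
        phase and summary arithmetic depends only on the lengths.
        """
        if len(intron_lengths) != len(exon_lengths) - 1:
            raise ValueError(
                f"{species_id}: {len(intron_lengths)} intron lengths for "
                f"{len(exon_lengths)} exons"
            )
        exons: list[tuple[int, int]] = []
        pos = 0
        for i, el in enumerate(exon_lengths):
            exons.append((pos, pos + el))
            pos += el
            if i < len(intron_lengths):
                pos += intron_lengths[i]
        return cls(species_id, exons, intron_lengths)

    @property
    def exon_lengths(self) -> tuple[int, ...]:
        return tuple(b - a for a, b in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)


def infer_intron_sites(model: GeneModel) -> list[IntronSite]:
    """One :class:`IntronSite` per exon/exon junction, ordered 5'->3'.

    The CDS offset of junction ``k`` is the cumulative exon length up to and
    including exon ``k``; a single-exon gene yields an empty list.
    """
    sites: list[IntronSite] = []
    cum = 0
    for k, length in enumerate(model.exon_lengths[:-1]):
        cum += length
        sites.append(
            IntronSite(
                species_id=model.species_id,
                cds_offset=cum,
                phase=intron_phase(cum),
                intron_length=model.intron_lengths[k],
            )
        )
    return sites


@dataclass(frozen=True)
class ExonNotation:
    """An exon described by flanking intron phases and codon count.

    ``upstream_phase``/``downstream_phase`` are the phases of the introns
    bounding the exon (0 for a terminal exon boundary at a codon edge);
    ``codon_count`` counts every codon with >= 1 nucleotide inside the exon.

    Published gene diagrams often print, instead of the upstream phase, the
    number of nucleotides the exon contributes to the split codon at its 5'
    boundary; :meth:`from_flanking_digits` converts that convention.
    """

    upstream_phase: int
    codon_count: int
    downstream_phase: int

    def __post_init__(self) -> None:
        if self.upstream_phase not in (0, 1, 2) or self.downstream_phase not in (0, 1, 2):
            raise ValueError("phases must be in {0,1,2}")
        if self.codon_count < 1:
            raise ValueError("codon_count must be >= 1")
        notation_to_length(self)  # raises if the notation admits no exon

    @classmethod
    def from_flanking_digits(cls, upstream_nt: int, codon_count: int, downstream_nt: int) -> "ExonNotation":
        """Convert a printed ``u-c-d`` triple of flanking nucleotide counts.

        The upstream digit gives the nucleotides completing the 5' split
        codon, hence the upstream intron phase is ``(3 - u) mod 3``; the
        downstream digit already equals the downstream intron phase.
        """
        return cls((3 - upstream_nt) % 3, codon_count, downstream_nt % 3)

    @property
    def as_tuple(self) -> tuple[int, int, int]:
        return (self.upstream_phase, self.codon_count, self.downstream_phase)


def notation_to_length(n: ExonNotation) -> int:
    """Nucleotide length of an exon given in phase/codon-count notation.

    ``L = 3*(c - [pu>0] - [pd>0]) + ((3 - pu) mod 3) + pd``: full codons plus
    the fragments completing the 5' split codon and starting the 3' one.  A
    codon count too small to host the flanking fragments is rejected.
    """
    pu, c, pd = n.upstream_phase, n.codon_count, n.downstream_phase
    length = 3 * (c - (pu > 0) - (pd > 0)) + ((3 - pu) % 3) + pd
    if length < 1:
        raise ValueError(f"notation {n.as_tuple} admits no exon of positive length")
    return length


def merge_exons(a: ExonNotation, b: ExonNotation) -> ExonNotation:
    """Fuse two exons that flank one lost intron into a single exon.

    The downstream phase of ``a`` must equal the upstream phase of ``b``
    (they describe the same boundary).  When the boundary phase is non-zero
    the split codon straddling it is counted once in the result, so the
    merged codon count is ``a.c + b.c - [boundary > 0]``.  Length is additive.
    """
    if a.downstream_phase != b.upstream_phase:
        raise ValueError(
            f"boundary phase mismatch: {a.as_tuple} ends phase "
            f"{a.downstream_phase}, {b.as_tuple} starts phase {b.upstream_phase}"
        )
    boundary = a.downstream_phase
    return ExonNotation(
        a.upstream_phase,
        a.codon_count + b.codon_count - (1 if boundary > 0 else 0),
        b.downstream_phase,
    )


def _codon_count(length: int, pu: int, pd: int) -> int:
    """Codon count of an exon of ``length`` nt with the given flank phases."""
    frag = ((3 - pu) % 3) + pd
    if (length - frag) % 3 != 0:
        raise ValueError(
            f"length {length} inconsistent with flank phases ({pu},{pd})"
        )
    c = (length - frag) // 3 + (pu > 0) + (pd > 0)
    if c < 1:
        raise ValueError(f"length {length} with phases ({pu},{pd}) has no codon")
    return c


def split_exon(n: ExonNotation, internal_offset: int) -> tuple[ExonNotation, ExonNotation]:
    """Split an exon at an internal nucleotide offset; inverse of merge.

    The new boundary phase follows the codon frame: an exon starting at
    upstream phase ``pu`` puts the cut at frame ``(pu + k) mod 3``.
    ``merge_exons(*split_exon(n, k)) == n`` for every valid ``k``.
    """
    total = notation_to_length(n)
    if not 0 < internal_offset < total:
        raise ValueError(
            f"internal_offset {internal_offset} outside (0, {total}) for {n.as_tuple}"
        )
    q = (n.upstream_phase + internal_offset) % 3
    left = ExonNotation(
        n.upstream_phase, _codon_count(internal_offset, n.upstream_phase, q), q
    )
    right = ExonNotation(
        q, _codon_count(total - internal_offset, q, n.downstream_phase), n.downstream_phase
    )
    return left, right


@dataclass(frozen=True)
class SpliceSiteReport:
    """Per-intron canonical (GT..AG) splice-site validity."""

    species_id: str
    donor_ok: tuple[bool, ...]
    acceptor_ok: tuple[bool, ...]

    @property
    def canonical(self) -> tuple[bool, ...]:
        return tuple(d and a for d, a in zip(self.donor_ok, self.acceptor_ok))

    @property
    def all_canonical(self) -> bool:
        return all(self.canonical)


def validate_splice_sites(model: GeneModel, genomic_seq: str) -> SpliceSiteReport:
    """Check every intron for the canonical GT donor / AG acceptor.

    ``genomic_seq`` is the coding-strand genomic sequence covering the whole
    gene span (coordinates as in ``model.exons``).  An intronless gene yields
    an empty report.
    """
    if len(genomic_seq) < model.exons[-1][1]:
        raise ValueError(
            f"{model.species_id}: sequence length {len(genomic_seq)} shorter than "
            f"gene span {model.exons[-1][1]}"
        )
    seq = genomic_seq.upper()
    donors: list[bool] = []
    acceptors: list[bool] = []
    for (a0, b0), (a1, b1) in zip(model.exons, model.exons[1:]):
        donors.append(seq[b0:b0 + 2] == "GT")
        acceptors.append(seq[a1 - 2:a1] == "AG")
    return SpliceSiteReport(model.species_id, tuple(donors), tuple(acceptors))


@dataclass(frozen=True)
class GeneSummary:
    """Exon/intron counts and total intronic sequence of one gene."""

    species_id: str
    n_exons: int
    n_introns: int
    total_intronic_bp: int
    exon_nt_lengths: tuple[int, ...]


def summarize_gene(model: GeneModel) -> GeneSummary:
    """Counts and total intronic length (the "total IS" of a gene)."""
    return GeneSummary(
        species_id=model.species_id,
        n_exons=model.n_exons,
        n_introns=len(model.intron_lengths),
        total_intronic_bp=sum(model.intron_lengths),
        exon_nt_lengths=model.exon_lengths,
    )
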