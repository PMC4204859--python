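# Methods

## Intron phases and the exon-notation algebra

A gene model is an ordered run of coding exons on the coding strand
(0-based half-open coordinates internally; GFF3 input is converted from
1-based closed, and minus-strand genes are re-ordered 5'→3' at load).
The CDS length includes the stop codon. An intron after `o` coding
nucleotides has phase `o mod 3`; for every junction the cumulative exon
length determines the phase, so phases are a pure function of exon lengths.

An exon is summarised as `(p_u, c, p_d)`: phases of the flanking introns
and the count of codons having at least one nucleotide in the exon. The
nucleotide length is

    L = 3 (c − [p_u>0] − [p_d>0]) + ((3 − p_u) mod 3) + p_d ,

i.e. the full codons plus the fragment completing the 5' split codon plus
the fragment opening the 3' one. The codon-counting convention is the one
under which intron loss is exactly additive: merging two exons across a
lost boundary of phase q gives codon count `c_a + c_b − [q>0]` (the split
codon straddling the lost intron is counted once) and `L_merged = L_a +
L_b`. Splitting is the exact inverse: a cut `k` nucleotides into the exon
creates a boundary of phase `(p_u + k) mod 3`, and split-then-merge is the
identity for every valid `k` (property-tested over random notations).

One caveat on published gene diagrams: they typically print, at the 5'
boundary, the number of nucleotides the exon contributes to its split codon
— which is `(3 − phase) mod 3`, not the phase. `ExonNotation.
from_flanking_digits` converts that convention; the API itself always
stores phases.

## Homologous insertion sites

A site at CDS offset `o` maps to residue `o div 3` with phase `o mod 3`; a
phase-0 site at residue r is the junction between residues r−1 and r.
Projection onto the protein alignment walks the species' row skipping gaps,
so the insertion point of a site becomes `(column, phase)`. Two sites are
homologous when they share the column (within a configurable tolerance,
default 0 — conserved sites are treated as exactly aligned) *and* the
phase: a conserved position with a different phase is scored as a distinct
site, following the empirical rule that conserved insertion sites conserve
their phase. Clustering is single-linkage per phase along columns.

Labelling numbers clusters `i1x…inx` in 5'→3' order from a reference
lineage. A reference pass may name several species jointly: the clusters
containing any of them are numbered together, which lets a family-specific
site (e.g. the formicid-only third hymenopteran site) receive its
positional number even though the primary reference species lacks it.
Successive passes with different suffixes never overwrite earlier labels;
chordate-specific labels therefore keep the full chordate gene numbering
(the 4th and 7th chordate sites) because the chordate reference carries its
two N-terminal sites that the shared-site tables do not print.

Near intron pairs are distinct clusters whose insertion points lie within
`max_nt_distance` (default 32 nt, chosen as a round bound comfortably
covering the published 24-nt case while excluding the 51-nt i4l/i4c pair)
on the CDS scale `3·column + phase`. When a scaffold species is given, its
ungapped residue numbering is used so the distance is measured on actual
sequence; without a common scaffold the raw column difference is used.
Pairs at distance 0 sharing a member species are the same site, not a pair.

## Dollo reconstruction and dating

Each site is a binary character on a rooted species tree: gained exactly
once, lost arbitrarily often. The gain is placed at the MRCA of all
carriers; the minimal loss set is the set of maximal carrier-free subtrees
inside the gain clade (computed by post-order tallies). Unknown states
(5'-truncated genes) are missing data: they never force a loss and never
move the gain. Correctness is established against an exhaustive oracle
that enumerates every gain placement and searches loss subsets by
increasing size over all small rooted topologies.

Convergent gains violate Dollo by construction; the package handles the
known convergent sites by treating each lineage-specific label as its own
character rather than relaxing the single-gain constraint. This is a
documented limitation, not a hidden assumption.

Events are dated by the age of the parent node of their branch — the
divergence that opens the branch — because published event dates cite
divergence times. A gain at the root carries the root's own age. The
packaged dated tree, ages and presence matrix are a **synthetic encoding**
(files named `*_synthetic.*`) of the published gain/loss scenario: the
original figure is not machine-readable, so seven lineage-level leaves and
six dated nodes were arranged so that the two explicitly dated, unambiguous
events (the deep gain at 855 MYA; the single arthropod loss at 372 MYA)
emerge from reconstruction under the stated dating convention. Dates the
source attaches to branches it does not identify are not asserted.

## Distance phylogeny

p-distance is the fraction of differing residues over retained columns;
complete deletion (drop any column with a gap or missing character in any
sequence) is the default, pairwise deletion is available. Neighbor-joining
uses the standard Q criterion with a deterministic lowest-index tie-break;
negative branch-length estimates are clamped to zero with a warning
(the convention of mainstream phylogenetics software). Bootstrap resamples
columns with replacement and reports, for each bipartition of the full-data
tree, the percentage of replicate trees containing it — support is mapped
onto the original tree rather than onto a majority-rule consensus, which is
simpler and sufficient for annotating one tree. NJ is verified exact on
additive matrices (trees regenerated from their own path distances) and
cross-checked topologically against an independent implementation.

## Start-codon context

The context model is a percentage PFM over positions −10…−1 from n
validated start windows (the packaged matrix comes from 168 genes; U and T
are identified). The consensus at a position is the set of nucleotides with
frequency ≥ threshold. The default threshold is **27%**: the unique integer
threshold reproducing the published consensus row cell by cell (27% cells
are in, 25–26% cells are out); it is configurable and the derivation is
monotone (raising it never adds a nucleotide). Scoring is the count of the
10 context positions whose nucleotide is in the consensus set — a set-
membership count, not a log-odds score, because that is what the published
per-candidate analysis encodes. Candidate ATGs are restricted to those in
frame with, and within, the annotated ORF (no in-frame stop between
candidate and ORF stop); ties select the 5'-most. The packaged cDNA is a
labelled synthetic construct carrying the three published candidate
contexts at in-frame ATGs, since the real transcript is not shipped.

## Synthetic histories

The simulator draws a random rooted binary tree (or accepts one), assigns
each site a distinct residue position and phase, places `n_ancestral_sites`
gains at the root and the remainder on uniformly chosen branches, and loses
each site on any branch below its gain with probability `1 − exp(−loss_rate)`
(no regain below a loss). Leaf gene models place surviving sites at their
residue positions using the leaf's own residue numbering; intron lengths
are log-normal (default mean-log 6.7 ≈ 800 bp median, sd-log 1.0, with
optional per-clade mean-logs emulating the observed clade dependence of
intron sizes, from sub-100-bp dipteran to multi-kb lepidopteran introns).
Proteins evolve by independent substitutions (default 0.05 per site per
branch) with no indels, so residue index equals alignment column and the
site→column map is exact; an optional per-leaf deletion mode introduces
gaps (and drops sites whose host residue is deleted) to stress gap-aware
projection. Everything is reproducible from the seed.

A simulated site is flagged *identifiable* when its true history is the
unique minimal Dollo explanation of the leaf pattern, decided structurally
from the truth (carriers survive on ≥ 2 child lineages of the gain node,
and every loss branch has surviving carriers beside it); recovery tests
assert exact event equality on those sites and report their fraction.
What passing these tests shows: the reconstruction logic is exact under
the model's assumptions (single gain, tree-consistent losses, correct
alignment). What they do not show: robustness to alignment error,
convergent gain, or rate variation, none of which the generator emulates.

## Numerical and edge-case choices

- Column information content is `log2 20 + Σ f log2 f` over non-gap
  residues (gap fraction reported separately); all-gap columns report NaN.
- Zero retained columns under a deletion mode is an error naming the mode.
- An intronless gene yields an empty site list and an empty splice report,
  not an error; a site absent from every taxon yields no events.
- The shipped tables are stored verbatim, including one internally
  inconsistent row (printed total 457 vs listed sum 602) which is flagged
  `discrepant_total` and excluded from totals checks rather than silently
  corrected, and one phase-variant cell (phase 0 where congeners have
  phase 2) which clusters apart by the phase rule.
- Fixture gene models place exon boundaries at synthetic offsets consistent
  with the printed phases; totals and counts are boundary-independent.
- Test problem sizes (all rooted topologies to 5 leaves plus sampled 6- and
  7-leaf topologies for the oracle comparison; 100 random trees to 8 leaves
  for NJ; 200-site histories on 6–12 leaves) were chosen as the smallest
  sets that exercise every structural case class.
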