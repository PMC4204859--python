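"""Packaged reference data: published intron-site tables and derived objects.

The package ships, as plain TSV, the per-species intron phase/length tables
for lepidoptera-referenced sites (``i*l``), hymenoptera-specific sites
(``i*h``) and chordate sites (``i*c``), the 168-gene start-codon position
frequency matrix with the three candidate ATG contexts of the Sf9 fut8 cDNA,
and a synthetic dated species tree encoding the published gain/loss scenario
(the original figure is not machine-readable, so tree, ages and presence
matrix are a constructed stand-in that reproduces its dated events).

Alignment coordinates: the tables identify homologous sites by label, not by
column, so this module assigns each label a fixed canonical alignment column
and phase (``SITE_COLUMNS``).  Columns are spaced so that the only sub-32-nt
proximities are the genuine near-intron pairs (i8l/i7c at 24 nt; the i1h
phase variant), while the i4l/i4c pair sits at its published 51 nt.
"""

from __future__ import annotations

from importlib import resources
from typing import Mapping

import dendropy
import pandas as pd

from .gene_models import GeneModel
from .projection import AlignedSite

__all__ = [
    "load_table",
    "lepidoptera_chordate_table",
    "hymenoptera_table",
    "chordate_marks_table",
    "start_pfm",
    "start_candidate_contexts",
    "sf9_cdna_synthetic",
    "SITE_COLUMNS",
    "gene_model_from_cells",
    "gene_models_from_tables",
    "aligned_sites_from_tables",
    "dated_tree",
    "node_ages",
    "dated_presence",
]


def _data_path(name: str):
    return resources.files("intronarch.data").joinpath(name)


def load_table(name: str) -> pd.DataFrame:
    with resources.as_file(_data_path(name)) as path:
        return pd.read_csv(path, sep="\t", dtype=str).fillna("")


def lepidoptera_chordate_table() -> pd.DataFrame:
    """Arthropod/chordate sites shared with the lepidopteran reference
    (phase/length cells, total intronic bp, intron counts)."""
    return load_table("shared_sites_lref.tsv")


def hymenoptera_table() -> pd.DataFrame:
    """Hymenoptera-specific sites; ``discrepant_total`` flags the one row
    whose printed total does not match the sum of its listed introns."""
    return load_table("hymenoptera_sites.tsv")


def chordate_marks_table() -> pd.DataFrame:
    """Presence marks (X = lepidopteran site, + = chordate site) for
    chordata, nematoda, annelida, placozoa and cnidaria."""
    return load_table("chordate_site_marks.tsv")


def start_pfm() -> pd.DataFrame:
    """Percentage PFM of the 10 nt upstream of 168 validated Sf9 start codons."""
    with resources.as_file(_data_path("start_pfm_168.tsv")) as path:
        df = pd.read_csv(path, sep="\t", index_col="position")
    return df.astype(float)


def start_candidate_contexts() -> dict[str, str]:
    """Upstream contexts of the three in-frame candidate ATGs of Sf9 fut8."""
    df = load_table("start_candidate_contexts.tsv")
    return dict(zip(df["candidate"], df["context"]))


def sf9_cdna_synthetic() -> tuple[str, int]:
    """Synthetic cDNA 5' region carrying the three published ATG contexts.

    The real cDNA is not shipped; this constructed sequence places three
    in-frame ATGs, each preceded by its published 10-nt context, with no
    intervening in-frame stop, followed by a short coding stretch and stop.
    Returns ``(sequence, offset_of_first_ATG)``.
    """
    contexts = start_candidate_contexts()
    c1 = contexts["ATG1"].replace("U", "T")
    c2 = contexts["ATG2"].replace("U", "T")
    c3 = contexts["ATG3"].replace("U", "T")
    # spacers keep the three ATGs in one frame (len(ctx)+3+len(spacer) % 3 == 0)
    spacer = "CC"
    body = "GCTGCTGCTGCCAAGCCT"
    seq = c1 + "ATG" + spacer + c2 + "ATG" + spacer + c3 + "ATG" + body + "TAA"
    return seq, len(c1)


# canonical (alignment_column, phase) per site label; columns are arbitrary
# but fixed, ordered 5'->3' as in the published tables
SITE_COLUMNS: dict[str, tuple[int, int]] = {
    "i1c": (0, 0),
    "i2c": (12, 0),
    "i1l": (25, 2),
    "i2l": (38, 2),
    "i3l": (51, 2),
    "i4l": (64, 0),
    "i4c": (81, 0),
    "i5l": (94, 1),
    "i6l": (107, 2),
    "i7l": (120, 2),
    "i8l": (133, 0),
    "i7c": (141, 0),
    "i9l": (155, 0),
    "i10l": (168, 0),
    "i11l": (181, 0),
    "i1h": (200, 2),
    "i2h": (213, 2),
    "i3h": (226, 2),
    "i4h": (239, 0),
}

_L_LABELS = [f"i{k}l" for k in range(1, 12)]
_H_LABELS = [f"i{k}h" for k in range(1, 5)]
_MARK_LABELS = ["i1l", "i2l", "i3l", "i4l", "i4c", "i5l", "i6l", "i7l", "i8l", "i7c", "i9l", "i10l", "i11l"]
# lineages whose genes carry the two chordate N-terminal sites not printed
# in the shared-site tables (8 introns total, 6 in the conserved region)
_CHORDATE_PHYLA = {"Chordata", "Echinodermata", "Hemichordata"}


def _parse_cell(cell: str) -> tuple[int, int] | None:
    cell = cell.strip()
    if not cell:
        return None
    phase, length = cell.split("/")
    return int(phase), int(length.replace(",", ""))


def gene_model_from_cells(
    species: str, phases_lengths: list[tuple[int, int]], cds_length: int | None = None
) -> GeneModel:
    """Gene model with introns at synthetic offsets realising given phases.

    Junction ``k`` is placed at CDS offset ``90*(k+1) + adjustment`` so the
    offset is congruent to the required phase; totals and intron counts are
    boundary-independent, which is all the published tables constrain.
    """
    n = len(phases_lengths)
    offsets = []
    for k, (phase, _) in enumerate(phases_lengths):
        base = 90 * (k + 1)
        offsets.append(base + phase)
    if cds_length is None:
        cds_length = 90 * (n + 2) + 3
    exon_lengths = []
    prev = 0
    for off in offsets:
        exon_lengths.append(off - prev)
        prev = off
    exon_lengths.append(cds_length - prev)
    return GeneModel.from_exon_lengths(
        species, exon_lengths, [length for _, length in phases_lengths]
    )


def sf9_gene_model() -> GeneModel:
    """Twelve-exon lepidopteran reference gene (561 aa + stop = 1686 nt CDS).

    Exon boundaries are placed at evenly spread offsets consistent with the
    published phases; sizes land in the published 75-216 bp range.
    """
    table = lepidoptera_chordate_table().set_index("species")
    cells = [_parse_cell(table.at["S_frugiperda", lab]) for lab in _L_LABELS]
    offsets = []
    for k, (phase, _) in enumerate(cells):
        base = 141 * (k + 1)
        offsets.append(base - (base - phase) % 3)
    exon_lengths = []
    prev = 0
    for off in offsets:
        exon_lengths.append(off - prev)
        prev = off
    exon_lengths.append(1686 - prev)
    return GeneModel.from_exon_lengths(
        "S_frugiperda", exon_lengths, [length for _, length in cells]
    )


def gene_models_from_tables() -> dict[str, GeneModel]:
    """Gene models for every species whose listed sites cover all introns.

    Rows where the printed intron count exceeds the listed sites (only the
    shared sites are tabulated) cannot be reconstructed and are skipped, as
    is the one row whose printed total contradicts its listed lengths.
    """
    models: dict[str, GeneModel] = {}
    shared = lepidoptera_chordate_table()
    for _, row in shared.iterrows():
        cells = [_parse_cell(row[lab]) for lab in _L_LABELS]
        sites = [c for c in cells if c is not None]
        if row["truncated"] == "1" or not sites:
            continue
        if int(row["n_introns"]) != len(sites):
            continue
        models[row["species"]] = gene_model_from_cells(row["species"], sites)
    hym = hymenoptera_table()
    for _, row in hym.iterrows():
        if row["discrepant_total"] == "1":
            continue
        sites = [c for c in (_parse_cell(row[lab]) for lab in _H_LABELS) if c is not None]
        if int(row["n_introns"]) != len(sites):
            continue
        models[row["species"]] = gene_model_from_cells(row["species"], sites)
    return models


def aligned_sites_from_tables() -> list[AlignedSite]:
    """Every tabulated site as an :class:`AlignedSite` at its canonical column.

    The published tables record homology by label; this expands them back
    into per-species projected sites (the inverse of the projection step) so
    the clustering/labelling/matrix machinery can be exercised end to end.
    The one phase-variant cell (a formicid whose first intron is phase 0
    where the other hymenopterans have phase 2) keeps the shared column but
    its own phase, and therefore clusters apart.
    """
    sites: list[AlignedSite] = []

    def add(species: str, label: str, phase: int, length: int | None) -> None:
        col, canonical_phase = SITE_COLUMNS[label]
        sites.append(
            AlignedSite(
                species_id=species,
                residue_index=col,
                alignment_column=col,
                phase=phase,
                intron_length=length,
            )
        )

    shared = lepidoptera_chordate_table()
    for _, row in shared.iterrows():
        for lab in _L_LABELS:
            cell = _parse_cell(row[lab])
            if cell is not None:
                add(row["species"], lab, cell[0], cell[1])
    hym = hymenoptera_table()
    for _, row in hym.iterrows():
        for lab in _H_LABELS:
            cell = _parse_cell(row[lab])
            if cell is not None:
                add(row["species"], lab, cell[0], cell[1])
    marks = chordate_marks_table()
    t4_species = set(shared["species"])
    for _, row in marks.iterrows():
        for lab in _MARK_LABELS:
            mark = row[lab].strip()
            if not mark:
                continue
            # species also present in the shared-site table already
            # contributed their l-sites with lengths there
            if row["species"] in t4_species and lab.endswith("l"):
                continue
            col, phase = SITE_COLUMNS[lab]
            add(row["species"], lab, phase, None)
        if row["phylum"] in _CHORDATE_PHYLA:
            for lab in ("i1c", "i2c"):
                col, phase = SITE_COLUMNS[lab]
                add(row["species"], lab, phase, None)
    return sites


def all_table_species() -> list[str]:
    seen: list[str] = []
    for df in (lepidoptera_chordate_table(), hymenoptera_table(), chordate_marks_table()):
        for sp in df["species"]:
            if sp not in seen:
                seen.append(sp)
    return seen


def truncated_before_columns() -> dict[str, int]:
    """Per truncated species, the first column covered by its sequence."""
    out: dict[str, int] = {}
    for df in (lepidoptera_chordate_table(), chordate_marks_table()):
        label_cols = [c for c in df.columns if c in SITE_COLUMNS]
        for _, row in df.iterrows():
            if row["truncated"] != "1":
                continue
            present = [SITE_COLUMNS[lab][0] for lab in label_cols if row[lab].strip()]
            if present:
                out.setdefault(row["species"], min(present))
    return out


def dated_tree() -> dendropy.Tree:
    """Rooted, node-labelled species tree of the dated gain/loss scenario."""
    with resources.as_file(_data_path("dated_tree_synthetic.nwk")) as path:
        tree = dendropy.Tree.get(path=str(path), schema="newick", rooting="force-rooted")
    return tree


def node_ages() -> dict[str, float]:
    """Divergence age (MYA) per node of the dated fixture tree."""
    with resources.as_file(_data_path("dated_ages_synthetic.tsv")) as path:
        df = pd.read_csv(path, sep="\t")
    return dict(zip(df["node"], df["age_mya"].astype(float)))


def dated_presence() -> pd.DataFrame:
    """Site x lineage presence matrix of the dated scenario (1/0)."""
    with resources.as_file(_data_path("dated_presence_synthetic.tsv")) as path:
        df = pd.read_csv(path, sep="\t", index_col="site")
    return df
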