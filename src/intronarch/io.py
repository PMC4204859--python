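"""Readers and writers for the pipeline's file formats.

Gene structures come in as GFF3 (gene/mRNA/CDS features, via gffutils) or as
a minimal three-column TSV (species_id, comma-separated exon lengths,
comma-separated intron lengths); protein alignments as aligned FASTA; species
trees as newick with optional node labels; node ages and column masks as TSV.
All gene models are normalised to the coding strand at load time.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO

from .gene_models import GeneModel

logger = logging.getLogger(__name__)

__all__ = [
    "read_gene_models_tsv",
    "write_gene_models_tsv",
    "read_gene_models_gff3",
    "read_alignment_fasta",
    "write_alignment_fasta",
    "read_tree",
    "write_tree",
    "read_node_ages",
    "read_column_mask",
]


def read_gene_models_tsv(path: str | Path) -> dict[str, GeneModel]:
    """Read the simple gene-structure TSV (one gene per row).

    Columns: ``species_id``, ``exon_lengths`` (comma list, nt),
    ``intron_lengths`` (comma list, nt; empty for intronless genes).
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"species_id", "exon_lengths", "intron_lengths"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    models: dict[str, GeneModel] = {}
    for _, row in df.iterrows():
        exons = [int(x) for x in row["exon_lengths"].split(",") if x.strip()]
        introns = [int(x) for x in row["intron_lengths"].split(",") if x.strip()]
        models[row["species_id"]] = GeneModel.from_exon_lengths(
            row["species_id"], exons, introns
        )
    return models


def write_gene_models_tsv(models: Mapping[str, GeneModel], path: str | Path) -> None:
    rows = []
    for sp, m in models.items():
        rows.append(
            {
                "species_id": sp,
                "exon_lengths": ",".join(map(str, m.exon_lengths)),
                "intron_lengths": ",".join(map(str, m.intron_lengths)),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gene_models_gff3(path: str | Path, species_from: str = "seqid") -> dict[str, GeneModel]:
    """Extract one gene model per mRNA from a GFF3 file.

    CDS features are grouped by parent mRNA and normalised to the coding
    strand: minus-strand genes are re-ordered 5'->3' (coordinates are
    rebuilt from exon/intron lengths, which is all downstream analysis
    uses).  The GFF3 phase column, where present, is cross-checked against
    the phase implied by cumulative CDS length; mismatches are logged, not
    fatal — annotation phase errors are a fact of life.

    ``species_from`` chooses the model key: ``"seqid"`` (default) or an
    attribute name on the mRNA feature (e.g. ``"ID"``).
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models: dict[str, GeneModel] = {}
    for mrna in db.features_of_type(("mRNA", "transcript")):
        cds = sorted(db.children(mrna, featuretype="CDS"), key=lambda f: f.start)
        if not cds:
            continue
        if mrna.strand == "-":
            cds = cds[::-1]
        exon_lengths = [f.end - f.start + 1 for f in cds]  # GFF3 is 1-based closed
        intron_lengths = []
        for a, b in zip(cds, cds[1:]):
            if mrna.strand == "-":
                intron_lengths.append(a.start - b.end - 1)
            else:
                intron_lengths.append(b.start - a.end - 1)
        if species_from == "seqid":
            key = mrna.seqid
        else:
            key = mrna.attributes.get(species_from, [mrna.id])[0]
        model = GeneModel.from_exon_lengths(key, exon_lengths, intron_lengths)
        cum = 0
        for f, length in zip(cds, exon_lengths):
            declared = f.frame
            if declared not in (None, ".", ""):
                expected = (3 - cum % 3) % 3
                if int(declared) != expected:
                    logger.warning(
                        "%s: CDS phase %s disagrees with computed %d at cumulative "
                        "offset %d", key, declared, expected, cum,
                    )
            cum += length
        models[key] = model
    return models


def read_alignment_fasta(path: str | Path) -> dict[str, str]:
    """Aligned FASTA -> {id: gapped sequence}; enforces equal lengths."""
    records = {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise ValueError(f"{path}: no sequences")
    lengths = {len(s) for s in records.values()}
    if len(lengths) != 1:
        raise ValueError(f"{path}: unequal aligned lengths {sorted(lengths)}")
    return records


def write_alignment_fasta(msa: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in msa.items():
            fh.write(f">{name}\n{seq}\n")


def read_tree(path: str | Path, rooted: bool = True) -> dendropy.Tree:
    return dendropy.Tree.get(
        path=str(path),
        schema="newick",
        rooting="force-rooted" if rooted else "default-unrooted",
        preserve_underscores=True,
    )


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=False)


def read_node_ages(path: str | Path) -> dict[str, float]:
    """Node-age TSV (columns ``node``, ``age_mya``) -> mapping."""
    df = pd.read_csv(path, sep="\t")
    if not {"node", "age_mya"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns node, age_mya")
    return dict(zip(df["node"].astype(str), df["age_mya"].astype(float)))


def read_column_mask(path: str | Path) -> list[bool]:
    """One kept/dropped flag per alignment column (1/0 or keep/drop)."""
    flags: list[bool] = []
    for line in Path(path).read_text().splitlines():
        tok = line.strip().lower()
        if not tok:
            continue
        flags.append(tok in {"1", "keep", "kept", "true"})
    return flags
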