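"""End-to-end orchestration: gene models -> projected sites -> clusters ->
presence/absence -> near pairs -> (optional) NJ tree -> Dollo event ledger.

Each stage is a thin call into the library modules; the pipeline adds input
validation, stage-labelled error reporting, deterministic TSV outputs and a
plain-text run log (versions, seed, thresholds), so a run can be reproduced
byte for byte from its config.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .dollo import annotate_ages, reconstruct_ledger
from .gene_models import infer_intron_sites, summarize_gene
from .io import (
    read_alignment_fasta,
    read_gene_models_tsv,
    read_node_ages,
    read_tree,
    write_tree,
)
from .phylo_nj import bootstrap_support, nj_tree, p_distance
from .projection import (
    auto_label_remaining,
    cluster_sites,
    label_clusters,
    near_intron_pairs,
    presence_absence,
    project_site,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and offending input."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Inputs and thresholds of one pipeline run."""

    gene_models: str
    msa: str
    out_dir: str
    tree: str | None = None
    ages: str | None = None
    reference_passes: Sequence[tuple[Sequence[str], str]] = field(default_factory=list)
    species: Sequence[str] | None = None
    column_tolerance: int = 0
    nearpair_nt: int = 32
    scaffold_species: str | None = None
    bootstrap: int = 0
    seed: int = 0


def run_pipeline(config: RunConfig) -> dict[str, object]:
    """Execute all stages and write the report bundle under ``out_dir``.

    Returns the in-memory results keyed by stage name.  Any stage failure
    raises :class:`PipelineError` naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict[str, object] = {}
    log_lines = [
        f"intronarch {__version__}",
        f"started {datetime.datetime.now().isoformat(timespec='seconds')}",
        f"seed {config.seed}",
        f"column_tolerance {config.column_tolerance}",
        f"nearpair_nt {config.nearpair_nt}",
        f"bootstrap {config.bootstrap}",
    ]

    try:
        models = read_gene_models_tsv(config.gene_models)
    except Exception as exc:
        raise PipelineError("load_gene_models", f"{config.gene_models}: {exc}") from exc
    if config.species is not None:
        if not config.species:
            raise PipelineError("validate", "empty species set")
        missing = [s for s in config.species if s not in models]
        if missing:
            raise PipelineError("validate", f"species without gene models: {missing}")
        models = {s: models[s] for s in config.species}
    if not models:
        raise PipelineError("validate", "no gene models loaded")

    summaries = pd.DataFrame(
        [
            {
                "species": s.species_id,
                "n_exons": s.n_exons,
                "n_introns": s.n_introns,
                "total_intronic_bp": s.total_intronic_bp,
            }
            for s in (summarize_gene(m) for m in models.values())
        ]
    ).set_index("species")
    summaries.to_csv(out / "gene_summaries.tsv", sep="\t")
    results["summaries"] = summaries

    try:
        msa = read_alignment_fasta(config.msa)
    except Exception as exc:
        raise PipelineError("load_alignment", f"{config.msa}: {exc}") from exc

    try:
        aligned = [
            project_site(site, msa)
            for m in models.values()
            for site in infer_intron_sites(m)
        ]
    except Exception as exc:
        raise PipelineError("project", str(exc)) from exc

    clusters = cluster_sites(aligned, column_tolerance=config.column_tolerance)
    for refs, suffix in config.reference_passes:
        try:
            clusters = label_clusters(clusters, list(refs), suffix)
        except Exception as exc:
            raise PipelineError("label", str(exc)) from exc
    clusters = auto_label_remaining(clusters)
    results["clusters"] = clusters
    pd.DataFrame(
        [
            {
                "label": c.label,
                "column": c.alignment_column,
                "phase": c.phase,
                "members": ",".join(sorted(c.members)),
            }
            for c in clusters
        ]
    ).to_csv(out / "site_clusters.tsv", sep="\t", index=False)

    matrix = presence_absence(clusters, list(models))
    matrix.to_csv(out / "presence_absence.tsv", sep="\t")
    results["presence_absence"] = matrix

    pairs = near_intron_pairs(
        clusters,
        max_nt_distance=config.nearpair_nt,
        msa=msa,
        scaffold_species=config.scaffold_species,
    )
    pd.DataFrame(pairs, columns=["site_a", "site_b", "nt_distance"]).to_csv(
        out / "near_intron_pairs.tsv", sep="\t", index=False
    )
    results["near_pairs"] = pairs

    if config.bootstrap > 0:
        try:
            tree_bs, support = bootstrap_support(msa, config.bootstrap, config.seed)
        except Exception as exc:
            raise PipelineError("nj", str(exc)) from exc
        write_tree(tree_bs, out / "nj_tree.nwk")
        results["nj_tree"] = tree_bs
        results["nj_support"] = support
    elif len(msa) >= 3:
        tree_nj = nj_tree(p_distance(msa))
        write_tree(tree_nj, out / "nj_tree.nwk")
        results["nj_tree"] = tree_nj

    if config.tree is not None:
        try:
            species_tree = read_tree(config.tree, rooted=True)
            # Dollo needs every matrix row on the tree; drop others
            leaf_labels = {lf.taxon.label for lf in species_tree.leaf_node_iter()}
            usable = matrix.loc[[s for s in matrix.index if s in leaf_labels]]
            ledger = reconstruct_ledger(usable, species_tree)
            if config.ages is not None:
                ledger = annotate_ages(ledger, read_node_ages(config.ages), species_tree)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("dollo", str(exc)) from exc
        ledger.to_frame().to_csv(out / "event_ledger.tsv", sep="\t", index=False)
        results["ledger"] = ledger

    log_lines.append(f"finished {datetime.datetime.now().isoformat(timespec='seconds')}")
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return results
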