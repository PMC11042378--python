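"""End-to-end pipeline: query -> assemble -> preprocess -> frame -> analyses.

``run_pipeline`` chains every stage against a local repository directory and
writes all stage outputs plus ``run_manifest.json`` (config echo, seed,
package version, per-stage shapes) and ``warnings.tsv`` (machine-readable
log of dropped features, unassigned loci, replicate collisions).  Outputs
are deterministic given (inputs, config, seed); no timestamps are written.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .annotate_frame import assign_loci, build_frame, pair_samples, write_frame
from .diffexpr import chdir_significance
from .errors import ValidationError
from .io_formats import read_gene_annotation, read_manifest, write_matrix
from .methexpr import (
    build_sequence_tensors,
    correlation_distribution,
    gene_correlations,
    gene_linear_fit,
    paired_density_table,
    promoter_summary,
)
from .preprocess import PreprocessConfig, log_counts, run_preprocess
from .repository_client import fetch_and_assemble, load_index, query, sample_metadata

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything the pipeline needs; only ``repository`` has no default."""

    repository: str
    out_dir: str = "methrna_out"
    contrast: str = "tissue"
    impute: bool = True
    quantile_normalize: bool = True
    drop_all_missing: bool = True
    log_pseudocount: float = 1.0
    max_abs_distance: int = 100_000
    statistic: str = "median"
    min_loci: int = 1
    tau: float = 0.3
    alpha: float = 0.05
    gamma: float = 0.5
    n_perm: int = 200
    seed: int = 0
    tensor_length: int = 20
    tensor_window: tuple[int, int] = (-1500, 1500)
    write_tensors: bool = False


class _WarningCollector(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.rows: list[dict] = []

    def emit(self, record: logging.LogRecord) -> None:
        self.rows.append(
            {"logger": record.name, "level": record.levelname, "message": record.getMessage()}
        )


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the output directory."""
    repo = Path(config.repository)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    collector = _WarningCollector()
    root = logging.getLogger("methrna")
    root.addHandler(collector)
    counts: dict[str, dict] = {}
    try:
        # query + assemble
        index = load_index(repo)
        meth = fetch_and_assemble(repo, query(index, {"assay": "methylation"}), "methylation")
        expr = fetch_and_assemble(repo, query(index, {"assay": "expression"}), "expression")
        counts["assemble"] = {
            "methylation": list(meth.data.shape),
            "expression": list(expr.data.shape),
        }

        # preprocess
        pconf = PreprocessConfig(
            impute=config.impute,
            quantile_normalize=config.quantile_normalize,
            drop_all_missing=config.drop_all_missing,
            log_pseudocount=config.log_pseudocount,
        )
        meth = run_preprocess(meth, pconf)
        expr = run_preprocess(expr, pconf)
        write_matrix(meth, out / "methylation.tsv")
        write_matrix(expr, out / "expression.tsv")
        counts["preprocess"] = {
            "methylation": list(meth.data.shape),
            "expression": list(expr.data.shape),
        }

        # annotate + pair + frame
        manifest = read_manifest(repo / "manifest.csv")
        genes = read_gene_annotation(repo / "genes.gtf")
        loci = assign_loci(manifest, genes, max_abs_distance=config.max_abs_distance)
        meta = sample_metadata(index)
        pairs = pair_samples(meta)
        frame = build_frame(meth, expr, loci, pairs, log_pseudocount=config.log_pseudocount)
        write_frame(frame, out / "frame.tsv", out / "frame_loci.tsv", out / "frame_pairs.tsv")
        counts["frame"] = {
            "pairs": len(frame.pairs),
            "genes": len(frame.gene_ids),
            "assigned_loci": int((frame.loci["gene_id"] != "").sum()),
        }

        # differential expression on the contrast field
        if config.contrast not in ("tissue", "patient_id"):
            raise ValidationError(
                f"unknown contrast field {config.contrast!r}; valid: tissue, patient_id"
            )
        expr_meta = {m.sample_id: getattr(m, config.contrast) for m in meta if m.assay == "expression"}
        labels = pd.Series(expr_meta)
        ddx = chdir_significance(
            log_counts(expr, config.log_pseudocount),
            labels,
            gamma=config.gamma,
            n_perm=config.n_perm,
            seed=config.seed,
        )
        ddx.to_csv(out / "ddx.tsv", sep="\t", index=False)
        counts["ddx"] = {"genes": len(ddx), "n_perm": config.n_perm}

        # promoter methylation vs expression
        summaries = promoter_summary(frame, statistic=config.statistic, min_loci=config.min_loci)
        records = gene_correlations(summaries, frame, tau=config.tau, alpha=config.alpha)
        records.to_csv(out / "correlations.tsv", sep="\t", index=False)
        hist, tallies = correlation_distribution(records)
        hist.to_csv(out / "correlation_histogram.tsv", sep="\t", index=False)
        fits = gene_linear_fit(summaries, frame)
        fits.to_csv(out / "linear_fits.tsv", sep="\t", index=False)
        density = paired_density_table(summaries, frame)
        density.to_csv(out / "density_table.tsv", sep="\t", index=False)
        counts["methexpr"] = {"genes": len(records), "density_rows": len(density), **tallies}

        if config.write_tensors:
            tensors = build_sequence_tensors(
                frame, L=config.tensor_length, window=config.tensor_window
            )
            tensors.to_table().to_csv(out / "sequence_tensors.tsv", sep="\t", index=False)
            counts["tensors"] = {"genes": len(tensors.gene_ids), "length": tensors.length}
    finally:
        root.removeHandler(collector)
        pd.DataFrame(collector.rows, columns=["logger", "level", "message"]).to_csv(
            out / "warnings.tsv", sep="\t", index=False
        )

    manifest_obj = {
        "package": "methrna",
        "version": __version__,
        "config": asdict(config),
        "seed": config.seed,
        "stages": counts,
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest_obj, indent=1, sort_keys=True) + "\n")
    return out
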