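"""Synthetic paired methylation/expression repository with planted effects.

Generates a complete local repository (index.json, per-sample TSVs, locus
manifest, gene GTF, sample metadata, truth table) emulating a paired 450K
methylation + RNA-seq study:

* every patient contributes one methylation and one expression sample per
  tissue, so (patient, tissue) pairs always exist;
* RNA-seq counts are negative binomial around a per-gene log-normal level,
  with per-sample biological variation on the log scale;
* beta values are logit-normal; each gene's promoter loci share a gene-level
  latent whose correlation with the expression latent is planted at -rho for
  canonical genes, +rho for non-canonical genes and 0 otherwise, so the
  planted correlation is exact on the logit scale and only observation noise
  (counting noise, per-locus noise, the logit link) attenuates it on the
  observed scale;
* differentially expressed genes get a +/- ``de_log_fold`` shift on the log
  mean between the first two tissues;
* cells are masked missing uniformly at random at ``missing_rate``.

Everything is reproducible from ``seed``: the structural plan (gene layout,
planted classes — the truth table) and the data draws use two independent
streams derived from it, so changing only data-level noise cannot move the
truth labels.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import (
    GeneModel,
    ManifestRow,
    SampleMeta,
    write_gene_annotation,
    write_manifest,
    write_sample_metadata,
)

logger = logging.getLogger(__name__)

CHROMS = ("1", "2", "3", "4", "5")
GENE_SPACING = 200_000  # bp between gene anchors on a chromosome
MAX_LOCUS_DISTANCE = 20_000  # |tss_distance| ceiling for planted loci

# observation-noise scales (see docs/methods.md for the rationale)
EXPR_BASE_LOG_MEAN = 6.0
EXPR_BASE_LOG_SD = 1.0
EXPR_SAMPLE_LOG_SD = 0.5
METH_GENE_LOGIT_SD = 1.0
METH_LOCUS_OFFSET_SD = 0.3
METH_LOCUS_NOISE_SD = 0.3
METH_BASELINE_SD = 1.0
NONPROMOTER_LOGIT_SD = 1.0


@dataclass
class SynthConfig:
    """Study-design and effect-size knobs for the generator."""

    n_patients: int = 20
    tissues: tuple[str, ...] = ("tumor", "normal")
    n_genes: int = 500
    loci_per_gene: tuple[int, int] = (3, 8)
    promoter_locus_fraction: float = 0.6
    n_canonical: int = 50
    n_non_canonical: int = 20
    n_de_genes: int = 20
    rho: float = 0.7
    de_log_fold: float = 1.0
    nb_dispersion: float = 0.02
    missing_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        self.tissues = tuple(self.tissues)
        self.loci_per_gene = tuple(self.loci_per_gene)
        if self.n_patients < 1 or self.n_genes < 1 or len(self.tissues) < 1:
            raise ValidationError("n_patients, n_genes and tissues must be non-empty")
        if self.n_canonical + self.n_non_canonical > self.n_genes:
            raise ValidationError("n_canonical + n_non_canonical exceeds n_genes")
        if self.n_de_genes > self.n_genes:
            raise ValidationError("n_de_genes exceeds n_genes")
        if not 0 < self.rho < 1:
            raise ValidationError("rho must be in (0, 1)")
        if not 0 < self.promoter_locus_fraction <= 1:
            raise ValidationError("promoter_locus_fraction must be in (0, 1]")
        if not 0 <= self.missing_rate < 1:
            raise ValidationError("missing_rate must be in [0, 1)")
        if self.nb_dispersion <= 0:
            raise ValidationError("nb_dispersion must be positive")
        lo, hi = self.loci_per_gene
        if lo < 1 or hi < lo:
            raise ValidationError("loci_per_gene must be a (low, high) range with low >= 1")


@dataclass
class _Plan:
    """Structural plan derived purely from (config, seed): truth, layout."""

    genes: list[GeneModel]
    manifest: list[ManifestRow]
    locus_gene_index: np.ndarray  # gene index per locus
    locus_is_promoter: np.ndarray
    corr_class: np.ndarray  # "canonical" / "non_canonical" / "null" per gene
    de_sign: np.ndarray  # +1 / -1 for DE genes, 0 otherwise


def _plan(config: SynthConfig) -> _Plan:
    rng = np.random.default_rng([config.seed, 0])
    n = config.n_genes

    genes: list[GeneModel] = []
    for i in range(n):
        chrom = CHROMS[i % len(CHROMS)]
        slot = i // len(CHROMS)
        start = 1_000_000 + slot * GENE_SPACING
        length = int(rng.integers(1_000, 20_001))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneModel(
                gene_id=f"g{i:04d}",
                chrom=chrom,
                start=start,
                end=start + length,
                strand=strand,
                gene_name=f"G{i:04d}",
            )
        )

    perm = rng.permutation(n)
    corr_class = np.full(n, "null", dtype=object)
    corr_class[perm[: config.n_canonical]] = "canonical"
    corr_class[perm[config.n_canonical : config.n_canonical + config.n_non_canonical]] = "non_canonical"
    rest = perm[config.n_canonical + config.n_non_canonical :]
    de_genes = rest[: config.n_de_genes] if len(rest) >= config.n_de_genes else perm[: config.n_de_genes]
    de_sign = np.zeros(n, dtype=int)
    de_sign[de_genes] = rng.choice([-1, 1], size=len(de_genes))

    manifest: list[ManifestRow] = []
    locus_gene_index: list[int] = []
    locus_is_promoter: list[bool] = []
    lo, hi = config.loci_per_gene
    locus_counter = 0
    for i, g in enumerate(genes):
        n_loci = int(rng.integers(lo, hi + 1))
        for _ in range(n_loci):
            if rng.random() < config.promoter_locus_fraction:
                d = int(rng.integers(-1500, 0))
                promoter = True
            else:
                if rng.random() < 0.5:
                    d = -int(rng.integers(1_501, MAX_LOCUS_DISTANCE + 1))
                else:
                    d = int(rng.integers(0, MAX_LOCUS_DISTANCE + 1))
                promoter = False
            pos = g.tss + d if g.strand == "+" else g.tss - d
            manifest.append(ManifestRow(f"cg{locus_counter:06d}", g.chrom, pos, g.gene_id))
            locus_gene_index.append(i)
            locus_is_promoter.append(promoter)
            locus_counter += 1

    return _Plan(
        genes,
        manifest,
        np.array(locus_gene_index),
        np.array(locus_is_promoter),
        corr_class,
        de_sign,
    )


def truth_table(config: SynthConfig) -> pd.DataFrame:
    """Ground-truth per-gene labels for recovery tests (byte-stable per seed)."""
    plan = _plan(config)
    signed_rho = np.where(
        plan.corr_class == "canonical",
        -config.rho,
        np.where(plan.corr_class == "non_canonical", config.rho, 0.0),
    )
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in plan.genes],
            "corr_class": plan.corr_class,
            "planted_rho": signed_rho,
            "is_de": plan.de_sign != 0,
            "planted_log_fold": plan.de_sign * config.de_log_fold,
        }
    )


def generate(config: SynthConfig, out_dir: str | Path) -> Path:
    """Write a repository-client-compatible directory; returns its path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "data").mkdir(exist_ok=True)

    plan = _plan(config)
    rng = np.random.default_rng([config.seed, 1])
    n_genes = config.n_genes
    n_loci = len(plan.manifest)

    patients = [f"P{i:04d}" for i in range(config.n_patients)]
    sample_keys = [(p, t) for p in patients for t in config.tissues]
    n_pairs = len(sample_keys)

    # gene-level parameters
    mu = rng.normal(EXPR_BASE_LOG_MEAN, EXPR_BASE_LOG_SD, size=n_genes)
    meth_base = rng.normal(0.0, METH_BASELINE_SD, size=n_genes)
    locus_offset = rng.normal(0.0, METH_LOCUS_OFFSET_SD, size=n_loci)

    # latent correlation structure: w = c*z + sqrt(1-c^2)*eps, exact per gene
    z = rng.normal(size=(n_genes, n_pairs))
    eps = rng.normal(size=(n_genes, n_pairs))
    c = np.where(
        plan.corr_class == "canonical",
        -config.rho,
        np.where(plan.corr_class == "non_canonical", config.rho, 0.0),
    )[:, None]
    w = c * z + np.sqrt(1.0 - c**2) * eps

    # expression: NB counts around exp(mu + biological latent + DE shift)
    de_shift = np.zeros((n_genes, n_pairs))
    if len(config.tissues) >= 2:
        in_second = np.array([t == config.tissues[1] for _, t in sample_keys])
        de_shift[:, in_second] = (plan.de_sign * config.de_log_fold)[:, None]
    log_mean = mu[:, None] + EXPR_SAMPLE_LOG_SD * z + de_shift
    nb_n = 1.0 / config.nb_dispersion
    nb_mean = np.exp(log_mean)
    counts = rng.negative_binomial(nb_n, nb_n / (nb_n + nb_mean))

    # methylation: logit-normal betas; promoter loci share the gene latent w
    locus_noise = rng.normal(size=(n_loci, n_pairs)) * METH_LOCUS_NOISE_SD
    indep = rng.normal(size=(n_loci, n_pairs)) * NONPROMOTER_LOGIT_SD
    gi = plan.locus_gene_index
    logit = locus_offset[:, None] + np.where(
        plan.locus_is_promoter[:, None],
        meth_base[gi][:, None] + METH_GENE_LOGIT_SD * w[gi] + locus_noise,
        indep,
    )
    betas = 1.0 / (1.0 + np.exp(-logit))

    meth_missing = rng.random((n_loci, n_pairs)) < config.missing_rate
    expr_missing = rng.random((n_genes, n_pairs)) < config.missing_rate

    # write per-sample files + index
    locus_ids = [m.locus_id for m in plan.manifest]
    gene_ids = [g.gene_id for g in plan.genes]
    meta: list[SampleMeta] = []
    file_entries: list[dict] = []
    for j, (patient, tissue) in enumerate(sample_keys):
        for assay, suffix in (("methylation", "M"), ("expression", "E")):
            sample_id = f"{patient}-{tissue}-{suffix}"
            rel = f"data/{sample_id}.tsv"
            meta.append(SampleMeta(sample_id, patient, tissue, assay))
            file_entries.append(
                {
                    "assay": assay,
                    "sample_id": sample_id,
                    "patient_id": patient,
                    "tissue": tissue,
                    "relative_path": rel,
                }
            )
            with (out_dir / rel).open("w") as fh:
                if assay == "methylation":
                    for i, locus in enumerate(locus_ids):
                        if not meth_missing[i, j]:
                            fh.write(f"{locus}\t{betas[i, j]:.6f}\n")
                else:
                    for i, gene in enumerate(gene_ids):
                        if not expr_missing[i, j]:
                            fh.write(f"{gene}\t{int(counts[i, j])}\n")

    file_entries.sort(key=lambda e: e["sample_id"])
    index = [{"file_id": f"f{k:05d}", **e} for k, e in enumerate(file_entries)]
    (out_dir / "index.json").write_text(json.dumps(index, indent=1, sort_keys=True) + "\n")

    write_manifest(plan.manifest, out_dir / "manifest.csv")
    write_gene_annotation(plan.genes, out_dir / "genes.gtf")
    write_sample_metadata(meta, out_dir / "samples.tsv")
    truth_table(config).to_csv(out_dir / "truth_table.tsv", sep="\t", index=False)
    (out_dir / "synth_config.json").write_text(json.dumps(asdict(config), sort_keys=True) + "\n")

    logger.info(
        "synthetic repository: %d genes, %d loci, %d sample pairs -> %s",
        n_genes, n_loci, n_pairs, out_dir,
    )
    return out_dir
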