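"""CpG-to-gene annotation, sample pairing, and the paired multi-omic frame.

Each CpG locus is assigned to the single gene (same chromosome) whose TSS is
nearest by absolute distance, within a configurable radius.  Distances are
signed and strand-aware: negative means upstream of the TSS in the gene's
reading direction (for + genes, distance = pos - tss; for - genes,
distance = tss - pos).  The promoter window is [-1500, 0): inclusive 1500 bp
upstream, exclusive at the TSS base itself.

Samples are paired within (patient, tissue): one methylation and one
expression sample per key.  The multi-omic frame has one row per pair and
hierarchical columns (gene, kind) where kind is ``expr`` for the gene's
log-expression column or a locus id for each of its methylation columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import AssayMatrix, GeneModel, ManifestRow, SampleMeta

logger = logging.getLogger(__name__)

PROMOTER_UPSTREAM = 1500  # bp upstream of the TSS defining the promoter window
EXPR_KIND = "expr"  # column-kind tag for the expression column of a gene


@dataclass(frozen=True)
class LocusAnnotation:
    """A CpG locus with its assigned gene and signed distance to that TSS.

    ``gene_id`` is ``None`` when no TSS lies within the assignment radius;
    such loci are reported but excluded from downstream analyses.
    """

    locus_id: str
    chrom: str
    pos: int
    gene_id: str | None
    tss_distance: int | None
    in_promoter: bool


@dataclass(frozen=True)
class SamplePair:
    """Matched methylation + expression samples from one (patient, tissue)."""

    patient_id: str
    tissue: str
    meth_sample_id: str
    expr_sample_id: str

    @property
    def key(self) -> tuple[str, str]:
        return (self.patient_id, self.tissue)


@dataclass
class MultiOmicFrame:
    """Paired frame: rows = sample pairs, hierarchical columns per gene.

    ``data`` is indexed by (patient_id, tissue) with MultiIndex columns
    (gene_id, kind); kind ``expr`` holds ln(count + pseudocount), any other
    kind is a locus id holding beta values.  ``loci`` is the locus metadata
    sidecar (indexed by locus_id: gene_id, tss_distance, in_promoter).
    """

    data: pd.DataFrame
    pairs: list[SamplePair]
    loci: pd.DataFrame
    log_pseudocount: float = 1.0

    @property
    def gene_ids(self) -> list[str]:
        return list(dict.fromkeys(self.data.columns.get_level_values(0)))

    def expression(self) -> pd.DataFrame:
        """Rows = pairs, columns = genes; log-scale expression."""
        cols = [c for c in self.data.columns if c[1] == EXPR_KIND]
        out = self.data[cols]
        out.columns = [c[0] for c in cols]
        return out

    def gene_loci(self, gene_id: str, promoter_only: bool = False) -> list[str]:
        """Locus ids under a gene, ordered by ascending tss_distance."""
        loci = [c[1] for c in self.data.columns if c[0] == gene_id and c[1] != EXPR_KIND]
        if promoter_only:
            loci = [l for l in loci if bool(self.loci.loc[l, "in_promoter"])]
        return loci


def signed_tss_distance(pos: int, gene: GeneModel) -> int:
    """Signed bp from a position to a gene's TSS; negative = upstream."""
    return pos - gene.tss if gene.strand == "+" else gene.tss - pos


def in_promoter_window(distance: int, upstream: int = PROMOTER_UPSTREAM) -> bool:
    return -upstream <= distance < 0


# ---------------------------------------------------------------------------
# Locus -> gene assignment
# ---------------------------------------------------------------------------


def assign_loci(
    manifest: Sequence[ManifestRow],
    genes: Sequence[GeneModel],
    max_abs_distance: int = 100_000,
) -> list[LocusAnnotation]:
    """Assign each locus to the nearest-TSS gene on its chromosome.

    Ties on absolute distance prefer the gene for which the locus lies
    upstream (negative signed distance), then the lexicographically smaller
    gene id.  Loci with no TSS within ``max_abs_distance`` get gene_id None.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in sorted(genes, key=lambda g: g.gene_id):
        by_chrom.setdefault(g.chrom, []).append(g)
    chrom_arrays = {
        c: (
            np.array([g.tss for g in gs], dtype=np.int64),
            np.array([g.strand == "+" for g in gs], dtype=bool),
            gs,
        )
        for c, gs in by_chrom.items()
    }

    out: list[LocusAnnotation] = []
    n_unassigned = 0
    for row in manifest:
        best = None
        if row.chrom in chrom_arrays:
            tss, plus, gs = chrom_arrays[row.chrom]
            d = np.where(plus, row.pos - tss, tss - row.pos)
            absd = np.abs(d)
            ok = absd <= max_abs_distance
            if ok.any():
                # lexicographic key (|d|, downstream?) over genes pre-sorted
                # by gene_id, so argmin lands on the stated tie-break
                score = np.where(ok, absd * 2 + (d >= 0), np.iinfo(np.int64).max)
                i = int(np.argmin(score))
                best = (gs[i], int(d[i]))
        if best is None:
            n_unassigned += 1
            out.append(LocusAnnotation(row.locus_id, row.chrom, row.pos, None, None, False))
        else:
            gene, dist = best
            out.append(
                LocusAnnotation(
                    row.locus_id, row.chrom, row.pos, gene.gene_id, dist, in_promoter_window(dist)
                )
            )
    if n_unassigned:
        logger.warning("%d locus/loci had no gene TSS within %d bp", n_unassigned, max_abs_distance)
    return out


def loci_table(loci: Sequence[LocusAnnotation]) -> pd.DataFrame:
    """Locus annotations as a DataFrame indexed by locus_id."""
    df = pd.DataFrame(
        {
            "locus_id": [l.locus_id for l in loci],
            "chrom": [l.chrom for l in loci],
            "pos": [l.pos for l in loci],
            "gene_id": [l.gene_id if l.gene_id is not None else "" for l in loci],
            "tss_distance": [l.tss_distance for l in loci],
            "in_promoter": [l.in_promoter for l in loci],
        }
    )
    return df.set_index("locus_id", drop=False)


# ---------------------------------------------------------------------------
# Sample pairing
# ---------------------------------------------------------------------------


def pair_samples(meta: Sequence[SampleMeta]) -> list[SamplePair]:
    """One pair per (patient, tissue) holding both assays.

    When a key has replicate samples for an assay, the lexicographically
    smallest sample id wins and a warning is logged.  Output is sorted by
    (patient_id, tissue).
    """
    buckets: dict[tuple[str, str], dict[str, list[str]]] = {}
    for s in meta:
        buckets.setdefault((s.patient_id, s.tissue), {}).setdefault(s.assay, []).append(s.sample_id)
    pairs: list[SamplePair] = []
    for (patient, tissue), assays in sorted(buckets.items()):
        meths = sorted(assays.get("methylation", []))
        exprs = sorted(assays.get("expression", []))
        if not meths or not exprs:
            continue
        for assay_name, ids in (("methylation", meths), ("expression", exprs)):
            if len(ids) > 1:
                logger.warning(
                    "(%s, %s) has %d %s replicates; keeping %s",
                    patient, tissue, len(ids), assay_name, ids[0],
                )
        pairs.append(SamplePair(patient, tissue, meths[0], exprs[0]))
    return pairs


# ---------------------------------------------------------------------------
# Frame construction
# ---------------------------------------------------------------------------


def build_frame(
    meth: AssayMatrix,
    expr: AssayMatrix,
    loci: Sequence[LocusAnnotation],
    pairs: Sequence[SamplePair],
    log_pseudocount: float = 1.0,
) -> MultiOmicFrame:
    """Assemble the paired multi-omic frame.

    Genes present are the expression matrix's features.  Methylation columns
    are grouped under their assigned gene, ordered by ascending tss_distance;
    expression is stored as ln(count + pseudocount) (matrices already on the
    log scale are taken as-is).
    """
    if not pairs:
        raise ValidationError("no paired samples: frame would be empty")
    for p in pairs:
        if p.meth_sample_id not in meth.data.columns:
            raise ValidationError(
                f"pair ({p.patient_id}, {p.tissue}): methylation sample "
                f"{p.meth_sample_id!r} absent from the methylation matrix"
            )
        if p.expr_sample_id not in expr.data.columns:
            raise ValidationError(
                f"pair ({p.patient_id}, {p.tissue}): expression sample "
                f"{p.expr_sample_id!r} absent from the expression matrix"
            )

    pairs = sorted(pairs, key=lambda p: p.key)
    row_index = pd.MultiIndex.from_tuples([p.key for p in pairs], names=["patient_id", "tissue"])

    expr_vals = expr.data[[p.expr_sample_id for p in pairs]].to_numpy(dtype=float).T
    if expr.scale != "log":
        expr_vals = np.log(expr_vals + log_pseudocount)

    gene_ids = list(expr.data.index)
    gene_set = set(gene_ids)
    loci_by_gene: dict[str, list[LocusAnnotation]] = {}
    for l in loci:
        if l.gene_id in gene_set and l.locus_id in meth.data.index:
            loci_by_gene.setdefault(l.gene_id, []).append(l)

    meth_cols = meth.data[[p.meth_sample_id for p in pairs]]

    columns: list[tuple[str, str]] = []
    blocks: list[np.ndarray] = []
    kept_loci: list[LocusAnnotation] = []
    for gi, gene in enumerate(gene_ids):
        columns.append((gene, EXPR_KIND))
        blocks.append(expr_vals[:, gi : gi + 1])
        for l in sorted(loci_by_gene.get(gene, []), key=lambda l: (l.tss_distance, l.locus_id)):
            columns.append((gene, l.locus_id))
            blocks.append(meth_cols.loc[[l.locus_id]].to_numpy(dtype=float).T)
            kept_loci.append(l)

    data = pd.DataFrame(
        np.hstack(blocks),
        index=row_index,
        columns=pd.MultiIndex.from_tuples(columns, names=["gene_id", "kind"]),
    )
    return MultiOmicFrame(data, list(pairs), loci_table(kept_loci), log_pseudocount)


# ---------------------------------------------------------------------------
# Frame serialization
# ---------------------------------------------------------------------------


def write_frame(
    frame: MultiOmicFrame,
    data_path: str | Path,
    loci_path: str | Path,
    pairs_path: str | Path | None = None,
) -> None:
    """Write the frame as a two-header-row TSV plus a locus sidecar TSV.

    ``pairs_path`` optionally records the pair -> sample-id mapping so a
    read back reconstructs the frame exactly.
    """
    frame.data.to_csv(data_path, sep="\t")
    frame.loci.to_csv(loci_path, sep="\t", index=False)
    if pairs_path is not None:
        pd.DataFrame([p.__dict__ for p in frame.pairs]).to_csv(pairs_path, sep="\t", index=False)


def read_frame(
    data_path: str | Path,
    loci_path: str | Path,
    pairs_path: str | Path | None = None,
) -> MultiOmicFrame:
    data = pd.read_csv(
        data_path, sep="\t", header=[0, 1], index_col=[0, 1], float_precision="round_trip"
    )
    data.index.names = ["patient_id", "tissue"]
    data.columns.names = ["gene_id", "kind"]
    loci = pd.read_csv(
        loci_path, sep="\t", dtype={"locus_id": str, "gene_id": str, "chrom": str}
    ).set_index("locus_id", drop=False)
    if pairs_path is not None:
        pdf = pd.read_csv(pairs_path, sep="\t", dtype=str)
        pairs = [SamplePair(**rec) for rec in pdf.to_dict("records")]
    else:
        pairs = [SamplePair(str(p), str(t), "", "") for p, t in data.index]
    return MultiOmicFrame(data, pairs, loci)
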