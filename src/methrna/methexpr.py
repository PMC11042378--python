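"""Promoter methylation vs. expression: summaries, correlation, classification.

For each gene, promoter methylation is summarized per sample pair (median by
default over loci in the [-1500, 0) promoter window) and correlated with the
gene's log expression across pairs (Pearson r, two-sided p from the exact
t-transform with n - 2 df, Benjamini-Hochberg q across genes).  Genes are
labelled ``canonical`` when significantly anti-correlated (the expected
silencing relationship, r <= -tau and q <= alpha), ``non_canonical`` when
significantly positively correlated, and ``unclassified`` otherwise.

Also provides the flat (gene, pair) table behind joint-density views, the
per-gene least-squares prediction of expression from promoter methylation,
and fixed-length locus-sequence tensors for downstream sequence models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotate_frame import EXPR_KIND, MultiOmicFrame
from .errors import ValidationError

logger = logging.getLogger(__name__)

LABELS = ("canonical", "non_canonical", "unclassified")
MIN_PAIRS = 3
HIST_BIN_WIDTH = 0.05


def promoter_summary(
    frame: MultiOmicFrame, statistic: str = "median", min_loci: int = 1
) -> pd.DataFrame:
    """Per-(gene, pair) summary of promoter beta values.

    Returns a DataFrame with one row per sample pair and one column per
    gene; genes with fewer than ``min_loci`` promoter loci are all-NaN and
    logged.
    """
    if statistic not in ("median", "mean"):
        raise ValidationError(f"statistic must be 'median' or 'mean', got {statistic!r}")
    if min_loci < 1:
        raise ValidationError("min_loci must be >= 1")
    fn = np.nanmedian if statistic == "median" else np.nanmean
    out: dict[str, np.ndarray] = {}
    short: list[str] = []
    nan_col = np.full(len(frame.data), np.nan)
    for gene in frame.gene_ids:
        loci = frame.gene_loci(gene, promoter_only=True)
        if len(loci) < min_loci:
            short.append(gene)
            out[gene] = nan_col.copy()
            continue
        block = frame.data[[(gene, l) for l in loci]].to_numpy(dtype=float)
        with np.errstate(all="ignore"):
            out[gene] = fn(block, axis=1)
    if short:
        logger.warning(
            "%d gene(s) with < %d promoter locus/loci have no summary: %s",
            len(short), min_loci, ", ".join(short[:5]),
        )
    return pd.DataFrame(out, index=frame.data.index)


def gene_correlations(
    summaries: pd.DataFrame,
    frame: MultiOmicFrame,
    tau: float = 0.3,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene Pearson correlation of promoter summary with log expression.

    Genes with fewer than 3 complete pairs or a constant input vector are
    ``unclassified`` with the reason recorded.  Returns a DataFrame with
    columns gene_id, n_pairs, r, p, q, label, reason.
    """
    if not 0 < tau < 1:
        raise ValidationError(f"tau must be in (0, 1), got {tau}")
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    expr = frame.expression()
    rows = []
    for gene in summaries.columns:
        s = summaries[gene].to_numpy(dtype=float)
        e = expr[gene].to_numpy(dtype=float) if gene in expr.columns else np.full(len(s), np.nan)
        ok = ~np.isnan(s) & ~np.isnan(e)
        n = int(ok.sum())
        if n < MIN_PAIRS:
            rows.append((gene, n, np.nan, np.nan, "insufficient pairs"))
            continue
        sv, ev = s[ok], e[ok]
        if np.ptp(sv) == 0 or np.ptp(ev) == 0:
            rows.append((gene, n, np.nan, np.nan, "constant input"))
            continue
        r, p = stats.pearsonr(sv, ev)
        rows.append((gene, n, float(r), float(p), ""))
    out = pd.DataFrame(rows, columns=["gene_id", "n_pairs", "r", "p", "reason"])

    tested = out["p"].notna()
    q = np.full(len(out), np.nan)
    if tested.any():
        q[tested.to_numpy()] = multipletests(out.loc[tested, "p"], method="fdr_bh")[1]
    out["q"] = q

    label = np.full(len(out), "unclassified", dtype=object)
    sig = tested.to_numpy() & (q <= alpha)
    label[sig & (out["r"].to_numpy() <= -tau)] = "canonical"
    label[sig & (out["r"].to_numpy() >= tau)] = "non_canonical"
    out["label"] = label
    return out[["gene_id", "n_pairs", "r", "p", "q", "label", "reason"]]


def correlation_distribution(records: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Histogram of r (bin width 0.05 over [-1, 1]) and per-label tallies."""
    edges = np.round(np.arange(-1.0, 1.0 + HIST_BIN_WIDTH / 2, HIST_BIN_WIDTH), 10)
    if len(records):
        r = records["r"].dropna().to_numpy(dtype=float)
        counts, _ = np.histogram(r, bins=edges)
        tallies = {
            f"n_{lab}": int((records["label"] == lab).sum()) for lab in LABELS
        }
    else:
        counts = np.zeros(len(edges) - 1, dtype=int)
        tallies = {f"n_{lab}": 0 for lab in LABELS}
    hist = pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts})
    return hist, tallies


def paired_density_table(summaries: pd.DataFrame, frame: MultiOmicFrame) -> pd.DataFrame:
    """Long table (gene_id, patient_id, tissue, promoter_summary, log_expr).

    One row per (gene, pair) where both values are present — the flat data
    behind a methylation-vs-expression joint density plot.
    """
    expr = frame.expression()
    long_s = summaries.stack(future_stack=True).rename("promoter_summary")
    long_e = expr.stack(future_stack=True).rename("log_expr")
    df = pd.concat([long_s, long_e], axis=1, join="inner").dropna()
    df = df.reset_index()
    df.columns = ["patient_id", "tissue", "gene_id", "promoter_summary", "log_expr"]
    return df[["gene_id", "patient_id", "tissue", "promoter_summary", "log_expr"]]


def gene_linear_fit(summaries: pd.DataFrame, frame: MultiOmicFrame) -> pd.DataFrame:
    """Per-gene OLS of log expression on the promoter summary.

    Returns gene_id, n_pairs, slope, intercept, r_squared, reason; constant
    predictors and genes below 3 pairs are skipped with the reason recorded.
    """
    expr = frame.expression()
    rows = []
    for gene in summaries.columns:
        s = summaries[gene].to_numpy(dtype=float)
        e = expr[gene].to_numpy(dtype=float) if gene in expr.columns else np.full(len(s), np.nan)
        ok = ~np.isnan(s) & ~np.isnan(e)
        n = int(ok.sum())
        if n < MIN_PAIRS:
            rows.append((gene, n, np.nan, np.nan, np.nan, "insufficient pairs"))
            continue
        sv, ev = s[ok], e[ok]
        if np.ptp(sv) == 0:
            rows.append((gene, n, np.nan, np.nan, np.nan, "constant predictor"))
            continue
        fit = stats.linregress(sv, ev)
        rows.append((gene, n, fit.slope, fit.intercept, fit.rvalue**2, ""))
    return pd.DataFrame(
        rows, columns=["gene_id", "n_pairs", "slope", "intercept", "r_squared", "reason"]
    )


# ---------------------------------------------------------------------------
# Sequence tensors
# ---------------------------------------------------------------------------


@dataclass
class SequenceTensorSet:
    """Fixed-length locus sequences per (gene, pair) for sequence models.

    ``values``: (n_genes, n_pairs, L) beta values, 0 in padded slots;
    ``tss_distance``: (n_genes, L) signed distances (0 in padding);
    ``mask``: (n_genes, L) True for real slots (real slots precede padding);
    ``target``: (n_genes, n_pairs) log expression.
    """

    gene_ids: list[str]
    pair_keys: list[tuple[str, str]]
    values: np.ndarray
    tss_distance: np.ndarray
    mask: np.ndarray
    target: np.ndarray
    length: int

    @property
    def n_tensors(self) -> int:
        return len(self.gene_ids) * len(self.pair_keys)

    def to_table(self) -> pd.DataFrame:
        """Flat TSV form: gene_id, pair_index, slot, beta, tss_distance, mask."""
        g, p, l = self.values.shape
        gi, pi, si = np.meshgrid(np.arange(g), np.arange(p), np.arange(l), indexing="ij")
        return pd.DataFrame(
            {
                "gene_id": np.array(self.gene_ids)[gi.ravel()],
                "pair_index": pi.ravel(),
                "slot": si.ravel(),
                "beta": self.values.ravel(),
                "tss_distance": self.tss_distance[:, None, :].repeat(p, axis=1).ravel(),
                "mask": self.mask[:, None, :].repeat(p, axis=1).ravel().astype(int),
            }
        )


def build_sequence_tensors(
    frame: MultiOmicFrame, L: int = 20, window: tuple[int, int] = (-1500, 1500)
) -> SequenceTensorSet:
    """Build padded/truncated locus sequences around each gene's TSS.

    Per gene, loci with tss_distance in ``window`` are ordered by ascending
    tss_distance; if more than ``L``, the loci farthest from the TSS are
    dropped first; if fewer, sequences are right-padded (value 0, mask
    False).  Genes with no in-window locus are omitted.  Targets are the
    aligned log-expression values.
    """
    if L < 1:
        raise ValidationError(f"sequence length L must be >= 1, got {L}")
    lo, hi = window
    if hi < lo:
        raise ValidationError(f"invalid window {window}")
    expr = frame.expression()

    gene_ids: list[str] = []
    val_rows, tss_rows, mask_rows, targets = [], [], [], []
    for gene in frame.gene_ids:
        loci = frame.gene_loci(gene)
        dists = {l: int(frame.loci.loc[l, "tss_distance"]) for l in loci}
        in_win = [l for l in loci if lo <= dists[l] <= hi]
        if not in_win:
            continue
        if len(in_win) > L:
            # drop farthest-from-TSS first, keep ascending-distance order
            keep = set(sorted(in_win, key=lambda l: (abs(dists[l]), dists[l], l))[:L])
            in_win = [l for l in in_win if l in keep]
        betas = frame.data[[(gene, l) for l in in_win]].to_numpy(dtype=float)
        k = len(in_win)
        pad = L - k
        val_rows.append(np.pad(betas, ((0, 0), (0, pad))))
        tss_rows.append(np.pad(np.array([dists[l] for l in in_win]), (0, pad)))
        mask_rows.append(np.pad(np.ones(k, dtype=bool), (0, pad)))
        targets.append(expr[gene].to_numpy(dtype=float))
        gene_ids.append(gene)

    pair_keys = [p.key for p in frame.pairs]
    if not gene_ids:
        shape = (0, len(pair_keys), L)
        return SequenceTensorSet(
            [], pair_keys, np.zeros(shape), np.zeros((0, L), dtype=int),
            np.zeros((0, L), dtype=bool), np.zeros((0, len(pair_keys))), L,
        )
    return SequenceTensorSet(
        gene_ids,
        pair_keys,
        np.stack(val_rows),
        np.stack(tss_rows).astype(int),
        np.stack(mask_rows),
        np.stack(targets),
        L,
    )
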