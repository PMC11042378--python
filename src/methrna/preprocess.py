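"""Matrix preprocessing: mean imputation, quantile normalization, transforms.

Imputation is per-feature (row) mean: the feature is the biological unit
shared across samples.  Quantile normalization is the classic rank-mean
procedure applied within one assay matrix at a time.  When both steps are
requested, imputation runs first, because normalization requires complete
data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import AssayMatrix

logger = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    """Knobs for the standard preprocessing chain.

    ``log_pseudocount`` is added to counts before the natural log;
    ``mvalue_epsilon`` clips beta values away from {0, 1} before the logit
    (must be < 0.5 or clipping would invert order).
    """

    impute: bool = True
    quantile_normalize: bool = True
    drop_all_missing: bool = True
    log_pseudocount: float = 1.0
    mvalue_epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if self.log_pseudocount <= 0:
            raise ValidationError("log_pseudocount must be positive")
        if not 0 < self.mvalue_epsilon < 0.5:
            raise ValidationError("mvalue_epsilon must be in (0, 0.5)")


def mean_impute(m: AssayMatrix, drop_all_missing: bool = True) -> AssayMatrix:
    """Replace each missing cell by the mean of its feature's observed values.

    Features with no observed value at all are dropped (and logged) when
    ``drop_all_missing`` is true, else an error names the feature.
    Idempotent: observed cells are never touched.
    """
    vals = m.data.to_numpy(dtype=float, copy=True)
    all_missing = np.isnan(vals).all(axis=1)
    if all_missing.any():
        names = list(m.data.index[all_missing])
        if not drop_all_missing:
            raise ValidationError(f"feature(s) with no observed values: {', '.join(names[:5])}")
        logger.warning("dropping %d all-missing feature(s): %s", len(names), ", ".join(names[:5]))
        vals = vals[~all_missing]
        index = m.data.index[~all_missing]
    else:
        index = m.data.index
    row_means = np.nanmean(vals, axis=1)
    miss = np.isnan(vals)
    vals[miss] = np.broadcast_to(row_means[:, None], vals.shape)[miss]
    return m.replace(pd.DataFrame(vals, index=index, columns=m.data.columns))


def quantile_normalize(m: AssayMatrix) -> AssayMatrix:
    """Classic rank-mean quantile normalization across sample columns.

    Each column is sorted, the reference distribution is the across-column
    mean at each rank, and each column's values are mapped to the reference
    by rank.  Ties within a column receive the mean of the reference values
    their tied ranks span.  Requires complete data (impute first).
    """
    vals = m.data.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValidationError("matrix has missing values; run mean_impute before quantile_normalize")
    n, k = vals.shape
    if n == 0 or k == 0:
        return m.replace(m.data.copy())
    order = np.argsort(vals, axis=0, kind="stable")
    ref = np.take_along_axis(vals, order, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(k):
        assigned = np.empty(n)
        assigned[order[:, j]] = ref
        col = pd.Series(assigned)
        # average the reference values across tied input values
        out[:, j] = col.groupby(vals[:, j]).transform("mean").to_numpy()
    return m.replace(pd.DataFrame(out, index=m.data.index, columns=m.data.columns))


def log_counts(m: AssayMatrix, pseudocount: float = 1.0) -> AssayMatrix:
    """Map expression counts x to ln(x + pseudocount)."""
    if m.assay != "expression":
        raise ValidationError(f"log_counts expects an expression matrix, got assay {m.assay!r}")
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    vals = m.data.to_numpy(dtype=float)
    if np.nanmin(vals, initial=0.0) < 0:
        raise ValidationError("negative count encountered")
    return m.replace(
        pd.DataFrame(np.log(vals + pseudocount), index=m.data.index, columns=m.data.columns),
        scale="log",
    )


def beta_to_mvalue(m: AssayMatrix, epsilon: float = 1e-6) -> AssayMatrix:
    """Map beta values to M-values: log2(b / (1 - b)) after clipping.

    Betas are clipped to [epsilon, 1 - epsilon] so boundary values stay
    finite; the M-value scale is the more homoscedastic choice for linear
    statistics on methylation.
    """
    if m.assay != "methylation" or m.scale != "beta":
        raise ValidationError("beta_to_mvalue expects a methylation matrix on the beta scale")
    if not 0 < epsilon < 0.5:
        raise ValidationError("epsilon must be in (0, 0.5)")
    b = np.clip(m.data.to_numpy(dtype=float), epsilon, 1 - epsilon)
    return m.replace(
        pd.DataFrame(np.log2(b / (1 - b)), index=m.data.index, columns=m.data.columns),
        scale="mvalue",
    )


def run_preprocess(m: AssayMatrix, config: PreprocessConfig | None = None) -> AssayMatrix:
    """Apply the configured chain: impute, then quantile-normalize."""
    config = config or PreprocessConfig()
    if config.impute:
        m = mean_impute(m, drop_all_missing=config.drop_all_missing)
    if config.quantile_normalize:
        m = quantile_normalize(m)
    return m
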