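"""Two-group differential expression via the characteristic direction.

The characteristic direction is the unit vector in gene space that best
separates two sample groups under shrinkage-regularized linear discriminant
analysis: it solves

    (gamma * S + (1 - gamma) * I) b = mu2 - mu1

where mu_g are the per-group gene means, S is the pooled within-group
covariance of genes, and gamma in (0, 1] trades the empirical covariance
against the identity.  Component magnitudes of the unit-normalized b rank
genes by their contribution to the class difference; the sign convention is
that positive components are higher in the second group (groups sorted
lexicographically unless given explicitly).

Significance is assessed by label permutation: the null distribution of
each gene's |component| is built by recomputing the direction on permuted
group labels, with Benjamini-Hochberg control across genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from statsmodels.stats.multitest import multipletests

from .errors import ComputationError, ValidationError
from .io_formats import AssayMatrix

logger = logging.getLogger(__name__)

_ZERO_NORM = 1e-12


@dataclass
class ChdirResult:
    """Characteristic-direction output.

    ``direction`` is the unit vector over retained genes; ``dropped_genes``
    lists genes removed for having zero variance in both groups.
    """

    direction: pd.Series
    gamma: float
    groups: tuple[str, str]
    dropped_genes: list[str] = field(default_factory=list)

    def ranked(self) -> pd.Series:
        return self.direction.reindex(self.direction.abs().sort_values(ascending=False).index)


def _as_frame(expr: AssayMatrix | pd.DataFrame) -> pd.DataFrame:
    return expr.data if isinstance(expr, AssayMatrix) else expr


def _group_masks(
    columns: pd.Index, labels: pd.Series, groups: tuple[str, str] | None
) -> tuple[np.ndarray, np.ndarray, tuple[str, str]]:
    labels = pd.Series(labels).astype(str)
    if not set(columns).issubset(set(labels.index)):
        missing = sorted(set(columns) - set(labels.index))
        raise ValidationError(f"samples without a group label: {', '.join(missing[:5])}")
    lab = labels.reindex(columns)
    uniq = sorted(lab.unique())
    if groups is None:
        if len(uniq) != 2:
            raise ValidationError(f"expected exactly 2 groups, found {len(uniq)}: {uniq[:6]}")
        groups = (uniq[0], uniq[1])
    else:
        extra = set(uniq) - set(groups)
        if extra or len(set(groups)) != 2:
            raise ValidationError(f"labels contain values outside the contrast {groups}: {sorted(extra)}")
    m1 = (lab == groups[0]).to_numpy()
    m2 = (lab == groups[1]).to_numpy()
    if m1.sum() < 2 or m2.sum() < 2:
        raise ValidationError(
            f"each group needs >= 2 samples; got {int(m1.sum())} {groups[0]!r}, "
            f"{int(m2.sum())} {groups[1]!r}"
        )
    return m1, m2, groups


def _direction(X: np.ndarray, m1: np.ndarray, m2: np.ndarray, gamma: float) -> np.ndarray:
    """Solve the regularized system for genes-x-samples data ``X``."""
    X1, X2 = X[:, m1], X[:, m2]
    n1, n2 = X1.shape[1], X2.shape[1]
    mu1, mu2 = X1.mean(axis=1), X2.mean(axis=1)
    delta = mu2 - mu1
    C1 = X1 - mu1[:, None]
    C2 = X2 - mu2[:, None]
    S = (C1 @ C1.T + C2 @ C2.T) / (n1 + n2 - 2)
    A = gamma * S + (1.0 - gamma) * np.eye(X.shape[0])
    try:
        b = linalg.solve(A, delta, assume_a="pos")
    except linalg.LinAlgError as e:  # singular S at gamma == 1
        raise ComputationError(f"regularized covariance system is singular: {e}") from None
    return b


def chdir(
    expr: AssayMatrix | pd.DataFrame,
    labels: pd.Series | dict,
    gamma: float = 0.5,
    groups: tuple[str, str] | None = None,
) -> ChdirResult:
    """Compute the characteristic direction between two sample groups.

    ``expr`` is a genes x samples matrix on the log scale; ``labels`` maps
    sample id to group.  Genes with zero variance in both groups are dropped
    with a warning.  Raises :class:`ComputationError` when the group means
    coincide (no direction exists).
    """
    if not 0 < gamma <= 1:
        raise ValidationError(f"gamma must be in (0, 1], got {gamma}")
    df = _as_frame(expr)
    m1, m2, groups = _group_masks(df.columns, pd.Series(labels), groups)
    X = df.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValidationError("expression matrix has missing values; impute first")

    v1 = X[:, m1].var(axis=1)
    v2 = X[:, m2].var(axis=1)
    dead = (v1 == 0) & (v2 == 0)
    dropped = list(df.index[dead])
    if dropped:
        logger.warning("dropping %d zero-variance gene(s): %s", len(dropped), ", ".join(dropped[:5]))
        X = X[~dead]
        index = df.index[~dead]
    else:
        index = df.index

    b = _direction(X, m1, m2, gamma)
    norm = float(np.linalg.norm(b))
    if norm < _ZERO_NORM:
        raise ComputationError("no direction: the group means are identical")
    return ChdirResult(pd.Series(b / norm, index=index), gamma, groups, dropped)


def chdir_significance(
    expr: AssayMatrix | pd.DataFrame,
    labels: pd.Series | dict,
    gamma: float = 0.5,
    n_perm: int = 200,
    seed: int = 0,
    groups: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Permutation p- and BH q-values for each gene's |direction component|.

    Per gene, p = (1 + #{permutations with |b_perm| >= |b_obs|}) / (n_perm + 1).
    The gene set is fixed to the genes retained under the observed labels.
    Returns a DataFrame (gene_id, direction_component, p, q, rank) sorted by
    |direction_component| descending.
    """
    if n_perm < 100:
        raise ValidationError(f"n_perm must be >= 100 for a usable null, got {n_perm}")
    obs = chdir(expr, labels, gamma=gamma, groups=groups)
    df = _as_frame(expr).loc[obs.direction.index]
    lab = pd.Series(labels).astype(str).reindex(df.columns)
    m1 = (lab == obs.groups[0]).to_numpy()
    m2 = (lab == obs.groups[1]).to_numpy()
    X = df.to_numpy(dtype=float)
    abs_obs = obs.direction.abs().to_numpy()

    rng = np.random.default_rng(seed)
    lab_arr = np.where(m2, 1, 0)
    exceed = np.zeros(X.shape[0], dtype=np.int64)
    for _ in range(n_perm):
        perm = rng.permutation(lab_arr)
        p1, p2 = perm == 0, perm == 1
        b = _direction(X, p1, p2, gamma)
        norm = float(np.linalg.norm(b))
        if norm < _ZERO_NORM:
            continue  # degenerate permutation contributes nothing extreme
        exceed += (np.abs(b) / norm) >= abs_obs
    p = (1.0 + exceed) / (n_perm + 1.0)
    q = multipletests(p, method="fdr_bh")[1]

    out = pd.DataFrame(
        {
            "gene_id": obs.direction.index,
            "direction_component": obs.direction.to_numpy(),
            "p": p,
            "q": q,
        }
    )
    out = out.reindex(out["direction_component"].abs().sort_values(ascending=False).index)
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)
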