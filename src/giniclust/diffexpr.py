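"""Cluster characterization: differential expression, overlap tests, and the
2C-like signature score.

For RNA-seq counts, differential expression between a rare cluster and the
reference cluster uses a two-part hurdle model: single-cell counts are mostly
zero, so the information splits into *whether* a gene is detected (a logistic
model on the detection indicator) and *how much* is expressed when detected
(a Gaussian model on log2 counts among detected cells).  Both parts include
the cellular detection rate (CDR, the fraction of genes detected per cell) as
a covariate, which absorbs the dominant technical axis of single-cell data.
The test statistic is the sum of the two components' likelihood-ratio
deviance drops for the group term, referred to a chi-square distribution with
one degree of freedom per estimable component.

This is a native implementation of the standard hurdle likelihood-ratio test;
it deliberately omits the empirical-Bayes variance shrinkage some hurdle
packages layer on top, so per-gene results are driven by that gene alone.

qPCR expression is approximately log-normal and rarely zero, so a Welch
two-sided t-test per gene replaces the hurdle model there.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import ExpressionMatrix

__all__ = [
    "fold_change",
    "hurdle_lrt",
    "t_test_de",
    "fisher_overlap",
    "signature_score",
    "cellular_detection_rate",
]

DEFAULT_PSEUDOCOUNT = 0.1


def _group_indices(m: ExpressionMatrix, group: Sequence[str]) -> np.ndarray:
    lookup = {c: i for i, c in enumerate(m.cell_names)}
    try:
        idx = np.array([lookup[str(c)] for c in group], dtype=int)
    except KeyError as err:
        raise KeyError(f"unknown cell: {err.args[0]!r}") from None
    if idx.size == 0:
        raise ValueError("empty cell group")
    return idx


def cellular_detection_rate(m: ExpressionMatrix) -> np.ndarray:
    """Fraction of genes detected (value > 0) in each cell."""
    return (m.values > 0).mean(axis=0)


def fold_change(
    m: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> np.ndarray:
    """Per-gene pseudocount-stabilized mean ratio of group A over group B.

    Computed on the raw expression scale; for qPCR matrices pass the
    exponentiated values (see :func:`t_test_de`, which does this itself).
    """
    ia, ib = _group_indices(m, group_a), _group_indices(m, group_b)
    if set(ia) & set(ib):
        raise ValueError("groups must be disjoint")
    mean_a = m.values[:, ia].mean(axis=1)
    mean_b = m.values[:, ib].mean(axis=1)
    return (mean_a + pseudocount) / (mean_b + pseudocount)


# ---------------------------------------------------------------------------
# Hurdle likelihood-ratio test
# ---------------------------------------------------------------------------

def _logistic_deviance(X: np.ndarray, y: np.ndarray, ridge: float = 1e-8,
                       maxiter: int = 60, tol: float = 1e-10) -> float:
    """Deviance (-2 log-likelihood) of a logistic fit by Newton iteration.

    A tiny ridge keeps the Hessian invertible under perfect separation; the
    deviance still converges to its infimum (0 for separated data) well
    within the iteration cap.
    """
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(maxiter):
        eta = np.clip(X @ beta, -35, 35)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1.0 - mu), 1e-12)
        grad = X.T @ (y - mu) - ridge * beta
        hess = (X * w[:, None]).T @ X + ridge * np.eye(p)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    eta = np.clip(X @ beta, -35, 35)
    mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
    ll = y @ np.log(mu) + (1 - y) @ np.log(1 - mu)
    return float(-2.0 * ll)


def _gaussian_deviance_drop(X_full: np.ndarray, X_red: np.ndarray,
                            y: np.ndarray) -> float:
    """Gaussian LRT statistic with profiled variance: n*log(RSS_red/RSS_full)."""
    n = y.size
    rss_full = _rss(X_full, y)
    rss_red = _rss(X_red, y)
    eps = 1e-12
    return float(n * np.log((rss_red + eps) / (rss_full + eps)))


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid)


def _hurdle_stat(values: np.ndarray, group: np.ndarray, cdr: np.ndarray
                 ) -> tuple[float, int]:
    """Hurdle LRT statistic and degrees of freedom for one gene.

    ``values``: expression across all cells of the two groups, ``group``:
    0/1 indicator, ``cdr``: per-cell detection rate covariate.
    """
    detected = (values > 0).astype(float)
    n_pos = int(detected.sum())
    stat, df = 0.0, 0

    X_full = np.column_stack([np.ones_like(cdr), group, cdr])
    X_red = np.column_stack([np.ones_like(cdr), cdr])

    # discrete component: needs variation in the detection indicator
    if 0 < n_pos < values.size:
        dev_full = _logistic_deviance(X_full, detected)
        dev_red = _logistic_deviance(X_red, detected)
        stat += max(dev_red - dev_full, 0.0)
        df += 1

    # continuous component: needs enough detected cells in both model ranks
    pos = detected.astype(bool)
    if n_pos >= 4:
        y = np.log2(values[pos] + 1.0)
        g = group[pos]
        if 0 < g.sum() < g.size and y.std() > 0:
            stat += max(_gaussian_deviance_drop(
                X_full[pos], X_red[pos], y), 0.0)
            df += 1
    return stat, df


def hurdle_lrt(
    m: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    p_cut: float = 1e-5,
    fc_cut: float = 2.0,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    cdr: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-gene hurdle likelihood-ratio test of group A versus group B.

    Returns a table with fold change (pseudocount-stabilized mean ratio),
    the chi-square LRT statistic, degrees of freedom, p-value, an
    ``untestable`` flag (genes detected in fewer than two cells, or with no
    estimable component; their p is 1), and a ``significant`` flag
    (``p < p_cut`` and ``fold_change > fc_cut``).
    """
    if m.modality not in ("umi", "read"):
        raise ValueError("hurdle_lrt requires a umi or read matrix")
    ia, ib = _group_indices(m, group_a), _group_indices(m, group_b)
    if set(ia) & set(ib):
        raise ValueError("groups must be disjoint")
    if ia.size < 2 or ib.size < 2:
        raise ValueError("both groups need at least two cells")

    if cdr is None:
        cdr = cellular_detection_rate(m)
    cells = np.concatenate([ia, ib])
    group = np.concatenate([np.ones(ia.size), np.zeros(ib.size)])
    cdr_sub = np.asarray(cdr, dtype=float)[cells]
    cdr_sub = cdr_sub - cdr_sub.mean()

    sub = m.values[:, cells]
    n_genes = m.n_genes
    stats_arr = np.zeros(n_genes)
    dfs = np.zeros(n_genes, dtype=int)
    pvals = np.ones(n_genes)
    untestable = np.zeros(n_genes, dtype=bool)
    for i in range(n_genes):
        v = sub[i]
        if (v > 0).sum() < 2:
            untestable[i] = True
            continue
        stat, df = _hurdle_stat(v, group, cdr_sub)
        if df == 0:
            untestable[i] = True
            continue
        stats_arr[i] = stat
        dfs[i] = df
        pvals[i] = stats.chi2.sf(stat, df)

    fc = fold_change(m, group_a, group_b, pseudocount)
    table = pd.DataFrame(
        {
            "gene": m.gene_names,
            "fold_change": fc,
            "statistic": stats_arr,
            "df": dfs,
            "p_value": pvals,
            "untestable": untestable,
        }
    )
    table["significant"] = (table["p_value"] < p_cut) & (table["fold_change"] > fc_cut)
    return table


def t_test_de(
    m: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    p_cut: float = 1e-5,
    fc_cut: float = 2.0,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Welch two-sided t-test per gene on qPCR log2 expression.

    Fold change is computed on the exponentiated (2**x) scale so that the
    conventional fold-change cutoffs apply.
    """
    if m.modality != "qpcr_log2":
        raise ValueError("t_test_de requires a qpcr_log2 matrix")
    ia, ib = _group_indices(m, group_a), _group_indices(m, group_b)
    if set(ia) & set(ib):
        raise ValueError("groups must be disjoint")
    if ia.size < 2 or ib.size < 2:
        raise ValueError("both groups need at least two cells")
    a, b = m.values[:, ia], m.values[:, ib]
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    pvals = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    statistic = np.where(np.isnan(res.statistic), 0.0, res.statistic)
    lin = np.exp2(m.values)
    mean_a = lin[:, ia].mean(axis=1)
    mean_b = lin[:, ib].mean(axis=1)
    fc = (mean_a + pseudocount) / (mean_b + pseudocount)
    table = pd.DataFrame(
        {
            "gene": m.gene_names,
            "fold_change": fc,
            "statistic": statistic,
            "p_value": pvals,
        }
    )
    table["significant"] = (table["p_value"] < p_cut) & (table["fold_change"] > fc_cut)
    return table


def fisher_overlap(
    set_a: Sequence[str],
    set_b: Sequence[str],
    universe: Sequence[str],
) -> tuple[float, float]:
    """One-sided (enrichment) Fisher exact test of gene-set overlap.

    Returns ``(odds_ratio, p_value)`` from the 2x2 table of membership in
    ``set_a`` and ``set_b`` over ``universe``.
    """
    uni = set(map(str, universe))
    if not uni:
        raise ValueError("empty universe")
    a = set(map(str, set_a))
    b = set(map(str, set_b))
    if not a <= uni or not b <= uni:
        raise ValueError("sets must be subsets of the universe")
    both = len(a & b)
    only_a = len(a - b)
    only_b = len(b - a)
    neither = len(uni) - both - only_a - only_b
    odds, p = stats.fisher_exact(
        [[both, only_a], [only_b, neither]], alternative="greater"
    )
    return float(odds), float(p)


def signature_score(
    m: ExpressionMatrix,
    weights: pd.Series | dict[str, float],
) -> pd.Series:
    """Weighted z-score signature per cell (e.g. the 2C-like score).

    Counts are log2(x+1)-transformed and z-scored per gene across cells;
    each cell's score is the inner product of its z-scores with the signature
    weights (typically fold changes between the signature state and the bulk).
    Weights for genes absent from the matrix are dropped; genes with zero
    variance are dropped with a warning.  Because every z-score has mean zero
    across cells, the score itself averages to zero over the population, and
    cells resembling the signature stand out with large positive scores.
    """
    w = pd.Series(weights, dtype=float)
    present = [g for g in w.index if g in set(m.gene_names)]
    if not present:
        raise ValueError("no signature gene present in the matrix")
    idx = {g: i for i, g in enumerate(m.gene_names)}
    rows = np.array([idx[g] for g in present])
    logx = np.log2(m.values[rows, :] + 1.0)
    mu = logx.mean(axis=1, keepdims=True)
    sd = logx.std(axis=1, keepdims=True)
    nonzero = sd.ravel() > 0
    if not nonzero.all():
        dropped = [g for g, ok in zip(present, nonzero) if not ok]
        if not nonzero.any():
            raise ValueError("all signature genes have zero variance")
        warnings.warn(
            f"dropping zero-variance signature genes: {dropped}", stacklevel=2
        )
    z = (logx[nonzero] - mu[nonzero]) / sd[nonzero]
    wv = w.loc[[g for g, ok in zip(present, nonzero) if ok]].to_numpy()
    scores = wv @ z
    return pd.Series(scores, index=m.cell_names, name="signature_score")
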