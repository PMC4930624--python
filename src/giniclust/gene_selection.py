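"""Trend normalization of Gini values and high-Gini gene selection.

Raw Gini indices are strongly anti-correlated with expression level: a lowly
expressed gene is zero in most cells for purely technical reasons and so has
a high Gini regardless of biology.  The remedy is to regress the per-gene
Gini on log2 maximum expression with a two-pass LOESS fit — fit, drop genes
whose (signed) residual lies above the 75th percentile, refit on the
remainder — and work with the residual from the second fit, the *normalized*
Gini.  The outlier pass exists precisely because the genes being sought are
the upward outliers: leaving them in would drag the trend toward them.

Selection then differs by modality.  RNA-seq provides enough genes to fit a
normal approximation to the normalized-Gini population and select at
``p < 1e-4``; qPCR panels have too few genes for a stable null fit, so a
fixed threshold (``normalized Gini > 0.05``) is used instead.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .gini import bidirectional_gini, gini_matrix
from .preprocess import ExpressionMatrix

__all__ = [
    "loess",
    "fit_trend",
    "gini_pvalues",
    "compute_gini_table",
    "select_high_gini",
]

#: pseudo-expression added before taking log2 of the per-gene maximum, so
#: genes whose maximum is below one (possible in normalized units) still get
#: a finite, monotone x coordinate.
LOG_MAX_OFFSET = 0.1


# ---------------------------------------------------------------------------
# LOESS (local polynomial regression, tricube weights)
# ---------------------------------------------------------------------------

def loess(
    x: np.ndarray,
    y: np.ndarray,
    xeval: np.ndarray | None = None,
    span: float = 0.9,
    degree: int = 2,
) -> np.ndarray:
    """Local polynomial regression with tricube weights.

    For each evaluation point the ``span`` fraction of nearest observations
    is tricube-weighted by distance and a degree-``degree`` polynomial is fit
    by weighted least squares; the fitted value at the point is returned.
    Unlike the smoothers that only return fits at the observed design points,
    this one evaluates at arbitrary ``xeval``, which the two-pass trend fit
    needs (pass-two fit must be evaluated at the dropped genes too).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if not (0 < span <= 1):
        raise ValueError("span must be in (0, 1]")
    n = x.size
    k = max(int(np.ceil(span * n)), degree + 1)
    if n < degree + 1:
        raise ValueError(
            f"need at least {degree + 1} points for degree-{degree} LOESS; "
            "increase the span or supply more genes"
        )
    k = min(k, n)
    if xeval is None:
        xeval = x
    xeval = np.asarray(xeval, dtype=float).ravel()
    out = np.empty(xeval.size)
    for i, x0 in enumerate(xeval):
        d = np.abs(x - x0)
        if k < n:
            idx = np.argpartition(d, k - 1)[:k]
        else:
            idx = np.arange(n)
        dmax = d[idx].max()
        if dmax > 0:
            w = (1.0 - (d[idx] / dmax) ** 3) ** 3
            w = np.maximum(w, 1e-9)  # keep boundary point from zeroing out
        else:
            w = np.ones(k)
        xc = x[idx] - x0
        deg = min(degree, max(np.unique(x[idx]).size - 1, 0))
        if deg == 0:
            out[i] = np.average(y[idx], weights=w)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", np.exceptions.RankWarning)
            coef = np.polyfit(xc, y[idx], deg, w=np.sqrt(w))
        out[i] = coef[-1]
    return out


def fit_trend(
    raw_gini: np.ndarray,
    log2_max_expr: np.ndarray,
    span: float = 0.9,
    degree: int = 2,
    outlier_quantile: float = 0.75,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-pass LOESS trend of raw Gini against log2 maximum expression.

    Pass 1 fits through all genes; genes whose signed residual exceeds the
    ``outlier_quantile`` of residuals are set aside (these are the candidate
    high-Gini genes); pass 2 refits on the remainder and is evaluated at every
    gene, dropped or not.

    Returns
    -------
    fitted_trend : ndarray
        Pass-2 fit at each gene's ``log2_max_expr``.
    kept : ndarray of bool
        Genes that survived the outlier removal (used for diagnostics).
    """
    raw_gini = np.asarray(raw_gini, dtype=float).ravel()
    log2_max_expr = np.asarray(log2_max_expr, dtype=float).ravel()
    if raw_gini.size != log2_max_expr.size:
        raise ValueError("raw_gini and log2_max_expr must have equal length")
    if raw_gini.size < 10:
        raise ValueError("need at least 10 genes to fit a Gini trend")
    if not (np.isfinite(raw_gini).all() and np.isfinite(log2_max_expr).all()):
        raise ValueError("non-finite inputs to trend fit")
    fit1 = loess(log2_max_expr, raw_gini, span=span, degree=degree)
    resid = raw_gini - fit1
    cutoff = np.quantile(resid, outlier_quantile)
    kept = resid <= cutoff
    fit2 = loess(
        log2_max_expr[kept], raw_gini[kept], xeval=log2_max_expr,
        span=span, degree=degree,
    )
    return fit2, kept


def gini_pvalues(normalized_gini: np.ndarray, robust: bool = True) -> np.ndarray:
    """Upper-tail normal p-values for normalized Gini values.

    The population of normalized Gini values is mostly null (genes following
    the technical trend) with a small upper tail of genuine rare-cell genes,
    so the default location/scale estimates are the median and the
    MAD-based scale, which ignore that tail.  ``robust=False`` switches to
    the plain mean/standard-deviation fit.
    """
    ng = np.asarray(normalized_gini, dtype=float).ravel()
    if ng.size < 10:
        raise ValueError("need at least 10 genes for the normal approximation")
    if robust:
        loc = float(np.median(ng))
        scale = float(stats.median_abs_deviation(ng, scale="normal"))
    else:
        loc = float(ng.mean())
        scale = float(ng.std(ddof=1))
    if scale <= 0:
        raise ValueError("estimated scale of normalized Gini is zero")
    return stats.norm.sf(ng, loc=loc, scale=scale)


def compute_gini_table(
    m: ExpressionMatrix,
    mode: str | None = None,
    span: float = 0.9,
    degree: int = 2,
    robust_pvalues: bool = True,
) -> pd.DataFrame:
    """Per-gene Gini statistics: raw, trend, normalized, and (RNA-seq) p-value.

    ``mode`` defaults to ``qpcr`` for qPCR matrices and ``rnaseq`` otherwise.
    In qPCR mode the bidirectional Gini is computed on exponentially
    transformed expression and no p-values are produced.  Genes with zero
    total expression must be filtered out beforehand.
    """
    if mode is None:
        mode = "qpcr" if m.modality == "qpcr_log2" else "rnaseq"
    if mode not in ("rnaseq", "qpcr"):
        raise ValueError(f"mode must be 'rnaseq' or 'qpcr', got {mode!r}")
    if mode == "qpcr" and m.modality != "qpcr_log2":
        raise ValueError("qpcr mode requires a qpcr_log2 matrix")
    if mode == "rnaseq" and m.modality == "qpcr_log2":
        raise ValueError("rnaseq mode requires a umi or read matrix")

    if mode == "qpcr":
        raw = np.empty(m.n_genes)
        direction = np.empty(m.n_genes, dtype=int)
        for i in range(m.n_genes):
            g = bidirectional_gini(m.values[i])
            raw[i], direction[i] = g.value, g.direction
        # trend x-axis uses the exponentially transformed scale the Gini saw
        max_expr = np.exp2(m.values.max(axis=1))
    else:
        totals = m.values.sum(axis=1)
        if (totals <= 0).any():
            raise ValueError(
                "matrix contains genes with zero total expression; apply "
                "filter_genes first"
            )
        raw = gini_matrix(m.values)
        direction = np.ones(m.n_genes, dtype=int)
        max_expr = m.values.max(axis=1)

    log2_max = np.log2(max_expr + LOG_MAX_OFFSET)
    fitted, kept = fit_trend(raw, log2_max, span=span, degree=degree)
    normalized = raw - fitted
    table = pd.DataFrame(
        {
            "gene": m.gene_names,
            "raw_gini": raw,
            "direction": direction,
            "log2_max_expr": log2_max,
            "fitted_trend": fitted,
            "normalized_gini": normalized,
            "trend_kept": kept,
        }
    )
    if mode == "rnaseq":
        table["p_value"] = gini_pvalues(normalized, robust=robust_pvalues)
    else:
        table["p_value"] = np.nan
    return table


def select_high_gini(
    table: pd.DataFrame,
    mode: str = "rnaseq",
    p_cutoff: float = 1e-4,
    gini_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Flag high-Gini genes: ``p < p_cutoff`` (RNA-seq, strict) or
    ``normalized Gini > gini_cutoff`` (qPCR, strict)."""
    table = table.copy()
    if mode == "rnaseq":
        if table["p_value"].isna().any():
            raise ValueError("rnaseq selection requires p-values for every gene")
        table["selected"] = table["p_value"] < p_cutoff
    elif mode == "qpcr":
        table["selected"] = table["normalized_gini"] > gini_cutoff
    else:
        raise ValueError(f"mode must be 'rnaseq' or 'qpcr', got {mode!r}")
    if not table["selected"].any():
        warnings.warn(
            "no high-Gini genes selected; downstream clustering will have "
            "no features", stacklevel=2,
        )
    return table
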