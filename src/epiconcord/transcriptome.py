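"""Differential expression with an intensity-based moderated t-statistic.

Expression arrives as a gene x sample matrix of log2 intensities (already
normalized and summarized per gene upstream). Per-gene pooled variances
s^2 with d residual degrees of freedom are shrunk toward an
intensity-dependent prior s0^2(A) estimated by tricube-weighted local
linear regression of log s^2 on the mean intensity A, with the prior
degrees of freedom d0 obtained by moment-matching the scaled-F
distribution of s^2 / s0^2(A) on the log scale:

    Var[log s^2] = trigamma(d/2) + trigamma(d0/2)
    s_tilde^2    = (d0 * s0^2(A) + d * s^2) / (d0 + d)
    t            = (mean_case - mean_ctrl) / sqrt(s_tilde^2 (1/n1 + 1/n2))

with a t reference distribution on d0 + d degrees of freedom. At d0 = 0
this reduces exactly to the ordinary pooled two-sample t; as d0 -> inf the
denominator uses the prior curve alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

_MAX_PRIOR_DF = 1e8  # effectively infinite shrinkage toward the prior curve


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample column onto the common row-mean distribution.

    After normalization all columns share the identical sorted value
    multiset (the mean of the per-rank sorted values); within-column ranks
    are preserved. Ties are resolved by order of appearance, which makes an
    already-normalized matrix a fixed point.
    """
    vals = matrix.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("quantile_normalize requires a complete matrix")
    if vals.shape[1] == 1:
        return matrix.copy()
    order = np.argsort(vals, axis=0, kind="stable")
    ranks = np.argsort(order, axis=0, kind="stable")
    reference = np.sort(vals, axis=0).mean(axis=1)
    out = reference[ranks]
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


@dataclass
class ModeratedVariancePrior:
    """Intensity-dependent variance prior for the moderated t.

    ``s0_squared`` holds the prior variance evaluated at each gene's mean
    intensity; ``prior_df`` (d0) is the weight of the prior in the shrunken
    variance; ``residual_df`` (d) is the per-gene residual df of the
    pooled variances the prior was fitted to.
    """

    prior_df: float
    s0_squared: pd.Series
    residual_df: int
    span: float = 0.3
    mean_intensity: pd.Series = field(default=None)

    def __post_init__(self) -> None:
        # fitted priors always have d0 > 0; d0 = 0 is accepted as the
        # explicit no-shrinkage limit (ordinary t)
        if self.prior_df < 0:
            raise ValueError("prior_df must be non-negative")
        if (self.s0_squared <= 0).any():
            raise ValueError("prior variances must be positive")


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton, as in empirical-Bayes
    variance moderation); y <= 0 maps to the +inf-df limit."""
    if y <= 1e-8:
        return _MAX_PRIOR_DF
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) / x < 1e-10:
            break
    return float(min(x, _MAX_PRIOR_DF))


def _pooled_stats(matrix: pd.DataFrame, groups) -> tuple:
    from epiconcord.methylome import _group_columns

    case_cols, ctrl_cols = _group_columns(matrix.columns, groups)
    case = matrix[case_cols].to_numpy(dtype=float)
    ctrl = matrix[ctrl_cols].to_numpy(dtype=float)
    if not np.isfinite(case).all() or not np.isfinite(ctrl).all():
        raise ValueError("expression matrix must be complete and finite")
    n1, n2 = case.shape[1], ctrl.shape[1]
    d = n1 + n2 - 2
    if d <= 0:
        raise ValueError("zero residual degrees of freedom")
    mean_case = case.mean(axis=1)
    mean_ctrl = ctrl.mean(axis=1)
    ss = case.var(axis=1, ddof=1) * (n1 - 1) + ctrl.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / d
    return mean_case, mean_ctrl, s2, n1, n2, d


def fit_intensity_prior(
    matrix: pd.DataFrame,
    groups,
    span: float = 0.3,
) -> ModeratedVariancePrior:
    """Estimate the intensity-dependent variance prior.

    Fits a lowess (tricube-weighted local linear) trend of log pooled
    variance on mean intensity, then moment-matches the prior df d0 from
    the excess spread of log s^2 around the trend. Requires at least 30
    genes and 3 samples per group for the smoother and the variance of the
    residuals to be identifiable.
    """
    if matrix.shape[0] < 30:
        raise ValueError("need >= 30 genes to fit the intensity prior")
    mean_case, mean_ctrl, s2, n1, n2, d = _pooled_stats(matrix, groups)
    if min(n1, n2) < 3:
        raise ValueError("need >= 3 samples per group")
    amean = (mean_case * n1 + mean_ctrl * n2) / (n1 + n2)
    z = np.log(np.maximum(s2, 1e-300))
    trend = lowess(z, amean, frac=span, return_sorted=False)
    resid = z - trend
    excess = float(np.var(resid, ddof=1)) - float(special.polygamma(1, d / 2.0))
    d0 = 2.0 * _trigamma_inverse(max(excess, 0.0))
    # bias-correct the trend from E[log s^2] to log s0^2 under the
    # scaled-F marginal of s^2 given the prior
    adj = (
        -special.digamma(d / 2.0)
        + np.log(d / 2.0)
        + (special.digamma(d0 / 2.0) - np.log(d0 / 2.0) if np.isfinite(d0) and d0 < _MAX_PRIOR_DF else 0.0)
    )
    s0_sq = np.exp(trend + adj)
    return ModeratedVariancePrior(
        prior_df=float(d0),
        s0_squared=pd.Series(s0_sq, index=matrix.index),
        residual_df=int(d),
        span=span,
        mean_intensity=pd.Series(amean, index=matrix.index),
    )


def moderated_t(
    matrix: pd.DataFrame,
    groups,
    prior: ModeratedVariancePrior,
) -> pd.DataFrame:
    """Per-gene moderated t-statistics against the fitted intensity prior.

    Returns a frame indexed by gene with columns ``mean_case``,
    ``mean_ctrl``, ``log2fc``, ``signed_fc``, ``t_moderated``, ``p_value``,
    ``q_value``, ``direction``.
    """
    mean_case, mean_ctrl, s2, n1, n2, d = _pooled_stats(matrix, groups)
    if d != prior.residual_df:
        raise ValueError("prior was fitted on a design with different residual df")
    s0_sq = prior.s0_squared.loc[matrix.index].to_numpy(dtype=float)
    d0 = prior.prior_df
    if d0 >= _MAX_PRIOR_DF:
        s_tilde = s0_sq
        df_total = np.inf
    else:
        s_tilde = (d0 * s0_sq + d * s2) / (d0 + d)
        df_total = d0 + d
    se = np.sqrt(s_tilde * (1.0 / n1 + 1.0 / n2))
    t = (mean_case - mean_ctrl) / se
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    log2fc = mean_case - mean_ctrl
    out = pd.DataFrame(
        {
            "mean_case": mean_case,
            "mean_ctrl": mean_ctrl,
            "log2fc": log2fc,
            "signed_fc": signed_fc_from_log2(log2fc),
            "t_moderated": t,
            "p_value": p,
        },
        index=matrix.index,
    )
    out.index.name = "gene_symbol"
    out["q_value"] = bh_fdr(out["p_value"].to_numpy())
    out["direction"] = np.where(out["log2fc"] >= 0, "up", "down")
    return out


def ordinary_t(matrix: pd.DataFrame, groups) -> pd.DataFrame:
    """Ordinary pooled two-sample t per gene (the d0 = 0 limit)."""
    mean_case, mean_ctrl, s2, n1, n2, d = _pooled_stats(matrix, groups)
    se = np.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean_case - mean_ctrl) / se
    p = 2.0 * stats.t.sf(np.abs(t), d)
    return pd.DataFrame(
        {"t": t, "p_value": p, "log2fc": mean_case - mean_ctrl}, index=matrix.index
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def signed_fold_change(mean_case_linear: float, mean_ctrl_linear: float) -> float:
    """Array-table signed fold change of two linear-scale group means.

    Returns the ratio r = case/ctrl when r >= 1, else the negative
    reciprocal -1/r, so magnitudes are always >= 1 and sign encodes
    direction.
    """
    if mean_case_linear <= 0 or mean_ctrl_linear <= 0:
        raise ValueError("group means must be positive")
    r = mean_case_linear / mean_ctrl_linear
    return r if r >= 1 else -1.0 / r


def signed_fc_from_log2(log2fc) -> np.ndarray | float:
    """Signed fold change from a log2 fold change (vectorized)."""
    lfc = np.asarray(log2fc, dtype=float)
    r = np.power(2.0, lfc)
    out = np.where(r >= 1, r, -1.0 / r)
    if out.ndim == 0:
        return float(out)
    return out


def round_half_away(x, decimals: int = 1):
    """Round half away from zero (the convention of printed array tables)."""
    arr = np.asarray(x, dtype=float)
    factor = 10.0 ** decimals
    out = np.sign(arr) * np.floor(np.abs(arr) * factor + 0.5) / factor
    if out.ndim == 0:
        return float(out)
    return out


def call_degs(results: pd.DataFrame, fdr: float = 0.10) -> pd.DataFrame:
    """Subset of DE results passing the BH FDR gate (default 10%)."""
    if not 0 < fdr < 1:
        raise ValueError("fdr must be in (0, 1)")
    return results[results["q_value"] <= fdr].copy()
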