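"""Small-sample targeted validation statistics.

Covers the statistics typically applied to bench confirmation data in a
two-group design: outlier exclusion by distance from the median in units
of the inter-quartile range, equal-variance two-sample t-tests computed
from raw values or from published mean/SEM/n summaries, group-mean fold
changes, relative qPCR quantification by the 2^-ddCt method, and
pyrosequencing region-mean percent methylation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class GroupSummary:
    """Published group summary: mean, standard error of the mean, n."""

    mean: float
    sem: float
    n: int

    def __post_init__(self) -> None:
        if self.sem <= 0:
            raise ValueError("sem must be positive")
        if self.n < 2:
            raise ValueError("n must be >= 2")

    @property
    def sd(self) -> float:
        return self.sem * math.sqrt(self.n)


def iqr_outlier_filter(
    values, k: float = 1.5, tukey_fences: bool = False
) -> np.ndarray:
    """Exclude values far from the center in IQR units.

    By default keeps values within ``median +/- k * IQR`` (the
    median-centered window some figure legends state); with
    ``tukey_fences=True`` the conventional ``[Q1 - k*IQR, Q3 + k*IQR]``
    fences are used instead. Quartiles are computed by linear
    interpolation between order statistics. The median itself can never
    be excluded, so the output is non-empty.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 3:
        raise ValueError("need at least 3 values for outlier filtering")
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    iqr = q3 - q1
    if tukey_fences:
        lo, hi = q1 - k * iqr, q3 + k * iqr
    else:
        lo, hi = med - k * iqr, med + k * iqr
    return vals[(vals >= lo) & (vals <= hi)]


def two_sample_t(
    values_case, values_ctrl, equal_variance: bool = True
) -> tuple[float, float, float]:
    """Two-sided two-sample t-test on raw values.

    Pooled-variance (equal-variance) form by default; Welch with
    ``equal_variance=False``. Identical groups with zero variance are the
    clean null (t=0, p=1); zero pooled variance with unequal means is
    flagged as an error.

    Returns ``(t, df, p)``.
    """
    case = np.asarray(values_case, dtype=float)
    ctrl = np.asarray(values_ctrl, dtype=float)
    if case.size < 2 or ctrl.size < 2:
        raise ValueError("need at least 2 values per group")
    if case.var(ddof=1) == 0 and ctrl.var(ddof=1) == 0:
        if case.mean() == ctrl.mean():
            df = case.size + ctrl.size - 2
            return 0.0, float(df), 1.0
        raise ValueError("zero pooled variance with unequal means")
    res = stats.ttest_ind(case, ctrl, equal_var=equal_variance)
    return float(res.statistic), float(res.df), float(res.pvalue)


def two_sample_t_summary(
    case: GroupSummary, ctrl: GroupSummary, equal_variance: bool = True
) -> tuple[float, float, float]:
    """Two-sided t-test from mean/SEM/n group summaries.

    Recovers the raw-data equal-variance (pooled) test exactly via the
    SEM -> SD conversion; a Welch form is available behind the flag.

    Returns ``(t, df, p)``.
    """
    v1, v2 = case.sd**2, ctrl.sd**2
    n1, n2 = case.n, ctrl.n
    delta = case.mean - ctrl.mean
    if equal_variance:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = float(n1 + n2 - 2)
    else:
        se = math.sqrt(v1 / n1 + v2 / n2)
        df = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
    if se == 0:
        return 0.0, df, 1.0
    t = delta / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def fold_change_means(mean_case: float, mean_ctrl: float) -> float:
    """Ratio of group means, case over control."""
    if mean_case <= 0 or mean_ctrl <= 0:
        raise ValueError("group means must be positive")
    return mean_case / mean_ctrl


def ddct_fold_change(samples: pd.DataFrame) -> pd.DataFrame:
    """Relative quantification by the 2^-ddCt method, per target.

    ``samples`` has columns ``sample_id``, ``group`` (case/control),
    ``target``, ``ct_target``, ``ct_housekeeping`` (replicate rows per
    sample/target are averaged first). Per sample,
    dCt = ct_target - ct_housekeeping; ddCt is the case-group mean dCt
    minus the control-group mean dCt, and fold = 2^-ddCt. Samples missing
    a Ct are excluded with a warning; an empty group after exclusion is
    an error.

    Returns one row per target with ``ddct``, ``fold`` and the table-style
    ``signed_fold`` (negative reciprocal below 1).
    """
    df = samples.copy()
    if "target" not in df.columns:
        df["target"] = "target"
    missing = df["ct_target"].isna() | df["ct_housekeeping"].isna()
    if missing.any():
        logger.warning(
            "ddct_fold_change: excluding %d samples with missing Ct values",
            int(missing.sum()),
        )
        df = df[~missing]
    # triplicate (or other replicate) wells collapse to one Ct per sample
    df = (
        df.groupby(["target", "group", "sample_id"], as_index=False)[
            ["ct_target", "ct_housekeeping"]
        ].mean()
    )
    df["dct"] = df["ct_target"] - df["ct_housekeeping"]
    rows = []
    for target, grp in df.groupby("target", sort=True):
        by_group = grp.groupby("group")["dct"].mean()
        if "case" not in by_group or "control" not in by_group:
            raise ValueError(f"target {target!r}: a group is empty after exclusions")
        ddct = float(by_group["case"] - by_group["control"])
        fold = float(2.0 ** (-ddct))
        rows.append(
            {
                "target": target,
                "ddct": ddct,
                "fold": fold,
                "signed_fold": fold if fold >= 1 else -1.0 / fold,
            }
        )
    return pd.DataFrame(rows).set_index("target")


def region_mean_methylation(regions: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pyrosequencing region summaries: group mean +/- SEM of percent
    methylation.

    ``regions`` has columns ``sample_id``, ``group``, ``region``,
    ``site_index``, ``percent``. Within a region every sample must report
    the same CpG sites (ragged site lists are an error). Each sample's
    region value is the mean over its sites; per-group mean and SEM of
    those values are returned, together with per-site group means.

    Returns ``(region_summary, site_summary)``.
    """
    df = regions.copy()
    if ((df["percent"] < 0) | (df["percent"] > 100)).any():
        raise ValueError("percent values must lie in [0, 100]")
    for region, grp in df.groupby("region"):
        site_sets = grp.groupby("sample_id")["site_index"].apply(
            lambda s: tuple(sorted(s))
        )
        if site_sets.nunique() != 1:
            raise ValueError(f"region {region!r}: samples report different sites")
    per_sample = (
        df.groupby(["region", "group", "sample_id"], as_index=False)["percent"].mean()
    )
    region_summary = (
        per_sample.groupby(["region", "group"])["percent"]
        .agg(mean="mean", sem=lambda v: stats.sem(v, ddof=1) if len(v) > 1 else 0.0,
             n="count")
        .reset_index()
    )
    site_summary = (
        df.groupby(["region", "site_index", "group"])["percent"]
        .agg(mean="mean", sem=lambda v: stats.sem(v, ddof=1) if len(v) > 1 else 0.0,
             n="count")
        .reset_index()
    )
    return region_summary, site_summary
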