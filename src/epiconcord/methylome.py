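"""Differential methylation calling on beta-value matrices.

The methylation level of a CpG probe is a beta value in [0, 1] (fraction of
methylated signal). Entries whose detection p-value exceeds a reliability
threshold are treated as missing; probes are compared between case and
control groups with an equal-variance two-sample t-test on beta values
(a logit/M-value variant is available behind a flag), and each probe's
p-value is folded into the signed DiffScore

    DiffScore = 10 * sgn(delta_beta) * (-log10 p)

so that p = 0.05, 0.01, 0.001 correspond to |DiffScore| ~ 13, 20, 30.
Genes are called differentially methylated when at least one autosomal
probe reaches |DiffScore| >= threshold; the gene's direction is taken from
the probe with maximal |DiffScore|.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from epiconcord.transcriptome import bh_fdr

logger = logging.getLogger(__name__)

#: DiffScore magnitude assigned when the t-test underflows to p = 0
#: (mirrors the ceiling commonly seen in array-software exports).
DIFFSCORE_CAP = 350.0

#: Chromosome labels treated as non-autosomal.
NON_AUTOSOMAL = {"X", "Y", "MT", "M", "chrX", "chrY", "chrM", "chrMT"}


@dataclass
class BetaMatrix:
    """Probe x sample beta values with paired detection p-values.

    Both frames are indexed by probe id with sample ids as columns; masked
    (unreliable) beta entries are NaN.
    """

    beta: pd.DataFrame
    detection_p: pd.DataFrame

    def __post_init__(self) -> None:
        if self.beta.shape != self.detection_p.shape:
            raise ValueError(
                f"beta {self.beta.shape} and detection_p "
                f"{self.detection_p.shape} shapes differ"
            )
        if not self.beta.index.equals(self.detection_p.index) or not (
            self.beta.columns.equals(self.detection_p.columns)
        ):
            raise ValueError("beta and detection_p must share probe and sample ids")
        for name, frame in (("beta", self.beta), ("detection_p", self.detection_p)):
            vals = frame.to_numpy(dtype=float)
            finite = vals[np.isfinite(vals)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise ValueError(f"{name} values must lie in [0, 1]")

    @property
    def probe_ids(self) -> pd.Index:
        return self.beta.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.beta.columns


def _group_columns(sample_ids: pd.Index, groups: pd.Series | dict) -> tuple[list, list]:
    groups = pd.Series(groups)
    missing = [s for s in sample_ids if s not in groups.index]
    if missing:
        raise ValueError(f"samples without group labels: {missing}")
    labels = set(groups.loc[list(sample_ids)])
    if not labels <= {"case", "control"}:
        raise ValueError(f"group labels must be 'case'/'control', got {labels}")
    case = [s for s in sample_ids if groups[s] == "case"]
    ctrl = [s for s in sample_ids if groups[s] == "control"]
    return case, ctrl


def mask_low_detection(
    matrix: BetaMatrix,
    groups: pd.Series | dict,
    threshold: float = 0.05,
    min_per_group: int = 3,
) -> BetaMatrix:
    """Mask unreliable entries and drop probes with too few usable values.

    Entries with detection p strictly greater than ``threshold`` become NaN
    (p equal to the threshold is retained). Probes left with fewer than
    ``min_per_group`` usable values in either group are dropped, since a
    group variance cannot be estimated stably from fewer observations.
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    case, ctrl = _group_columns(matrix.sample_ids, groups)
    masked = matrix.beta.where(matrix.detection_p <= threshold)
    n_case = masked[case].notna().sum(axis=1)
    n_ctrl = masked[ctrl].notna().sum(axis=1)
    keep = (n_case >= min_per_group) & (n_ctrl >= min_per_group)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "mask_low_detection: dropped %d/%d probes with <%d usable "
            "values in a group",
            n_dropped,
            len(keep),
            min_per_group,
        )
    return BetaMatrix(masked.loc[keep], matrix.detection_p.loc[keep])


def compute_diffscore(
    p_value, delta_beta, cap: float = DIFFSCORE_CAP
):
    """Signed DiffScore ``10 * sgn(delta_beta) * (-log10 p)``.

    ``delta_beta = 0`` yields 0 regardless of p; ``p = 0`` (numerical
    underflow) is capped at ``+/-cap``. Accepts scalars or arrays.
    """
    p = np.asarray(p_value, dtype=float)
    db = np.asarray(delta_beta, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        magnitude = np.where(p > 0, -10.0 * np.log10(np.maximum(p, 1e-320)), cap)
    magnitude = np.minimum(magnitude, cap)
    score = np.sign(db) * magnitude
    if score.ndim == 0:
        return float(score)
    return score


def diffscore_to_p(diff_score) -> float | np.ndarray:
    """Invert the DiffScore transform back to a two-sided p-value."""
    ds = np.asarray(diff_score, dtype=float)
    p = np.power(10.0, -np.abs(ds) / 10.0)
    if p.ndim == 0:
        return float(p)
    return p


def delta_5mc_percent(mean_beta_case, mean_beta_ctrl):
    """Percent methylation change, ``100 * |b_case - b_ctrl| / b_ctrl``.

    A zero control mean makes the ratio undefined; such entries come back
    as NaN with a warning.
    """
    case = np.asarray(mean_beta_case, dtype=float)
    ctrl = np.asarray(mean_beta_ctrl, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * np.abs(case - ctrl) / ctrl
    undefined = ctrl == 0
    if np.any(undefined):
        warnings.warn(
            "delta_5mc_percent undefined where the control mean beta is 0; "
            "emitting NaN",
            RuntimeWarning,
            stacklevel=2,
        )
        pct = np.where(undefined, np.nan, pct)
    if pct.ndim == 0:
        return float(pct)
    return pct


def _logit(beta: np.ndarray, eps: float = 1e-3) -> np.ndarray:
    clipped = np.clip(beta, eps, 1 - eps)
    return np.log2(clipped / (1 - clipped))


def test_probe_dm(
    matrix: BetaMatrix,
    groups: pd.Series | dict,
    use_mvalues: bool = False,
    diffscore_cap: float = DIFFSCORE_CAP,
) -> pd.DataFrame:
    """Per-probe two-group differential methylation statistics.

    Runs an equal-variance two-sample t-test per probe on the unmasked beta
    values (or on M-values, ``logit2(beta)``, when ``use_mvalues``; group
    means and delta-beta are always reported on the beta scale). Probes with
    fewer than two usable values in a group are excluded with a logged
    reason.

    Returns a frame indexed by probe id with columns ``mean_beta_case``,
    ``mean_beta_ctrl``, ``delta_beta``, ``p_value``, ``q_value``,
    ``diff_score``, ``delta_5mc_pct``, ``n_case_used``, ``n_ctrl_used``.
    """
    case_cols, ctrl_cols = _group_columns(matrix.sample_ids, groups)
    case = matrix.beta[case_cols].to_numpy(dtype=float)
    ctrl = matrix.beta[ctrl_cols].to_numpy(dtype=float)

    n_case = np.sum(~np.isnan(case), axis=1)
    n_ctrl = np.sum(~np.isnan(ctrl), axis=1)
    usable = (n_case >= 2) & (n_ctrl >= 2)
    n_excluded = int((~usable).sum())
    if n_excluded:
        logger.info(
            "test_probe_dm: excluded %d probes with <2 usable values in a group",
            n_excluded,
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_case = np.nanmean(np.where(usable[:, None], case, np.nan), axis=1)
        mean_ctrl = np.nanmean(np.where(usable[:, None], ctrl, np.nan), axis=1)

    tc, tt = ((_logit(case), _logit(ctrl)) if use_mvalues else (case, ctrl))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t_stat, p = stats.ttest_ind(
            tc, tt, axis=1, equal_var=True, nan_policy="omit"
        )
    p = np.asarray(p, dtype=float)
    delta = mean_case - mean_ctrl

    # zero pooled variance: identical groups are a clean null (p=1); a
    # nonzero difference with zero variance underflows to p=0 and is capped
    # by the DiffScore ceiling.
    degenerate = ~np.isfinite(p)
    p = np.where(degenerate & (delta == 0), 1.0, p)
    p = np.where(degenerate & (delta != 0), 0.0, p)

    out = pd.DataFrame(
        {
            "mean_beta_case": mean_case,
            "mean_beta_ctrl": mean_ctrl,
            "delta_beta": delta,
            "p_value": p,
            "n_case_used": n_case,
            "n_ctrl_used": n_ctrl,
        },
        index=matrix.probe_ids,
    ).loc[usable]
    out.index.name = "probe_id"
    out["q_value"] = bh_fdr(out["p_value"].to_numpy())
    out["diff_score"] = compute_diffscore(
        out["p_value"].to_numpy(), out["delta_beta"].to_numpy(), cap=diffscore_cap
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out["delta_5mc_pct"] = delta_5mc_percent(
            out["mean_beta_case"].to_numpy(), out["mean_beta_ctrl"].to_numpy()
        )
    return out[
        [
            "mean_beta_case",
            "mean_beta_ctrl",
            "delta_beta",
            "p_value",
            "q_value",
            "diff_score",
            "delta_5mc_pct",
            "n_case_used",
            "n_ctrl_used",
        ]
    ]


def is_autosomal(chromosome: pd.Series | str) -> pd.Series | bool:
    """True for chromosome labels not in the X/Y/mitochondrial vocabulary."""
    if isinstance(chromosome, str):
        return chromosome not in NON_AUTOSOMAL
    return ~chromosome.astype(str).isin(NON_AUTOSOMAL)


def call_dmgs(
    results: pd.DataFrame,
    annotation: pd.DataFrame,
    diffscore_threshold: float = 13.0,
) -> pd.DataFrame:
    """Aggregate per-probe statistics to gene-level DMG calls.

    Only autosomal probes are considered. A gene is differentially
    methylated iff at least one of its probes reaches
    ``|diff_score| >= diffscore_threshold``; its direction (hyper for
    positive scores, hypo for negative) is taken from the probe with the
    maximal absolute DiffScore. When probes of opposite sign tie at the
    maximal absolute score the gene is marked ``ambiguous`` (downstream
    concordance excludes it). Probes present in ``results`` but absent from
    ``annotation`` are skipped with a log message; probes annotated to
    several genes contribute to each.

    Returns a frame indexed by gene symbol with columns ``direction``,
    ``best_diff_score``, ``best_probe``, ``delta_5mc_pct``, ``p_value``,
    ``n_probes_total``, ``n_probes_significant``.
    """
    if diffscore_threshold <= 0:
        raise ValueError("diffscore_threshold must be positive")
    ann = annotation.copy()
    if "is_autosomal" not in ann.columns:
        ann["is_autosomal"] = is_autosomal(ann["chromosome"])
    ann = ann[ann["is_autosomal"].astype(bool)]

    unknown = results.index.difference(ann["probe_id"])
    annotated_all = annotation["probe_id"] if "probe_id" in annotation else pd.Index([])
    truly_unknown = unknown.difference(pd.Index(annotated_all))
    if len(truly_unknown):
        logger.info(
            "call_dmgs: %d probes absent from the annotation were skipped",
            len(truly_unknown),
        )

    merged = ann.merge(
        results.reset_index(), left_on="probe_id", right_on="probe_id", how="inner"
    )
    calls = []
    for gene, grp in merged.groupby("gene_symbol", sort=True):
        abs_ds = grp["diff_score"].abs()
        n_sig = int((abs_ds >= diffscore_threshold).sum())
        if n_sig == 0:
            continue
        best_abs = abs_ds.max()
        at_max = grp[np.isclose(abs_ds, best_abs)]
        signs = set(np.sign(at_max["diff_score"]))
        if len(signs) > 1:
            direction = "ambiguous"
            best = at_max.iloc[0]
        else:
            best = at_max.loc[at_max["diff_score"].abs().idxmax()]
            direction = "hyper" if best["diff_score"] > 0 else "hypo"
        calls.append(
            {
                "gene_symbol": gene,
                "direction": direction,
                "best_diff_score": float(best["diff_score"]),
                "best_probe": best["probe_id"],
                "delta_5mc_pct": float(best["delta_5mc_pct"]),
                "p_value": float(best["p_value"]),
                "n_probes_total": int(len(grp)),
                "n_probes_significant": n_sig,
            }
        )
    out = pd.DataFrame(
        calls,
        columns=[
            "gene_symbol",
            "direction",
            "best_diff_score",
            "best_probe",
            "delta_5mc_pct",
            "p_value",
            "n_probes_total",
            "n_probes_significant",
        ],
    ).set_index("gene_symbol")
    n_amb = int((out["direction"] == "ambiguous").sum())
    if n_amb:
        logger.info("call_dmgs: %d genes with sign-conflicting top probes", n_amb)
    return out
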