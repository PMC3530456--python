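"""Synthetic two-group omics data with planted, bookkept effects.

The generator emulates the data model of a two-group (case vs control)
integrative array study: a CpG-probe x sample beta-value matrix with the
characteristic bimodal baseline of Infinium arrays plus a paired
detection-p matrix, a probe -> gene annotation at roughly 1.9 probes per
gene, a gene x sample log2 expression matrix whose residual spread depends
on mean intensity, and small ELISA / qPCR validation tables. Effects are
planted additively on the beta scale (the percent-methylation-change
statistic downstream is defined on raw beta) and as shifts of the group
mean on the log2 expression scale; every planted effect is recorded in a
:class:`TruthSet` so recovery can be scored exactly.

Each data modality draws from its own RNG stream derived from the master
seed, so modalities can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from epiconcord.methylome import BetaMatrix

# fraction of genes placed on sex chromosomes so the autosomal
# restriction downstream is exercised
_DEFAULT_FRAC_NON_AUTOSOMAL = 0.05

# mixture of Beta modes for per-probe baseline methylation:
# unmethylated (~0.1), methylated (~0.85), minor intermediate (~0.5)
_BASELINE_MODES = ((2.0, 18.0), (17.0, 3.0), (8.0, 8.0))

# keep planted case means away from the boundaries of (0, 1)
_CLIP_MARGIN = 0.02

_STREAMS = {"annotation": 0, "methylation": 1, "expression": 2, "elisa": 3, "qpcr": 4}


def _rng(seed: int, modality: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), _STREAMS[modality])))


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic two-group dataset.

    Defaults encode the benchmark conditions the pipeline's recovery
    properties are stated under: 2,000 probes over 1,000 genes (about two
    probes per gene, matching the ~1.9 probes/gene density of a 27K-scale
    methylation array), 12 cases vs 12 controls, planted beta-shifts of
    0.15 on 20% of probes, planted log2 fold changes of +/-1 on 20% of
    genes, and 10% of genes concordant (hypo-methylated/up-regulated or
    hyper-methylated/down-regulated).
    """

    n_probes: int | None = 2000
    n_genes: int = 1000
    probes_per_gene_mean: float = 1.9
    n_case: int = 12
    n_ctrl: int = 12
    frac_dm_probes: float = 0.20
    delta_beta: float = 0.15
    beta_precision: float = 50.0
    detection_fail_rate: float = 0.01
    frac_de_genes: float = 0.20
    log2fc_effect: float = 1.0
    expr_base_mean: float = 8.0
    expr_noise_sd: float = 0.4
    expr_sd_slope: float = -0.1
    frac_concordant: float = 0.10
    frac_non_autosomal: float = _DEFAULT_FRAC_NON_AUTOSOMAL
    baseline_mode_weights: tuple = (0.45, 0.45, 0.10)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_probes is None:
            self.n_probes = int(round(self.n_genes * self.probes_per_gene_mean))
        for name in ("n_probes", "n_genes", "n_case", "n_ctrl"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_probes < self.n_genes:
            raise ValueError("n_probes must be >= n_genes (every gene needs a probe)")
        for name in (
            "frac_dm_probes",
            "detection_fail_rate",
            "frac_de_genes",
            "frac_concordant",
            "frac_non_autosomal",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.beta_precision <= 0:
            raise ValueError("beta_precision must be positive")
        if not 0 < self.delta_beta < 1:
            raise ValueError("delta_beta must lie in (0, 1)")
        if self.probes_per_gene_mean <= 0:
            raise ValueError("probes_per_gene_mean must be positive")
        if self.frac_concordant > min(self.frac_dm_probes, self.frac_de_genes):
            raise ValueError(
                "frac_concordant cannot exceed the planted DM/DE fractions"
            )

    @property
    def sample_ids_case(self) -> list[str]:
        return [f"case_{i + 1:02d}" for i in range(self.n_case)]

    @property
    def sample_ids_ctrl(self) -> list[str]:
        return [f"control_{i + 1:02d}" for i in range(self.n_ctrl)]

    def sample_sheet(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids_case + self.sample_ids_ctrl,
                "group": ["case"] * self.n_case + ["control"] * self.n_ctrl,
            }
        )


@dataclass
class TruthSet:
    """Bookkeeping of every planted effect, for recovery scoring.

    ``probe_effects`` holds the achieved signed beta-shift per probe (0 for
    null probes; shifts truncated by clipping near the (0, 1) boundary are
    recorded at their achieved value). ``concordant_genes`` maps each
    planted concordant gene to its class (``hypo_up`` or ``hyper_down``).
    """

    probe_effects: pd.Series
    gene_dm_direction: pd.Series
    gene_de_direction: pd.Series
    concordant_genes: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))

    def __post_init__(self) -> None:
        pair = {"hypo": "up", "hyper": "down"}
        for gene, cls in self.concordant_genes.items():
            dm = self.gene_dm_direction.get(gene, "none")
            de = self.gene_de_direction.get(gene, "none")
            if cls not in ("hypo_up", "hyper_down") or pair[dm] != de:
                raise ValueError(f"inconsistent concordant truth for {gene}")

    def to_frame(self) -> pd.DataFrame:
        genes = self.gene_dm_direction.index
        return pd.DataFrame(
            {
                "gene_symbol": genes,
                "dm_direction": self.gene_dm_direction.values,
                "de_direction": self.gene_de_direction.loc[genes].values,
                "concordant_class": [
                    self.concordant_genes.get(g, "none") for g in genes
                ],
            }
        )


def simulate_annotation(config: SimulationConfig) -> pd.DataFrame:
    """Probe -> gene annotation table.

    Every gene receives at least one probe; the remaining probes are
    scattered uniformly, so probes-per-gene counts spread around
    ``n_probes / n_genes``. Whole genes (a ``frac_non_autosomal`` fraction)
    are placed on sex chromosomes; a gene's probes share its chromosome.

    Columns: ``probe_id``, ``gene_symbol``, ``chromosome``,
    ``is_autosomal``.
    """
    rng = _rng(config.seed, "annotation")
    genes = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    # one probe per gene, then uniform assignment of the surplus
    gene_idx = np.concatenate(
        [
            np.arange(config.n_genes),
            rng.integers(0, config.n_genes, size=config.n_probes - config.n_genes),
        ]
    )
    rng.shuffle(gene_idx)
    n_sex = int(round(config.frac_non_autosomal * config.n_genes))
    sex_genes = set(rng.choice(config.n_genes, size=n_sex, replace=False).tolist())
    gene_chrom = {}
    for gi in range(config.n_genes):
        if gi in sex_genes:
            gene_chrom[gi] = str(rng.choice(["X", "Y"]))
        else:
            gene_chrom[gi] = str(rng.integers(1, 23))
    ann = pd.DataFrame(
        {
            "probe_id": [f"cg{i + 1:06d}" for i in range(config.n_probes)],
            "gene_symbol": [genes[gi] for gi in gene_idx],
            "chromosome": [gene_chrom[gi] for gi in gene_idx],
        }
    )
    ann["is_autosomal"] = ~ann["chromosome"].isin(["X", "Y"])
    return ann


def _plan_effects(
    config: SimulationConfig, annotation: pd.DataFrame, rng: np.random.Generator
) -> tuple[pd.Series, pd.Series, pd.Series]:
    """Choose which genes carry DM, DE and concordant effects."""
    genes = sorted(annotation["gene_symbol"].unique())
    autosomal = sorted(
        annotation.loc[annotation["is_autosomal"], "gene_symbol"].unique()
    )
    probes_per_gene = annotation.groupby("gene_symbol").size()

    shuffled = list(rng.permutation(autosomal))
    n_conc = int(round(config.frac_concordant * len(genes)))
    conc_genes = shuffled[:n_conc]
    conc_class = pd.Series(
        ["hypo_up" if i % 2 == 0 else "hyper_down" for i in range(n_conc)],
        index=conc_genes,
        dtype=object,
    )

    dm_dir = pd.Series("none", index=genes, dtype=object)
    de_dir = pd.Series("none", index=genes, dtype=object)
    for g, cls in conc_class.items():
        dm_dir[g] = "hypo" if cls == "hypo_up" else "hyper"
        de_dir[g] = "up" if cls == "hypo_up" else "down"

    # extend DM genes until the planted-probe budget is met
    probe_budget = int(round(config.frac_dm_probes * config.n_probes))
    n_planted = int(probes_per_gene.loc[conc_genes].sum()) if conc_genes else 0
    for g in shuffled[n_conc:]:
        if n_planted >= probe_budget:
            break
        dm_dir[g] = "hypo" if rng.random() < 0.5 else "hyper"
        n_planted += int(probes_per_gene[g])

    # extend DE genes (any chromosome) to the DE budget
    n_de_target = int(round(config.frac_de_genes * len(genes)))
    n_de = n_conc
    for g in rng.permutation(genes):
        if n_de >= n_de_target:
            break
        if de_dir[g] == "none":
            de_dir[g] = "up" if rng.random() < 0.5 else "down"
            n_de += 1
    return dm_dir, de_dir, conc_class


def simulate_methylation(
    config: SimulationConfig, annotation: pd.DataFrame
) -> tuple[BetaMatrix, TruthSet]:
    """Two-group beta-value matrix with planted shifts and a truth set.

    Per-probe baselines come from a three-mode Beta mixture (unmethylated,
    methylated, intermediate). For probes of planted genes the case-group
    mean is shifted by +/-``delta_beta`` and clipped away from the (0, 1)
    boundary; the achieved shift is what the truth records. Sample values
    are Beta-distributed around the group mean with concentration
    ``beta_precision``. Detection p-values are uniform on [0, 0.05] except
    for a ``detection_fail_rate`` fraction of entries pushed above 0.05.
    """
    rng = _rng(config.seed, "methylation")
    dm_dir, de_dir, conc_class = _plan_effects(config, annotation, rng)

    n_probes = len(annotation)
    modes = rng.choice(3, size=n_probes, p=list(config.baseline_mode_weights))
    a = np.array([_BASELINE_MODES[m][0] for m in modes])
    b = np.array([_BASELINE_MODES[m][1] for m in modes])
    baseline = rng.beta(a, b)
    baseline = np.clip(baseline, _CLIP_MARGIN, 1 - _CLIP_MARGIN)

    probe_dir = annotation["gene_symbol"].map(dm_dir).to_numpy()
    signed = np.where(
        probe_dir == "hyper", config.delta_beta,
        np.where(probe_dir == "hypo", -config.delta_beta, 0.0),
    )
    case_mean = np.clip(baseline + signed, _CLIP_MARGIN, 1 - _CLIP_MARGIN)
    achieved = case_mean - baseline  # truncated where clipping bit

    n_case, n_ctrl = config.n_case, config.n_ctrl
    prec = config.beta_precision
    case_vals = rng.beta(
        case_mean[:, None] * prec, (1 - case_mean[:, None]) * prec,
        size=(n_probes, n_case),
    )
    ctrl_vals = rng.beta(
        baseline[:, None] * prec, (1 - baseline[:, None]) * prec,
        size=(n_probes, n_ctrl),
    )
    beta = pd.DataFrame(
        np.hstack([case_vals, ctrl_vals]),
        index=pd.Index(annotation["probe_id"].to_numpy(), name="probe_id"),
        columns=config.sample_ids_case + config.sample_ids_ctrl,
    )

    fails = rng.random(beta.shape) < config.detection_fail_rate
    det = rng.uniform(0.0, 0.05, size=beta.shape)
    det_fail = rng.uniform(np.nextafter(0.05, 1.0), 1.0, size=beta.shape)
    detection = pd.DataFrame(
        np.where(fails, det_fail, det), index=beta.index, columns=beta.columns
    )

    truth = TruthSet(
        probe_effects=pd.Series(achieved, index=beta.index),
        gene_dm_direction=dm_dir,
        gene_de_direction=de_dir,
        concordant_genes=conc_class,
    )
    return BetaMatrix(beta, detection), truth


def simulate_expression(config: SimulationConfig, truth: TruthSet) -> pd.DataFrame:
    """Gene x sample log2 intensities with planted fold changes.

    Baseline intensities are Normal around ``expr_base_mean``; residual
    noise has standard deviation ``expr_noise_sd`` at the anchor intensity,
    scaled so that the slope of log residual variance on mean intensity is
    ``expr_sd_slope`` (an identifiable intensity-variance trend for the
    moderated-t prior). Planted DE genes have group means split by
    +/-``log2fc_effect``; concordant genes inherit their truth direction.
    """
    rng = _rng(config.seed, "expression")
    genes = truth.gene_de_direction.index
    n_genes = len(genes)
    base = rng.normal(config.expr_base_mean, 1.5, size=n_genes)
    log_sd = np.log(config.expr_noise_sd) + 0.5 * config.expr_sd_slope * (
        base - config.expr_base_mean
    )
    sd = np.exp(log_sd)
    direction = truth.gene_de_direction.to_numpy()
    shift = np.where(
        direction == "up", config.log2fc_effect,
        np.where(direction == "down", -config.log2fc_effect, 0.0),
    )
    case = rng.normal(
        (base + shift)[:, None], sd[:, None], size=(n_genes, config.n_case)
    )
    ctrl = rng.normal(base[:, None], sd[:, None], size=(n_genes, config.n_ctrl))
    return pd.DataFrame(
        np.hstack([case, ctrl]),
        index=pd.Index(genes, name="gene_symbol"),
        columns=config.sample_ids_case + config.sample_ids_ctrl,
    )


def simulate_elisa(
    mean_case: float,
    mean_ctrl: float,
    sem: float,
    n_per_group: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-sample percent values for a two-group ELISA-style comparison.

    Sample values are Normal with the target group mean and standard
    deviation ``sem * sqrt(n)`` (so the standard error of the group mean
    matches the stated SEM).
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if sem <= 0:
        raise ValueError("sem must be positive")
    rng = _rng(seed, "elisa")
    sd = sem * np.sqrt(n_per_group)
    case = rng.normal(mean_case, sd, size=n_per_group)
    ctrl = rng.normal(mean_ctrl, sd, size=n_per_group)
    return pd.DataFrame(
        {
            "sample_id": [f"case_{i + 1:02d}" for i in range(n_per_group)]
            + [f"control_{i + 1:02d}" for i in range(n_per_group)],
            "group": ["case"] * n_per_group + ["control"] * n_per_group,
            "percent": np.concatenate([case, ctrl]),
        }
    )


def simulate_qpcr(
    true_fold: float | dict,
    ct_hk: float = 20.0,
    noise_sd: float = 0.0,
    n_per_group: int = 10,
    seed: int = 0,
    base_dct: float = 5.0,
) -> pd.DataFrame:
    """qPCR Ct table with planted expression fold changes.

    For each target the control-group delta-Ct (target minus housekeeping)
    sits at ``base_dct``; the case group is offset by ``-log2(true_fold)``,
    so the 2^-ddCt quantification recovers ``true_fold`` exactly when
    ``noise_sd`` is zero. Per-sample housekeeping Ct noise cancels in the
    within-sample delta-Ct; ``noise_sd`` adds independent cycle noise to
    the target Ct.

    Columns: ``sample_id``, ``group``, ``target``, ``ct_target``,
    ``ct_housekeeping``.
    """
    folds = true_fold if isinstance(true_fold, dict) else {"target": float(true_fold)}
    if any(f <= 0 for f in folds.values()):
        raise ValueError("true_fold must be positive")
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    rng = _rng(seed, "qpcr")
    rows = []
    for target, fold in folds.items():
        for group, offset, n in (
            ("case", -np.log2(fold), n_per_group),
            ("control", 0.0, n_per_group),
        ):
            hk = ct_hk + rng.normal(0.0, noise_sd, size=n)
            tgt = hk + base_dct + offset + rng.normal(0.0, noise_sd, size=n)
            for i in range(n):
                rows.append(
                    {
                        "sample_id": f"{group}_{i + 1:02d}",
                        "group": group,
                        "target": target,
                        "ct_target": float(tgt[i]),
                        "ct_housekeeping": float(hk[i]),
                    }
                )
    return pd.DataFrame(rows)
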