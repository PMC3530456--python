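"""Pipeline orchestration: dm -> de -> integrate -> enrich with a manifest.

:class:`PipelineConfig` collects input paths, thresholds and flags (YAML
loadable, unknown keys rejected); :func:`run_all` executes the stages,
writes every intermediate table under the output directory, and records a
run manifest (config, seed, package versions, row counts per stage) so
repeated runs are auditable and bit-identical for a fixed config.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from epiconcord import io as eio
from epiconcord import concord, enrich, methylome, transcriptome

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    beta: str | None = None
    detection: str | None = None
    annotation: str | None = None
    expression: str | None = None
    samples: str | None = None
    gmt: str | None = None
    outdir: str = "epiconcord_out"
    detection_p: float = 0.05
    diffscore: float = 13.0
    de_fdr: float = 0.10
    enrich_alpha: float = 0.05
    min_per_group: int = 3
    mvalue_test: bool = False
    welch: bool = False
    ease_variant: bool = False
    tukey_fences: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.detection_p < 1:
            raise ValueError("detection_p must be in (0, 1)")
        if self.diffscore <= 0:
            raise ValueError("diffscore must be positive")
        if not 0 < self.de_fdr < 1:
            raise ValueError("de_fdr must be in (0, 1)")
        if not 0 < self.enrich_alpha < 1:
            raise ValueError("enrich_alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _versions() -> dict:
    import numpy, scipy, statsmodels  # noqa: E401

    import epiconcord

    return {
        "epiconcord": epiconcord.__version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "statsmodels": statsmodels.__version__,
    }


def _write_manifest(path: Path, config: PipelineConfig, counts: dict) -> None:
    lines = ["[config]"]
    for k, v in sorted(config.to_dict().items()):
        lines.append(f"{k} = {v}")
    lines.append("[versions]")
    for k, v in sorted(_versions().items()):
        lines.append(f"{k} = {v}")
    lines.append("[row_counts]")
    for k, v in counts.items():
        lines.append(f"{k} = {v}")
    path.write_text("\n".join(lines) + "\n")


def run_all(config: PipelineConfig) -> concord.IntegrationSummary:
    """Execute dm -> de -> integrate (-> enrich) and write all artifacts.

    Any stage failure raises with the stage name in the message; the CLI
    maps that to a non-zero exit status.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict = {}

    stage = "dm"
    try:
        groups = eio.read_sample_sheet(config.samples)
        matrix = eio.read_beta_matrix(config.beta, config.detection)
        annotation = eio.read_annotation(config.annotation)
        counts["probes_in"] = len(matrix.beta)
        masked = methylome.mask_low_detection(
            matrix, groups, threshold=config.detection_p,
            min_per_group=config.min_per_group,
        )
        counts["probes_after_masking"] = len(masked.beta)
        probe_results = methylome.test_probe_dm(
            masked, groups, use_mvalues=config.mvalue_test
        )
        counts["probes_tested"] = len(probe_results)
        dmgs = methylome.call_dmgs(
            probe_results, annotation, diffscore_threshold=config.diffscore
        )
        counts["dmg_genes"] = len(dmgs)
        eio.write_results(probe_results, outdir / "probe_dm.tsv")
        eio.write_results(dmgs, outdir / "gene_dm_calls.tsv")

        stage = "de"
        expr = eio.read_expression(config.expression)
        counts["genes_in"] = len(expr)
        prior = transcriptome.fit_intensity_prior(expr, groups)
        de_results = transcriptome.moderated_t(expr, groups, prior)
        degs = transcriptome.call_degs(de_results, fdr=config.de_fdr)
        counts["deg_genes"] = len(degs)
        eio.write_results(de_results, outdir / "de_results.tsv")
        eio.write_results(degs, outdir / "deg_calls.tsv")

        stage = "integrate"
        records = concord.build_epigene_records(dmgs, degs)
        summary = concord.summarize_integration(dmgs, degs, records)
        counts["common_genes"] = summary.n_common
        counts["concordant_genes"] = summary.n_concordant
        eio.write_results(records, outdir / "epigene_records.tsv")
        concord.write_epigene_tables(records, outdir)
        pd.DataFrame([dataclasses.asdict(summary)]).to_csv(
            outdir / "integration_summary.tsv", sep="\t", index=False
        )

        if config.gmt:
            stage = "enrich"
            collection = enrich.read_gmt(config.gmt)
            universe = sorted(annotation["gene_symbol"].unique())
            conc_genes = concord.concordant_records(records).index
            query = sorted(set(conc_genes) & set(universe))
            enr = enrich.enrich_collection(
                query, collection, universe,
                alpha=config.enrich_alpha, ease=config.ease_variant,
            )
            counts["enriched_terms"] = int(enr["significant"].sum()) if len(enr) else 0
            enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    _write_manifest(outdir / "manifest.txt", config, counts)
    logger.info("run_all complete: %s", counts)
    return summary
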