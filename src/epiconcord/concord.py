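"""Methylome-transcriptome integration and concordance classification.

Genes called in both layers (DMG and DEG) are joined by exact gene-symbol
match and classified by direction: a concordant epigene is hypo-methylated
and up-regulated (``hypo_up``) or hyper-methylated and down-regulated
(``hyper_down``); same-direction genes (``hyper_up``, ``hypo_down``) are
kept in the output with their class label but do not count as concordant.
A machine-readable copy of a published 112-gene concordant-epigene table
(51 hypo_up + 61 hyper_down) ships with the package as a reference
fixture.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONCORDANT_CLASSES = frozenset({"hypo_up", "hyper_down"})

_CLASS_MAP = {
    ("hypo", "up"): "hypo_up",
    ("hyper", "down"): "hyper_down",
    ("hyper", "up"): "hyper_up",
    ("hypo", "down"): "hypo_down",
}


@dataclass
class IntegrationSummary:
    n_dmg: int
    n_deg: int
    n_common: int
    n_concordant: int
    n_hypo_up: int
    n_hyper_down: int
    pct_hyper_of_common: float

    def __post_init__(self) -> None:
        if self.n_concordant != self.n_hypo_up + self.n_hyper_down:
            raise ValueError("concordant count must equal hypo_up + hyper_down")
        if not (
            self.n_concordant <= self.n_common <= min(self.n_dmg, self.n_deg)
        ):
            raise ValueError("inconsistent overlap counts")


def overlap(dmg_genes, deg_genes) -> list[str]:
    """Sorted intersection of DMG and DEG gene symbols (exact match)."""
    return sorted(set(dmg_genes) & set(deg_genes))


def classify_concordance(dm_direction: str, de_direction: str) -> str:
    """Map a (methylation, expression) direction pair to its class.

    Raises for an ambiguous methylation direction; callers building
    records drop such genes with a logged reason.
    """
    key = (dm_direction, de_direction)
    if key not in _CLASS_MAP:
        raise ValueError(f"undefined direction pair {key!r}")
    return _CLASS_MAP[key]


def build_epigene_records(
    dmgs: pd.DataFrame, degs: pd.DataFrame
) -> pd.DataFrame:
    """Join gene-level DMG calls with DEG results on the common genes.

    ``dmgs`` is the frame from :func:`epiconcord.methylome.call_dmgs`
    (indexed by gene; genes with ambiguous direction are excluded here
    with a log message), ``degs`` the frame from
    :func:`epiconcord.transcriptome.call_degs`. Symbols present in only
    one layer are reported in a single warning-level log line.

    Returns one row per common gene with columns ``dm_direction``,
    ``diff_score``, ``delta_5mc_pct``, ``signed_fc``, ``log2fc``,
    ``de_direction``, ``concord_class``.
    """
    ambiguous = dmgs.index[dmgs["direction"] == "ambiguous"]
    if len(ambiguous):
        logger.info(
            "build_epigene_records: dropping %d ambiguous-direction DMGs: %s",
            len(ambiguous),
            ", ".join(map(str, ambiguous[:10])),
        )
    clean = dmgs.drop(index=ambiguous)
    only_dm = set(clean.index) - set(degs.index)
    only_de = set(degs.index) - set(clean.index)
    if only_dm or only_de:
        logger.warning(
            "gene symbols in one omics layer only: %d methylation-only, "
            "%d expression-only",
            len(only_dm),
            len(only_de),
        )
    common = overlap(clean.index, degs.index)
    records = pd.DataFrame(
        {
            "dm_direction": clean.loc[common, "direction"],
            "diff_score": clean.loc[common, "best_diff_score"],
            "delta_5mc_pct": clean.loc[common, "delta_5mc_pct"],
            "signed_fc": degs.loc[common, "signed_fc"],
            "log2fc": degs.loc[common, "log2fc"],
            "de_direction": degs.loc[common, "direction"],
        },
        index=pd.Index(common, name="gene_symbol"),
    )
    records["concord_class"] = [
        classify_concordance(dm, de)
        for dm, de in zip(records["dm_direction"], records["de_direction"])
    ]
    return records


def concordant_records(records: pd.DataFrame) -> pd.DataFrame:
    return records[records["concord_class"].isin(CONCORDANT_CLASSES)]


def summarize_integration(
    dmgs: pd.DataFrame, degs: pd.DataFrame, records: pd.DataFrame
) -> IntegrationSummary:
    """Overlap and concordance counts for the integrated gene sets."""
    n_common = len(records)
    n_hyper = int((records["dm_direction"] == "hyper").sum())
    classes = records["concord_class"].value_counts()
    n_hypo_up = int(classes.get("hypo_up", 0))
    n_hyper_down = int(classes.get("hyper_down", 0))
    return IntegrationSummary(
        n_dmg=len(dmgs),
        n_deg=len(degs),
        n_common=n_common,
        n_concordant=n_hypo_up + n_hyper_down,
        n_hypo_up=n_hypo_up,
        n_hyper_down=n_hyper_down,
        pct_hyper_of_common=(100.0 * n_hyper / n_common) if n_common else float("nan"),
    )


def write_epigene_tables(
    records: pd.DataFrame, outdir=None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split concordant records into the two published-style tables.

    Each table is sorted by descending absolute signed fold change (the
    printed ordering); the sort is stable, so equal fold changes keep
    their input order. When ``outdir`` is given the tables are written as
    ``epigenes_hypo_up.tsv`` and ``epigenes_hyper_down.tsv``.
    """
    conc = concordant_records(records)
    tables = []
    for cls in ("hypo_up", "hyper_down"):
        tbl = conc[conc["concord_class"] == cls].copy()
        order = np.argsort(-tbl["signed_fc"].abs().to_numpy(), kind="stable")
        tbl = tbl.iloc[order][
            ["delta_5mc_pct", "diff_score", "signed_fc", "concord_class"]
        ]
        tables.append(tbl)
    if outdir is not None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for cls, tbl in zip(("hypo_up", "hyper_down"), tables):
            tbl.to_csv(outdir / f"epigenes_{cls}.tsv", sep="\t", na_rep="NA")
    return tables[0], tables[1]


def load_reference_epigenes() -> pd.DataFrame:
    """Packaged 112-row reference table of concordant epigenes.

    Columns: ``gene_id``, ``gene_symbol``, ``delta_5mc_pct``,
    ``diff_score``, ``signed_fc``, ``table`` (``hypo_up`` or
    ``hyper_down``). Values are as printed in the source tables; signs of
    ``diff_score`` and ``signed_fc`` encode the methylation and expression
    directions.
    """
    with resources.files("epiconcord.data").joinpath(
        "concordant_epigenes.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_reference_rtpcr() -> pd.DataFrame:
    """Packaged RT-PCR validation summary table (14 targets).

    Columns: ``gene_symbol``, ``mean_ctrl``, ``sem_ctrl``, ``mean_case``,
    ``sem_case``, ``p_printed``, ``fold_printed``, ``microarray_fc``,
    ``confirmed``. Group means are 2^-ddCt relative quantities.
    """
    with resources.files("epiconcord.data").joinpath(
        "rtpcr_validation.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")
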