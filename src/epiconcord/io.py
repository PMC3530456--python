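"""Tab-separated readers and writers for the pipeline's file formats.

One tabular dialect throughout: UTF-8, tab-delimited, '.' decimal, 'NA'
for missing values. Matrices are written with the feature id as the first
column (``probe_id`` or ``gene_symbol``) and sample ids as the header
row. Gene symbols are opaque case-sensitive strings.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from epiconcord.methylome import BetaMatrix

_TSV = dict(sep="\t", na_rep="NA")


def read_sample_sheet(path) -> pd.Series:
    """Sample sheet TSV (columns ``sample_id``, ``group``) -> sample->group.

    Groups must be ``case`` or ``control``; duplicate sample ids and
    empty sheets are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise ValueError(f"{path}: sample sheet is empty")
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    bad = df[~df["group"].isin(["case", "control"])]
    if len(bad):
        row = bad.iloc[0]
        raise ValueError(
            f"{path}: unknown group label {row['group']!r} for sample "
            f"{row['sample_id']!r}"
        )
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate sample_id {dup.iloc[0]!r}")
    return pd.Series(df["group"].to_numpy(), index=df["sample_id"].to_numpy())


def write_sample_sheet(groups: pd.Series | pd.DataFrame, path) -> None:
    if isinstance(groups, pd.Series):
        df = pd.DataFrame({"sample_id": groups.index, "group": groups.to_numpy()})
    else:
        df = groups
    df.to_csv(path, index=False, **_TSV)


def read_matrix(path, index_name: str) -> pd.DataFrame:
    """Feature x sample TSV matrix with the feature id as first column."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    df.index.name = index_name
    return df


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, **_TSV)


def read_beta_matrix(beta_path, detection_path) -> BetaMatrix:
    beta = read_matrix(beta_path, "probe_id")
    det = read_matrix(detection_path, "probe_id")
    return BetaMatrix(beta, det)


def write_beta_matrix(matrix: BetaMatrix, beta_path, detection_path) -> None:
    write_matrix(matrix.beta, beta_path)
    write_matrix(matrix.detection_p, detection_path)


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chromosome": str})
    for col in ("probe_id", "gene_symbol", "chromosome"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return df


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, index=False, **_TSV)


def read_expression(path) -> pd.DataFrame:
    return read_matrix(path, "gene_symbol")


def read_gene_list(path) -> list[str]:
    """Plain-text gene list, one symbol per line; blanks skipped."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes, path) -> None:
    Path(path).write_text("\n".join(genes) + "\n")


def read_results(path) -> pd.DataFrame:
    """Per-feature results table written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])


def write_results(results: pd.DataFrame, path) -> None:
    results.to_csv(path, **_TSV)
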