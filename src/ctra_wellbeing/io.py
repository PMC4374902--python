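"""Readers and writers: item tables, covariates, expression TSV, GEO series-matrix.

All tabular I/O goes through pandas; the GEO series-matrix *text* format
(header lines of ``!Key<TAB>value`` pairs plus one expression table between
``!series_matrix_table_begin`` / ``!series_matrix_table_end``) is parsed by a
small line-oriented reader here.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .psychometrics import ItemMatrix


def read_expression_tsv(path: str | Path, value_space: str = "log2") -> ExpressionMatrix:
    """Genes x subjects TSV (first column = gene symbol)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene"
    if df.isna().any().any():
        raise ValueError(f"{path}: expression matrix contains missing values")
    return ExpressionMatrix(values=df, value_space=value_space)


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> Path:
    path = Path(path)
    matrix.values.to_csv(path, sep="\t")
    return path


def read_items(
    path: str | Path,
    instrument: str = "MHC-SF",
    item_map: Mapping[str, str] | None = None,
    subset_flag: str | None = None,
) -> ItemMatrix:
    """Read an item-response table (CSV or XLSX; header row = item IDs).

    ``subset_flag`` names an optional 0/1 column marking the analyzable
    subjects; flagged-out rows are dropped before validation.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path, index_col=0)
    else:
        df = pd.read_csv(path, index_col=0)
    df.index.name = "subject_id"
    if subset_flag is not None and subset_flag in df.columns:
        keep = df[subset_flag].astype(float) > 0
        df = df.loc[keep].drop(columns=[subset_flag])
    kwargs = {"item_map": dict(item_map)} if item_map else {}
    return ItemMatrix(instrument=instrument, responses=df, **kwargs)


_COVARIATE_SCHEMAS = {
    "confirmation": {
        "age": (18.0, 100.0),
        "sex_female": (0, 1),
        "race_white": (0, 1),
        "bmi": (10.0, 80.0),
        "smoking": (0, 1),
        "alcohol": (0, 1),
        "illness_symptoms": (0.0, 8.0),
    },
    "generalization": {
        "age": (18.0, 100.0),
        "sex_female": (0, 1),
        "bmi": (10.0, 80.0),
        "smoking": (0, 1),
        "alcohol": (0, 1),
    },
}


def read_covariates(path: str | Path, schema: str = "confirmation") -> pd.DataFrame:
    """Typed, range-validated subject covariate table (CSV)."""
    if schema not in _COVARIATE_SCHEMAS:
        raise ValueError(f"unknown covariate schema {schema!r}")
    df = pd.read_csv(path, index_col=0)
    df.index.name = "subject_id"
    ranges = _COVARIATE_SCHEMAS[schema]
    missing = sorted(set(ranges) - set(df.columns))
    if missing:
        raise ValueError(f"{path}: covariate columns missing: {missing}")
    for col, (lo, hi) in ranges.items():
        vals = df[col].dropna().astype(float)
        bad = vals[(vals < lo) | (vals > hi)]
        if len(bad):
            raise ValueError(
                f"{path}: {col!r} out of range [{lo}, {hi}] at row {bad.index[0]!r}: "
                f"{bad.iloc[0]}"
            )
    return df


def read_geo_series_matrix(path: str | Path):
    """Parse a GEO series-matrix text file.

    Returns ``(ExpressionMatrix, sample_metadata)`` where the metadata frame
    has one row per sample built from the ``!Sample_*`` header lines.
    Requires a complete matrix (no empty or ``null`` cells).
    """
    path = Path(path)
    meta_rows: dict[str, list[str]] = {}
    table_lines: list[str] = []
    in_table = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if line.startswith("!series_matrix_table_end"):
                in_table = False
                continue
            if in_table:
                table_lines.append(line)
            elif line.startswith("!Sample_"):
                key, *vals = line.split("\t")
                vals = [v.strip('"') for v in vals]
                base = key[len("!Sample_"):]
                name = base
                i = 2
                while name in meta_rows:  # repeated keys (characteristics_ch1 ...)
                    name = f"{base}.{i}"
                    i += 1
                meta_rows[name] = vals
            elif line.startswith(("!Series_", "!platform", "!Platform")):
                continue
            elif not line.startswith(("!", "#")) and not in_table:
                raise ValueError(f"{path}:{lineno}: malformed series-matrix line: {line[:60]!r}")
    if not table_lines:
        raise ValueError(f"{path}: no series_matrix table found")
    header = [c.strip('"') for c in table_lines[0].split("\t")]
    if not header or header[0] not in ("ID_REF", '"ID_REF"'):
        raise ValueError(f"{path}: table header must start with ID_REF, got {header[:1]}")
    records = []
    for offset, line in enumerate(table_lines[1:], start=2):
        cells = [c.strip('"') for c in line.split("\t")]
        if len(cells) != len(header):
            raise ValueError(
                f"{path}: table row {offset} has {len(cells)} cells, expected {len(header)}"
            )
        records.append(cells)
    df = pd.DataFrame(records, columns=header).set_index(header[0])
    df.index.name = "gene"
    df = df.replace({"": np.nan, "null": np.nan, "NULL": np.nan})
    if df.isna().any().any():
        raise ValueError(f"{path}: expression table contains missing values")
    df = df.astype(float)
    meta = pd.DataFrame(meta_rows)
    if "geo_accession" in meta.columns:
        meta.index = pd.Index(meta["geo_accession"], name="sample")
        df.columns = meta.index[: len(df.columns)] if len(meta) == len(df.columns) else df.columns
    matrix = ExpressionMatrix(values=df, value_space="raw")
    return matrix, meta


def collapse_probes(
    matrix: ExpressionMatrix, probe_map: Mapping[str, str], rule: str = "max_mean"
) -> ExpressionMatrix:
    """Collapse probe rows to gene symbols.

    ``max_mean`` (default) keeps, per symbol, the probe with the largest mean
    across subjects; ``mean`` averages probes within a symbol.
    """
    from dataclasses import replace

    df = matrix.values
    known = df.index.intersection(list(probe_map))
    df = df.loc[known]
    symbols = pd.Index([probe_map[p] for p in df.index], name="gene")
    if rule == "max_mean":
        means = df.mean(axis=1)
        order = means.groupby(symbols).idxmax()
        out = df.loc[order.to_numpy()]
        out.index = pd.Index(order.index, name="gene")
    elif rule == "mean":
        out = df.groupby(symbols).mean()
    else:
        raise ValueError(f"unknown probe-collapse rule {rule!r}")
    return replace(matrix, values=out)
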