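"""CTRA expression-response preparation.

Fixed pipeline order (asserted via ``value_space`` provenance flags):

    quantile-normalize -> log2 -> standardize within gene -> sign-adjust
    -> long format

Quantile normalization forces every subject column to the same reference
distribution (the cross-subject mean of sorted values), log2 is applied with
a configurable floor, genes are centered (and optionally scaled to SD 1),
negative CTRA elements (interferon / antibody genes) are sign-inverted once,
and the result is melted to one row per (subject, gene) joined to the
subject-level predictors, complete cases only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genesets import CtraGeneSet


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x subjects expression values with provenance flags."""

    values: pd.DataFrame  # index: gene symbols, columns: subject ids
    value_space: str = "raw"  # raw | log2 | standardized
    quantile_normalized: bool = False
    sign_adjusted: bool = False

    def __post_init__(self) -> None:
        if self.value_space not in ("raw", "log2", "standardized"):
            raise ValueError(f"unknown value_space {self.value_space!r}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene symbols in expression matrix")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def subjects(self) -> pd.Index:
        return self.values.columns

    def subset(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = set(genes) - set(self.values.index)
        if missing:
            raise KeyError(f"genes absent from matrix: {sorted(missing)}")
        return replace(self, values=self.values.loc[list(genes)])


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force all subject columns to the cross-subject rank-mean reference.

    Ties within a column receive the mean of the reference values at the tied
    ranks.  Requires a complete matrix.
    """
    if matrix.value_space != "raw":
        raise ValueError("quantile normalization expects raw intensities")
    X = matrix.values.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("quantile normalization requires a complete matrix")
    n_genes, n_subj = X.shape
    if n_subj < 2:
        raise ValueError("need at least 2 subjects")
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(n_subj):
        ranks = stats.rankdata(X[:, j], method="average")  # 1-based, ties averaged
        out[:, j] = np.interp(ranks, np.arange(1, n_genes + 1), reference)
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return replace(matrix, values=values, quantile_normalized=True)


def log2_transform(matrix: ExpressionMatrix, floor: float = 1.0) -> ExpressionMatrix:
    """log2 with values clipped at ``floor`` to guard nonpositive intensities."""
    if matrix.value_space != "raw":
        raise ValueError("log2 transform expects raw intensities")
    if floor <= 0:
        raise ValueError("floor must be positive")
    values = np.log2(matrix.values.clip(lower=floor))
    return replace(matrix, values=values, value_space="log2")


def standardize_genes(matrix: ExpressionMatrix, scale_sd: bool = True) -> ExpressionMatrix:
    """Center each gene to mean 0; divide by the gene SD when ``scale_sd``.

    The generalization-study convention centers only, retaining native log2
    dispersion (``scale_sd=False``).
    """
    if matrix.value_space != "log2":
        raise ValueError("standardization expects log2 values")
    X = matrix.values
    centered = X.sub(X.mean(axis=1), axis=0)
    if scale_sd:
        sd = X.std(axis=1, ddof=1)
        zero = sd[sd <= 0]
        if len(zero):
            raise ValueError(f"zero-variance genes cannot be scaled: {list(zero.index)}")
        centered = centered.div(sd, axis=0)
    return replace(matrix, values=centered, value_space="standardized")


def sign_adjust(matrix: ExpressionMatrix, gene_set: CtraGeneSet) -> ExpressionMatrix:
    """Multiply negative-contrast gene rows by -1, exactly once."""
    if matrix.sign_adjusted:
        raise ValueError("matrix is already sign-adjusted")
    sub = matrix.subset(gene_set.symbols)
    signs = pd.Series(gene_set.signs, index=list(gene_set.symbols), dtype=float)
    values = sub.values.mul(signs, axis=0)
    return replace(sub, values=values, sign_adjusted=True)


def marker_covariates(matrix: ExpressionMatrix, marker_list: Sequence[str]) -> pd.DataFrame:
    """Subject-level covariate columns from the 8 leukocyte-marker transcripts."""
    if len(marker_list) != 8:
        raise ValueError(f"expected 8 marker transcripts, got {len(marker_list)}")
    missing = sorted(set(marker_list) - set(matrix.values.index))
    if missing:
        raise KeyError(f"marker transcripts absent from matrix: {missing}")
    return matrix.values.loc[list(marker_list)].T.copy()


def prepare_ctra_response(
    matrix: ExpressionMatrix,
    gene_set: CtraGeneSet,
    scale_sd: bool = True,
    log2_floor: float = 1.0,
) -> ExpressionMatrix:
    """Run the fixed preparation order from any entry point.

    Raw input is quantile-normalized and log2-transformed first; log2 input
    skips those stages.  Output is standardized and sign-adjusted.
    """
    if matrix.value_space == "raw":
        matrix = log2_transform(quantile_normalize(matrix), floor=log2_floor)
    if matrix.value_space == "log2":
        matrix = standardize_genes(matrix, scale_sd=scale_sd)
    return sign_adjust(matrix, gene_set)


def to_long_format(
    matrix: ExpressionMatrix,
    gene_set: CtraGeneSet,
    predictors: pd.DataFrame,
    verbose: bool = False,
) -> pd.DataFrame:
    """Melt to (subject, gene, value) rows joined to complete-case predictors.

    Subjects missing any predictor are dropped entirely (complete-case rule);
    the attrition count is reported via ``attrs['n_input'] / attrs['n_complete']``.
    """
    if not matrix.sign_adjusted:
        raise ValueError("assemble the long format from the sign-adjusted matrix")
    sub = matrix.subset(gene_set.symbols)
    common = sub.values.columns.intersection(predictors.index)
    complete = predictors.loc[common].dropna(axis=0, how="any")
    n_input, n_complete = len(common), len(complete)
    if verbose or n_complete < n_input:
        print(f"complete-case predictors: {n_complete} of {n_input} subjects retained")
    long = (
        sub.values[complete.index]
        .rename_axis(index="gene", columns="subject_id")
        .T.stack()
        .rename("value")
        .reset_index()
    )
    long["gene_index"] = long["gene"].map(
        {g: i for i, g in enumerate(gene_set.symbols)}
    )
    long = long.merge(complete, left_on="subject_id", right_index=True, how="left")
    long = long.sort_values(["subject_id", "gene_index"], kind="stable").reset_index(drop=True)
    long.attrs["n_input"] = n_input
    long.attrs["n_complete"] = n_complete
    return long


def long_to_wide(long: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`to_long_format`: subjects x genes value matrix."""
    wide = long.pivot(index="subject_id", columns="gene", values="value")
    order = long.drop_duplicates("gene").sort_values("gene_index")["gene"]
    return wide[list(order)]
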