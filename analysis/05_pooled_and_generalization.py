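#!/usr/bin/env python
"""Pooled (discovery + confirmation) and generalization-study analyses.

Pooled: the two MHC-SF samples are concatenated, a study indicator is added
to the covariate set (18 subject-level predictors, so the 2-d eudaimonic
test carries df = 198 - 19 = 179), and the same HCS repeated-measures model
is fit on the 52 genes common to both studies.

Generalization: the Ryff-PWB sample (n = 107, 53 genes) is analyzed with
centered-only (native log2 dispersion) genes and an unstructured covariance,
for the 1-d total score and the 6 scales mutually adjusted.
"""
from pathlib import Path

import pandas as pd

from ctra_wellbeing import io as cio
from ctra_wellbeing.expression import (
    ExpressionMatrix,
    marker_covariates,
    prepare_ctra_response,
    to_long_format,
)
from ctra_wellbeing.genesets import default_marker_transcripts, load_gene_set
from ctra_wellbeing.model import contrast_test, fit_ctra_model, omnibus_f
from ctra_wellbeing.pipeline import AnalysisConfig, run_analysis
from ctra_wellbeing.psychometrics import score_mhcsf

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "study_data"
TABLES = ROOT / "results" / "tables"

DEMOGRAPHICS = ["age", "sex_female", "race_white", "bmi", "smoking", "alcohol",
                "illness_symptoms"]


def pooled_analysis() -> None:
    gene_set = load_gene_set(exclude=["IL6"])  # intersection of both panels
    markers = default_marker_transcripts()
    parts = []
    for study, flag in (("discovery", 0.0), ("confirmation", 1.0)):
        d = DATA / study
        items = cio.read_items(d / "items.xlsx", instrument="MHC-SF")
        scores = score_mhcsf(items).drop(columns="flourishing")
        cov = cio.read_covariates(d / "covariates.csv")
        matrix = cio.read_expression_tsv(d / "expression.tsv")
        pred = scores.join(cov.drop(columns="cesd")).join(marker_covariates(matrix, markers))
        pred["study"] = flag
        pred.index = [f"{study[:4]}_{i}" for i in pred.index]
        values = matrix.values.loc[list(gene_set.symbols) + list(markers)]
        values.columns = pred.index
        parts.append((pred, values))
    predictors = pd.concat([p for p, _ in parts])
    pooled_matrix = ExpressionMatrix(
        values=pd.concat([v for _, v in parts], axis=1), value_space="log2"
    )
    response = prepare_ctra_response(pooled_matrix, gene_set)
    terms = ["hedonic", "eudaimonic"] + DEMOGRAPHICS + list(markers) + ["study"]
    long = to_long_format(response, gene_set, predictors[terms])
    fit = fit_ctra_model(long, predictors=terms, structure="hcs",
                         standardize=["hedonic", "eudaimonic"])
    table = fit.params.loc[["hedonic", "eudaimonic"]].round(4)
    F, (df1, df2), pF = omnibus_f(fit, ["hedonic", "eudaimonic"])
    t, df, pc = contrast_test(fit, "eudaimonic", "hedonic")

    TABLES.mkdir(parents=True, exist_ok=True)
    table.to_csv(TABLES / "pooled_association.csv")
    print(f"pooled n = {fit.n_subjects} over {fit.n_genes} genes")
    print(table[["b", "se", "t", "df", "p", "vif"]].to_string())
    print(f"omnibus F({df1}, {df2}) = {F:.2f}, p = {pF:.2g}")
    print(f"eudaimonic vs hedonic: t({df}) = {t:.2f}, p = {pc:.2g}")


def generalization_analysis() -> None:
    d = DATA / "generalization"
    config = AnalysisConfig(
        study="generalization",
        items_path=str(d / "items.xlsx"),
        covariates_path=str(d / "covariates.csv"),
        expression_path=str(d / "expression.tsv"),
        representations=("ryff1d", "ryff6d"),
        covariance_structure="un",
        scale_sd=False,  # centered only, native log2 dispersion
        exclude_genes=(),
        run_cfa=False,
        seed=0,
    )
    report = run_analysis(config)
    frames = []
    for rep, panel in report["panels"].items():
        t = panel["table"].round(4)
        frames.append(t)
        F = panel["omnibus_f"]
        print(f"\n[{rep}] omnibus F({F['df1']}, {F['df2']}) = {F['F']:.2f}, p = {F['p']:.2g}")
        print(t[["b", "se", "t", "df", "p", "vif"]].to_string())
    pd.concat(frames).to_csv(TABLES / "generalization_association.csv")


def main() -> None:
    print("=== pooled discovery + confirmation ===")
    pooled_analysis()
    print("\n=== generalization (Ryff-PWB, unstructured covariance) ===")
    generalization_analysis()
    print(f"\nwrote tables under {TABLES}")


if __name__ == "__main__":
    main()
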