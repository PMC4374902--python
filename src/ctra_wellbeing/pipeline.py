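"""Config-driven orchestration: score -> CFA -> expression prep -> model -> report.

``run_analysis`` reproduces a study analysis end to end on synthetic or
supplied inputs and writes sample-characteristics and association-table
reports (CSV/JSON) plus a run log with complete-case accounting.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .cfa import fit_cfa_ml, mhcsf_cfa_specs, nested_chisq_test
from .expression import marker_covariates, prepare_ctra_response, to_long_format
from .genesets import default_marker_transcripts, load_gene_set
from .model import (
    contrast_test,
    fit_ctra_model,
    omnibus_f,
    percent_difference_effect,
    wald_t,
)
from .psychometrics import (
    cronbach_alpha,
    score_mhcsf,
    score_ryff,
    sign_test_predominance,
)
from .synthetic import StudyBundleConfig, gen_study_bundle

DEMOGRAPHIC_COVARIATES = {
    "confirmation": [
        "age", "sex_female", "race_white", "bmi", "smoking", "alcohol", "illness_symptoms",
    ],
    "generalization": ["age", "sex_female", "bmi", "smoking", "alcohol"],
}

REPRESENTATION_TERMS = {
    "2d": ["hedonic", "eudaimonic"],
    "3d": ["hedonic", "psychological", "social"],
    "1d": ["total"],
    "categorical": ["flourishing"],
    "ryff6d": [
        "purpose_in_life", "environmental_mastery", "self_acceptance",
        "autonomy", "personal_growth", "positive_relations",
    ],
    "ryff1d": ["total_pwb"],
}


@dataclass(frozen=True)
class AnalysisConfig:
    """One study analysis: inputs (files or synthetic spec) + model options."""

    study: str = "confirmation"  # confirmation | generalization
    synthetic: StudyBundleConfig | None = None
    items_path: str | None = None
    covariates_path: str | None = None
    expression_path: str | None = None
    expression_space: str = "log2"
    instrument: str = "MHC-SF"
    representations: tuple[str, ...] = ("2d", "3d", "1d", "categorical")
    gene_set_path: str | None = None
    exclude_genes: tuple[str, ...] = ("IL6",)
    covariance_structure: str = "hcs"
    scale_sd: bool = True
    run_cfa: bool = True
    include_cesd: bool = False
    interactions: tuple[str, ...] = ()  # e.g. ("alcohol:eudaimonic",)
    seed: int = 0
    out_dir: str | None = None

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _load_inputs(config: AnalysisConfig, log: list[str]):
    if config.synthetic is not None:
        out = Path(config.out_dir or ".") / "synthetic_inputs"
        paths = gen_study_bundle(config.synthetic, out)
        log.append(f"synthetic bundle written under {out}")
        items_path, cov_path, expr_path = paths["items"], paths["covariates"], paths["expression"]
        expr_space = config.synthetic.expression_space
    else:
        for name in ("items_path", "covariates_path", "expression_path"):
            if getattr(config, name) is None:
                raise ValueError(f"{name} required when no synthetic spec is given")
        items_path, cov_path, expr_path = (
            config.items_path, config.covariates_path, config.expression_path,
        )
        expr_space = config.expression_space
    instrument = "Ryff-PWB" if config.study == "generalization" else config.instrument
    items = cio.read_items(items_path, instrument=instrument, subset_flag="analyzable")
    covariates = cio.read_covariates(cov_path, schema=config.study)
    matrix = cio.read_expression_tsv(expr_path, value_space=expr_space)
    log.append(
        f"inputs: {len(items.responses)} subjects with items, "
        f"{len(covariates)} with covariates, {matrix.values.shape[1]} with expression"
    )
    return items, covariates, matrix


def _sample_table(items, scores: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    rows = {}
    for col in scores.columns:
        s = scores[col].astype(float)
        rows[col] = {"mean": s.mean(), "sd": s.std(ddof=1)}
    for scale in set(items.item_map.values()):
        cols = items.items_for(scale)
        frame = items.responses[cols].dropna()
        if items.reverse_keyed:
            rev = [c for c in cols if c in items.reverse_keyed]
            frame = frame.copy()
            frame[rev] = 7 - frame[rev]
        if scale in rows and len(frame) >= 3:
            rows[scale]["alpha"] = cronbach_alpha(frame)
    out = pd.DataFrame(rows).T
    out.index.name = "scale"
    return out


def run_analysis(config: AnalysisConfig) -> dict:
    """Execute the full pipeline; returns the report bundle as a dict."""
    log: list[str] = [f"config hash {config.config_hash()}, seed {config.seed}"]
    items, covariates, matrix = _load_inputs(config, log)

    # psychometrics
    if items.instrument == "MHC-SF":
        scores = score_mhcsf(items)
        prop, p_sign = sign_test_predominance(scores)
        log.append(f"eudaimonic predominance {prop:.3f} (sign test p={p_sign:.2e})")
        psych_extras = {
            "eudaimonic_predominance": prop,
            "sign_test_p": p_sign,
            "flourishing_prevalence": float(scores["flourishing"].mean()),
        }
    else:
        scores = score_ryff(items)
        psych_extras = {}
    sample_table = _sample_table(items, scores.drop(columns="flourishing", errors="ignore"), covariates)

    # CFA (MHC-SF only)
    cfa_report = None
    if config.run_cfa and items.instrument == "MHC-SF":
        complete_items = items.responses[list(items.item_map)].dropna()
        fits = {
            name: fit_cfa_ml(spec, data=complete_items, seed=config.seed)
            for name, spec in mhcsf_cfa_specs().items()
        }
        d21 = nested_chisq_test(fits["1-factor"], fits["2-factor"])
        d32 = nested_chisq_test(fits["2-factor"], fits["3-factor"])
        cfa_report = {
            "statistics": {name: f.statistic for name, f in fits.items()},
            "df": {name: f.df for name, f in fits.items()},
            "delta_2f_vs_1f": {"chisq": d21[0], "df": d21[1], "p": d21[2]},
            "delta_3f_vs_2f": {"chisq": d32[0], "df": d32[1], "p": d32[2]},
        }
        log.append(
            f"CFA dX2(1f->2f)={d21[0]:.2f} (df {d21[1]}), dX2(2f->3f)={d32[0]:.2f} (df {d32[1]})"
        )

    # expression preparation
    gene_set = load_gene_set(config.gene_set_path, exclude=config.exclude_genes)
    markers = default_marker_transcripts(config.gene_set_path)
    marker_cols = marker_covariates(matrix, markers)
    response = prepare_ctra_response(matrix, gene_set, scale_sd=config.scale_sd)

    # predictors: scores + demographics (+ optional CES-D) + markers
    demo = list(DEMOGRAPHIC_COVARIATES[config.study])
    if config.include_cesd:
        demo.append("cesd")
    cov = covariates.copy()
    if config.study == "generalization" and "ethnicity" in cov.columns:
        dummies = pd.get_dummies(cov["ethnicity"], prefix="eth", drop_first=True).astype(float)
        cov = cov.drop(columns=["ethnicity"]).join(dummies)
        demo = [c for c in demo if c != "ethnicity"] + list(dummies.columns)
    predictors = scores.astype(float).join(cov, how="inner").join(marker_cols, how="inner")

    panels = {}
    for rep in config.representations:
        terms = REPRESENTATION_TERMS[rep]
        model_terms = terms + demo + list(markers)
        # a covariate can be constant in small samples (e.g. no smokers drawn);
        # it carries no information and would make the design singular
        complete = predictors[model_terms].dropna()
        constant = [c for c in model_terms if c not in terms and complete[c].std(ddof=0) == 0]
        if constant:
            log.append(f"[{rep}] dropping constant covariates: {constant}")
            model_terms = [c for c in model_terms if c not in constant]
        inter_cols = []
        for spec_str in config.interactions:
            a, b = spec_str.split(":")
            name = f"{a}_x_{b}"
            if a in predictors and b in model_terms:
                predictors[name] = (
                    _z(predictors[a]) * _z(predictors[b])
                )
                inter_cols.append(name)
        long = to_long_format(response, gene_set, predictors[model_terms + inter_cols])
        log.append(
            f"[{rep}] complete cases: {long.attrs['n_complete']} of {long.attrs['n_input']} subjects"
        )
        fit = fit_ctra_model(
            long,
            predictors=model_terms + inter_cols,
            structure=config.covariance_structure,
            standardize=[t for t in terms if t != "flourishing"],
            seed=config.seed,
        )
        table = fit.params.loc[terms].copy()
        table.insert(0, "representation", rep)
        F, (df1, df2), pF = omnibus_f(fit, terms)
        panel = {
            "table": table,
            "omnibus_f": {"F": F, "df1": df1, "df2": df2, "p": pF},
            "loglik": fit.loglik,
            "rho": fit.rho,
            "n_predictors": len(model_terms) + len(inter_cols),
            "n_subjects": fit.n_subjects,
            "n_genes": fit.n_genes,
            "converged": fit.converged,
        }
        if rep in ("2d",):
            t, df, pc = contrast_test(fit, "eudaimonic", "hedonic")
            panel["eud_vs_hed_contrast"] = {"t": t, "df": df, "p": pc}
        panels[rep] = panel
        log.append(
            f"[{rep}] F({df1},{df2})={F:.2f}, terms: "
            + ", ".join(f"{t} b={table.at[t, 'b']:.3f} t={table.at[t, 't']:.2f}" for t in terms)
        )

    report = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "sample_table": sample_table,
        "psychometrics": psych_extras,
        "cfa": cfa_report,
        "panels": panels,
        "log": log,
    }
    if config.out_dir is not None:
        _write_report(report, Path(config.out_dir))
    return report


def _z(s: pd.Series) -> pd.Series:
    return (s - s.mean()) / s.std(ddof=1)


def _write_report(report: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    report["sample_table"].to_csv(out_dir / "sample_characteristics.csv")
    tables = [p["table"] for p in report["panels"].values()]
    if tables:
        pd.concat(tables).to_csv(out_dir / "association_table.csv")
    serializable = {
        k: v for k, v in report.items() if k not in ("sample_table", "panels")
    }
    serializable["panels"] = {
        rep: {k: v for k, v in panel.items() if k != "table"}
        for rep, panel in report["panels"].items()
    }
    with open(out_dir / "report.json", "w") as fh:
        json.dump(serializable, fh, indent=2, default=_json_default)
    with open(out_dir / "run_log.txt", "w") as fh:
        fh.write("\n".join(report["log"]) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def load_config(path: str | Path) -> AnalysisConfig:
    """Read an AnalysisConfig from YAML (``synthetic:`` maps to StudyBundleConfig)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "synthetic" in raw and raw["synthetic"] is not None:
        raw["synthetic"] = StudyBundleConfig(**{
            **raw["synthetic"],
            "exclude_genes": tuple(raw["synthetic"].get("exclude_genes", ("IL6",))),
        })
    for key in ("representations", "exclude_genes", "interactions"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    return AnalysisConfig(**raw)
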