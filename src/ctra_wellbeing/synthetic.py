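"""Synthetic study-data generator with known ground truth.

Every downstream stage (psychometric scoring, CFA, expression preparation,
the repeated-measures association model) is exercised on data from this
module, so the whole pipeline runs with no external downloads.

Well-being items are generated from a congeneric factor model — item latent
``x = m + lambda * f + sqrt(1 - lambda^2) * e`` with correlated standard-normal
factors — and discretized by fixed threshold cuts into the instrument's
integer response range.  The default parameters are calibrated so that the
confirmation-sample emulation reproduces the published sample moments:
scale means/SDs, Cronbach alphas (.82-.93), hedonic-eudaimonic r ~ .74,
psychological-social r ~ .80, ~22% eudaimonic predominance and ~50%
flourishing prevalence.

CTRA expression is generated gene-by-gene as

    y_ig = mu_g + sigma_g * (sign_g * eta_i + sqrt(1 - v) * eps_ig)

where ``eta_i`` is the linear predictor built from standardized well-being
scores and covariates (``v = var(eta)``), and ``eps_i`` has a heterogeneous
compound-symmetry correlation (one common within-subject correlation ``rho``).
Scaling the noise by ``sqrt(1 - v)`` makes each gene's total SD ``sigma_g``,
so the effect sizes ``b_true`` are on the standardized-response scale the
association model reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genesets import CtraGeneSet, default_marker_transcripts, load_gene_set
from .psychometrics import (
    ItemMatrix,
    MHCSF_KEYES_MAP,
    RYFF_MAP,
    RYFF_REVERSE_DEFAULT,
    RYFF_SCALES,
)

# ---------------------------------------------------------------------------
# well-being items

# Calibrated defaults for the confirmation-sample emulation (see docs/methods.md).
MHCSF_DOMAIN_LOADINGS = {"hedonic": 0.862, "psychological": 0.787, "social": 0.713}
MHCSF_DOMAIN_LATENT_MEANS = {"hedonic": 0.846, "psychological": 0.661, "social": 0.144}
MHCSF_FACTOR_CORR = pd.DataFrame(
    [[1.0, 0.828, 0.828], [0.828, 1.0, 0.946], [0.828, 0.946, 1.0]],
    index=["hedonic", "psychological", "social"],
    columns=["hedonic", "psychological", "social"],
)
MHCSF_CUT_SCALE = 1.37

RYFF_DOMAIN_LOADINGS = {
    "purpose_in_life": 0.461,
    "environmental_mastery": 0.562,
    "self_acceptance": 0.611,
    "autonomy": 0.592,
    "personal_growth": 0.620,
    "positive_relations": 0.634,
}
RYFF_FACTOR_CORR_DEFAULT = 0.66
RYFF_DOMAIN_LATENT_MEANS = {
    "purpose_in_life": 0.999,
    "environmental_mastery": 0.875,
    "self_acceptance": 0.877,
    "autonomy": 0.580,
    "personal_growth": 1.038,
    "positive_relations": 1.060,
}
RYFF_CUT_SCALE = 1.38


@dataclass(frozen=True)
class WellBeingSimSpec:
    """Factor-structured item generator specification.

    ``factor_model`` chooses the latent layout: 1, 2 or 3 correlated factors
    over the 14 MHC-SF items, or 6 factors over the 54 Ryff items.  Loadings
    are per item in [0, 1); ``latent_means`` shift each item's latent scale
    (they set the marginal response distribution); ``cut_scale`` spreads the
    discretization thresholds (larger -> responses concentrate centrally).
    """

    n_subjects: int
    instrument: str = "MHC-SF"
    factor_model: int = 3
    loadings: Mapping[str, float] = field(default_factory=dict)  # item -> loading
    factor_correlations: pd.DataFrame | None = None
    latent_means: Mapping[str, float] = field(default_factory=dict)  # item -> mean
    cut_scale: float = MHCSF_CUT_SCALE
    item_scale: tuple[int, int] = (0, 5)
    seed: int = 0

    def item_map(self) -> dict[str, str]:
        if self.instrument == "MHC-SF":
            if self.factor_model == 1:
                return {i: "wellbeing" for i in MHCSF_KEYES_MAP}
            if self.factor_model == 2:
                return {
                    i: ("hedonic" if s == "hedonic" else "eudaimonic")
                    for i, s in MHCSF_KEYES_MAP.items()
                }
            if self.factor_model == 3:
                return dict(MHCSF_KEYES_MAP)
            raise ValueError("MHC-SF factor_model must be 1, 2 or 3")
        if self.instrument == "Ryff-PWB":
            if self.factor_model != 6:
                raise ValueError("Ryff-PWB uses the 6-factor layout")
            return dict(RYFF_MAP)
        raise ValueError(f"unknown instrument {self.instrument!r}")

    def factors(self) -> list[str]:
        seen: dict[str, None] = {}
        for f in self.item_map().values():
            seen.setdefault(f)
        return list(seen)


def confirmation_wellbeing_spec(n_subjects: int = 122, seed: int = 0) -> WellBeingSimSpec:
    """Calibrated 3-factor MHC-SF spec emulating the confirmation sample."""
    loadings = {i: MHCSF_DOMAIN_LOADINGS[d] for i, d in MHCSF_KEYES_MAP.items()}
    means = {i: MHCSF_DOMAIN_LATENT_MEANS[d] for i, d in MHCSF_KEYES_MAP.items()}
    return WellBeingSimSpec(
        n_subjects=n_subjects,
        instrument="MHC-SF",
        factor_model=3,
        loadings=loadings,
        factor_correlations=MHCSF_FACTOR_CORR.copy(),
        latent_means=means,
        cut_scale=MHCSF_CUT_SCALE,
        item_scale=(0, 5),
        seed=seed,
    )


def generalization_ryff_spec(n_subjects: int = 107, seed: int = 0) -> WellBeingSimSpec:
    """6-factor Ryff-PWB spec patterned on the generalization sample."""
    corr = pd.DataFrame(
        RYFF_FACTOR_CORR_DEFAULT * np.ones((6, 6)) + (1 - RYFF_FACTOR_CORR_DEFAULT) * np.eye(6),
        index=list(RYFF_SCALES),
        columns=list(RYFF_SCALES),
    )
    loadings = {i: RYFF_DOMAIN_LOADINGS[d] for i, d in RYFF_MAP.items()}
    means = {i: RYFF_DOMAIN_LATENT_MEANS[d] for i, d in RYFF_MAP.items()}
    return WellBeingSimSpec(
        n_subjects=n_subjects,
        instrument="Ryff-PWB",
        factor_model=6,
        loadings=loadings,
        factor_correlations=corr,
        latent_means=means,
        cut_scale=RYFF_CUT_SCALE,
        item_scale=(1, 6),
        seed=seed,
    )


def _subject_ids(n: int) -> pd.Index:
    return pd.Index([f"s{i:04d}" for i in range(1, n + 1)], name="subject_id")


def _check_psd_corr(Phi: np.ndarray) -> None:
    if not np.allclose(Phi, Phi.T):
        raise ValueError("factor_correlations must be symmetric")
    if not np.allclose(np.diag(Phi), 1.0):
        raise ValueError("factor_correlations must have unit diagonal")
    eigmin = np.linalg.eigvalsh(Phi).min()
    if eigmin < -1e-10:
        raise ValueError(
            f"factor_correlations is not positive semi-definite (min eigenvalue {eigmin:.3g})"
        )


def gen_wellbeing_items(spec: WellBeingSimSpec, rng: np.random.Generator | None = None) -> ItemMatrix:
    """Draw discretized factor-structured item responses."""
    if spec.n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    item_map = spec.item_map()
    items = list(item_map)
    factors = spec.factors()
    k = len(factors)
    if spec.factor_correlations is None:
        Phi = np.eye(k)
    else:
        Phi = spec.factor_correlations.loc[factors, factors].to_numpy(dtype=float)
    _check_psd_corr(Phi)
    lam = np.array([spec.loadings.get(i, 0.0) for i in items])
    if ((lam < 0) | (lam >= 1)).any():
        raise ValueError("loadings must lie in [0, 1)")
    means = np.array([spec.latent_means.get(i, 0.0) for i in items])
    rng = np.random.default_rng(spec.seed) if rng is None else rng

    # correlated factors via Cholesky (PSD guard above; jitter exact-singular)
    try:
        L = np.linalg.cholesky(Phi)
    except np.linalg.LinAlgError:
        L = np.linalg.cholesky(Phi + 1e-10 * np.eye(k))
    F = rng.standard_normal((spec.n_subjects, k)) @ L.T
    fidx = np.array([factors.index(item_map[i]) for i in items])
    eps = rng.standard_normal((spec.n_subjects, len(items)))
    latent = means + lam * F[:, fidx] + np.sqrt(1.0 - lam**2) * eps

    lo, hi = spec.item_scale
    n_cat = hi - lo + 1
    cuts = spec.cut_scale * stats.norm.ppf(np.arange(1, n_cat) / n_cat)
    responses = lo + (latent[..., None] > cuts).sum(axis=-1)
    df = pd.DataFrame(responses.astype(int), index=_subject_ids(spec.n_subjects), columns=items)
    instrument = spec.instrument
    reverse = RYFF_REVERSE_DEFAULT if instrument == "Ryff-PWB" else frozenset()
    if reverse:
        rev_cols = [c for c in df.columns if c in reverse]
        df[rev_cols] = (lo + hi) - df[rev_cols]
    # scoring always uses the instrument's standard scale map, regardless of
    # the latent factor layout used to generate the data
    scoring_map = MHCSF_KEYES_MAP if instrument == "MHC-SF" else RYFF_MAP
    return ItemMatrix(
        instrument=instrument, responses=df, item_map=dict(scoring_map), reverse_keyed=reverse
    )


# ---------------------------------------------------------------------------
# covariates

_CONFIRMATION_PROFILE = {
    "age": (48.4, 8.8, 35.0, 64.0),
    "bmi": (27.4, 6.2, 16.0, 55.0),
    "female": 0.60,
    "white": 0.761,
    "smoking": 0.033,
    "alcohol": 0.746,
    "illness": (1.05, 0.9),  # mean, SD of the 0-8 symptom scale
    "cesd": (12.5, 9.4, 0.0, 60.0),
}
_GENERALIZATION_PROFILE = {
    "age": (45.3, 5.6, 34.0, 61.0),
    "bmi": (25.8, 4.2, 16.0, 45.0),
    "female": 0.794,
    "smoking": 0.056,
    "alcohol": 0.318,
    "ethnicity": (
        ("White", "Chinese", "Indian", "Other Asian", "Other"),
        (0.570, 0.187, 0.075, 0.122, 0.046),
    ),
}


def gen_covariates(n: int, seed: int = 0, profile: str = "confirmation") -> pd.DataFrame:
    """Subject covariate table patterned on the study sample characteristics."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    idx = _subject_ids(n)
    if profile == "confirmation":
        p = _CONFIRMATION_PROFILE
        m, s, lo, hi = p["age"]
        age = np.clip(rng.normal(m, s, n), lo, hi)
        m, s, lo, hi = p["bmi"]
        bmi = np.clip(rng.normal(m, s, n), lo, hi)
        mean, sd = p["illness"]
        shape = (mean / sd) ** 2
        illness = np.clip(rng.gamma(shape, sd**2 / mean, n), 0.0, 8.0)
        m, s, lo, hi = p["cesd"]
        cesd = np.clip(np.round(rng.normal(m, s, n)), lo, hi)
        return pd.DataFrame(
            {
                "age": np.round(age, 1),
                "sex_female": (rng.random(n) < p["female"]).astype(int),
                "race_white": (rng.random(n) < p["white"]).astype(int),
                "bmi": np.round(bmi, 1),
                "smoking": (rng.random(n) < p["smoking"]).astype(int),
                "alcohol": (rng.random(n) < p["alcohol"]).astype(int),
                "illness_symptoms": np.round(illness, 1),
                "cesd": cesd,
            },
            index=idx,
        )
    if profile == "generalization":
        p = _GENERALIZATION_PROFILE
        m, s, lo, hi = p["age"]
        age = np.clip(rng.normal(m, s, n), lo, hi)
        m, s, lo, hi = p["bmi"]
        bmi = np.clip(rng.normal(m, s, n), lo, hi)
        labels, probs = p["ethnicity"]
        ethnicity = rng.choice(labels, size=n, p=probs)
        return pd.DataFrame(
            {
                "age": np.round(age, 1),
                "sex_female": (rng.random(n) < p["female"]).astype(int),
                "ethnicity": ethnicity,
                "bmi": np.round(bmi, 1),
                "smoking": (rng.random(n) < p["smoking"]).astype(int),
                "alcohol": (rng.random(n) < p["alcohol"]).astype(int),
            },
            index=idx,
        )
    raise ValueError(f"unknown covariate profile {profile!r}")


def apply_mcar(
    df: pd.DataFrame, rate: float, seed: int = 0, columns: Sequence[str] | None = None
) -> pd.DataFrame:
    """Missing-completely-at-random mask, to exercise complete-case handling."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    out = df.copy()
    cols = list(columns) if columns is not None else list(df.columns)
    mask = rng.random((len(df), len(cols))) < rate
    values = out[cols].astype(float)
    values[pd.DataFrame(mask, index=df.index, columns=cols)] = np.nan
    out[cols] = values
    return out


# ---------------------------------------------------------------------------
# expression

@dataclass(frozen=True)
class ExpressionSimSpec:
    """Ground-truth generative spec for the CTRA expression matrix."""

    n_subjects: int
    gene_set: CtraGeneSet
    b_true: Mapping[str, float] = field(default_factory=dict)  # score column -> effect
    covariate_effects: Mapping[str, float] = field(default_factory=dict)
    rho: float = 0.65  # common within-subject residual correlation
    sigma_g: pd.Series | None = None  # per-gene residual SD; drawn if None
    marker_genes: tuple[str, ...] = ()
    marker_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        G = len(self.gene_set)
        lo = -1.0 / (G - 1) if G > 1 else -1.0
        if not lo < self.rho < 1.0:
            raise ValueError(f"rho must lie in ({lo:.4f}, 1) for G={G}")
        if not self.marker_genes:
            object.__setattr__(self, "marker_genes", default_marker_transcripts())
        if len(self.marker_genes) != 8:
            raise ValueError("exactly 8 marker transcripts expected")


def _standardize_cols(df: pd.DataFrame) -> pd.DataFrame:
    sd = df.std(ddof=1)
    if (sd <= 0).any():
        bad = list(sd.index[sd <= 0])
        raise ValueError(f"cannot standardize constant columns {bad}")
    return (df - df.mean()) / sd


def gen_expression(
    spec: ExpressionSimSpec,
    scores: pd.DataFrame,
    covariates: pd.DataFrame,
    rng: np.random.Generator | None = None,
):
    """Simulate the gene-by-subject log2 matrix (CTRA genes + 8 markers).

    Returns an :class:`~ctra_wellbeing.expression.ExpressionMatrix` in log2
    space whose rows are the spec's CTRA genes followed by the 8 marker
    transcripts.
    """
    from .expression import ExpressionMatrix

    if not scores.index.equals(covariates.index):
        common = scores.index.intersection(covariates.index)
        if len(common) != len(scores) or len(common) != len(covariates):
            raise ValueError("scores and covariates must share subject identifiers")
        covariates = covariates.loc[scores.index]
    n = len(scores)
    if n != spec.n_subjects:
        raise ValueError(f"scores have {n} subjects, spec expects {spec.n_subjects}")
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    G = len(spec.gene_set)
    genes = list(spec.gene_set.symbols)
    signs = np.array(spec.gene_set.signs, dtype=float)

    eta = np.zeros(n)
    for col, b in spec.b_true.items():
        eta += b * _standardize_cols(scores[[col]])[col].to_numpy()
    for col, b in spec.covariate_effects.items():
        eta += b * _standardize_cols(covariates[[col]].astype(float))[col].to_numpy()
    v = float(np.var(eta, ddof=1)) if n > 1 else 0.0
    if v >= 1.0:
        raise ValueError(f"total effect variance {v:.3f} >= 1; reduce effect sizes")

    mu_g = rng.uniform(6.0, 12.0, G)
    sigma_g = (
        spec.sigma_g.reindex(genes).to_numpy(dtype=float)
        if spec.sigma_g is not None
        else rng.uniform(0.25, 0.9, G)
    )
    if np.isnan(sigma_g).any() or (sigma_g <= 0).any():
        raise ValueError("sigma_g must be positive for every gene in the set")

    # the repeated-measures covariance structure is defined on the
    # sign-adjusted responses, so the equicorrelated noise is injected on that
    # scale and un-adjusted together with the effect (raw-scale residual
    # correlations are sign_g * sign_h * rho)
    R = np.full((G, G), spec.rho)
    np.fill_diagonal(R, 1.0)
    Lr = np.linalg.cholesky(R)
    eps = rng.standard_normal((n, G)) @ Lr.T
    adjusted = eta[:, None] + np.sqrt(max(1.0 - v, 1e-6)) * eps
    Y = mu_g + sigma_g * signs * adjusted

    markers = rng.uniform(7.0, 11.0, 8) + spec.marker_sd * rng.standard_normal((n, 8))
    values = pd.DataFrame(
        np.vstack([Y.T, markers.T]),
        index=pd.Index(genes + list(spec.marker_genes), name="gene"),
        columns=scores.index,
    )
    return ExpressionMatrix(values=values, value_space="log2", quantile_normalized=True)


# ---------------------------------------------------------------------------
# study bundles on disk

@dataclass(frozen=True)
class StudyBundleConfig:
    """End-to-end synthetic study configuration (files on disk)."""

    study: str = "confirmation"
    n_subjects: int = 122
    b_true: Mapping[str, float] = field(default_factory=lambda: {"eudaimonic": -0.5})
    covariate_effects: Mapping[str, float] = field(default_factory=dict)
    rho: float = 0.65
    exclude_genes: tuple[str, ...] = ("IL6",)
    expression_space: str = "log2"  # or "raw" (2**log2, exercises QN + log2 stages)
    items_format: str = "xlsx"  # or "csv"
    missing_rate: float = 0.0
    seed: int = 0


def gen_study_bundle(config: StudyBundleConfig, out_dir) -> dict[str, "Path"]:
    """Generate and write a complete synthetic study (items, covariates, expression).

    Files round-trip losslessly through :mod:`ctra_wellbeing.io` readers.
    """
    from pathlib import Path

    from .psychometrics import score_mhcsf, score_ryff

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.seed)
    if config.study == "confirmation":
        wb_spec = confirmation_wellbeing_spec(config.n_subjects, seed=seed)
        covariates = gen_covariates(config.n_subjects, seed=seed + 1, profile="confirmation")
    elif config.study == "generalization":
        wb_spec = generalization_ryff_spec(config.n_subjects, seed=seed)
        covariates = gen_covariates(config.n_subjects, seed=seed + 1, profile="generalization")
    else:
        raise ValueError(f"unknown study {config.study!r}")
    items = gen_wellbeing_items(wb_spec)
    scores = score_mhcsf(items) if config.study == "confirmation" else score_ryff(items)
    gene_set = load_gene_set(exclude=config.exclude_genes)
    expr_spec = ExpressionSimSpec(
        n_subjects=config.n_subjects,
        gene_set=gene_set,
        b_true=dict(config.b_true),
        covariate_effects=dict(config.covariate_effects),
        rho=config.rho,
        seed=seed + 2,
    )
    matrix = gen_expression(expr_spec, scores.drop(columns="flourishing", errors="ignore"), covariates)
    values = matrix.values
    if config.expression_space == "raw":
        values = 2.0**values

    responses = items.responses
    if config.missing_rate > 0:
        responses = apply_mcar(responses, config.missing_rate, seed=seed + 3)
        covariates = apply_mcar(
            covariates, config.missing_rate, seed=seed + 4,
            columns=[c for c in covariates.columns if c != "ethnicity"],
        )

    items_path = out / f"items.{config.items_format}"
    if config.items_format == "xlsx":
        responses.to_excel(items_path)
    elif config.items_format == "csv":
        responses.to_csv(items_path)
    else:
        raise ValueError(f"unknown items_format {config.items_format!r}")
    cov_path = out / "covariates.csv"
    covariates.to_csv(cov_path)
    expr_path = out / "expression.tsv"
    values.to_csv(expr_path, sep="\t")  # default repr round-trips exactly
    return {"items": items_path, "covariates": cov_path, "expression": expr_path}
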