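"""Scoring and descriptive statistics for well-being instruments.

Two instruments are supported:

* **MHC-SF** (Mental Health Continuum — Short Form): 14 items on a 0–5
  frequency scale ("never" … "every day"); 3 hedonic, 5 social and 6
  psychological items.  Scale scores are item *means* (range 0–5).  Four
  representations are produced: 3-d (hedonic / psychological / social),
  2-d (hedonic / eudaimonic, the latter pooling the 11 psychological+social
  items), 1-d (mean of all 14 items) and a categorical flourishing flag.
* **Ryff-PWB** (Ryff Scales of Psychological Well-Being): 6 scales x 9 items
  on a 1–6 agreement scale, reverse-keyed items flipped before summing.
  Scale scores are item *sums* (range 9–54); total PWB is the mean of the
  6 scale scores.

Also provided: Cronbach's alpha, the correlation helpers used in the
sample-characteristics tables (Pearson, point-biserial, ANOVA effect-size r),
and the sign test for eudaimonic predominance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

MHCSF_ITEMS = tuple(f"mhcsf_{i:02d}" for i in range(1, 15))
# Keyes' standard allocation: items 1-3 hedonic, 4-8 social, 9-14 psychological.
MHCSF_KEYES_MAP: dict[str, str] = {
    **{f"mhcsf_{i:02d}": "hedonic" for i in (1, 2, 3)},
    **{f"mhcsf_{i:02d}": "social" for i in (4, 5, 6, 7, 8)},
    **{f"mhcsf_{i:02d}": "psychological" for i in (9, 10, 11, 12, 13, 14)},
}

RYFF_SCALES = (
    "purpose_in_life",
    "environmental_mastery",
    "self_acceptance",
    "autonomy",
    "personal_growth",
    "positive_relations",
)
RYFF_ITEMS = tuple(
    f"ryff_{scale}_{j}" for scale in RYFF_SCALES for j in range(1, 10)
)
RYFF_MAP: dict[str, str] = {item: item.rsplit("_", 1)[0][5:] for item in RYFF_ITEMS}
# Package default: items 4, 6 and 8 of each 9-item scale are reverse-keyed.
RYFF_REVERSE_DEFAULT = frozenset(
    f"ryff_{scale}_{j}" for scale in RYFF_SCALES for j in (4, 6, 8)
)

_SCALE_RANGE = {"MHC-SF": (0, 5), "Ryff-PWB": (1, 6)}


def brown_item_map(reallocate: Sequence[str] = ("mhcsf_04", "mhcsf_05")) -> dict[str, str]:
    """Alternative 3-d MHC-SF allocation moving 2 social items to psychological."""
    m = dict(MHCSF_KEYES_MAP)
    for item in reallocate:
        if m.get(item) != "social":
            raise ValueError(f"{item} is not a social item in the standard map")
        m[item] = "psychological"
    return m


@dataclass(frozen=True)
class ItemMatrix:
    """Per-subject integer item responses for one well-being instrument."""

    instrument: Literal["MHC-SF", "Ryff-PWB"]
    responses: pd.DataFrame  # index: subject_id, columns: item ids
    item_map: Mapping[str, str] = field(default_factory=dict)
    reverse_keyed: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.instrument not in _SCALE_RANGE:
            raise ValueError(f"unknown instrument {self.instrument!r}")
        if not self.item_map:
            default = MHCSF_KEYES_MAP if self.instrument == "MHC-SF" else RYFF_MAP
            object.__setattr__(self, "item_map", dict(default))
            if self.instrument == "Ryff-PWB" and not self.reverse_keyed:
                object.__setattr__(self, "reverse_keyed", RYFF_REVERSE_DEFAULT)
        missing = set(self.item_map) - set(self.responses.columns)
        if missing:
            raise ValueError(f"item_map references absent items: {sorted(missing)}")
        self._validate_range()

    def _validate_range(self) -> None:
        lo, hi = _SCALE_RANGE[self.instrument]
        vals = self.responses[list(self.item_map)]
        bad = (vals < lo) | (vals > hi)
        if bad.to_numpy(na_value=False).any():
            rows, cols = np.nonzero(bad.to_numpy(na_value=False))
            subj, item = vals.index[rows[0]], vals.columns[cols[0]]
            raise ValueError(
                f"response out of range [{lo}, {hi}] for subject {subj!r}, "
                f"item {item!r}: {vals.at[subj, item]}"
            )

    def items_for(self, scale: str) -> list[str]:
        items = [i for i, s in self.item_map.items() if s == scale]
        if not items:
            raise KeyError(f"no items mapped to scale {scale!r}")
        return items

    def with_item_map(self, item_map: Mapping[str, str]) -> "ItemMatrix":
        return replace(self, item_map=dict(item_map))


def _complete_rows(df: pd.DataFrame) -> pd.DataFrame:
    """Complete-case rule: subjects missing any item of a scale drop from it."""
    return df.dropna(axis=0, how="any")


def score_mhcsf(
    items: ItemMatrix,
    representation: Literal["3d", "2d", "1d", "categorical", "all"] = "all",
) -> pd.DataFrame:
    """Score the MHC-SF under the requested representation.

    Returns one row per subject with the scale scores of the representation
    (``all`` returns every column).  Eudaimonic (2-d) is the mean of the 11
    psychological + social items, i.e. the item-count-weighted combination
    (6*psychological + 5*social) / 11.
    """
    if items.instrument != "MHC-SF":
        raise ValueError("score_mhcsf requires an MHC-SF ItemMatrix")
    scales = {}
    for scale in ("hedonic", "psychological", "social"):
        cols = items.items_for(scale)
        scales[scale] = _complete_rows(items.responses[cols]).mean(axis=1)
    eud_cols = items.items_for("psychological") + items.items_for("social")
    scales["eudaimonic"] = _complete_rows(items.responses[eud_cols]).mean(axis=1)
    scales["total"] = _complete_rows(items.responses[list(items.item_map)]).mean(axis=1)
    scales["flourishing"] = classify_flourishing(items)
    out = pd.DataFrame(scales)
    columns = {
        "3d": ["hedonic", "psychological", "social"],
        "2d": ["hedonic", "eudaimonic"],
        "1d": ["total"],
        "categorical": ["flourishing"],
        "all": list(out.columns),
    }[representation]
    return out[columns]


def classify_flourishing(items: ItemMatrix, response_threshold: int = 4) -> pd.Series:
    """Categorical flourishing: >=1 of 3 hedonic and >=6 of 11 eudaimonic signs
    experienced "every day" (5) or "5-6 times a week" (4)."""
    if items.instrument != "MHC-SF":
        raise ValueError("flourishing is defined for the MHC-SF")
    hed = items.responses[items.items_for("hedonic")]
    eud = items.responses[items.items_for("psychological") + items.items_for("social")]
    hed, eud = _complete_rows(hed), _complete_rows(eud)
    common = hed.index.intersection(eud.index)
    n_hed = (hed.loc[common] >= response_threshold).sum(axis=1)
    n_eud = (eud.loc[common] >= response_threshold).sum(axis=1)
    return (n_hed >= 1) & (n_eud >= 6)


def score_ryff(items: ItemMatrix) -> pd.DataFrame:
    """Score the six 9-item Ryff-PWB scales (sums, 9-54) and their mean."""
    if items.instrument != "Ryff-PWB":
        raise ValueError("score_ryff requires a Ryff-PWB ItemMatrix")
    keyed = items.responses.copy()
    rev = [c for c in keyed.columns if c in items.reverse_keyed]
    keyed[rev] = 7 - keyed[rev]
    out = {}
    for scale in RYFF_SCALES:
        cols = items.items_for(scale)
        out[scale] = _complete_rows(keyed[cols]).sum(axis=1)
    scores = pd.DataFrame(out)
    scores["total_pwb"] = scores[list(RYFF_SCALES)].mean(axis=1)
    return scores


def cronbach_alpha(item_scores: pd.DataFrame | np.ndarray) -> float:
    """Cronbach's alpha: (k/(k-1)) * (1 - sum of item variances / variance of sum)."""
    x = np.asarray(item_scores, dtype=float)
    x = x[~np.isnan(x).any(axis=1)]
    n, k = x.shape
    if k < 2:
        raise ValueError("alpha requires at least 2 items")
    if n < 3:
        raise ValueError("alpha requires at least 3 subjects")
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("alpha undefined: zero variance of the item sum")
    item_var = x.var(axis=0, ddof=1).sum()
    return k / (k - 1) * (1.0 - item_var / total_var)


def correlate(
    x: Sequence | pd.Series,
    y: Sequence | pd.Series,
    kind: Literal["pearson", "point_biserial", "anova_r"] = "pearson",
) -> tuple[float, float]:
    """Bivariate association as used in the sample-characteristics tables.

    ``anova_r`` treats ``x`` as categorical and reports the one-way ANOVA
    effect size r = sqrt(SS_between / SS_total) with the F-test p-value.
    """
    x = pd.Series(x).reset_index(drop=True)
    y = pd.Series(np.asarray(y, dtype=float)).reset_index(drop=True)
    keep = y.notna() & x.notna()
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    if kind == "anova_r":
        groups = [g.to_numpy() for _, g in y.groupby(x)]
        if len(groups) < 2:
            raise ValueError("anova_r needs >=2 groups")
        grand = y.mean()
        ss_total = ((y - grand) ** 2).sum()
        if ss_total == 0:
            raise ValueError("anova_r undefined for constant y")
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        _, p = stats.f_oneway(*groups)
        return float(np.sqrt(ss_between / ss_total)), float(p)
    xv = np.asarray(x, dtype=float)
    if np.ptp(xv) == 0 or np.ptp(y.to_numpy()) == 0:
        raise ValueError(f"{kind} correlation undefined for constant input")
    if kind == "pearson":
        r, p = stats.pearsonr(xv, y)
    elif kind == "point_biserial":
        r, p = stats.pointbiserialr(xv, y)
    else:
        raise ValueError(f"unknown kind {kind!r}")
    return float(r), float(p)


def sign_test_predominance(
    scores: pd.DataFrame,
    eudaimonic: str = "eudaimonic",
    hedonic: str = "hedonic",
) -> tuple[float, float]:
    """Proportion of subjects with eudaimonic >= hedonic, with an exact
    two-sided binomial sign test on the non-tied pairs.

    Ties count toward the proportion (the ">=" definition) but are excluded
    from the test, per the usual sign-test convention.
    """
    d = scores[eudaimonic] - scores[hedonic]
    d = d.dropna()
    if len(d) == 0:
        raise ValueError("no complete score pairs")
    proportion = float((d >= 0).mean())
    nontied = d[d != 0]
    if len(nontied) == 0:
        return proportion, 1.0
    test = stats.binomtest(int((nontied > 0).sum()), len(nontied), p=0.5)
    return proportion, float(test.pvalue)
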