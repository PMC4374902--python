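# Methods

This package implements an analysis pipeline linking self-reported
well-being to the conserved transcriptional response to adversity (CTRA), a
leukocyte gene-expression signature of up-regulated pro-inflammatory genes
and down-regulated type I interferon and antibody-synthesis genes.  The
pipeline has four computational stages — psychometric scoring, confirmatory
factor analysis (CFA), expression-response preparation, and a pooled
repeated-measures association model — plus a synthetic-data generator that
emulates the study conditions so every stage runs and is testable with no
external data.

## Psychometric scoring

**MHC-SF** (14 items, 0–5 frequency responses: 3 hedonic, 5 social, 6
psychological) is scored as item *means* under four representations: 3-d
(hedonic / psychological / social), 2-d (hedonic / eudaimonic, where the
eudaimonic score is the mean of the 11 psychological + social items, i.e.
(6·psychological + 5·social)/11), 1-d (mean of all 14 items), and a
categorical flourishing flag requiring ≥ 1 of 3 hedonic and ≥ 6 of 11
eudaimonic items experienced "5–6 times a week" (code 4) or "every day"
(code 5).  **Ryff-PWB** (6 scales × 9 items, 1–6 agreement responses) is
scored as item *sums* per scale (range 9–54) after reverse-keying, with a
total score averaging the 6 scale scores.  The choice of mean-scoring for
the MHC-SF and sum-scoring for Ryff matches the score ranges of the
published sample-characteristic tables.

Complete-case handling throughout: a subject missing any item of a scale is
dropped from that scale; a subject missing any model predictor is dropped
from the association analysis, with attrition counts logged at each stage.
No imputation is performed.

Reliability is Cronbach's α = k/(k−1) · (1 − Σ var(itemᵢ)/var(Σ items)).
Bivariate descriptive associations use Pearson or point-biserial
correlation, or the one-way ANOVA effect size r = √(SS_between/SS_total)
for categorical covariates.  Eudaimonic predominance is the proportion of
subjects with eudaimonic ≥ hedonic score; its sign test is the exact
two-sided binomial test on the non-tied pairs (ties count toward the
proportion, not the test).

The alternative 3-d item allocation that moves two social items to the
psychological scale is supported through a configurable item map
(`brown_item_map`); the default map is the standard allocation.  Which two
items move is configurable because the source analyses do not fix them.

## Confirmatory factor analysis

Congeneric ML CFA: each item loads on exactly one factor, factor variances
are fixed at 1, uniquenesses ψⱼ > 0, factor correlations free.  The fit
minimizes the ML discrepancy

  F_ML = ln|Σ(θ)| + tr(S Σ(θ)⁻¹) − ln|S| − p,  Σ(θ) = ΛΦΛ′ + Ψ,

on the Pearson covariance S of the raw item scores (items treated as
continuous; polychoric CFA is out of scope and is the main reason an exact
match to ordinal-data results is not guaranteed).  The test statistic is
T = (n−1)·F_ML with df = p(p+1)/2 − (2p + k(k−1)/2).  Nested structures
(two factors merged, equivalently their correlation fixed at 1) are
compared by ΔX² = T_restricted − T_general on Δdf = df_r − df_g; for the 14
MHC-SF items the 1- vs 2-factor comparison has Δdf = 1 and the 2- vs
3-factor comparison Δdf = 2.

Numerics: L-BFGS-B with analytic gradients (dF/dΣ = Σ⁻¹ − Σ⁻¹SΣ⁻¹ chained
to loadings, log-uniquenesses, and correlations), 5 seeded starts plus
restart polishing, convergence declared only below a 1e-5 gradient-infinity
norm (typically ~1e-8 is reached); uniquenesses below 0.5% of the item
variance are flagged as Heywood cases.  Factor correlations are estimated
*unconstrained* — improper |φ| > 1 solutions are permitted and only
positive-definiteness of Σ(θ) is enforced (via a smooth minimum-eigenvalue
penalty outside the feasible region).  This matches standard ML-CFA
software behavior and matters for inference: the merged-factor null lies on
the φ = 1 boundary, and constraining φ ≤ 1 would turn the ΔX² reference
into a boundary mixture instead of χ²(Δdf).

Finite-sample caveat: the χ²(Δdf) reference for ΔX² is asymptotic.  In our
calibration experiments with 14 indicators the difference statistic is
inflated by roughly 18% in the mean at n = 300 and is indistinguishable
from χ²(1) at n = 3000 (KS p ≈ 0.4–0.6); the shipped calibration test
therefore runs at n = 3000.  Printed χ² values from modest samples should
be read with this in mind.

## Expression preparation

The preparation order is fixed and enforced through provenance flags:

  quantile-normalize → log2 → standardize within gene → sign-adjust → long format

Quantile normalization maps every subject column onto the cross-subject
mean of sorted values (ties receive the mean of the tied reference
positions).  log2 uses a configurable floor (default 1.0) against
nonpositive intensities.  Standardization centers each gene to mean 0 and
divides by the gene SD when `scale_sd=True` (the confirmation-study
convention; the generalization convention centers only, keeping native log2
dispersion).  Sign adjustment multiplies the 34 negative CTRA elements
(interferon- and antibody-related genes) by −1, exactly once, so that a
larger value always means a more CTRA-like profile.  Sign adjustment and
SD-standardization commute, which is tested.

The default CTRA panel ships as a YAML config with 53 genes
(19 pro-inflammatory +1, 31 interferon −1, 3 antibody −1); its composition
counts are validated on load, and the confirmation panel is obtained by
excluding `IL6` (52 genes).  Because the primary sources name only exemplar
genes and families, the shipped membership is a package default and is
explicitly replaceable, as are the 8 leukocyte-subset marker transcripts
(defaults CD3D, CD3E, CD4, CD8A, CD19, FCGR3A, NCAM1, CD14) used as
subject-level covariates for CD4+/CD8+ T cells, B cells, NK cells and
monocytes.  For array data, probes collapse to symbols by the maximum-mean
probe (configurable to averaging); this rule and the marker identities are
the two main degrees of freedom when reproducing accession-based numbers.

## Repeated-measures association model

For subject i and gene g, the sign-adjusted prepared response y_ig follows

  y_ig = μ_g + x_i′β + e_ig,   (e_i1 … e_iG) ~ N(0, Σ),

with gene-specific fixed intercepts μ_g (the repeated-measures gene
effect), a common subject-level slope vector β, and within-subject residual
covariance Σ structured as:

* **HCS** (heterogeneous compound symmetry, the primary structure):
  Σ_gh = ρ σ_g σ_h for g ≠ h, σ_g² on the diagonal — one common correlation,
  gene-specific variances; PSD requires ρ ∈ (−1/(G−1), 1).
* **CS**: one variance, one correlation (equivalent to a subject random
  intercept for ρ ≥ 0).
* **UN**: a free G×G matrix, for sensitivity analyses.

Estimation is maximum likelihood (not REML).  Fixed effects are profiled
out by GLS — the balanced layout reduces the whitened normal equations to
closed-form blocks in Σ⁻¹, Σ⁻¹1, 1′Σ⁻¹1 and the design moments — inside an
ascent loop over the covariance parameters: for HCS/CS a quasi-Newton inner
step on (log σ_g, logit-transformed ρ) with analytic gradients of
ln|Σ| + tr(SΣ⁻¹); for UN the iterated-GLS update Σ ← E′E/n with optional
ridge stabilization (a configurable fraction of the mean residual variance
added to the diagonal) for G approaching n.  Multiple seeded starts are
used (default 3; replicate simulations use 1, which we verified reaches the
same optimum to ~1e-11 in log-likelihood).  Fits match a brute-force dense
multivariate-normal likelihood optimizer to better than 1e-5 in both
log-likelihood and slopes on small instances, and the CS-balanced fit
reproduces OLS on the per-subject gene-mean composite to 1e-10.

Inference: Wald t = b/SE with the **between-within denominator df
convention, df = n_subjects − p − 1** (p = number of subject-level
predictor columns), chosen because it reproduces exactly every printed
denominator df given the stated sample sizes and covariate sets
(e.g. n=122 with 17 predictors → t(104); n=198 with 18 → t(179); n=107
with 23 → t(83)).  Satterthwaite/Kenward-Roger df are not implemented.
Group tests use the Wald F on the joint null with df1 = group size and
df2 = the same denominator df; single-term F equals t².  The
eudaimonic-vs-hedonic comparison is the contrast b_eud − b_hed tested with
the estimated coefficient covariance.  Collinearity is quantified by
VIF = 1/(1−R²) of each regressor on all the others (threshold 10).
Unstandardized log2 slopes b per predictor SD translate to the
percent-difference effect 100·(2^{4b} − 1), the fold change across a
[−2 SD, +2 SD] predictor span.

### Small-sample inference caveat (important)

The model-based SE conditions on the estimated Σ.  Two regimes make it
anticonservative at the confirmation scale (G = 52, n = 122):

1. When the gene variances are truly (near-)equal, the 52 HCS variance
   parameters are redundant, and their estimation noise — ignored by the
   model SE — inflates the slope estimator's true sampling SD by ~10%
   (a Kackar–Harville-type effect).  CS fits do not show this.
2. Standardizing every gene to sample SD 1 pins each gene's total variance,
   mechanically anticorrelating estimated residual variances with realized
   gene-level slopes; the resulting precision weights couple to the noise.
   Under this convention the empirical-SD/model-SE ratio reaches ~1.25 with
   a single predictor and ~1.4–1.5 with the full 17-predictor design, i.e.
   null rejection rates of 13–26% at nominal 5% depending on the residual
   correlation.

We verified this is a property of exact ML, not of our optimizer (fits
match the dense-likelihood oracle on standardized data), and that the same
estimator is well calibrated (≈5–6% rejection, SE ratio ≈1.05) on draws
from the HCS model itself at the full confirmation scale, as well as
through the full pipeline under the centered-only convention.  The caveat
applies equally to the original SAS analyses, which used the same
standardization and ML machinery.  Operating characteristics for all these
regimes are computed by `analysis/06_operating_characteristics.py` and
`scripts/acceptance.py`.

## Synthetic-data generator

**Well-being items** come from a congeneric factor model: item latent
x = m + λf + √(1−λ²)ε with correlated standard-normal factors, discretized
by fixed cuts (scale · Φ⁻¹(k/K)) into the instrument's response range.  The
defaults were calibrated once, by moment matching at large n, to the
published confirmation-sample moments: scale means 3.63/3.40/2.70, alphas
.87/.89/.82 (eudaimonic .92, total .93), hedonic–eudaimonic r ≈ .74,
psychological–social r ≈ .80.  The calibrated constants are domain loadings
(.862/.787/.713), domain latent means (.846/.661/.144), factor correlations
(hed–psych = hed–soc = .828, psych–soc = .946) and cut scale 1.37.  Two
derived quantities then emerge without further tuning: eudaimonic
predominance ≈ 23% (published 22%) and flourishing prevalence ≈ 41%
(published 50%) — the flourishing shortfall is a known limitation of the
single-threshold discretized-Gaussian item model, which slightly
under-produces subjects with many top-category responses.  The Ryff
generator is calibrated the same way to the generalization-sample scale
means, SDs and alphas, with a common inter-factor correlation of .66
(inter-scale R² ≈ .3, inside the published .14–.52 range).

**Covariates** are drawn from distributions patterned on the published
sample-characteristics tables (age 48.4 ± 8.8 truncated to 35–64, 60%
female, 76% white, BMI 27.4 ± 6.2, 3.3% smokers, 74.6% alcohol, illness
symptoms gamma with mean 1.05 and SD 0.9, CES-D 12.5 ± 9.4; a separate
profile for the generalization sample includes a 5-category ethnicity).
Covariates are generated independently of the well-being scores; the
published covariate–well-being correlations (mostly |r| < .2) are not
reproduced, so covariate adjustment in the synthetic studies removes noise
but not confounding.  An MCAR missingness option exercises the
complete-case accounting.

**Expression**: y_ig = μ_g + σ_g · sign_g · (η_i + √(1−v) ε_ig), with
η_i the linear predictor over standardized scores and covariates,
v = var(η), and ε equicorrelated (HCS) *on the sign-adjusted scale* — the
scale on which the model defines its covariance.  The √(1−v) noise scaling
makes each gene's total SD σ_g, so effects in `b_true` are on the
standardized-response scale the model reports.  Defaults: μ_g ~ U(6, 12)
log2 units, σ_g ~ U(0.25, 0.9), and ρ = 0.65, chosen so the confirmation
emulation reproduces the printed inferential scale (model SE ≈ 0.11
against the published 0.125, |t| ≈ 4–5).  The 8 marker transcripts are
independent Gaussians (U(7, 11) mean, SD 0.5); real marker–CTRA
correlation structure is not emulated, so marker adjustment in synthetic
runs is a pure machinery test.

What passing on synthetic data does *not* show: robustness to probe-level
array artifacts, to block-structured residual correlations (real interferon
genes correlate more among themselves than with inflammatory genes —
HCS is itself an approximation there), to informative missingness, or to
confounding between well-being and health covariates.

## Problem sizes used by the shipped experiments

Moment-fidelity checks use n = 2000–5000 subjects; effect recovery runs
100 replicates at the confirmation scale (52 genes, n = 122, b = −0.5 SD);
null calibration 500 replicates at the same scale; CFA calibration 300
replicates at n = 3000.  These sizes give Monte-Carlo standard errors
comfortably inside the asserted tolerances.
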