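# Methods notes

This note records the modelling assumptions, conventions and numerical
choices behind `clpnet`, and what the synthetic-data experiments do and do
not establish about real panel data.

## Estimation model

The CLPN is estimated node-wise: for each of the 14 symptoms, an
L1-penalized logistic regression of the dichotomized wave-2 item on all 14
dichotomized wave-1 items plus age (z-scored) and gender. Items are
declared "present" when the 0–3 Likert value exceeds 0; the threshold is
configurable (0/1/2) because the binary coding of ordinal symptom items is
a genuine modelling choice with no canonical answer, and edge odds ratios
are only interpretable relative to it. A gaussian family fallback (LASSO on
raw 0–3 scores, standardized predictors) is available for users who prefer
not to dichotomize; its exported "OR" column is then exp of a linear
coefficient and flagged as such.

Covariates are unpenalized by default: the adjustment exists to absorb
confounding, and shrinking it away would re-open the back door. The
intercept is never penalized.

**Penalty selection.** Fivefold stratified cross-validation on the binomial
deviance over a 15-point log-spaced lambda path (lambda_max set where the
first penalized predictor would enter; path floor 0.01·lambda_max). The
default selection rule is the **1-SE rule** (largest lambda within one
standard error of the CV minimum). We measured both rules on synthetic
panels: with 20 true edges of |β| ≥ 0.5 at n = 3000 the CV-minimum rule
recovers every true edge but carries precision ≈ 0.26 and selects ≈ 17% of
the 182 candidate cells on pure-null data, whereas the 1-SE rule keeps
sensitivity ≈ 1.0 with precision ≈ 0.86 and a null selection rate ≈ 0.2%.
For a sparse-network method whose edges are read substantively, the 1-SE
operating point is the defensible default; `lambda_rule="min"` remains
available and is the better choice when the goal is accuracy of a known
edge's coefficient (the 1-SE penalty shrinks a true log-OR of 1.0 to ≈ 0.7,
the CV-min fit sits within ±0.1–0.15).

**Solver.** A pathwise coordinate-descent solver (IRLS outer loop,
soft-thresholding inner loop, warm starts down the lambda path, per-feature
penalty factors so covariates are exactly unpenalized), numba-compiled
(`clpnet._cd`). Its objective parameterization matches glmnet with
`standardize=FALSE`; the test suite checks a fixed-lambda fit against
R glmnet with `penalty.factor` to ~0.03 absolute. Predictors are left
unstandardized because binary predictors already share scale. Working
weights are floored at 1e-5 and linear predictors capped at ±30 so
separation degrades gracefully into a penalty-bounded fit. A wave-2 target
with a single observed class (or fewer positives than folds) yields an
all-zero "degenerate" node fit with a logged warning; zero-variance wave-1
columns are retained as isolated nodes.

The estimator refuses datasets with n ≤ 36 (the total variable count across
both waves and covariates), below which the design is rank-deficient.

## Synthetic panel generator

The generator is built so that the estimation target is *well defined*:
wave-2 presence follows exactly the logistic model the estimator fits.

- **Wave 1.** A latent Gaussian with exchangeable correlation 0.4 within
  each symptom community and 0.2 between (enough shared variance to create
  the tangled inter-community structure seen in real comorbidity panels
  without making items collinear), thresholded at cutpoints placing
  ≈ 55/25/15/5% mass on values 0/1/2/3 — the right skew typical of
  community symptom screens. Configurable.
- **Wave 2.** Linear predictor = intercept + autoregressive term on the
  node's own dichotomized wave-1 item + cross-lagged terms + covariate
  terms; a standard-logistic noise draw is added and the latent value
  thresholded at 0 for presence, so P(present) = sigmoid(η) exactly, and at
  two higher offsets for severities 2 and 3. The offsets are derived from
  the wave-1 cutpoints so that, at the default intercept, the wave-2
  marginal reproduces the wave-1 marginal. We deliberately do *not*
  standardize the latent score per node before thresholding: any rescaling
  would multiply the true coefficients by an unknown factor and make
  "parameter recovery" meaningless. Autoregressive coefficients default to
  U(1.0, 1.5) — persistence dominates any single cross path, as in real
  panels.
- **Missingness and attrition.** Item cells are deleted MCAR with a fixed
  rate, or MAR with the cell's missingness log-odds shifted by
  `mar_strength` per SD of age. Whole-person wave-2 loss comes in two
  flavours: `dropout` (imputable) and `deceased` (wave-2 structurally
  absent, never imputed, excluded from estimation). Defaults for the cohort
  emulation scripts (sample sizes 1258/1118/548, attrition 8.4%/18.9%/1%,
  elderly mortality 15.7%, age distributions per cohort) mirror the study
  design this package operationalizes; the college cohort uses MAR-on-age
  missingness strong enough (3.5 log-odds/SD) for the screening stage to
  flag it, emulating a cohort whose missingness fails the MCAR test.

What passing recovery tests shows: the chain estimator-on-generator is
consistent and well calibrated. What it does not show: robustness to
measurement error, ordinal-threshold misspecification, unmodelled
confounding or time-varying effects — real items are not generated by a
logistic presence model, so real-data edge lists inherit all the usual
observational caveats.

## Missing-data machinery

`em_mvn` fits a multivariate-normal mean/covariance by EM with
missingness-pattern grouping (diagonal-covariance start so the likelihood
ascent property holds from iteration one; convergence when the relative
parameter change drops below 1e-6, cap 500 iterations, non-convergence is
an error carrying the last delta). Imputation fills missing item cells with
conditional means given the row's observed items and age, then rounds and
clips to 0–3 so downstream dichotomization is deterministic. Little's MCAR
test uses the EM estimates: Σ_j n_j (ȳ_j − μ̂_j)' Σ̂_j⁻¹ (ȳ_j − μ̂_j) over
patterns, df = Σ_j p_j − p, referred to chi-square. Age is appended as an
always-observed variable so covariate-dependent missingness is detectable;
with items only, MAR-on-age is indistinguishable from MCAR. Singular
pattern covariances are ridge-regularized with a warning. The items are
ordinal, not normal; simulation shows the test's type-I rate stays near the
nominal 5% regardless (3/100 at n = 400), and the normal EM conditional
mean is a sensible linear imputation for 0–3 items.

Deceased participants are excluded from both the MCAR test and imputation —
their wave-2 absence is a competing event, not a missing value. Attrition
checks use Welch t-tests (completers vs dropouts on baseline subscale
totals and age); Welch because equal variances buy nothing here.
Prevalence denominators: all scorable rows at wave 1; non-deceased at
wave 2; computed after imputation when the pipeline runs end-to-end
(configurable by scoring before imputation).

## Centrality and stability conventions

Centralities are computed on the coefficient (log-OR) scale, where an
absent edge contributes exactly 0 (on the OR scale it would contribute 1).
Autoregressive paths are excluded from every index. Bridge-EI counts both
incoming and outgoing cross-community coefficients by default; a switch
restricts it to outgoing, since the literature is not unanimous on
directionality.

Edge bootstrap: resample participants with replacement, refit the entire
network per replicate (fresh fold seed from the master seed), percentile
2.5/97.5 intervals (no BCa — the refit cost dwarfs the correction's
benefit at these n), and a per-edge "same side of OR = 1" frequency.
Edge-difference tests call two edges different when the central 95%
interval of their coefficient difference excludes 0, and report the
fraction of the network's other edges an edge significantly exceeds.

Case-drop bootstrap: drop grid 0.05–0.75 in steps of 0.05 (250 subsamples
per level by default; the analysis scripts and tests use coarser grids and
fewer subsamples to stay desk-scale — grid and count are arguments, not
constants). CS coefficient = largest drop fraction at which ≥ 95% of
subsamples correlate ≥ 0.7 (Pearson; Spearman available) with the
full-sample centralities; ≥ 0.25 is flagged reliable. Drop fraction 0
reuses the full-sample fit, making its correlation exactly 1 by
construction. Degenerate subsample centralities (zero variance) count as
below threshold. Subsamples at or below the minimum-n rule are marked
infeasible rather than fitted.

## Global metrics and comparison

Transitivity, APL and the small-world index are computed on the binarized,
symmetrized, loop-free cross-lagged graph — the setting where these indices
are classically defined; no weighted-directed variant is attempted. APL on
a disconnected graph averages over reachable pairs and reports the
unreachable-pair count. Baselines are means over 1000 seeded Erdős–Rényi
G(n, m) graphs with matching node and edge counts. The Jaccard index
compares directed signed edge sets: an edge matches only if source, target
and coefficient sign all agree; the same pair with opposite signs counts
twice in the union and never in the intersection.

## Problem sizes

The default test and acceptance runs use n = 2000–4000 for recovery and
null-calibration experiments (20 seeds), 100 seeds for MCAR calibration at
n = 400, 20 case-drop subsamples per level on a 4-level grid, and 500–1000
random graphs per baseline — sizes at which the Monte-Carlo error is small
relative to every margin asserted, while a full run stays in the minutes
range on one core.

## Known limitations

- Two waves only; no continuous-time or multi-wave dynamics.
- The binary outcome coding (>0) is a convention; edge ORs change under
  other thresholds, which is why the threshold is surfaced in the config.
- EM assumes joint normality of ordinal items; fine for point imputation,
  not for drawing multiply-imputed datasets (single imputation only).
- No permutation-based network comparison test; the Jaccard index describes
  overlap, it does not test a null.
- Bootstrap intervals inherit the usual post-selection caveat: LASSO
  shrinkage biases edge coefficients toward zero, so intervals are honest
  about variability, not about bias.
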