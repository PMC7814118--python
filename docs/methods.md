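# Statistical methods

This document records the model underlying `mbscore`, the numerical choices
made in the implementation, the default parameters and their rationale, and
the known limitations of the procedure.

## 1. The score

The Molecular-Based Score (MBS) is a risk-factor count. A fitted model is a
set of components, each a gene with an expression cutpoint and a risk
direction. For a patient with expression `x_g`:

- a `high_is_risk` component contributes 1 when `x_g > cutpoint`;
- a `low_is_risk` component contributes 1 when `x_g <= cutpoint`.

"High expression" is always *strictly above* the cutpoint; this convention is
applied consistently in cutpoint search, screening and scoring, so a value
exactly at the cutpoint is deterministically "low". The count maps to tiers:
0 → favourable, 1 → intermediate, ≥ 2 → adverse (`TierRule`, configurable).

## 2. Cutpoint determination

`optimal_cutpoint` considers midpoints between consecutive sorted unique
expression values. A candidate is admissible when both induced groups contain
at least `floor(min_group_frac · n)` patients (default `min_group_frac` =
0.10), which prevents degenerate splits driven by a handful of outliers.

The default metric is the Youden index of the high-expression indicator
against the observed death label, |sensitivity + specificity − 1|, taken as an
absolute value so that protective and hazardous genes are treated
symmetrically; `metric="concordance"` instead maximizes `max(C, 1−C)` of the
indicator against the censored survival outcome. Ties in the metric break
toward the more balanced split, then the smaller cutpoint — a deterministic
rule so results never depend on iteration order. The risk direction is the
side whose univariate Cox hazard ratio exceeds 1.

Preconditions: at least 20 patients, at least one event, a non-constant
marker. A marker whose metric is constant over all admissible candidates
raises `UninformativeMarkerError` rather than returning an arbitrary split.

**Caveat.** An outcome-optimized cutpoint is a minimum p-value over many
candidate thresholds. Any downstream test of the dichotomized gene on the
*same* data inherits that optimization and is anti-conservative (measured
here: a per-null-gene two-stage selection rate of ≈ 0.22 at n = 500 when the
cutpoint is optimized, versus ≈ 0.04 with a fixed median cutpoint). The
package implements the procedure as specified; consumers should interpret
screening p-values as ranking devices, not calibrated error rates.

## 3. Two-stage screening

`screen_genes` fits, per gene, a univariate Cox model on the high-expression
indicator. Genes with univariate Wald p ≤ α (default 0.05) proceed to one
multivariate Cox model each, adjusted for age (years, linear), gender (male
indicator) and IPSS-R as a binary contrast (low = {very-low, low} versus
non-low = {intermediate, high, very-high}). Patients missing any confounder
are dropped from stage two only (complete-case analysis; counts logged). A
gene is selected when its adjusted p ≤ α; its risk direction is the
expression state with adjusted HR > 1. Non-convergent fits mark the gene
failed and the screen continues.

Because both stages test the same indicator on the same cohort, passing the
adjusted stage conditional on the univariate stage has probability near
0.85 under the null, not α — so the two-stage selection rate for a null gene
is ≈ 0.04 (close to the single-stage α), and across a 37-gene panel a few
false positives are expected whenever no multiplicity correction is applied.
This is intrinsic to the specified procedure and is characterized, not
"fixed", by the implementation; the acceptance suite pins the measured rates.

## 4. Survival machinery

All estimators are implemented in `mbscore.stats` and cross-checked in the
test suite against independent oracles (exhaustive pairwise scans, closed
forms, and the `lifelines` package).

- **Kaplan–Meier**: product-limit estimate with Greenwood variance;
  pointwise intervals on the log(−log) scale so bounds stay in [0, 1]; the
  median is the smallest event time with S(t) ≤ 0.5, reported as "not
  reached" (`None`) otherwise. `survival_at` is the right-continuous step
  function; beyond the last observed time the last estimate is carried
  forward.
- **Log-rank**: k-sample statistic with the hypergeometric variance, χ² with
  k − 1 degrees of freedom (pseudo-inverse guards a singular covariance).
- **Cox regression**: Newton maximization of the partial likelihood with
  analytic gradient and Hessian and step-halving to guarantee ascent.
  Efron (default) and Breslow tie handling. Convergence requires both a
  small step and gradient norm < 1e-6. The linear predictor is max-shifted
  before exponentiation (the shift cancels within every per-event term).
  Coefficients exceeding |β| > 15 are flagged as monotone-likelihood
  (complete separation); for flagged coefficients a profile-likelihood lower
  confidence bound is available (`profile_lower_bound`), since the Wald
  interval is meaningless there. Categorical covariates in a DataFrame are
  reference-coded with a joint Wald test per source covariate.
- **Harrell's C**: usable pairs are (i, j) with `t_i < t_j` and i dead, or
  tied times with i dead and j censored; score ties count ½.
- **ROC AUC**: Mann–Whitney identity with midranks; the DeLong structural
  components give the variance and the paired z-test.
- **Proportional hazards check**: score test correlating scaled Schoenfeld
  residuals with a transform of event time (Kaplan–Meier transform by
  default; rank and identity available).

## 5. Internal validation

- **Tier survival bootstrap** (`bootstrap_km`): the whole cohort is resampled
  with replacement (unstratified, so tier sizes vary across replicates);
  each replicate recomputes per-tier KM survival at the horizons (defaults
  24 and 36 months). Intervals are **BCa**: bias correction `z0` from the
  fraction of replicates below the original estimate (ties counted half,
  clipped away from 0/1), acceleration from the leave-one-out jackknife.
  When both corrections vanish the interval reduces exactly to the
  percentile interval. Replicates lacking a tier are recorded as missing
  cells, not errors. The cross-tier Kruskal–Wallis p-value compares
  replicate distributions, which are resamples of one cohort rather than
  independent observations — it is descriptive, not inferential, and is
  labelled as such.
- **AUC comparison** (`compare_auc_bootstrap`): a paired bootstrap of
  Δ-AUC = AUC(score) − AUC(baseline) over subject resamples (default
  R = 10000); percentile interval; the p-value is the symmetric tail
  probability `2·min(P(Δ* ≤ 0), P(Δ* ≥ 0))` floored at 1/R. Single-class
  replicates are redrawn (capped at 10·R draws, counts logged).
- **Final multivariable model** (`final_multivariable`): one Cox model of
  intermediate-vs-favourable and adverse-vs-favourable indicators plus the
  confounders, ranked by Wald χ². A zero-event favourable tier — expected
  when the reference tier is small and low-risk — makes the tier
  coefficients monotone; they are flagged and reported with the profile
  lower bound.

## 6. Synthetic cohorts

`simulate_cohort` draws from the model the pipeline assumes: gene-wise
Gaussian log-expression (means ~ N(7, 1), unit variance); a subset of genes
carries a proportional-hazards effect through a threshold indicator at a
population quantile; survival is exponential with rate
`λ0 · exp(Σ β_g z_g + 0.03·(age − 67) + ipssr effect)`, censored by the
minimum of an independent exponential and a 120-month administrative horizon.

Defaults emulate a mid-size MDS cohort: five prognostic genes (ACLY, PANK1,
SLC25A5 protective-when-high i.e. low-is-risk; ANPEP, PKM high-is-risk) at
|log HR| = 0.8 with risky-state prevalence 0.28 each — chosen so the
favourable/intermediate/adverse split lands near 18/38/44% (counts are
Binomial(5, 0.28)); baseline hazard 0.003/month so the cohort median
survival lands near 50 months after covariate effects; censoring 0.006/month
plus the horizon, giving roughly 40% censoring; age truncated-normal (67, 10)
on [19, 87]; ~64% male; IPSS-R drawn from realistic category frequencies
with a monotone log-hazard effect (0, 0.2, 0.5, 0.8, 1.1). Optional healthy
donors shift about half the panel by ±0.8 and enter as censored,
non-modelled samples (`group_label = "healthy-donor"`), used only for
patient-vs-donor expression comparisons.

Everything derives from a single `numpy` `default_rng(seed)`;
`simulate_null_cohort` zeroes every effect for calibration studies. The
generator's scope is testing and calibration — it makes no claim to model
MDS biology beyond the statistical structure the pipeline exploits
(thresholded proportional hazards with Gaussian markers).

## 7. Reproducibility

Every resampling routine takes an explicit seed and derives one sub-seed per
replicate through `numpy.random.SeedSequence.spawn`, so results are
byte-identical across runs and independent of verbosity, thread count or
evaluation order. The CLI derives all stage seeds from a single top-level
seed; `run-all` records the seed and a configuration hash in its manifest.

## 8. Limitations

- **Selection inference is anti-conservative by construction** (sections 2
  and 3): no multiplicity correction across the panel, cutpoints optimized
  on outcome, and correlated screening stages. At n = 500 with 37 genes and
  5 true effects, the full pipeline recovers all true genes essentially
  always, but with a mean of ≈ 7 false positives when cutpoints are
  optimized (≈ 1.4 with fixed cutpoints). A score built from the inflated
  selection still separates risk strongly, but its tier shares shift toward
  adverse.
- Bootstrap validation is *internal*: it quantifies sampling variability of
  the fitted score on the same cohort, not transportability to external
  cohorts.
- The Cox stages assume proportional hazards; `check_ph` is provided but not
  run automatically inside the screen.
- The cross-tier Kruskal–Wallis p-values in the bootstrap summary are
  descriptive (section 5).
- Complete-case confounder adjustment assumes confounders are missing
  completely at random.
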