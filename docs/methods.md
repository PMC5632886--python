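# Methods

This note documents the statistical procedures implemented in
`xyloval`, the assumptions behind them, the defaults and why they were
chosen, and what the synthetic-data generators do and do not emulate.

## Setting

An enzymatic urinary d-xylose assay (xylose dehydrogenase, NADH read as
ΔA₃₄₀) is validated on automated clinical analyzers and compared against
the manual phloroglucinol colorimetric reference method. Urinary xylose
after an oral gaxilose dose measures intestinal lactase activity: a
patient whose 5-hour cumulated xylose total falls strictly below a
decision threshold is classified hypolactasic. The colorimetric method
is known to pick up a variable, positive, non-xylose background in some
urines (harsh acid/heat chemistry), so the enzymatic method reads
systematically lower and needs its own decision threshold.

## Assay response model

The photometric response is treated as linear in concentration,
`A = a·c + y₀`, with `a` in AU·dL/mg. Chemistry (incubation kinetics,
NADH extinction) is out of scope; only the response model matters.

**Single-point calibration.** With one calibrator (default 3.75 mg/dL)
and a water blank, concentration is linear interpolation:
`c = c_cal · (A − A_blank)/(A_cal − A_blank)`. Sub-blank responses give
negative concentrations and are returned as-is so callers can flag
them; silently clipping would hide blank drift.

**Linearity.** Ordinary least squares of response on nominal
concentration, all replicates entering individually (pre-averaging
would discard residual degrees of freedom). The reported dispersion,
`residual_sd`, is the residual standard deviation with n−2 degrees of
freedom, in absorbance units. This is deliberately the quantity the
detection-limit formulas consume: `3·s/a` and `10·s/a` only carry
concentration units when `s` is a response-scale dispersion divided by
a response-per-concentration slope. Published validation tables
sometimes label this quantity "CV"; the code does not, because it is
not a ratio. The intercept is likewise stored in absorbance units even
though such tables sometimes label it with concentration units.

**Reagent on-board stability.** Recovery of control materials over the
storage period is reported under two plain definitions — percent of the
day-1 reading and percent of the assigned control value — with a
configurable acceptance band (default 85–115%). Published recovery
figures for this assay match neither plain definition exactly (the
averaging window used is unstated), so both are emitted and neither is
privileged.

## Detection capability

* **LoB** = mean + 1.645·SD of a blank series (sample SD, n−1
  throughout the package). Separate blank solutions (water, buffer) are
  processed separately; the method LoB is the **maximum** across
  solutions — the conservative combination, since how to pool different
  blank matrices is not standardized.
* **LoD** = 3·s/a, **LoQ** = 10·s/a from the linearity fit. The LoD
  multiplier is 3, not the 3.3 of some guidelines, matching the
  validation convention this pipeline reproduces; LoQ/LoD = 10/3 holds
  identically for every fit.
* **LLoQ**: lowest nominal level whose CV% and |inaccuracy|% are both
  ≤ 20% — inclusive, so a level with exactly 20.0% error qualifies.
  When no level passes, the LLoQ is explicitly undetermined (`None`),
  never zero.
* **Selectivity**: a basal (analyte-free) urine passes when its mean
  signal is below 20% of the LLoQ; the method passes when every basal
  sample does.

## Precision decomposition

Within-run statistics are replicate mean/SD; CV% is relative to the
observed mean (the quantity actually measured), inaccuracy% relative to
the nominal (the quantity targeted). The day-to-day design — the same
material in duplicate across consecutive days — is a one-way
random-effects layout, decomposed by ANOVA: within-run variance is the
pooled within-day mean square; the between-run component is
max(0, (MS_between − MS_within)/n₀), clipped at zero because a variance
cannot be negative, with n₀ the effective replicates per day (the usual
unbalanced-design correction, equal to the common size when balanced).
Total CV is the root-sum-of-squares of the two components. A nested
dual-run-per-day model is deliberately not implemented; the design has
a single day factor.

**Carry-over** from an alternating high/low sequence:
`100·(mean(L after H) − mean(L after L)) / (mean(H) − mean(L after L))`,
i.e. the excess signal in a low sample that follows a high one,
expressed as a fraction of the high-low span. Negative values (noise)
are reported as-is. The parser only requires that the sequence contain
low measurements following highs and following lows, so both block
designs and repeated H→L couplets work.

## Method comparison

Let x be the reference (colorimetric) total and y the candidate
(enzymatic) total, both in mg.

**Deming regression** allows error on both axes. With error-variance
ratio λ = Var(e_y)/Var(e_x) (default 1; the true ratio is rarely known
and the results are insensitive near 1), the estimate minimizes
Σ wᵢ(yᵢ − β₀ − β₁xᵢ)²/(λ + β₁²). Unweighted: wᵢ = 1. Weighted: wᵢ =
1/d̂ᵢ², where d̂ᵢ is the average of the projected (fitted) x and y for
pair i — the standard choice when imprecision is proportional to level,
as CV-based validation implies. The weights depend on the fit, so the
weighted estimate is computed by iterated reweighting from the
unweighted solution (relative tolerance 1e-10, max 100 iterations;
non-convergence is flagged on the result rather than raised, so a
report still shows the last iterate). Confidence intervals use the
leave-one-out jackknife with a t quantile on n−2 degrees of freedom:
deterministic, conventional for Deming, and agnostic about the error
distribution. The fit satisfies axis-swap reciprocity: regressing x on
y with λ inverted returns slope 1/β₁ and intercept −β₀/β₁.

**Bland-Altman.** Differences are candidate − reference, so the
background inflation of the reference method appears as a negative
bias. Limits of agreement are bias ± 1.96·SD of the differences,
exactly. Percent mode divides each difference by the pair average
(×100): under a constant absolute bias, percent differences shrink in
magnitude as totals grow — the diagnostic signature distinguishing
constant from proportional bias.

**Pearson correlation** with a two-sided t-test p-value, via scipy.

## Cut-off transfer and concordance

Reference labels come from classifying x at the reference cut-off
(37.87 mg by default; strictly-below = hypolactasic, so a patient
exactly at the cut-off is normolactasic). The ROC curve of the
candidate totals against those labels uses thresholds at midpoints
between adjacent sorted unique scores plus ±∞ sentinels; a low
candidate total indicates disease, so sensitivity at threshold t is
P(y < t | hypolactasic). AUC is the trapezoidal area, identical to the
pairwise concordance statistic P(y_case < y_control) with ties counted
½. The transferred cut-off maximizes Youden's J = sensitivity +
specificity − 1, tie-broken toward the lower threshold; the rule is
recorded in the result so alternatives (closest-to-(0,1), cost-
weighted) can be added unambiguously. The AUC interval is DeLong's,
chosen over the bootstrap because it is deterministic.

**Cohen's kappa** from the 2×2 table of the two classifications:
κ = (p_o − p_e)/(1 − p_e), SE = √(p_o(1−p_o)/(n(1−p_e)²)),
CI = κ ± 1.96·SE. When both raters assign the same constant label,
p_e = 1 and κ is undefined; the result carries an explicit status
instead of raising, since a degenerate cohort is a data property, not a
programming error.

**Adjudication.** Discordant patients (reference and candidate labels
disagree at their respective cut-offs) are listed; externally justified
overrides (e.g. clinical follow-up) replace the *reference* label for
the listed patients only. The corrected table feeds the ROC and kappa
reruns, mirroring the before/after-adjudication reporting convention.

## Synthetic data

The generators produce every input the pipeline reads, with the
dependence structure the analyses assume:

* **Replicates**: value = nominal·(1 + run_effect + within_noise), run
  effects N(0, between_CV²) shared within a run, within noise
  N(0, within_CV²) per replicate, floored at 0. Multiplicative noise
  matches how validation expresses imprecision (CV, not SD).
* **Linearity**: response = a·c + y₀ + N(0, σ) in absorbance units,
  each level in configurable replicate.
* **Paired cohort**: per patient, a true excreted total T is drawn from
  a class-conditional log-normal (log-normal keeps totals positive;
  moment-matched to the configured mean/SD). The candidate method reads
  T·(1+e_b); the reference reads (T+B)·(1+e_a), with B a positive
  interfering background from a truncated Gaussian. Defaults: n = 224;
  prevalence 0.5 (the cohort is a referred-for-testing population, not
  a general one, so neither class should be rare); hypolactasic T mean
  10 SD 6 mg and normolactasic T mean 60 SD 25 mg (placing the classes
  on either side of the enzymatic decision region with realistic
  overlap); background mean 12.92, SD 5.26, truncated to
  1.93–22.64 mg (the published placebo-arm background distribution);
  5% measurement CV per method (within the reference method's stated
  0.48–6.45% error range, and of the order of the validated analyzer
  CVs). The truncated Gaussian is the minimal distribution consistent
  with a stated mean, SD and range.

All generators are pure functions of (config, seed) via
`numpy.random.default_rng`; identical inputs give identical tables.

What the generator does **not** emulate: matrix effects that correlate
background with the true total; inter-hospital storage and assay
differences; the heavier-than-Gaussian tails real percent differences
show at very low totals; any pharmacokinetics of gaxilose dosing.
Passing recovery tests therefore demonstrate estimator correctness
under the stated model, not field performance of the assay.

## Problem sizes and numerical choices

Monte-Carlo checks in the test suite use sizes chosen to make their
sampling error small relative to the asserted tolerances: 400–500
simulated datasets for variance-component recovery, jackknife CI
coverage (asserted ≥ 90% for a nominal 95% interval) and cohort bias
recovery (±0.5 mg on a mean over 500 cohorts of n = 224); 150 cohorts
per noise level for the cut-off consistency check. Ties in ROC scores
are handled by the ½-count convention everywhere; the Deming
reweighting starts from the unweighted fit; the between-run variance
component is clipped at zero; all sample SDs use n−1.

## Known limitations

* The weighted-Deming weight convention and the jackknife CI are *a*
  standard choice, not the only one; published intervals computed by
  other software (e.g. analytical CIs or different weights) will differ
  slightly even on identical data. Point estimates are the comparable
  quantities.
* The transferred cut-off is a midpoint between observed scores, so on
  small cohorts it carries sampling scatter of a few mg even without
  measurement noise.
* The kappa SE is the large-sample approximation; for very small n or
  extreme prevalence an exact or bootstrap interval would be
  preferable.
* LoD/LoQ are regression-based by design; hit-rate (probit) detection
  limits are out of scope.
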