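# Methods

This note documents the statistical model behind `micmeta`, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical corner cases.

## Data model

A *study summary* is one two-group comparison: per-arm sample size, mean
and SD of MIC-1/GDF15 expression, with the case arm being T2DM. SDs use
the n−1 convention throughout. Expression stays on whatever scale the
source platform used — the bundled collection spans raw means from ~0.1
to ~870 across microarray and immunoassay platforms — because the
standardized mean difference is invariant to per-study affine rescaling
(a·x+b, a>0), which is exactly what licenses pooling mRNA and protein
studies on one axis. That invariance is enforced by property tests, and
the synthetic generator deliberately randomizes per-dataset scale and
offset so that any scale leakage in downstream code fails the suite.

The inclusion rule retains studies with at least `min_total_samples`
(default 10) subjects in total. On the bundled table this keeps all 14
studies (the smallest has 5+5).

## Effect sizes

For one study, d = (x̄₁ − x̄₂)/s_p with the pooled within-group SD, and
Var(d) = N/(n₁n₂) + d²/(2N). Hedges' g multiplies d by J = 1 − 3/(4N−9)
and the variance by J². Direction is case minus control, so positive
values mean higher expression in T2DM.

Defaults: `hedges_g` is the library default because it is unbiased at
small n (arms of 5–12 occur in the bundled table). The bundled
collection's published pooling is reproduced to printed precision by
Cohen's d — the default of the era's meta-analysis software — so the
reproduction script requests `cohen_d` explicitly; at these sample sizes
the two flavors differ by less than 0.02 in the pooled estimate and
either is within the reproduction tolerance.

A zero pooled SD with equal means yields effect 0 with a warning; with
unequal means the SMD is undefined and raises.

Log odds ratios from 2×2 tables add a 0.5 continuity correction to all
four cells of tables containing a zero (affected tables only); the
variance is the Woolf sum of reciprocal cells.

## Pooling and heterogeneity

Fixed-effect pooling is inverse-variance weighting. Random effects is
DerSimonian–Laird: τ̂² = max(0, (Q−(k−1))/(Σw − Σw²/Σw)) from the
fixed-effect Q, then re-weighting by 1/(vᵢ+τ̂²). When τ̂² truncates to
zero the random-effects result equals the fixed-effect result exactly
(same weights, bit for bit), and the suite asserts this. CIs are Wald
intervals with z = 1.959964; no Hartung–Knapp or t correction, matching
conventional forest-plot software. The DL arithmetic is cross-checked in
the test suite against R's `metafor::rma(method="DL")` on identical
inputs to 1e-8.

Model screening: the random-effects model is used when Q's p-value is
below 0.05 **and/or** I² exceeds 50%. The disjunction ("or") is the
default because it is the conservative reading (heterogeneity flagged by
either signal triggers the wider intervals), and on the bundled data it
selects random effects everywhere the published analysis did; a strict
conjunction is available via `rule="and"`.

Subgroup pooling applies the same screening rule independently per
subgroup; a singleton subgroup returns the study's own effect and CI
rather than erroring. Leave-one-out re-pools k times under the same rule
and reports the min/max estimates as the stability summary.

## Publication bias

Begg's test standardizes each effect against the fixed-effect pooled
estimate, tᵢ = (θᵢ − θ̂)/√(vᵢ − 1/Σw), and rank-correlates tᵢ with vᵢ.
The fixed-effect θ̂ is used even when random effects was selected for
reporting — that is the original construction, and it is what reproduces
the published p-value on the bundled table (p = 0.511, which matches the
continuity-corrected z exactly). For k ≤ 8 the permutation null of the
Kendall score is enumerated exactly; otherwise the normal approximation
with tie-corrected variance and continuity correction is used. Identical
variances make the correlation undefined; the test then returns p = 1
with a degeneracy flag.

Two calibration facts are documented by the suite rather than assumed:

- The continuity-corrected p is discrete and mildly conservative. Under
  a canonical no-bias null (θᵢ ~ N(μ, vᵢ) with vᵢ independent of θᵢ),
  empirical rejection rates sit at or just below nominal at every α
  tested; exact uniformity of p is *not* attainable for a discrete
  statistic and is not asserted.
- When effects are SMDs, the d²/(2N) term couples each effect to its own
  variance estimate, which inflates Begg rejection somewhat under the
  no-bias null (≈8% at α = 5% in simulations at k = 14 with the
  generator's study sizes). This is a property of applying the test to
  SMDs, not of the implementation; the calibration simulation therefore
  draws effects directly from their sampling distribution.

## Diagnostic meta-analysis

Per-sample datasets are dichotomized with elevated expression as
test-positive. Three threshold rules exist:

- `youden` (default): the observed value maximizing sens + spec − 1,
  ties toward the lower threshold;
- a numeric fixed cut-point;
- `("quantile", q)` / `"median"`: the q-th quantile of the pooled
  observed values.

The in-sample Youden optimum *overfits* each dataset's operating point:
with ~30 samples per arm the maximized J is biased upward enough to push
the SROC AUC of null data to ≈0.6–0.7. The quantile rule does not adapt
to the labels and is unbiased (simulations: true AUC 0.80 recovered with
SD ≈ 0.014 over seeds at 30/arm, null data at 0.50). Recovery tests and
the SROC validation therefore use the median rule; Youden remains the
default for single-dataset descriptive use, where its optimism is the
familiar one of any optimal-cut-point analysis.

Sensitivity and specificity are pooled on the logit scale (0.5
correction at boundary proportions, per affected table only) under the
same model-screening rule as the SMD pooling, then back-transformed. The
diagnostic odds ratio is pooled on the log scale and exponentiated.

The summary ROC is Moses–Littenberg: D = a + bS fitted by unweighted
least squares over tables (0.5 correction for zero cells), back-solved
as TPR(FPR) = expit[(a + (1+b)·logit(FPR))/(1−b)], with AUC integrated
by the trapezoid rule over the full FPR ∈ [0,1] on a 2001-point grid
(endpoints fixed at (0,0) and (1,1); interior logits clipped at 1e−12).
|b| ≥ 1 leaves no valid curve and is returned flagged with NaN AUC. The
AUC interval is a parametric draw (2000 samples, fixed internal seed,
SVD factorization) from the normal approximation of (a, b); it is a
convenience summary, not an exact interval. The unweighted
Moses–Littenberg model was chosen over a bivariate random-effects ROC
model because it is fully desk-checkable from 2×2 tables; a bivariate
upgrade is out of scope.

## Covariate adjustment

Each dataset with age and BMI is fitted by OLS:
expression ~ intercept + group + age + BMI, covariates centered at the
per-dataset grand mean (not per-group means), so the intercept and the
group coefficient are directly the least-squares means. A multivariate
analysis of covariance with a single response reduces to exactly this
univariate ANCOVA. Constant covariates make the design rank-deficient
and raise an error naming the covariate (adjustment for a constant is
requested misuse, not a silent no-op); insufficient residual df also
raises.

The adjusted SMD standardizes the LS-mean difference by the ANCOVA
residual SD — the estimand consistent with the LS-mean standard errors —
with the same variance formula and Hedges correction as the unadjusted
SMD, pooled by DL random effects. When covariates are balanced and
outcome-irrelevant, residual SD equals the marginal SD in expectation
and adjusted and unadjusted pooled SMDs coincide (asserted to 0.02 in
the suite at k = 20, 50/arm).

## Synthetic generator

`GeneratorSpec` draws, per dataset: arm sizes uniform on `n_range`, a
true standardized shift θᵢ ~ N(`true_smd`, `tau_squared`), an expression
scale σ uniform on `scale_range` and an offset uniform on
`offset_range`. Summary-level generation draws means as N(μ, σ²/n) and
SDs from the scaled chi distribution σ·√(χ²ₙ₋₁/(n−1)), so simulated SDs
carry realistic variance-of-variance. Sample-level generation draws
expression = offset + σ·(θ·case + slopes·z-covariates + ε), ε ~ N(0,1):
the direct group effect in residual-SD units is exactly θ. Covariate
slopes are standardized (expression SDs per covariate SD) so confounding
scenarios are scale-free; `bmi_case_shift` (kg/m²) moves the case BMI
mean to create confounding.

Defaults mirror the bundled collection: k = 14, true SMD 0.54, τ² 0.15
(the DL estimate on the bundled table is 0.16), per-arm n from 5 to 180,
scales 0.1–200, offsets 0–500, age ~ N(54, 9²) years,
BMI ~ N(29, 4.5²) kg/m². Everything is deterministic given `seed`.

What the generator does **not** emulate: probe-level microarray noise,
quantile normalization, batch structure, non-normal expression
distributions, or missingness mechanisms other than
missing-completely-at-random cells in written series-matrix files.
Passing recovery tests therefore demonstrate correctness of the
estimators under the model the analysis assumes, not robustness to real
microarray artifacts.

## Problem sizes used in validation

Stochastic validation uses sizes chosen to keep Monte Carlo error well
below the asserted tolerances: DL bias is averaged over 20 replicates of
k = 50 studies; null calibration uses 1000 replicates at k = 14; SROC
recovery uses k = 20 datasets of 30/arm; ANCOVA recovery k = 20 of
50/arm. The Q-statistic uniformity check runs at per-arm sizes 50–100,
where the chi-square null of Q holds to simulation accuracy (at arms of
5 the SMD's sampling skewness visibly perturbs it).

## Known limitations

- Which probe represents MIC-1/GDF15 per platform, and whether sources
  log-transformed, is caller-supplied knowledge; the readers record
  values as-is.
- Group labels in series-matrix metadata are inferred by keyword only as
  a convenience and error on ambiguity; an explicit mapping file is the
  reliable path.
- The heterogeneity-screened two-step (test, then choose fixed/random)
  is the conventional workflow it reproduces, not the currently
  recommended one (always-random with Hartung–Knapp would be the modern
  choice).
- Begg's test has low power at k = 14, and applied to SMDs is slightly
  anti-conservative (see above); its non-significance is weak evidence
  of absence of bias.
- The Moses–Littenberg SROC ignores within-study sampling variability
  and between-study correlation of sensitivity and specificity.
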