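# Methods

## The choice model

A CCAF session yields, per subject and relative point level
x ∈ {−2, 0, +2}, a count k of alcohol choices out of n responded trials.
We model

    k ~ Binomial(n, p(x)),      p(x) = λ + (1 − 2λ) · logistic(β(x − α))

with `logistic(u) = 1/(1+e^(−u))`. The location α is the point of
subjective equality (PSE): the relative point level at which alcohol and
snack are equally likely to be chosen, in relative-point units. The
curve passes through 0.5 at x = α for any lapse rate λ, so "interpolating
the PSE from the fitted sigmoid" is reading off α — no delta-method step
is needed, which is why we fit in the location–slope parameterization
rather than intercept–slope (the two are related by α = −b₀/b₁, β = b₁).
A negative PSE means alcohol is preferred when point values are equal.
The slope β (logit units per relative-point unit) indexes cost
sensitivity: the flatter the curve, the less choice responds to the
point manipulation — behaviourally, a lower price elasticity.

The lapse rate λ (stimulus-independent error) exists in the simulator
(default 0) but is deliberately **not** part of the fitted model: the
fitted model is plain two-parameter binomial logistic regression, so
robustness to lapses can be probed in simulation without changing the
estimator.

### Fitting

The binomial log-likelihood is globally concave in (intercept, slope),
so the optimiser runs Newton–Raphson with analytic gradient and Hessian
in that parameterization, on a standardized predictor, with damped steps
that never decrease the objective; the estimates are converted back
algebraically. By likelihood invariance this yields exactly the MLE of
(α, β); tests verify agreement with an independently fitted statsmodels
binomial GLM to 1e−6 and optimality against a grid search at 1e−3
resolution. Convergence is declared when both score components fall
below 1e−8; the solver is vectorised over many datasets at once, which
is what makes the bootstrap and the Monte-Carlo calibration studies
cheap.

**Separation.** When observed proportions are all 0/1 in predictor order
(common for extreme subjects on 32 trials/level) the MLE is unbounded.
Such fits are flagged and re-run with a weak ridge penalty (1e−4 on the
standardized slope), which keeps estimates finite while leaving
well-behaved fits untouched. A fully saturated, flat dataset (e.g. every
trial alcohol at every level) has slope ≈ 0 and an unidentifiable
location; its PSE is treated as signed-infinite (always-alcohol ⇒ −∞),
which is exactly the information the preference classification needs.
Requesting a numeric PSE from such a fit raises with a diagnostic.

**Group fits pool counts** across subjects per level (binomial
weighting). Averaging per-subject proportions instead is available via
`pooling="mean_proportion"`; pooled counts are the default because the
group curve is then the MLE of a single-observer model on all trials.
Per-subject fits use only that subject's three (k, n) cells — no partial
pooling.

### Parametric bootstrap

CIs on (α, β) come from simulating k* ~ Binomial(n, p̂) at the observed
design points, refitting, and taking percentile intervals — 1000
resamples for 95% intervals by default, all refit in one vectorised
solve. Refits that fail even with the ridge fallback are dropped and
counted; more than 20% failures raises rather than returning a
misleading interval. Percentiles are nearest-rank when saturated draws
put mass at ±∞ (linear interpolation is undefined there), linear
otherwise. Coverage is checked empirically: over 300 simulated group
datasets at the reference size the 95% interval covers the true α
between 92% and 98% of the time (see `ccaf.studies` and
`scripts/acceptance.py`).

## Transforms and aggregation

Choice percentages per subject × level sit near ceiling (+2) and floor
(−2), so group modelling uses the adjusted ("empirical") logit
`ln((k+0.5)/(n−k+0.5))`, finite at 0 and n and exactly antisymmetric
under k ↔ n−k. A clamped raw logit is available behind a switch; the
+0.5 adjustment is the default because it needs no tuning constant.
Missing responses (the task's 3000 ms response window allows omissions)
earn no points and leave both k and n; a subject × level cell with no
responded trials is carried with a missing-data flag and excluded from
fits. Percentages are reported on the 0–100 scale; all modelling happens
on the logit scale.

## Split-plot group model

The group analysis is a balanced split-plot (mixed-design) ANOVA on the
adjusted logits: one row per subject × level, between-subject factors
group and sex (with their interaction), within-subject factor level.
Between-subject effects are tested on subject means against the
between-subject residual (df = 60 − 4 = 56); within-subject effects
(level and its interactions with every between term) on within-subject
deviations against the within-subject residual (df = 60·2 − 8 = 112).
Sums of squares are drop-one (Type III with sum-to-zero coding; on the
balanced factorial all types coincide), and partial η² uses each
effect's own error stratum. On complete balanced data this decomposition
is numerically identical to a subject-random-intercept mixed model;
tests verify equality of every F with both `pingouin.mixed_anova` and an
R `lmerTest` fit to 1e−6 (relative — lmer converges iteratively). We
chose the closed-form decomposition over an iterative mixed-model fit
because it is exact, fast enough to run thousands of null simulations,
and makes the error strata explicit. Unbalanced data are rejected with
the list of incomplete subjects rather than silently reweighted.

The AUDIT variant enters AUDIT as a centred between-subject covariate
additively with group and sex (no factor interactions; between error
df 56) and codes level as a linear trend (within error df 116),
matching the degrees-of-freedom structure of a severity-as-continuous
analysis. Degenerate variance (zero residual in a stratum) yields a
capped F with a flag instead of an exception.

Marginal mean percentages are back-transformed from per-subject mean
logits with t-intervals across subjects, then inverse-logit scaled to
0–100. This is a paired-design summary, not a model-based emmeans
computation; it is exact for between margins on balanced data.

**χ² tests** are Pearson tests of independence (scipy backend) with
expected counts from the margins. The preference-classification table
and its per-category 2×2 follow-ups use no continuity correction; the
dichotomised-AUDIT 2×2 uses the Yates correction by default — the two
defaults differ because each matches how the corresponding published
statistic was evidently computed, and the inconsistency is inherited,
not introduced. One caveat for users comparing against the published
per-category 2×2 values: the printed statistics for the
alcohol-preferring (6.97) and snack-preferring (5.95) categories appear
transposed relative to their own count tables (uncorrected values on
those counts are ≈5.96 and ≈6.94); this package reports whatever the
supplied table implies.

## The synthetic cohort

Each group's participants draw α ~ Normal(α_g, 0.5) and
β ~ Normal(β_g, 0.2) truncated at 0.05, with anchors (α, β) = (+0.9,
0.98) for light and (−0.1, 0.76) for heavy drinkers — the fitted
group-level values of the reference study. The SDs are a modelling
choice, not estimates: 0.5 in PSE units spreads individuals across the
three preference categories the way individual-level fits do in
practice, while keeping the pooled-curve flattening caused by location
heterogeneity below ~3% of β, so pooled group fits still recover the
anchors (checked to ±0.15 over 200 replicate cohorts). AUDIT and
drinks/week come from a bivariate normal (Gaussian copula) with
correlation 0.74, AUDIT rounded and clipped to [0, 40], drinks clipped
at 0, using each group's published moments. Sexes are balanced 15/15
per group; an optional additive male PSE shift exists but defaults to 0
(the sex effect in the reference data was marginal and its generative
mechanism is unidentified — in particular the published sex × level
interaction is not emulated). Randomness uses one root seed with named
substreams per subject (hash of the subject id), so simulations are
independent of iteration order.

What the generator does **not** emulate: sequential dependence between
trials (satiation, win-stay strategies), reaction times, missingness
mechanisms other than trial-independent omission, lapse asymmetry, and
any subject-level correlation between α and β or between α and AUDIT
within group. Passing calibration tests therefore show the *estimators*
are correct and calibrated under the stated model, not that real choice
data satisfy that model.

## Null and calibration studies

`ccaf.studies` fixes the study conditions: 30 subjects/group × 96
balanced trials. The type-I error study gives both groups identical
parameter distributions (α ~ N(0.4, 0.5), β ~ N(0.87, 0.2) — midpoints
of the two anchors — and whole-sample AUDIT/drinks moments) and runs the
full simulate → aggregate → logit → split-plot pipeline 1000 times; the
group test rejects at 4–6% at nominal 5%. The bootstrap coverage study
simulates pooled group counts from a single observer (α = 0.9,
β = 0.98), 300 replicates × 1000 resamples. These sizes make the whole
default test suite and the acceptance script each run in a few minutes
on one CPU.

## Numerical conventions

- Linear predictors are clipped at ±35 before the logistic (beyond
  which probabilities are 1 ulp from 0/1).
- Reward-tally ties default to "snack" with a tie flag (a seeded random
  rule is available); the deterministic default keeps pipeline runs
  reproducible since no tie rule is specified by the task description.
- Level-0 trials split evenly between (1,1) and (3,3) point pairs, and
  side counterbalancing is enforced within each level (slightly stronger
  than "counterbalanced across trials"), which removes any side × level
  confound from simulations.
- All derived seeds are reduced below 2³¹; identical configuration +
  seed gives byte-identical pipeline outputs.

## Known limitations

- The split-plot model requires complete balanced data; subjects with a
  missing level cell must be dropped explicitly.
- The per-category 2×2 χ² follow-ups and the published sex effects are
  reported but not validated against simulation (no generative mechanism
  is specified for them).
- Percentile (not BCa) bootstrap intervals; with 3 design points and
  strong separation the intervals for β can be wide and asymmetric.
- The covariate (AUDIT) psychometric fit pools subjects with the same
  score; it does not model within-score overdispersion.
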