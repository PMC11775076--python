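# ccaf

Analysis tools for the **Concurrent Choice Alcohol-Food (CCAF) task** — a
laboratory paradigm in which participants make repeated forced choices
between an alcohol image and a snack image, each worth 1 or 3 points
toward the corresponding end-of-session reward. The point difference
(*relative point level*: −2, 0, +2, alcohol minus snack) is the task's
cost manipulation; a session has 32 trials per level (96 total) with
left/right positions counterbalanced.

The package is aimed at researchers analysing (or piloting) concurrent
drug-vs-alternative choice experiments in light (LD) and heavy (HD)
social drinkers. It covers the full analysis chain:

- **Trial schedules** with exact level/side counterbalancing, and the
  end-of-session point tally rule (`ccaf.task_design`).
- **Synthetic cohorts**: per-subject logistic choice rules with group
  anchors, AUDIT scores correlated with weekly drinking, and seeded
  trial-by-trial simulation (`ccaf.cohort`) — because no trial-level
  dataset is publicly deposited, every downstream stage is testable
  against simulation.
- **Aggregation** to subject × level counts and the adjusted logit
  `ln((k+0.5)/(n−k+0.5))`, finite at 0% and 100% (`ccaf.preprocessing`).
- **Psychometric fits**: the choice probability is modelled as
  `P(alcohol | x) = 1 / (1 + exp(−β(x − α)))`, fitted by maximum
  likelihood on binomial counts. `α` is the **point of subjective
  equality (PSE)** — the relative point level at which alcohol and snack
  are equally likely to be chosen (negative PSE ⇒ alcohol preferred at
  equal points) — and `β` the slope in logit units per point, an index
  of cost sensitivity. Confidence intervals come from a parametric
  bootstrap (1000 resamples, percentile method) (`ccaf.psychometrics`).
- **Group statistics**: preference classification from individual PSE
  intervals, χ² contingency tests, and a balanced split-plot
  (mixed-design) ANOVA on logit-transformed choice percentages —
  numerically identical to a subject-random-intercept mixed model on
  complete balanced data (`ccaf.preference_stats`).
- **Calibration studies** (bootstrap coverage, type-I error, parameter
  recovery) in `ccaf.studies`, and an end-to-end pipeline with manifest
  and markdown report (`ccaf.pipeline`, `ccaf` CLI).

## Worked example

```python
import ccaf

schedule = ccaf.generate_schedule(n_per_level=32, seed=0)
profiles = ccaf.generate_cohort(ccaf.CohortConfig(seed=7))   # 2 x 30 subjects
trials   = ccaf.simulate_cohort_trials(profiles, schedule, seed=11)
summary  = ccaf.aggregate(trials)

for grp in ("HD", "LD"):
    res  = ccaf.fit_psychometric(summary[summary["group"] == grp])
    boot = res.parametric_bootstrap(n_boot=1000, seed=1)
    print(grp, f"PSE {res.alpha:+.2f} CI [{boot.alpha_ci[0]:.2f}, "
          f"{boot.alpha_ci[1]:.2f}]  slope {res.beta:.2f}")

anova = ccaf.split_plot_model(summary)
print(anova.effect("group")[["F", "df1", "df2", "p"]].to_dict())
```

prints

```
HD PSE +0.06 CI [-0.07, 0.18]  slope 0.66
LD PSE +0.85 CI [0.75, 0.95]  slope 0.94
{'F': 34.38355671569119, 'df1': 1, 'df2': 56.0, 'p': 2.529728660753514e-07}
```

The HD interval straddles 0 (no reliable preference at equal points)
while the LD group needs roughly one extra alcohol point before alcohol
and snack are valued equally; the split-plot group effect is tested on
(1, 56) degrees of freedom. The same chain runs from a shell:

```sh
ccaf run-all --seed 42 --outdir out/   # writes out/report.md + CSV/JSON stages
```

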