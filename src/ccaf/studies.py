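"""Monte-Carlo calibration and recovery studies for the choice pipeline.

These are the package's own validity checks, run at the reference study's
scale (2 groups x 30 subjects, 96 balanced trials per subject):

* ``bootstrap_coverage_study`` — does the 95% parametric-bootstrap
  interval for the PSE cover the true value ~95% of the time?
* ``type_i_error_study`` — does the split-plot between-group F test
  reject at its nominal rate when both groups share the same choice
  parameter distributions?
* ``parameter_recovery_study`` — do pooled group fits on simulated
  cohorts recover the group-level (alpha, beta) anchors?
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .task_design import generate_schedule
from .cohort import (CohortConfig, DEFAULT_GROUPS, NULL_GROUPS,
                     choice_probability, generate_cohort,
                     simulate_cohort_trials)
from .preprocessing import aggregate
from .psychometrics import PsychometricModel, fit_psychometric
from .preference_stats import split_plot_model


def _spawn_ints(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n, dtype=np.uint64) \
        % (2 ** 31)


def bootstrap_coverage_study(n_reps: int = 300, *, alpha: float = 0.9,
                             beta: float = 0.98, n_subjects: int = 30,
                             n_per_level: int = 32, n_boot: int = 1000,
                             level: float = 0.95, seed: int = 0) -> dict:
    """Empirical coverage of the percentile bootstrap CI for the PSE.

    Each replicate simulates pooled group counts at the three relative
    point levels from a single logistic observer (``n_subjects`` x
    ``n_per_level`` trials per level), fits, bootstraps, and records
    whether the interval covers the generating ``alpha``.  Returns the
    coverage as a percentage plus per-replicate bookkeeping.
    """
    x = np.array([-2.0, 0.0, 2.0])
    n = np.full(3, n_subjects * n_per_level)
    p_true = choice_probability(x, alpha, beta)
    seeds = _spawn_ints(seed, 2 * n_reps)
    covered = np.zeros(n_reps, bool)
    widths = np.zeros(n_reps)
    for i in range(n_reps):
        rng = np.random.default_rng(int(seeds[2 * i]))
        k = rng.binomial(n.astype(int), p_true)
        res = PsychometricModel(x, n, k).fit()
        boot = res.parametric_bootstrap(n_boot=n_boot, level=level,
                                        seed=int(seeds[2 * i + 1]))
        lo, hi = boot.alpha_ci
        covered[i] = lo <= alpha <= hi
        widths[i] = hi - lo
    return {"coverage_pct": 100.0 * covered.mean(), "n_reps": n_reps,
            "mean_ci_width": float(widths.mean()), "covered": covered}


def type_i_error_study(n_sims: int = 1000, *, n_per_group: int = 30,
                       n_per_level: int = 32, alpha_level: float = 0.05,
                       seed: int = 0) -> dict:
    """Rejection rate of the split-plot group test under the null.

    Both groups draw their psychometric parameters from identical
    distributions; each simulated cohort runs through the full
    aggregate -> adjusted logit -> split-plot pipeline and the
    between-group p-value is compared to ``alpha_level``.
    """
    schedule = generate_schedule(n_per_level, int(_spawn_ints(seed, 1)[0]))
    seeds = _spawn_ints(seed + 1, 2 * n_sims)
    pvals = np.zeros(n_sims)
    for i in range(n_sims):
        config = CohortConfig(n_per_group=n_per_group,
                              groups=dict(NULL_GROUPS),
                              seed=int(seeds[2 * i]))
        profiles = generate_cohort(config)
        trials = simulate_cohort_trials(profiles, schedule,
                                        int(seeds[2 * i + 1]))
        summary = aggregate(trials)
        res = split_plot_model(summary, between=("group", "sex"))
        pvals[i] = res.effect("group")["p"]
    return {"rejection_rate": float((pvals < alpha_level).mean()),
            "n_sims": n_sims, "pvals": pvals}


def parameter_recovery_study(n_reps: int = 200, *, n_per_group: int = 30,
                             n_per_level: int = 32, seed: int = 0
                             ) -> pd.DataFrame:
    """Pooled group-fit recovery of the (alpha, beta) group anchors.

    Returns one row per replicate x group with the fitted pooled alpha
    and beta; compare column means to the configured group means.
    """
    schedule = generate_schedule(n_per_level, int(_spawn_ints(seed, 1)[0]))
    seeds = _spawn_ints(seed + 1, 2 * n_reps)
    rows = []
    for i in range(n_reps):
        config = CohortConfig(n_per_group=n_per_group,
                              seed=int(seeds[2 * i]))
        profiles = generate_cohort(config)
        trials = simulate_cohort_trials(profiles, schedule,
                                        int(seeds[2 * i + 1]))
        summary = aggregate(trials)
        for grp in sorted(DEFAULT_GROUPS):
            res = fit_psychometric(summary[summary["group"] == grp])
            rows.append((i, grp, res.alpha, res.beta,
                         DEFAULT_GROUPS[grp].alpha_mean,
                         DEFAULT_GROUPS[grp].beta_mean))
    return pd.DataFrame(rows, columns=["rep", "group", "alpha_hat", "beta_hat",
                                       "alpha_true", "beta_true"])
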