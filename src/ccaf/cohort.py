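"""Synthetic cohorts of light (LD) and heavy (HD) social drinkers.

No raw choice data are deposited with the study this package models, so
everything downstream is exercised against simulated participants.  Each
participant carries a latent logistic choice rule: the probability of
choosing alcohol at relative point level ``x`` is

    P(alcohol | x) = lapse + (1 - 2*lapse) / (1 + exp(-beta * (x - alpha)))

where ``alpha`` is the point of subjective equality (PSE; the level at
which alcohol and snack are equally likely to be chosen — note the curve
passes through 0.5 at ``x = alpha`` for any lapse rate) and ``beta > 0``
is the slope in logit units per relative-point unit, an index of cost
sensitivity.  Group anchors for (alpha, beta) default to the fitted
group-level values of the reference study: LD (+0.9, 0.98), HD (-0.1,
0.76).  AUDIT scores and weekly drink counts are drawn from a Gaussian
copula honouring their reported correlation (r = 0.74), with AUDIT
rounded and clipped to its 0-40 range.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

from .task_design import TrialRecord, TrialSchedule

COHORT_COLUMNS = [
    "subject_id", "group", "sex", "audit", "drinks_per_week",
    "alpha", "beta", "lapse",
]


@dataclass(frozen=True)
class ParticipantProfile:
    """One (simulated) participant with latent psychometric parameters."""

    subject_id: str
    group: str                 # "LD" or "HD"
    sex: str                   # "female" or "male"
    audit: int                 # 0-40 severity score
    drinks_per_week: float
    alpha: float               # true PSE, relative-point units
    beta: float                # true slope, logit per relative-point unit
    lapse: float = 0.0         # stimulus-independent error rate

    def __post_init__(self) -> None:
        if not 0 <= self.audit <= 40:
            raise ValueError("audit must lie in [0, 40]")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if not 0 <= self.lapse < 0.5:
            raise ValueError("lapse must lie in [0, 0.5)")


@dataclass(frozen=True)
class GroupParams:
    """Population moments for one drinking group."""

    alpha_mean: float
    alpha_sd: float
    beta_mean: float
    beta_sd: float
    audit_mean: float
    audit_sd: float
    drinks_mean: float
    drinks_sd: float

    def __post_init__(self) -> None:
        for name in ("alpha_sd", "beta_sd", "audit_sd", "drinks_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


# Group anchors: (alpha, beta) from the reference group-level fits; AUDIT and
# drinks/week moments from the reference sample table.  The alpha/beta SDs are
# a modelling choice (individual heterogeneity around the group anchors); see
# docs/methods.md.
DEFAULT_GROUPS: dict[str, GroupParams] = {
    "LD": GroupParams(alpha_mean=0.9, alpha_sd=0.5, beta_mean=0.98, beta_sd=0.2,
                      audit_mean=7.57, audit_sd=3.91,
                      drinks_mean=5.1, drinks_sd=3.43),
    "HD": GroupParams(alpha_mean=-0.1, alpha_sd=0.5, beta_mean=0.76, beta_sd=0.2,
                      audit_mean=15.17, audit_sd=4.97,
                      drinks_mean=16.47, drinks_sd=3.74),
}

#: null-study groups: identical choice-parameter distributions (midpoints of
#: the two anchors) and whole-sample AUDIT/drinks moments in both groups.
NULL_GROUPS: dict[str, GroupParams] = {
    g: GroupParams(alpha_mean=0.4, alpha_sd=0.5, beta_mean=0.87, beta_sd=0.2,
                   audit_mean=11.37, audit_sd=5.86,
                   drinks_mean=10.78, drinks_sd=6.74)
    for g in ("LD", "HD")
}


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level simulation settings.

    ``sex_alpha_shift`` is an optional additive PSE shift applied to male
    participants (positive values move males toward snack preference); it
    defaults to 0 and no claim is made about its realistic size.
    """

    n_per_group: int = 30
    groups: dict[str, GroupParams] = field(
        default_factory=lambda: dict(DEFAULT_GROUPS))
    audit_drinks_corr: float = 0.74
    lapse: float = 0.0
    sex_alpha_shift: float = 0.0
    beta_floor: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if not -1 < self.audit_drinks_corr < 1:
            raise ValueError("audit_drinks_corr must lie in (-1, 1)")
        if not 0 <= self.lapse < 0.5:
            raise ValueError("lapse must lie in [0, 0.5)")


def choice_probability(x, alpha: float, beta: float, lapse: float = 0.0):
    """Probability of choosing alcohol at relative point level ``x``.

    Strictly increasing in ``x`` for ``beta > 0`` and ``lapse < 0.5``;
    equals 0.5 at ``x = alpha`` for any lapse.
    """
    if not 0 <= lapse < 0.5:
        raise ValueError("lapse must lie in [0, 0.5)")
    return lapse + (1.0 - 2.0 * lapse) * expit(beta * (np.asarray(x, float) - alpha))


def _subject_seed_seq(root_seed: int, subject_id: str) -> np.random.SeedSequence:
    # named substream: stable under subject iteration order
    return np.random.SeedSequence([int(root_seed), zlib.crc32(subject_id.encode())])


def _draw_truncated_normal(rng, mean, sd, lower, size):
    if sd == 0:
        return np.full(size, float(mean))
    a = (lower - mean) / sd
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(config: CohortConfig) -> list[ParticipantProfile]:
    """Draw a cohort of participants, sexes balanced within each group.

    AUDIT and drinks/week come from a bivariate normal with the configured
    correlation; AUDIT is then rounded and clipped to [0, 40] and drinks
    clipped at 0 (Gaussian copula with marginal rounding/clipping).  The
    slope ``beta`` is truncated-normal above ``beta_floor``.  Reproducible
    under ``config.seed``; each group uses a named substream so results do
    not depend on group iteration order.
    """
    profiles: list[ParticipantProfile] = []
    for group in sorted(config.groups):
        gp = config.groups[group]
        n = config.n_per_group
        rng = np.random.default_rng(_subject_seed_seq(config.seed, f"group:{group}"))

        n_female = n // 2 + (n % 2)
        sexes = ["female"] * n_female + ["male"] * (n - n_female)

        alpha = rng.normal(gp.alpha_mean, gp.alpha_sd, size=n)
        beta = _draw_truncated_normal(rng, gp.beta_mean, gp.beta_sd,
                                      config.beta_floor, n)
        z = rng.multivariate_normal(
            [0.0, 0.0],
            [[1.0, config.audit_drinks_corr], [config.audit_drinks_corr, 1.0]],
            size=n,
        )
        audit = np.clip(np.rint(gp.audit_mean + gp.audit_sd * z[:, 0]), 0, 40)
        drinks = np.clip(gp.drinks_mean + gp.drinks_sd * z[:, 1], 0.0, None)

        for i in range(n):
            a = alpha[i] + (config.sex_alpha_shift if sexes[i] == "male" else 0.0)
            profiles.append(ParticipantProfile(
                subject_id=f"{group}{i + 1:03d}",
                group=group,
                sex=sexes[i],
                audit=int(audit[i]),
                drinks_per_week=float(drinks[i]),
                alpha=float(a),
                beta=float(beta[i]),
                lapse=config.lapse,
            ))
    return profiles


def simulate_choices(
    profile: ParticipantProfile,
    schedule: TrialSchedule,
    seed: int | np.random.SeedSequence | None = None,
    p_missing: float = 0.0,
) -> list[TrialRecord]:
    """Simulate one participant's session on a schedule.

    Each trial is an independent Bernoulli draw with success probability
    ``choice_probability(level, alpha, beta, lapse)``; an optional
    ``p_missing`` fraction of trials is marked unanswered.  Same seed,
    same output.
    """
    if len(schedule.trials) == 0:
        raise ValueError("schedule is empty")
    rng = np.random.default_rng(seed)
    levels = np.array([t.relative_point_level for t in schedule.trials], float)
    p = choice_probability(levels, profile.alpha, profile.beta, profile.lapse)
    alcohol = rng.random(len(levels)) < p
    missing = (rng.random(len(levels)) < p_missing) if p_missing > 0 else \
        np.zeros(len(levels), bool)
    out = []
    for t, a, m in zip(schedule.trials, alcohol, missing):
        choice = "missing" if m else ("alcohol" if a else "snack")
        out.append(t.with_choice(choice))
    return out


def simulate_cohort_trials(
    profiles: list[ParticipantProfile],
    schedule: TrialSchedule,
    seed: int,
    p_missing: float = 0.0,
) -> pd.DataFrame:
    """Simulate every participant on the same schedule; tidy trial table.

    Per-subject named RNG substreams keyed on (seed, subject_id) make the
    result independent of the iteration order of ``profiles``.
    """
    frames = []
    for prof in profiles:
        trials = simulate_choices(
            prof, schedule, seed=_subject_seed_seq(seed, prof.subject_id),
            p_missing=p_missing)
        frames.append(pd.DataFrame({
            "subject_id": prof.subject_id,
            "group": prof.group,
            "sex": prof.sex,
            "audit": prof.audit,
            "drinks_per_week": prof.drinks_per_week,
            "trial_index": [t.trial_index for t in trials],
            "relative_point_level": [t.relative_point_level for t in trials],
            "alcohol_points": [t.alcohol_points for t in trials],
            "snack_points": [t.snack_points for t in trials],
            "alcohol_side": [t.alcohol_side for t in trials],
            "choice": [t.choice for t in trials],
        }))
    return pd.concat(frames, ignore_index=True)


def cohort_to_frame(profiles: list[ParticipantProfile]) -> pd.DataFrame:
    return pd.DataFrame([asdict(p) for p in profiles], columns=COHORT_COLUMNS)


def cohort_from_frame(frame: pd.DataFrame) -> list[ParticipantProfile]:
    return [
        ParticipantProfile(
            subject_id=str(r.subject_id), group=str(r.group), sex=str(r.sex),
            audit=int(r.audit), drinks_per_week=float(r.drinks_per_week),
            alpha=float(r.alpha), beta=float(r.beta), lapse=float(r.lapse),
        )
        for r in frame.itertuples(index=False)
    ]
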