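"""Trial schedule construction and end-of-session reward tally for the
concurrent choice alcohol-food (CCAF) task.

Each trial offers an alcohol image and a snack image, each worth 1 or 3
points toward the corresponding reward.  The *relative point level*
(alcohol points minus snack points) takes values -2, 0 or +2 and is the
cost manipulation of the task.  A session has ``n_per_level`` trials at
each level (32 in the reference design, 96 trials total), with the
left/right position of the alcohol image counterbalanced within each
level.  At the end of the session the reward category with the larger
accumulated point total is delivered.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

LEVELS = (-2, 0, 2)

SCHEDULE_COLUMNS = [
    "trial_index",
    "relative_point_level",
    "alcohol_points",
    "snack_points",
    "alcohol_side",
]

#: point pair (alcohol, snack) forced by each non-zero level
_LEVEL_POINTS = {-2: (1, 3), 2: (3, 1)}


@dataclass(frozen=True)
class TrialRecord:
    """A single CCAF trial.

    ``choice`` is ``None`` for a scheduled (not yet run) trial, otherwise
    one of ``"alcohol"``, ``"snack"`` or ``"missing"`` (no response inside
    the response window).
    """

    trial_index: int
    relative_point_level: int
    alcohol_points: int
    snack_points: int
    alcohol_side: str
    choice: str | None = None

    def __post_init__(self) -> None:
        if self.relative_point_level not in LEVELS:
            raise ValueError(
                f"relative_point_level must be one of {LEVELS}, "
                f"got {self.relative_point_level}"
            )
        if self.alcohol_points not in (1, 3) or self.snack_points not in (1, 3):
            raise ValueError("point values must be 1 or 3")
        if self.alcohol_points - self.snack_points != self.relative_point_level:
            raise ValueError(
                "relative_point_level must equal alcohol_points - snack_points"
            )
        if self.alcohol_side not in ("left", "right"):
            raise ValueError("alcohol_side must be 'left' or 'right'")
        if self.choice not in (None, "alcohol", "snack", "missing"):
            raise ValueError("choice must be alcohol/snack/missing or None")

    def with_choice(self, choice: str) -> "TrialRecord":
        return replace(self, choice=choice)


@dataclass
class TrialSchedule:
    """An ordered session of trials with exact level and side balance."""

    trials: list[TrialRecord]
    n_per_level: int

    def __len__(self) -> int:
        return len(self.trials)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (t.trial_index, t.relative_point_level, t.alcohol_points,
             t.snack_points, t.alcohol_side)
            for t in self.trials
        ]
        return pd.DataFrame(rows, columns=SCHEDULE_COLUMNS)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TrialSchedule":
        trials = [
            TrialRecord(
                trial_index=int(r.trial_index),
                relative_point_level=int(r.relative_point_level),
                alcohol_points=int(r.alcohol_points),
                snack_points=int(r.snack_points),
                alcohol_side=str(r.alcohol_side),
            )
            for r in frame.itertuples(index=False)
        ]
        levels = frame["relative_point_level"].value_counts()
        n_per_level = int(levels.iloc[0])
        return cls(trials=trials, n_per_level=n_per_level)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "TrialSchedule":
        return cls.from_frame(pd.read_csv(path))


def generate_schedule(n_per_level: int, seed: int) -> TrialSchedule:
    """Build a seeded random ordering of the fixed trial multiset.

    The multiset of (level, points, side) combinations is the same for
    every seed: ``n_per_level`` trials per level, half with the alcohol
    image on the left within each level, and level-0 trials split evenly
    between (1,1) and (3,3) point pairs.  Only the presentation order is
    randomised.

    Parameters
    ----------
    n_per_level : int
        Trials per relative point level; must be even and >= 2 so the
        side and point-pair counterbalancing is exact.
    seed : int
        Seed for the order permutation; identical seeds give identical
        schedules.
    """
    if n_per_level < 2 or n_per_level % 2 != 0:
        raise ValueError(
            f"n_per_level must be an even integer >= 2, got {n_per_level}"
        )
    half = n_per_level // 2
    proto: list[tuple[int, int, int, str]] = []
    for level in LEVELS:
        if level == 0:
            pairs = [(1, 1)] * half + [(3, 3)] * half
        else:
            pairs = [_LEVEL_POINTS[level]] * n_per_level
        # alternating sides give an exact half/half split within the level
        for i, (a, s) in enumerate(pairs):
            side = "left" if i % 2 == 0 else "right"
            proto.append((level, a, s, side))

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(proto))
    trials = [
        TrialRecord(
            trial_index=idx + 1,
            relative_point_level=proto[j][0],
            alcohol_points=proto[j][1],
            snack_points=proto[j][2],
            alcohol_side=proto[j][3],
        )
        for idx, j in enumerate(order)
    ]
    return TrialSchedule(trials=trials, n_per_level=n_per_level)


@dataclass(frozen=True)
class RewardTally:
    """Outcome of the end-of-session point count."""

    winner: str  # "alcohol" or "snack"
    alcohol_points: int
    snack_points: int
    tie: bool = False


def tally_reward(
    trials: list[TrialRecord],
    tie_break: str = "snack",
    seed: int | None = None,
) -> RewardTally:
    """Sum the points earned for each chosen option and pick the reward.

    Missing-response trials earn no points.  Exact ties are resolved by
    ``tie_break``: the default deterministic ``"snack"`` rule, or
    ``"random"`` (seeded) — either way the result carries ``tie=True``.
    """
    alcohol = snack = 0
    any_response = False
    for t in trials:
        if t.choice == "alcohol":
            alcohol += t.alcohol_points
            any_response = True
        elif t.choice == "snack":
            snack += t.snack_points
            any_response = True
        elif t.choice is None:
            raise ValueError("tally_reward requires completed trials")
    if not any_response:
        raise ValueError("all choices missing: no points to tally")
    if alcohol != snack:
        winner = "alcohol" if alcohol > snack else "snack"
        return RewardTally(winner, alcohol, snack, tie=False)
    if tie_break == "snack":
        winner = "snack"
    elif tie_break == "random":
        winner = ["alcohol", "snack"][np.random.default_rng(seed).integers(2)]
    else:
        raise ValueError(f"unknown tie_break rule {tie_break!r}")
    return RewardTally(winner, alcohol, snack, tie=True)
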