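"""Aggregation of trial-level choices and the adjusted logit transform.

Percent alcohol choice per subject x relative point level shows strong
ceiling/floor effects (near 100% at +2, near 0% at -2), so group-level
modelling is done on the logit scale.  A plain logit is undefined at 0%
and 100%; the default transform is the adjusted ("empirical") logit

    elogit(k, n) = ln((k + 0.5) / (n - k + 0.5)),

finite for all 0 <= k <= n and exactly antisymmetric under k <-> n - k.
A clamped raw logit is available as an alternative.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

SUMMARY_COLUMNS = [
    "subject_id", "group", "sex", "audit", "drinks_per_week",
    "relative_point_level", "k", "n", "pct", "elogit", "no_data",
]

#: subject-level covariates carried through aggregation when present
_CARRY = ["group", "sex", "audit", "drinks_per_week"]


def empirical_logit(k, n, method: str = "adjusted", clamp: float = 0.01):
    """Logit of a binomial proportion, finite at 0 and 1.

    ``method="adjusted"`` (default) adds 0.5 to both count cells;
    ``method="clamped"`` clamps k/n into [clamp, 1 - clamp] before a raw
    logit.  Vectorised over array inputs.
    """
    k = np.asarray(k, float)
    n = np.asarray(n, float)
    if np.any(n < 1):
        raise ValueError("n must be >= 1")
    if np.any((k < 0) | (k > n)):
        raise ValueError("k must lie in [0, n]")
    if method == "adjusted":
        out = np.log((k + 0.5) / (n - k + 0.5))
    elif method == "clamped":
        p = np.clip(k / n, clamp, 1.0 - clamp)
        out = np.log(p / (1.0 - p))
    else:
        raise ValueError(f"unknown logit method {method!r}")
    return out if out.ndim else float(out)


def aggregate(trials: pd.DataFrame, logit_method: str = "adjusted") -> pd.DataFrame:
    """Collapse a tidy trial table to subject x level choice summaries.

    ``k`` counts alcohol choices, ``n`` counts responded (non-missing)
    trials; missing-response trials drop out of both.  A subject x level
    cell where every trial is missing is kept with ``no_data=True`` and an
    undefined (NaN) percentage/logit so downstream fits can exclude it.
    """
    required = {"subject_id", "relative_point_level", "choice"}
    if not required.issubset(trials.columns):
        raise ValueError(f"trial table must have columns {sorted(required)}")
    bad = set(trials["relative_point_level"].unique()) - {-2, 0, 2}
    if bad:
        raise ValueError(f"unexpected relative point levels: {sorted(bad)}")

    carry = [c for c in _CARRY if c in trials.columns]
    flagged = trials.assign(
        _alcohol=(trials["choice"] == "alcohol").astype(int),
        _responded=(trials["choice"] != "missing").astype(int),
    )
    out = (
        flagged.groupby(["subject_id", "relative_point_level"], sort=True)[
            ["_alcohol", "_responded"]]
        .sum()
        .reset_index()
        .rename(columns={"_alcohol": "k", "_responded": "n"})
    )
    if carry:
        meta = trials.groupby("subject_id", sort=True)[carry].first().reset_index()
        out = out.merge(meta, on="subject_id", how="left")

    out["no_data"] = out["n"] == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        out["pct"] = np.where(out["no_data"], np.nan, 100.0 * out["k"] / out["n"])
    out["elogit"] = np.nan
    ok = ~out["no_data"]
    out.loc[ok, "elogit"] = empirical_logit(
        out.loc[ok, "k"].to_numpy(), out.loc[ok, "n"].to_numpy(),
        method=logit_method)
    cols = ["subject_id", *carry, "relative_point_level",
            "k", "n", "pct", "elogit", "no_data"]
    return out[cols]
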