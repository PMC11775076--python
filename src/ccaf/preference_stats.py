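"""Preference classification, contingency tests and split-plot group model.

Individual preference is read off the 95% parametric-bootstrap interval
of the subject's PSE: entirely below 0 means alcohol is preferred at
equal point values ("alcohol"), entirely above 0 "snack", straddling 0
"neither".  Group frequency differences in those categories (and in
dichotomised AUDIT scores) are compared with Pearson chi-square tests.

The group analysis of logit-transformed choice percentages is a balanced
split-plot (mixed-design) decomposition: between-subject effects (group,
sex, their interaction — or a continuous AUDIT covariate) are tested on
subject means against the between-subject residual; within-subject
effects (relative point level and its interactions with every
between-subject term) are tested on within-subject deviations against
the within-subject residual.  On complete balanced data this is
numerically identical to a subject-random-intercept mixed model, without
an iterative fit.  Each effect reports F, its two degrees of freedom, a
two-sided p-value and partial eta squared computed against its own error
stratum.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "classify_preference", "classify_cohort", "preference_table",
    "chi2_independence", "ContingencyResult",
    "SplitPlotModel", "SplitPlotResults", "split_plot_model",
    "backtransform_means",
]

_F_CAP = 1e12


# -- preference classification -------------------------------------------

def classify_preference(pse_ci: tuple[float, float]) -> str:
    """Label a subject from the 95% CI of their PSE.

    A PSE below zero means alcohol is chosen when point values are equal,
    i.e. an alcohol preference.
    """
    lo, hi = pse_ci
    if lo > hi:
        raise ValueError(f"malformed interval ({lo}, {hi})")
    if hi < 0:
        return "alcohol"
    if lo > 0:
        return "snack"
    return "neither"


def classify_cohort(subject_cis: dict[str, tuple[float, float]]) -> pd.DataFrame:
    """Classify every subject; returns subject_id, category, ci_lo, ci_hi."""
    rows = [
        (sid, classify_preference(ci), ci[0], ci[1])
        for sid, ci in subject_cis.items()
    ]
    return pd.DataFrame(rows, columns=["subject_id", "category", "ci_lo", "ci_hi"])


def preference_table(classification: pd.DataFrame,
                     groups: pd.Series | pd.DataFrame) -> pd.DataFrame:
    """Group x category count table (categories alcohol, snack, neither)."""
    df = classification.copy()
    if isinstance(groups, pd.DataFrame):
        groups = groups.set_index("subject_id")["group"]
    df["group"] = df["subject_id"].map(groups)
    tab = pd.crosstab(df["group"], df["category"])
    return tab.reindex(columns=["alcohol", "snack", "neither"], fill_value=0)


# -- chi-square ----------------------------------------------------------

@dataclass(frozen=True)
class ContingencyResult:
    observed: np.ndarray
    expected: np.ndarray
    chi2: float
    df: int
    p: float
    correction: str  # "none" or "yates"


def chi2_independence(table, correction: str = "none") -> ContingencyResult:
    """Pearson chi-square test of independence on an r x c count table.

    ``correction="yates"`` applies the continuity correction (2x2 tables
    only).  Expected counts come from the margins in the usual way.
    """
    obs = np.asarray(table, float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    if np.any(obs.sum(0) == 0) or np.any(obs.sum(1) == 0):
        raise ValueError("zero row or column margin")
    if correction not in ("none", "yates"):
        raise ValueError(f"unknown correction {correction!r}")
    if correction == "yates" and obs.shape != (2, 2):
        raise ValueError("Yates correction applies to 2x2 tables only")
    chi2, p, df, expected = stats.chi2_contingency(
        obs, correction=(correction == "yates"))
    return ContingencyResult(observed=obs, expected=expected,
                             chi2=float(chi2), df=int(df), p=float(p),
                             correction=correction)


# -- split-plot ANOVA -----------------------------------------------------

def _sum_code(values: pd.Series) -> tuple[np.ndarray, list[str]]:
    """Effect (sum-to-zero) coding; last sorted level is the reference."""
    levels = sorted(values.unique())
    if len(levels) < 2:
        raise ValueError(f"factor {values.name!r} has a single level")
    cols = np.zeros((len(values), len(levels) - 1))
    arr = values.to_numpy()
    for j, lev in enumerate(levels[:-1]):
        cols[arr == lev, j] = 1.0
    cols[arr == levels[-1], :] = -1.0
    return cols, levels


def _drop_one_anova(y: np.ndarray, blocks: dict[str, np.ndarray],
                    intercept: bool):
    """Type-III style sums of squares: SS(effect) = SSE(without) - SSE(full)."""
    def sse(mats):
        if not mats:
            return float(y @ y), 0
        X = np.column_stack(mats)
        coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ coef
        return float(r @ r), int(rank)

    base = [np.ones((len(y), 1))] if intercept else []
    sse_full, rank_full = sse(base + list(blocks.values()))
    out = {}
    for name in blocks:
        reduced = base + [m for nm, m in blocks.items() if nm != name]
        sse_red, _ = sse(reduced)
        out[name] = max(sse_red - sse_full, 0.0)
    df_err = len(y) - rank_full
    return out, sse_full, df_err


class SplitPlotModel:
    """Split-plot model for subject x level logit choice data.

    Parameters
    ----------
    data : summary table with one row per subject x relative point level,
        carrying the dependent variable and the between-subject columns.
    between : categorical between-subject factors; all their interactions
        are included (e.g. ``("group", "sex")`` gives group, sex and
        group:sex).
    covariates : continuous between-subject predictors (centred), entered
        additively (e.g. ``("audit",)``).
    level_coding : "categorical" (sum-coded, df = levels-1) or "linear"
        (single centred linear trend, df = 1).
    dv : dependent-variable column, default the adjusted logit.
    """

    def __init__(self, data: pd.DataFrame, *, between=("group", "sex"),
                 covariates=(), within="relative_point_level",
                 level_coding="categorical", dv="elogit",
                 subject="subject_id", factor_interactions=True):
        if level_coding not in ("categorical", "linear"):
            raise ValueError(f"unknown level_coding {level_coding!r}")
        self.between = tuple(between)
        self.factor_interactions = factor_interactions
        self.covariates = tuple(covariates)
        self.level_coding = level_coding
        self.dv = dv
        self.within = within
        self.subject = subject

        df = data.copy()
        if df[dv].isna().any():
            bad = df.loc[df[dv].isna(), subject].unique().tolist()
            raise ValueError(
                f"non-finite {dv} values; drop incomplete subjects {bad}")
        wide = df.pivot(index=subject, columns=within, values=dv)
        if wide.isna().any().any():
            bad = wide.index[wide.isna().any(axis=1)].tolist()
            raise ValueError(
                "unbalanced design: every subject needs every level; "
                f"drop incomplete subjects {bad}")
        self.levels = [float(c) for c in wide.columns]
        self.Y = wide.to_numpy(float)
        meta_cols = list(self.between) + list(self.covariates)
        self.meta = (df.groupby(subject, sort=True)[meta_cols].first()
                     .loc[wide.index])

    def fit(self) -> "SplitPlotResults":
        S, L = self.Y.shape
        ybar = self.Y.mean(axis=1)

        # between-subject blocks: sum-coded factors, all factor interactions,
        # centred covariates
        fac_codes = {}
        for f in self.between:
            fac_codes[f], _ = _sum_code(self.meta[f])
        b_blocks: dict[str, np.ndarray] = {}
        max_order = len(self.between) if self.factor_interactions else 1
        for order in range(1, max_order + 1):
            for combo in itertools.combinations(self.between, order):
                mats = [fac_codes[f] for f in combo]
                prod = mats[0]
                for m in mats[1:]:
                    prod = np.einsum("ij,ik->ijk", prod, m).reshape(S, -1)
                b_blocks[":".join(combo)] = prod
        for c in self.covariates:
            v = self.meta[c].to_numpy(float)
            if np.ptp(v) == 0:
                raise ValueError(f"covariate {c!r} is constant")
            b_blocks[c] = (v - v.mean())[:, None]

        ss_b, sse_b, df_b_err = _drop_one_anova(ybar, b_blocks, intercept=True)
        # scale subject-mean SS to the per-observation scale
        ss_b = {k: v * L for k, v in ss_b.items()}
        sse_b *= L

        # within-subject stratum: deviations from subject means
        D = (self.Y - ybar[:, None]).ravel()
        if self.level_coding == "categorical":
            lev_series = pd.Series(
                np.tile(self.levels, S), name=self.within)
            Lc, _ = _sum_code(lev_series)
        else:
            lv = np.tile(self.levels, S)
            Lc = (lv - np.mean(self.levels))[:, None]
        w_blocks: dict[str, np.ndarray] = {self.within: Lc}
        for name, mat in b_blocks.items():
            rep = np.repeat(mat, L, axis=0)
            w_blocks[f"{self.within}:{name}"] = \
                np.einsum("ij,ik->ijk", Lc, rep).reshape(S * L, -1)
        ss_w, sse_w, _ = _drop_one_anova(D, w_blocks, intercept=False)
        p_w = sum(m.shape[1] for m in w_blocks.values())
        df_w_err = S * (L - 1) - p_w

        rows = []
        for name, mat in b_blocks.items():
            rows.append(self._effect_row(
                name, ss_b[name], mat.shape[1], sse_b, df_b_err, "between"))
        for name, mat in w_blocks.items():
            rows.append(self._effect_row(
                name, ss_w[name], mat.shape[1], sse_w, df_w_err, "within"))
        rows.append(("between_error", sse_b, df_b_err, np.nan, np.nan, np.nan,
                     np.nan, "between", ""))
        rows.append(("within_error", sse_w, df_w_err, np.nan, np.nan, np.nan,
                     np.nan, "within", ""))
        anova = pd.DataFrame(
            rows, columns=["effect", "ss", "df1", "df2", "F", "p",
                           "partial_eta_sq", "stratum", "flag"])
        return SplitPlotResults(self, anova,
                                ss_between_error=sse_b, df_between_error=df_b_err,
                                ss_within_error=sse_w, df_within_error=df_w_err)

    @staticmethod
    def _effect_row(name, ss, df1, sse, df_err, stratum):
        flag = ""
        if df_err <= 0 or sse <= 1e-12 * max(ss, 1.0):
            if ss <= 1e-12:
                return (name, ss, df1, df_err, np.nan, np.nan, np.nan,
                        stratum, "degenerate")
            return (name, ss, df1, df_err, _F_CAP, 0.0, 1.0, stratum, "capped")
        F = (ss / df1) / (sse / df_err)
        if F > _F_CAP:
            F, flag = _F_CAP, "capped"
        p = float(stats.f.sf(F, df1, df_err))
        pes = ss / (ss + sse)
        return (name, ss, df1, df_err, F, p, pes, stratum, flag)


class SplitPlotResults:
    """Fitted split-plot decomposition with per-stratum F tests."""

    def __init__(self, model: SplitPlotModel, anova: pd.DataFrame, *,
                 ss_between_error, df_between_error,
                 ss_within_error, df_within_error):
        self.model = model
        self.anova = anova
        self.ss_between_error = ss_between_error
        self.df_between_error = df_between_error
        self.ss_within_error = ss_within_error
        self.df_within_error = df_within_error
        Y = model.Y
        self.ss_total = float(((Y - Y.mean()) ** 2).sum())
        self.ss_between_total = float(
            Y.shape[1] * ((Y.mean(1) - Y.mean()) ** 2).sum())
        self.ss_within_total = float(
            ((Y - Y.mean(1)[:, None]) ** 2).sum())

    def effect(self, name: str) -> pd.Series:
        row = self.anova[self.anova["effect"] == name]
        if row.empty:
            raise KeyError(f"no effect {name!r}; have "
                           f"{self.anova['effect'].tolist()}")
        return row.iloc[0]

    def summary(self) -> str:
        tab = self.anova.copy()
        for c in ("ss", "F"):
            tab[c] = tab[c].map(lambda v: f"{v:.4g}" if pd.notna(v) else "")
        tab["p"] = tab["p"].map(lambda v: f"{v:.4g}" if pd.notna(v) else "")
        tab["partial_eta_sq"] = tab["partial_eta_sq"].map(
            lambda v: f"{v:.3f}" if pd.notna(v) else "")
        header = ("Split-plot ANOVA on "
                  f"{self.model.dv} ({self.model.level_coding} level coding)")
        return header + "\n" + tab.to_string(index=False)


def split_plot_model(summaries: pd.DataFrame, *, between=("group", "sex"),
                     covariates=(), level_coding="categorical",
                     dv="elogit", factor_interactions=True) -> SplitPlotResults:
    """Fit the split-plot group model on a subject x level summary table."""
    return SplitPlotModel(summaries, between=between, covariates=covariates,
                          level_coding=level_coding, dv=dv,
                          factor_interactions=factor_interactions).fit()


# -- back-transformed marginal means --------------------------------------

def backtransform_means(summaries: pd.DataFrame, by, ci_level: float = 0.95,
                        dv: str = "elogit",
                        subject: str = "subject_id") -> pd.DataFrame:
    """Marginal mean choice percentages with t-intervals, on the 0-100 scale.

    For each category of ``by`` (a column name or list of them), the
    subject's ``dv`` values are averaged within the category, a t-based
    confidence interval is taken across subjects, and mean and bounds are
    inverse-logit transformed to percentages.
    """
    if isinstance(by, str):
        by = [by]
    by = list(by)
    per_subj = (summaries.dropna(subset=[dv])
                .groupby([*by, subject], sort=True)[dv].mean().reset_index())
    rows = []
    for keys, grp in per_subj.groupby(by, sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        vals = grp[dv].to_numpy()
        n = len(vals)
        mean = vals.mean()
        if n > 1 and vals.std(ddof=1) > 0:
            half = stats.t.ppf((1 + ci_level) / 2, n - 1) * \
                vals.std(ddof=1) / np.sqrt(n)
        else:
            half = 0.0
        inv = lambda v: 100.0 / (1.0 + np.exp(-v))
        rows.append((*keys, n, mean, inv(mean), inv(mean - half),
                     inv(mean + half)))
    return pd.DataFrame(
        rows, columns=[*by, "n_subjects", "mean_elogit", "pct",
                       "pct_lo", "pct_hi"])
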