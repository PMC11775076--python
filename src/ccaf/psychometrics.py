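"""Binomial logistic psychometric functions, PSE and parametric bootstrap.

The psychometric model for a choice count ``k`` out of ``n`` at predictor
value ``x`` (relative point level, or AUDIT score in the covariate
variant) is

    k ~ Binomial(n, p(x)),   p(x) = 1 / (1 + exp(-beta * (x - alpha)))

in the location-slope parameterization: ``alpha`` is the point of
subjective equality (PSE) — the predictor value where alcohol and snack
are equally likely to be chosen — and ``beta`` the slope in logit units
per predictor unit.  Interpolating the PSE from the fitted curve is then
just reading off ``alpha``.

Fitting maximises the binomial log-likelihood by Newton-Raphson in the
(intercept, slope) parameterization, where the likelihood is globally
concave, on a standardized predictor; estimates are converted back
algebraically (``alpha = -b0/b1``, ``beta = b1``).  Perfectly separated
data (all observed proportions at 0/1 in predictor order) have no finite
maximiser; such fits are flagged and re-run with a weak ridge penalty on
the standardized slope so downstream bootstrap percentiles stay usable.

Uncertainty comes from a parametric bootstrap: new counts are drawn from
the fitted binomial model at the observed design points, refitted, and
percentile intervals taken — 1000 resamples for a 95% interval by
default.  The refits for all resamples run through one vectorised Newton
solve, so subject-level and calibration studies stay cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln

__all__ = [
    "PsychometricModel", "PsychometricResults", "BootstrapResult",
    "fit_psychometric", "interpolate_pse", "parametric_bootstrap",
    "fit_vs_covariate",
]

# |standardized slope| beyond which the data are treated as separated:
# fitted probabilities at the design points are numerically 0/1 there.
_SEPARATION_SLOPE = 15.0
_MAX_ITER = 200
_GRAD_TOL = 1e-8


def _bin_loglik(eta, n, k, b1=None, ridge=0.0):
    # log-likelihood kernel (no binomial coefficient); optional ridge on b1
    ll = np.sum(k * eta - n * np.logaddexp(0.0, eta), axis=-1)
    if ridge:
        ll = ll - ridge * b1 ** 2
    return ll


def _newton_logistic(z, n, K, ridge=0.0, max_iter=_MAX_ITER, tol=_GRAD_TOL):
    """Newton-Raphson for ``K[..., j] ~ Binomial(n[j], expit(b0 + b1 z[j]))``.

    Vectorised over the leading axes of ``K``.  Returns ``(b0, b1,
    converged)`` on the standardized-z scale.
    """
    z = np.asarray(z, float)
    n = np.asarray(n, float)
    K = np.asarray(K, float)
    shape = K.shape[:-1]
    ktot = K.sum(-1)
    ntot = n.sum()
    # adjusted-logit intercept start, flat slope
    b0 = np.log((ktot + 0.5) / (ntot - ktot + 0.5))
    b1 = np.zeros(shape)
    eta = np.clip(b0[..., None] + b1[..., None] * z, -35.0, 35.0)
    ll = _bin_loglik(eta, n, K, b1, ridge)
    converged = np.zeros(shape, bool)
    for _ in range(max_iter):
        p = expit(eta)
        resid = K - n * p
        w = n * p * (1.0 - p)
        g0 = resid.sum(-1)
        g1 = (resid * z).sum(-1) - 2.0 * ridge * b1
        h00 = w.sum(-1)
        h01 = (w * z).sum(-1)
        h11 = (w * z * z).sum(-1) + 2.0 * ridge
        newly = (np.abs(g0) < tol) & (np.abs(g1) < tol)
        converged |= newly
        if converged.all():
            break
        det = h00 * h11 - h01 * h01
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        d0 = (h11 * g0 - h01 * g1) / det
        d1 = (h00 * g1 - h01 * g0) / det
        step = np.ones(shape)
        for _ in range(40):  # damped step: never decrease the objective
            nb0 = b0 + step * d0
            nb1 = b1 + step * d1
            eta_new = np.clip(nb0[..., None] + nb1[..., None] * z, -35.0, 35.0)
            ll_new = _bin_loglik(eta_new, n, K, nb1, ridge)
            worse = (ll_new < ll - 1e-12) & ~converged
            if not worse.any():
                break
            step = np.where(worse, step * 0.5, step)
        advance = ~converged
        b0 = np.where(advance, nb0, b0)
        b1 = np.where(advance, nb1, b1)
        eta = np.clip(b0[..., None] + b1[..., None] * z, -35.0, 35.0)
        ll = _bin_loglik(eta, n, K, b1, ridge)
    return b0, b1, converged


@dataclass(frozen=True)
class BootstrapResult:
    """Percentile bootstrap intervals for (alpha, beta)."""

    n_boot: int
    level: float
    alpha_ci: tuple[float, float]
    beta_ci: tuple[float, float]
    n_failed: int
    seed: int | None
    alpha_samples: np.ndarray = field(repr=False)
    beta_samples: np.ndarray = field(repr=False)


class PsychometricModel:
    """Two-parameter binomial logistic choice model.

    Parameters
    ----------
    x : array of predictor values (one per design point)
    n : array of trial counts per design point
    k : array of alcohol-choice counts per design point
    predictor : name of the predictor ("relative_point_level" or "audit")
    scope : "group", "subject" or "covariate" — bookkeeping only
    """

    def __init__(self, x, n, k, *, predictor="relative_point_level",
                 scope="group"):
        self.x = np.asarray(x, float)
        self.n = np.asarray(n, float)
        self.k = np.asarray(k, float)
        if not (self.x.shape == self.n.shape == self.k.shape):
            raise ValueError("x, n, k must have identical shapes")
        if np.any((self.k < 0) | (self.k > self.n)) or np.any(self.n < 1):
            raise ValueError("need 0 <= k <= n and n >= 1 at every design point")
        if len(np.unique(self.x[self.n >= 1])) < 2:
            raise ValueError(
                "need >= 2 distinct predictor values: slope is unidentifiable")
        self.predictor = predictor
        self.scope = scope
        self._mx = float(self.x.mean())
        sx = float(self.x.std())
        self._sx = sx if sx > 0 else 1.0
        self._z = (self.x - self._mx) / self._sx

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_summaries(cls, summaries: pd.DataFrame, *, scope="group",
                       subject_id: str | None = None,
                       predictor="relative_point_level",
                       pooling="counts"):
        """Build a model from a subject x level summary table.

        ``scope="group"`` pools counts over all rows per predictor value
        (binomial weighting); ``pooling="mean_proportion"`` instead
        averages per-subject proportions and converts back to effective
        counts.  ``scope="subject"`` restricts to one subject's rows.
        """
        df = summaries[~summaries.get("no_data", False).astype(bool)]
        if subject_id is not None:
            df = df[df["subject_id"] == subject_id]
            scope = "subject"
        if df.empty:
            raise ValueError("no usable summary rows")
        if predictor == "relative_point_level":
            key = "relative_point_level"
            g = df.groupby(key)
            if pooling == "counts":
                tab = g[["k", "n"]].sum()
            elif pooling == "mean_proportion":
                prop = g.apply(lambda d: (d["k"] / d["n"]).mean(),
                               include_groups=False)
                ntot = g["n"].sum()
                tab = pd.DataFrame({"k": prop * ntot, "n": ntot})
            else:
                raise ValueError(f"unknown pooling {pooling!r}")
            return cls(tab.index.to_numpy(float), tab["n"].to_numpy(),
                       tab["k"].to_numpy(), predictor=predictor, scope=scope)
        # continuous covariate: pool counts by covariate value
        g = df.groupby(predictor)[["k", "n"]].sum()
        return cls(g.index.to_numpy(float), g["n"].to_numpy(),
                   g["k"].to_numpy(), predictor=predictor, scope="covariate")

    # -- fitting ----------------------------------------------------------
    def fit(self, ridge_on_separation: float = 1e-4) -> "PsychometricResults":
        """Maximum-likelihood fit; ridge-stabilised when separated."""
        K = self.k[None, :]
        b0, b1, conv = _newton_logistic(self._z, self.n, K)
        b0, b1, conv = float(b0[0]), float(b1[0]), bool(conv[0])
        props = self.k / self.n
        degenerate = bool(np.all((props == 0.0) | (props == 1.0)))
        separated = degenerate or (not conv) or abs(b1) > _SEPARATION_SLOPE
        if separated and ridge_on_separation > 0:
            b0a, b1a, conva = _newton_logistic(
                self._z, self.n, K, ridge=ridge_on_separation)
            b0, b1, conv = float(b0a[0]), float(b1a[0]), bool(conva[0])
        return PsychometricResults(self, b0, b1, converged=conv,
                                   separation_flag=separated,
                                   ridge=ridge_on_separation if separated else 0.0)

    def loglik(self, alpha: float, beta: float) -> float:
        """Full binomial log-likelihood (with combinatorial terms) at (alpha, beta)."""
        eta = np.clip(beta * (self.x - alpha), -35.0, 35.0)
        p = expit(eta)
        const = gammaln(self.n + 1) - gammaln(self.k + 1) - gammaln(self.n - self.k + 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = self.k * np.log(p) + (self.n - self.k) * np.log1p(-p)
        terms = np.where((self.k == 0) & (p == 0), 0.0, terms)
        terms = np.where((self.k == self.n) & (p == 1), 0.0, terms)
        return float(np.sum(const + terms))

    def _convert(self, b0, b1):
        """(b0, b1) on the z scale -> (alpha, beta) on the predictor scale."""
        beta = b1 / self._sx
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha = self._mx - self._sx * b0 / b1
        return alpha, beta


class PsychometricResults:
    """Fitted psychometric function: PSE, slope, likelihood, bootstrap."""

    def __init__(self, model: PsychometricModel, b0: float, b1: float, *,
                 converged: bool, separation_flag: bool, ridge: float = 0.0):
        self.model = model
        self._b0 = b0
        self._b1 = b1
        self.converged = converged
        self.separation_flag = separation_flag
        self.ridge = ridge
        alpha, beta = model._convert(np.asarray(b0), np.asarray(b1))
        self.alpha = float(alpha)
        self.beta = float(beta)
        p = self.predict(model.x)
        const = gammaln(model.n + 1) - gammaln(model.k + 1) \
            - gammaln(model.n - model.k + 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = model.k * np.log(p) + (model.n - model.k) * np.log1p(-p)
        terms = np.where((model.k == 0) & (p == 0), 0.0, terms)
        terms = np.where((model.k == model.n) & (p == 1), 0.0, terms)
        self.loglik = float(np.sum(const + terms))

    # location parameterization: interpolating the 50% point is the identity
    @property
    def pse(self) -> float:
        if not self.converged:
            raise RuntimeError("PSE undefined: fit did not converge")
        if not np.isfinite(self.alpha) or abs(self.beta) < 1e-12:
            raise RuntimeError(
                "PSE undefined: flat or unbounded fitted curve "
                f"(alpha={self.alpha}, beta={self.beta}, "
                f"separation={self.separation_flag})")
        return self.alpha

    def predict(self, x):
        """Fitted P(alcohol) at predictor value(s) x."""
        eta = self._b0 + self._b1 * (np.asarray(x, float) - self.model._mx) / self.model._sx
        return expit(np.clip(eta, -35.0, 35.0))

    def parametric_bootstrap(self, n_boot: int = 1000, level: float = 0.95,
                             seed=None) -> BootstrapResult:
        """Percentile bootstrap CIs by simulating from the fitted model.

        Each resample draws ``k* ~ Binomial(n, p_hat)`` at the observed
        design points and refits.  Resamples whose refit fails even with
        the ridge fallback are dropped and counted; more than 20% failures
        raises (the fit is too unstable for percentile intervals).
        """
        if n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if not 0 < level < 1:
            raise ValueError("level must lie in (0, 1)")
        m = self.model
        rng = np.random.default_rng(seed)
        p_hat = self.predict(m.x)
        K = rng.binomial(m.n.astype(int), p_hat, size=(n_boot, m.x.size))
        b0, b1, conv = _newton_logistic(m._z, m.n, K)
        bad = ~conv | (np.abs(b1) > _SEPARATION_SLOPE)
        if bad.any():
            rb0, rb1, rconv = _newton_logistic(
                m._z, m.n, K[bad], ridge=max(self.ridge, 1e-4))
            b0[bad], b1[bad], conv[bad] = rb0, rb1, rconv
        # flat saturated refits (slope ~ 0, intercept pinned at a boundary)
        # carry a signed-infinite location: an always-alcohol draw has its
        # 50% point at -inf, an always-snack draw at +inf
        flat = conv & (np.abs(b1) <= 1e-12)
        ok = conv & (~flat | (np.abs(b0) > 1e-8))
        n_failed = int((~ok).sum())
        if n_failed > 0.2 * n_boot:
            raise RuntimeError(
                f"{n_failed}/{n_boot} bootstrap refits failed; "
                "fit too unstable for percentile intervals")
        alpha_s, beta_s = m._convert(b0[ok], b1[ok])
        flat_ok = flat[ok]
        if flat_ok.any():
            alpha_s = np.where(flat_ok, np.where(b0[ok] > 0, -np.inf, np.inf),
                               alpha_s)
        lo, hi = 100 * (1 - level) / 2, 100 * (1 + level) / 2

        def pct(samples):
            # nearest-rank percentiles when saturated draws put mass at +-inf
            method = "nearest" if np.isinf(samples).any() else "linear"
            return tuple(np.percentile(samples, [lo, hi], method=method))

        return BootstrapResult(
            n_boot=n_boot, level=level,
            alpha_ci=pct(alpha_s),
            beta_ci=pct(beta_s),
            n_failed=n_failed,
            seed=seed if isinstance(seed, (int, np.integer)) else None,
            alpha_samples=alpha_s, beta_samples=beta_s)

    def summary(self) -> str:
        lines = [
            "Psychometric fit (binomial logistic, location-slope)",
            f"  scope: {self.model.scope}   predictor: {self.model.predictor}",
            f"  design points: {self.model.x.size}   "
            f"trials: {int(self.model.n.sum())}",
            f"  alpha (PSE): {self.alpha: .4f}",
            f"  beta (slope): {self.beta: .4f}",
            f"  log-likelihood: {self.loglik: .3f}",
            f"  converged: {self.converged}   separation: {self.separation_flag}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "scope": self.model.scope,
            "predictor": self.model.predictor,
            "alpha": self.alpha,
            "beta": self.beta,
            "loglik": self.loglik,
            "converged": self.converged,
            "separation_flag": self.separation_flag,
        }


# -- functional wrappers --------------------------------------------------

def fit_psychometric(summaries: pd.DataFrame, scope: str = "group",
                     predictor: str = "relative_point_level",
                     subject_id: str | None = None,
                     pooling: str = "counts") -> PsychometricResults:
    """Fit a psychometric curve from a subject x level summary table."""
    model = PsychometricModel.from_summaries(
        summaries, scope=scope, subject_id=subject_id, predictor=predictor,
        pooling=pooling)
    return model.fit()


def interpolate_pse(fit: PsychometricResults) -> float:
    """Predictor value at which both options are equally likely to be chosen."""
    return fit.pse


def parametric_bootstrap(fit: PsychometricResults, n_boot: int = 1000,
                         level: float = 0.95, seed=None) -> BootstrapResult:
    return fit.parametric_bootstrap(n_boot=n_boot, level=level, seed=seed)


def fit_vs_covariate(summaries: pd.DataFrame, level: int,
                     covariate: str = "audit", n_boot: int = 1000,
                     ci_level: float = 0.95, seed=None):
    """Choice counts vs a continuous covariate within one relative point level.

    Returns ``(PsychometricResults, BootstrapResult)``; the slope is in
    logit units per covariate point.
    """
    df = summaries[summaries["relative_point_level"] == level]
    if df.empty:
        raise ValueError(f"no rows at relative point level {level}")
    if covariate not in df.columns:
        raise ValueError(f"summaries lack a {covariate!r} column")
    if df[covariate].nunique() < 2:
        raise ValueError(f"{covariate} is constant: slope unidentifiable")
    model = PsychometricModel.from_summaries(df, predictor=covariate)
    res = model.fit()
    boot = res.parametric_bootstrap(n_boot=n_boot, level=ci_level, seed=seed)
    return res, boot
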