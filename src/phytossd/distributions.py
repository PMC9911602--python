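"""Parametric SSD machinery: four positive-support families, maximum
likelihood for exact and interval-censored doses, AICc model selection.

A species sensitivity distribution (SSD) treats the per-species required dose
as a random draw from a positive continuous distribution. Four two-parameter
candidate families are supported — log-normal, log-logistic, gamma and
Weibull — and the family with the lowest small-sample-corrected Akaike
information criterion (AICc, k = 2) is selected.

Exact doses contribute log densities to the likelihood; an interval-censored
observation ``[L, U]`` contributes ``log(F(U) - F(L))``, with a degenerate
interval (``L == U``) falling back to the log density so that censored fitting
on degenerate intervals reproduces the exact-data fit.

Maximum likelihood uses closed forms where they exist (log-normal), a Newton
solve of the profile score for the gamma shape, a bracketed root solve of the
Weibull profile score, and deterministic Nelder–Mead on log-parameters
elsewhere (moment-based starting values, no randomness).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator

__all__ = [
    "FAMILIES",
    "DistributionSpec",
    "FitResult",
    "ModelSet",
    "loglik",
    "fit_mle",
    "fit_all",
    "ssd_cdf",
    "ssd_quantile",
    "ssd_sample",
    "anderson_darling",
    "ParametricSSD",
]

#: supported families, in deterministic tie-break order for model selection
FAMILIES: tuple[str, ...] = ("gamma", "lognormal", "loglogistic", "weibull")

_PARAM_NAMES: Mapping[str, tuple[str, str]] = {
    "gamma": ("shape", "scale"),
    "lognormal": ("meanlog", "sdlog"),
    "loglogistic": ("shape", "scale"),
    "weibull": ("shape", "scale"),
}


@dataclass(frozen=True)
class DistributionSpec:
    """A distribution family plus its two parameters.

    Parameterizations:

    * ``gamma``: shape ``a`` > 0, scale > 0 (mean = shape * scale)
    * ``lognormal``: meanlog (real), sdlog > 0 (of the log dose)
    * ``loglogistic``: shape > 0, scale > 0, CDF ``1 / (1 + (x/scale)^-shape)``
    * ``weibull``: shape > 0, scale > 0, CDF ``1 - exp(-(x/scale)^shape)``
    """

    family: str
    params: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        names = _PARAM_NAMES[self.family]
        if set(self.params) != set(names):
            raise ValueError(f"{self.family} needs parameters {names}")
        object.__setattr__(self, "params", dict(self.params))
        for name, value in self.params.items():
            if name != "meanlog" and not value > 0:
                raise ValueError(f"{self.family} parameter {name} must be > 0")

    @property
    def frozen(self):
        """The scipy.stats frozen distribution for this spec."""
        p = self.params
        if self.family == "gamma":
            return stats.gamma(p["shape"], scale=p["scale"])
        if self.family == "lognormal":
            return stats.lognorm(p["sdlog"], scale=math.exp(p["meanlog"]))
        if self.family == "loglogistic":
            return stats.fisk(p["shape"], scale=p["scale"])
        return stats.weibull_min(p["shape"], scale=p["scale"])

    def to_dict(self) -> dict:
        return {"family": self.family, "params": dict(self.params)}


@dataclass(frozen=True)
class FitResult:
    """A maximum-likelihood fit of one family, with AICc bookkeeping."""

    spec: DistributionSpec
    loglik: float
    aic: float
    aicc: float
    n_obs: int
    converged: bool
    data_kind: str  # "exact" or "interval"

    def to_dict(self) -> dict:
        d = self.spec.to_dict()
        d.update(
            loglik=self.loglik, aic=self.aic, aicc=self.aicc,
            n_obs=self.n_obs, converged=self.converged, data_kind=self.data_kind,
        )
        return d


@dataclass
class ModelSet:
    """Fits of all candidate families, with the AICc-best one selected.

    Ties (to within floating equality) resolve by the fixed order of
    :data:`FAMILIES`, so reruns are deterministic.
    """

    fits: dict[str, FitResult] = field(default_factory=dict)

    @property
    def best(self) -> FitResult:
        converged = [f for f in (self.fits.get(n) for n in FAMILIES) if f and f.converged]
        if not converged:
            raise RuntimeError("no candidate family converged")
        return min(converged, key=lambda f: f.aicc)

    def table(self) -> list[dict]:
        best = self.best
        return [
            dict(self.fits[name].to_dict(), selected=self.fits[name] is best)
            for name in FAMILIES
            if name in self.fits
        ]


# --------------------------------------------------------------------------
# data handling


def _as_intervals(data) -> tuple[np.ndarray, np.ndarray, str]:
    """Normalize input to (lower, upper) arrays; exact data has lower == upper.

    Accepts a 1-D sequence of doses, an (n, 2) array of interval bounds, or a
    sequence of objects with ``lower_gy``/``upper_gy`` or ``dose_gy``
    attributes (``CensoredInterval`` / ``SpeciesDose``).
    """
    seq = list(data) if not isinstance(data, np.ndarray) else data
    if len(seq) == 0:
        raise ValueError("no observations")
    first = seq[0] if not isinstance(seq, np.ndarray) else None
    if first is not None and hasattr(first, "lower_gy"):
        lo = np.array([r.lower_gy for r in seq], dtype=float)
        hi = np.array([r.upper_gy for r in seq], dtype=float)
        kind = "interval"
    elif first is not None and hasattr(first, "dose_gy"):
        lo = hi = np.array([r.dose_gy for r in seq], dtype=float)
        kind = "exact"
    else:
        arr = np.asarray(seq, dtype=float)
        if arr.ndim == 1:
            lo = hi = arr
            kind = "exact"
        elif arr.ndim == 2 and arr.shape[1] == 2:
            lo, hi = arr[:, 0], arr[:, 1]
            kind = "interval"
        else:
            raise ValueError("data must be 1-D doses or an (n, 2) interval array")
    if np.any(lo <= 0) or np.any(hi <= 0):
        raise ValueError("doses and interval bounds must be > 0")
    if np.any(hi < lo):
        raise ValueError("interval upper bounds must be >= lower bounds")
    if kind == "interval" and np.all(lo == hi):
        kind = "exact"
    return lo, hi, kind


def loglik(spec: DistributionSpec, data) -> float:
    """Log-likelihood of exact or interval-censored doses under ``spec``.

    Zero-probability intervals contribute ``-inf`` rather than raising.
    """
    lo, hi, _ = _as_intervals(data)
    frozen = spec.frozen
    exact = lo == hi
    total = 0.0
    if exact.any():
        total += float(frozen.logpdf(lo[exact]).sum())
    if (~exact).any():
        prob = frozen.cdf(hi[~exact]) - frozen.cdf(lo[~exact])
        with np.errstate(divide="ignore"):
            total += float(np.log(prob).sum())
    return total


# --------------------------------------------------------------------------
# exact-data maximum likelihood (closed form / profile score)


def _mle_lognormal(x: np.ndarray) -> dict[str, float]:
    logx = np.log(x)
    return {"meanlog": float(logx.mean()), "sdlog": float(max(logx.std(), 1e-12))}


def _gamma_shape_from_s(s: float) -> float:
    """Solve ``log(a) - digamma(a) = s`` by Newton from the Minka start."""
    a = (3.0 - s + math.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
    for _ in range(200):
        f = math.log(a) - special.digamma(a) - s
        step = f / (1.0 / a - special.polygamma(1, a))
        a_new = a - step
        if a_new <= 0:
            a_new = a / 2.0
        if abs(a_new - a) <= 1e-13 * a:
            return a_new
        a = a_new
    return a


def _mle_gamma(x: np.ndarray) -> dict[str, float]:
    m = float(x.mean())
    s = math.log(m) - float(np.log(x).mean())
    if s <= 0:  # degenerate (all values equal)
        s = 1e-12
    a = _gamma_shape_from_s(s)
    return {"shape": a, "scale": m / a}


def _mle_weibull(x: np.ndarray) -> dict[str, float]:
    logx = np.log(x)
    mlog = float(logx.mean())

    def score(c: float) -> float:
        w = np.exp(c * (logx - logx.max()))  # stabilized x**c weights
        return 1.0 / c + mlog - float((w * logx).sum() / w.sum())

    lo, hi = 1e-3, 1.0
    while score(hi) > 0 and hi < 1e4:
        lo, hi = hi, hi * 2.0
    if score(lo) < 0 or score(hi) > 0:
        raise RuntimeError("weibull profile score has no admissible root")
    c = optimize.brentq(score, lo, hi, xtol=1e-12, rtol=1e-14)
    scale = float(np.exp(logx.max()) * (np.exp(c * (logx - logx.max())).mean()) ** (1.0 / c))
    return {"shape": c, "scale": scale}


def _nelder_mead(negll, start_log: np.ndarray) -> tuple[np.ndarray, bool]:
    res = optimize.minimize(
        negll, start_log, method="Nelder-Mead",
        options=dict(xatol=1e-10, fatol=1e-12, maxiter=20_000, maxfev=20_000),
    )
    return res.x, bool(res.success) and np.isfinite(res.fun)


def _mle_loglogistic(x: np.ndarray) -> tuple[dict[str, float], bool]:
    logx = np.log(x)
    sdlog = max(float(logx.std()), 1e-6)
    start = np.log([math.pi / (math.sqrt(3.0) * sdlog), math.exp(float(logx.mean()))])

    def negll(th):
        c, s = np.exp(th)
        return -float(stats.fisk.logpdf(x, c, scale=s).sum())

    th, ok = _nelder_mead(negll, start)
    c, s = np.exp(th)
    return {"shape": float(c), "scale": float(s)}, ok


def _exact_start(family: str, x: np.ndarray) -> dict[str, float]:
    if family == "lognormal":
        return _mle_lognormal(x)
    if family == "gamma":
        return _mle_gamma(x)
    if family == "weibull":
        return _mle_weibull(x)
    params, _ = _mle_loglogistic(x)
    return params


# --------------------------------------------------------------------------
# fitting


def _aicc(ll: float, n: int, k: int = 2) -> tuple[float, float]:
    aic = -2.0 * ll + 2.0 * k
    if n - k - 1 <= 0:
        warnings.warn("too few observations for the AICc correction", stacklevel=2)
        return aic, math.inf
    return aic, aic + 2.0 * k * (k + 1) / (n - k - 1)


def fit_mle(family: str, data) -> FitResult:
    """Fit one family by maximum likelihood to exact or censored doses.

    Deterministic: fixed moment-based starting values, no randomness. A fit
    that fails to converge is returned with ``converged=False`` (and a
    warning) rather than raising, so model selection can skip it.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    lo, hi, kind = _as_intervals(data)
    n = lo.size
    if n < 3:
        raise ValueError("at least 3 observations are required for fitting")

    if kind == "exact":
        x = lo
        converged = True
        try:
            if family == "loglogistic":
                params, converged = _mle_loglogistic(x)
            else:
                params = _exact_start(family, x)
        except (RuntimeError, FloatingPointError) as exc:
            warnings.warn(f"{family} fit failed: {exc}", stacklevel=2)
            params = _exact_start("lognormal", x) if family == "lognormal" else None
            if params is None:
                params = dict(zip(_PARAM_NAMES[family], (1.0, float(x.mean()))))
            converged = False
        spec = DistributionSpec(family, params)
    else:
        mid = 0.5 * (lo + hi)
        start_params = _exact_start(family, mid)
        names = _PARAM_NAMES[family]
        if family == "lognormal":
            start = np.array([start_params["meanlog"], math.log(start_params["sdlog"])])

            def unpack(th):
                return {"meanlog": th[0], "sdlog": math.exp(th[1])}
        else:
            start = np.log([start_params[names[0]], start_params[names[1]]])

            def unpack(th):
                return {names[0]: math.exp(th[0]), names[1]: math.exp(th[1])}

        def negll(th):
            try:
                return -loglik(DistributionSpec(family, unpack(th)), np.c_[lo, hi])
            except (OverflowError, FloatingPointError):
                return math.inf

        th, converged = _nelder_mead(negll, start)
        spec = DistributionSpec(family, unpack(th))

    ll = loglik(spec, np.c_[lo, hi] if kind == "interval" else lo)
    if not np.isfinite(ll):
        converged = False
    if not converged:
        warnings.warn(f"{family} fit did not converge", stacklevel=2)
    aic, aicc = _aicc(ll, n)
    return FitResult(
        spec=spec, loglik=ll, aic=aic, aicc=aicc,
        n_obs=n, converged=converged, data_kind=kind,
    )


def fit_all(data, families: Sequence[str] = FAMILIES) -> ModelSet:
    """Fit every candidate family and select the lowest converged AICc."""
    ms = ModelSet()
    for family in families:
        ms.fits[family] = fit_mle(family, data)
    ms.best  # raises if nothing converged
    return ms


# --------------------------------------------------------------------------
# distribution functions


def ssd_cdf(spec: DistributionSpec, dose):
    """Fitted cumulative probability (taxonomic coverage as a fraction)."""
    dose = np.asarray(dose, dtype=float)
    if np.any(dose < 0):
        raise ValueError("dose must be >= 0")
    out = spec.frozen.cdf(dose)
    return float(out) if out.ndim == 0 else out


def ssd_quantile(spec: DistributionSpec, p):
    """Dose at cumulative probability ``p`` (the GD_p generic dose)."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("p must lie strictly in (0, 1)")
    out = spec.frozen.ppf(p)
    return float(out) if out.ndim == 0 else out


def ssd_sample(spec: DistributionSpec, count: int, seed) -> np.ndarray:
    """Draw ``count`` doses; reproducible for a fixed seed or Generator."""
    if count < 1:
        raise ValueError("count must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return spec.frozen.rvs(size=count, random_state=rng)


def anderson_darling(spec: DistributionSpec, data) -> float:
    """Anderson–Darling statistic of exact doses against a fitted spec.

    Diagnostic only; model selection uses AICc.
    """
    lo, hi, kind = _as_intervals(data)
    if kind != "exact":
        raise ValueError("Anderson-Darling statistic is defined for exact data only")
    z = np.sort(spec.frozen.cdf(lo))
    n = z.size
    i = np.arange(1, n + 1)
    z = np.clip(z, 1e-300, 1 - 1e-16)
    return float(-n - np.mean((2 * i - 1) * (np.log(z) + np.log1p(-z[::-1]))))


# --------------------------------------------------------------------------
# estimator


class ParametricSSD(BaseEstimator):
    """Parametric species-sensitivity-distribution estimator.

    Fits a positive two-parameter distribution to per-species doses (exact or
    interval-censored) by maximum likelihood, in the scikit-learn estimator
    idiom.

    Parameters
    ----------
    family : str, default "auto"
        One of "gamma", "lognormal", "loglogistic", "weibull", or "auto" to
        fit all four and select the lowest AICc among converged fits.

    Attributes
    ----------
    result_ : FitResult
        The (selected) fit.
    model_set_ : ModelSet
        All fits; a single-entry set when ``family`` is fixed.
    family_, params_, loglik_, aicc_, n_obs_ :
        Convenience views of ``result_``.

    Examples
    --------
    >>> ssd = ParametricSSD(family="gamma").fit([40, 60, 80, 120, 150])
    >>> round(ssd.quantile(0.95), 1)  # doctest: +SKIP
    170.3
    """

    def __init__(self, family: str = "auto"):
        self.family = family

    def fit(self, X, y=None):
        if self.family != "auto" and self.family not in FAMILIES:
            raise ValueError(f"family must be 'auto' or one of {FAMILIES}")
        families = FAMILIES if self.family == "auto" else (self.family,)
        self.model_set_ = fit_all(X, families=families)
        self.result_ = self.model_set_.best
        self.family_ = self.result_.spec.family
        self.params_ = dict(self.result_.spec.params)
        self.loglik_ = self.result_.loglik
        self.aicc_ = self.result_.aicc
        self.n_obs_ = self.result_.n_obs
        return self

    def _check_fitted(self) -> DistributionSpec:
        if not hasattr(self, "result_"):
            raise RuntimeError("this ParametricSSD instance is not fitted yet")
        return self.result_.spec

    def cdf(self, dose):
        return ssd_cdf(self._check_fitted(), dose)

    def quantile(self, p):
        return ssd_quantile(self._check_fitted(), p)

    def sample(self, count: int, seed=None) -> np.ndarray:
        return ssd_sample(self._check_fitted(), count, seed)

    def score(self, X, y=None) -> float:
        """Total log-likelihood of ``X`` under the fitted distribution."""
        return loglik(self._check_fitted(), X)
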