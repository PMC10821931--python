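"""Heavy-tailed fitting of pooled blinking-event durations.

Pooled on/off interval (or segment) durations are summarised as
complementary cumulative distribution functions, CCDF(t) = P(T >= t), and
fitted by maximum likelihood to candidate families: lognormal (dispersive
electron-transfer kinetics with normally distributed activation barriers),
Weibull (stretched-exponential off states), pure and exponentially
truncated power laws, and exponential (first-order triplet blinking).
Goodness of fit is quantified by the Kolmogorov-Smirnov statistic with a
parametric-bootstrap p value (each replicate refit).

Lognormal parameters are in log10 of the duration in seconds: ``mu`` is
the log10 median, ``sigma`` the dispersion in decades.  An optional
``fit_floor`` conditions every likelihood on ``t >= floor`` — durations
shorter than one acquisition bin are unobservable, so pipeline fits on
trace-derived events use the bin time as floor; standalone fits default to
no conditioning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator

__all__ = [
    "FIT_FAMILIES",
    "CCDFData",
    "DistFit",
    "build_ccdf",
    "fit_mle",
    "goodness_of_fit",
    "select_family",
    "DurationFitter",
]

FIT_FAMILIES = ("lognormal", "weibull", "power_law", "truncated_power_law", "exponential")

LN10 = np.log(10.0)

_N_PARAMS = {
    "lognormal": 2,
    "weibull": 2,
    "exponential": 1,
    "power_law": 1,
    "truncated_power_law": 2,
}


# ---------------------------------------------------------------------------
# CCDF


@dataclass
class CCDFData:
    """Empirical survival function of pooled event durations."""

    t: np.ndarray
    survival: np.ndarray
    n: int
    kind: str = ""
    censoring: str = "boundary-censored events excluded"

    def __post_init__(self) -> None:
        if self.survival[0] != 1.0 or np.any(np.diff(self.survival) > 0):
            raise ValueError("survival must start at 1 and be non-increasing")


def build_ccdf(durations, kind: str = "") -> CCDFData:
    """Empirical CCDF: P(T >= t) = (# durations >= t) / n at each observed t."""
    d = np.asarray(durations, dtype=float)
    if d.size == 0:
        raise ValueError("need at least one duration")
    if np.any(d <= 0):
        raise ValueError("durations must be strictly positive")
    t, counts = np.unique(d, return_counts=True)
    n_ge = counts[::-1].cumsum()[::-1]  # durations >= each unique t
    return CCDFData(t=t, survival=n_ge / d.size, n=int(d.size), kind=kind)


# ---------------------------------------------------------------------------
# Family densities and CDFs


def _upper_gamma(a: float, x: np.ndarray) -> np.ndarray:
    """Upper incomplete gamma Gamma(a, x) for real a (including a <= 0).

    Uses the recurrence Gamma(a, x) = (Gamma(a+1, x) - x**a * exp(-x)) / a
    to step down from a positive shift where scipy's regularised form
    applies.
    """
    x = np.asarray(x, dtype=float)
    m = int(np.ceil(max(0.0, 1.0 - a)))
    aa = a + m
    if abs(aa - round(aa)) < 1e-9 and round(aa) <= 0:
        aa += 1e-8  # avoid the poles of Gamma at non-positive integers
    with np.errstate(all="ignore"):
        g = special.gammaincc(aa, x) * special.gamma(aa)
        for i in range(m):
            ai = aa - 1 - i
            g = (g - x ** ai * np.exp(-x)) / ai
    return g


def _tpl_norm(alpha: float, lam: float, x_min: float) -> float:
    """Normalisation integral of t**-alpha * exp(-lam t) over [x_min, inf)."""
    if lam <= 0:
        return x_min ** (1.0 - alpha) / (alpha - 1.0)
    return float(lam ** (alpha - 1.0) * _upper_gamma(1.0 - alpha, lam * x_min))


def _logpdf(family: str, params: dict, t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if family == "lognormal":
        mu, sigma = params["mu"], params["sigma"]
        y = np.log10(t)
        return (
            -0.5 * ((y - mu) / sigma) ** 2
            - np.log(sigma)
            - 0.5 * np.log(2 * np.pi)
            - np.log(t)
            - np.log(LN10)
        )
    if family == "weibull":
        k, lam = params["k"], params["lambda_s"]
        return np.log(k) - k * np.log(lam) + (k - 1) * np.log(t) - (t / lam) ** k
    if family == "exponential":
        r = params["rate"]
        return np.log(r) - r * t
    if family == "power_law":
        a, xm = params["alpha"], params["x_min"]
        out = np.full(t.shape, -np.inf)
        ok = t >= xm
        out[ok] = np.log(a - 1) - np.log(xm) - a * (np.log(t[ok]) - np.log(xm))
        return out
    if family == "truncated_power_law":
        a, xm, lam = params["alpha"], params["x_min"], params["cutoff_rate"]
        out = np.full(t.shape, -np.inf)
        ok = t >= xm
        with np.errstate(all="ignore"):
            out[ok] = -a * np.log(t[ok]) - lam * t[ok] - np.log(_tpl_norm(a, lam, xm))
        return out
    raise ValueError(f"unknown family {family!r}")


def _cdf(family: str, params: dict, t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if family == "lognormal":
        return stats.norm.cdf((np.log10(t) - params["mu"]) / params["sigma"])
    if family == "weibull":
        return 1.0 - np.exp(-((t / params["lambda_s"]) ** params["k"]))
    if family == "exponential":
        return 1.0 - np.exp(-params["rate"] * t)
    if family == "power_law":
        a, xm = params["alpha"], params["x_min"]
        return np.where(t < xm, 0.0, 1.0 - (np.maximum(t, xm) / xm) ** (1.0 - a))
    if family == "truncated_power_law":
        a, xm, lam = params["alpha"], params["x_min"], params["cutoff_rate"]
        if lam <= 0:
            return _cdf("power_law", {"alpha": a, "x_min": xm}, t)
        norm = _tpl_norm(a, lam, xm)
        tail = lam ** (a - 1.0) * _upper_gamma(1.0 - a, lam * np.maximum(t, xm))
        return np.where(t < xm, 0.0, 1.0 - tail / norm)
    raise ValueError(f"unknown family {family!r}")


def _survival_at(family: str, params: dict, floor: float) -> float:
    return 1.0 if floor <= 0 else float(1.0 - _cdf(family, params, np.array([floor]))[0])


def _conditional_loglik(family: str, params: dict, t: np.ndarray, floor: float) -> float:
    s = _survival_at(family, params, floor)
    if s <= 0:
        return -np.inf
    return float(_logpdf(family, params, t).sum() - t.size * np.log(s))


# ---------------------------------------------------------------------------
# MLE


@dataclass
class DistFit:
    """A fitted duration distribution."""

    family: str
    params: dict
    log_likelihood: float
    n: int
    fit_floor: float = 0.0
    ks_D: float | None = None
    ks_p: float | None = None

    @property
    def n_params(self) -> int:
        return _N_PARAMS[self.family]

    @property
    def bic(self) -> float:
        return -2.0 * self.log_likelihood + self.n_params * np.log(self.n)


def _minimize(nll, x0) -> np.ndarray:
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
    return res.x


def fit_mle(durations, family: str, fit_floor: float = 0.0) -> DistFit:
    """Maximum-likelihood fit of one duration family.

    With ``fit_floor > 0`` the likelihood is conditioned on
    ``t >= fit_floor`` (observations below the floor are rejected as a
    precondition violation).  Lognormal fits without a floor use the exact
    closed form mu = mean(log10 t), sigma = population sd(log10 t); all
    numerical fits start from moment-based values and use a deterministic
    simplex search.
    """
    t = np.asarray(durations, dtype=float)
    if np.any(t <= 0):
        raise ValueError("durations must be strictly positive")
    if fit_floor > 0 and np.any(t < fit_floor):
        raise ValueError("durations below fit_floor; filter before fitting")
    n = t.size
    if n < _N_PARAMS[family] + 1:
        raise ValueError(f"need at least {_N_PARAMS[family] + 1} durations for {family}")
    if n < 10:
        warnings.warn(f"only {n} durations; {family} fit may be unstable", stacklevel=2)
    if family in ("lognormal", "weibull") and np.all(t == t[0]):
        raise ValueError(f"all durations identical; {family} scale fit degenerate")

    if family == "lognormal":
        y = np.log10(t)
        mu0, sigma0 = float(y.mean()), float(y.std())  # population denominator
        if fit_floor <= 0:
            params = {"mu": mu0, "sigma": sigma0}
        else:
            def nll(x):
                p = {"mu": x[0], "sigma": np.exp(x[1])}
                return -_conditional_loglik(family, p, t, fit_floor)

            x = _minimize(nll, [mu0, np.log(max(sigma0, 1e-6))])
            params = {"mu": float(x[0]), "sigma": float(np.exp(x[1]))}
    elif family == "exponential":
        if fit_floor <= 0:
            params = {"rate": float(1.0 / t.mean())}
        else:
            # memoryless: conditional MLE is 1 / (mean excess over the floor)
            params = {"rate": float(1.0 / (t.mean() - fit_floor))}
    elif family == "weibull":
        lam0, k0 = float(t.mean()), 1.0

        def nll(x):
            p = {"k": np.exp(x[0]), "lambda_s": np.exp(x[1])}
            return -_conditional_loglik(family, p, t, fit_floor)

        x = _minimize(nll, [np.log(k0), np.log(lam0)])
        params = {"k": float(np.exp(x[0])), "lambda_s": float(np.exp(x[1]))}
    elif family == "power_law":
        xm = fit_floor if fit_floor > 0 else float(t.min())
        s = np.log(t / xm).sum()
        if s <= 0:
            raise ValueError("all durations at x_min; power-law fit degenerate")
        params = {"alpha": float(1.0 + n / s), "x_min": xm}
    elif family == "truncated_power_law":
        xm = fit_floor if fit_floor > 0 else float(t.min())
        s = np.log(t / xm).sum()
        a0 = 1.0 + n / max(s, 1e-9)
        lam0 = 1.0 / t.mean()

        def nll(x):
            a = 1.0 + np.exp(x[0])
            lam = np.exp(x[1])
            p = {"alpha": a, "x_min": xm, "cutoff_rate": lam}
            ll = _logpdf(family, p, t).sum()  # already normalised over [xm, inf)
            if fit_floor > 0 and fit_floor > xm:
                ll -= n * np.log(_survival_at(family, p, fit_floor))
            return -ll if np.isfinite(ll) else 1e300

        x = _minimize(nll, [np.log(max(a0 - 1.0, 1e-3)), np.log(lam0)])
        params = {
            "alpha": float(1.0 + np.exp(x[0])),
            "x_min": xm,
            "cutoff_rate": float(np.exp(x[1])),
        }
    else:
        raise ValueError(f"unknown family {family!r}; choose from {FIT_FAMILIES}")

    ll = _conditional_loglik(family, params, t, fit_floor)
    return DistFit(family=family, params=params, log_likelihood=ll, n=n, fit_floor=fit_floor)


# ---------------------------------------------------------------------------
# Goodness of fit


def _ks_statistic(t: np.ndarray, fit: DistFit) -> float:
    """sup |empirical CDF - fitted CDF| conditioned above the fit floor."""
    x = np.sort(t)
    n = x.size
    f = _cdf(fit.family, fit.params, x)
    if fit.fit_floor > 0:
        f0 = _cdf(fit.family, fit.params, np.array([fit.fit_floor]))[0]
        f = (f - f0) / max(1.0 - f0, 1e-300)
    emp_hi = np.arange(1, n + 1) / n
    emp_lo = np.arange(0, n) / n
    return float(np.maximum(np.abs(f - emp_hi), np.abs(f - emp_lo)).max())


def _sample_fitted(fit: DistFit, n: int, rng: np.random.Generator) -> np.ndarray:
    from .synth import sample_durations

    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = sample_durations(fit.family, fit.params, max(n - filled, 64), rng)
        draw = draw[draw >= fit.fit_floor] if fit.fit_floor > 0 else draw
        take = min(draw.size, n - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


def goodness_of_fit(
    durations, fit: DistFit, n_bootstrap: int = 200, rng_seed: int = 0
) -> tuple[float, float]:
    """KS statistic and parametric-bootstrap p value of a fit.

    Each bootstrap replicate resamples from the fitted distribution
    (conditioned above the fit floor), refits the same family, and records
    its KS statistic; the p value is the fraction of replicates at least as
    discrepant as the observed fit.
    """
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be >= 1")
    t = np.asarray(durations, dtype=float)
    d_obs = _ks_statistic(t, fit)
    rng = np.random.default_rng(rng_seed)
    exceed = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_bootstrap):
            sample = _sample_fitted(fit, t.size, rng)
            refit = fit_mle(sample, fit.family, fit.fit_floor)
            if _ks_statistic(sample, refit) >= d_obs:
                exceed += 1
    return d_obs, exceed / n_bootstrap


def select_family(
    durations,
    families=FIT_FAMILIES,
    n_bootstrap: int = 0,
    rng_seed: int = 0,
    criterion: str = "loglik",
    fit_floor: float = 0.0,
) -> list[DistFit]:
    """Fit candidate families and rank them (best first).

    ``criterion='loglik'`` ranks by log-likelihood; ``'bic'`` penalises
    parameter count.  The KS statistic is always reported; a bootstrap p
    value is attached when ``n_bootstrap > 0``.  Pass the acquisition
    floor as ``fit_floor`` when the durations come from a binned window:
    comparing unconditioned likelihoods on floor-truncated data biases the
    ranking toward power laws.
    """
    families = list(families)
    if not families:
        raise ValueError("need at least one family")
    if criterion not in ("loglik", "bic"):
        raise ValueError("criterion must be 'loglik' or 'bic'")
    t = np.asarray(durations, dtype=float)
    fits = []
    for fam in families:
        try:
            fit = fit_mle(t, fam, fit_floor)
        except ValueError:
            continue
        d = _ks_statistic(t, fit)
        fit = replace(fit, ks_D=d)
        if n_bootstrap > 0:
            _, p = goodness_of_fit(t, fit, n_bootstrap, rng_seed)
            fit = replace(fit, ks_p=p)
        fits.append(fit)
    if not fits:
        raise ValueError("no family could be fitted")
    key = (lambda f: -f.log_likelihood) if criterion == "loglik" else (lambda f: f.bic)
    return sorted(fits, key=key)


# ---------------------------------------------------------------------------
# Estimator facade


class DurationFitter(BaseEstimator):
    """Sklearn-style wrapper around `fit_mle` / `goodness_of_fit`.

    Parameters
    ----------
    family : str
        One of ``FIT_FAMILIES``.
    fit_floor : float
        Condition the likelihood on ``t >= fit_floor`` (0 disables).
    n_bootstrap : int
        Bootstrap replicates for the KS p value (0 skips it).
    random_state : int
        Bootstrap seed.

    Attributes
    ----------
    fit_ : DistFit
    params_ : dict
    log_likelihood_ : float
    ks_d_ : float
    ks_p_ : float or None
    """

    def __init__(self, family: str = "lognormal", fit_floor: float = 0.0,
                 n_bootstrap: int = 0, random_state: int = 0):
        self.family = family
        self.fit_floor = fit_floor
        self.n_bootstrap = n_bootstrap
        self.random_state = random_state

    def fit(self, durations, y=None):
        t = np.asarray(durations, dtype=float).ravel()
        fit = fit_mle(t, self.family, self.fit_floor)
        d = _ks_statistic(t, fit)
        p = None
        if self.n_bootstrap > 0:
            _, p = goodness_of_fit(t, fit, self.n_bootstrap, self.random_state)
        self.fit_ = replace(fit, ks_D=d, ks_p=p)
        self.params_ = self.fit_.params
        self.log_likelihood_ = self.fit_.log_likelihood
        self.ks_d_ = d
        self.ks_p_ = p
        return self
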