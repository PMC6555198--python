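"""Maximum-likelihood fitting of six positive-support distribution families
with AIC-based model comparison, plus an ECDF helper and a power-law-backed
low-expression cutoff report.

Families and parameterizations
------------------------------
lognormal   mu, sigma            logs are Normal(mu, sigma)
pareto      alpha, xmin          density alpha * xmin^alpha / x^(alpha+1), x >= xmin
loglogistic shape c, scale       scipy ``fisk``
gamma       shape, scale         scipy ``gamma`` with loc fixed at 0
weibull     shape, scale         scipy ``weibull_min`` with loc fixed at 0
burr        c, k, scale          Burr type XII:
                                 f(x) = (c*k/s)(x/s)^(c-1) [1+(x/s)^c]^(-(k+1))
                                 (scipy ``burr12`` with c=c, d=k)

Closed-form MLEs are used for lognormal (mean/sd of logs, population sd) and
Pareto (location at the sample minimum, shape = n / sum(log(x/xmin))); the
remaining families use multi-start L-BFGS-B on log-parameters.  Zeros are
excluded before fitting (all supports are strictly positive) and counted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from transtat.exceptions import ValidationError

__all__ = [
    "FAMILIES",
    "DistributionFit",
    "FitComparison",
    "ECDF",
    "ecdf",
    "fit_family",
    "compare_fits",
    "powerlaw_cutoff",
    "CutoffReport",
]

FAMILIES = ("lognormal", "pareto", "loglogistic", "gamma", "weibull", "burr")

_N_PARAMS = {
    "lognormal": 2,
    "pareto": 2,
    "loglogistic": 2,
    "gamma": 2,
    "weibull": 2,
    "burr": 3,
}

_OPT_TOL = 1e-8


@dataclass
class DistributionFit:
    """One fitted family: MLE parameters, log-likelihood, and AIC."""

    family: str
    params: dict[str, float]
    loglik: float
    aic: float
    n: int
    converged: bool
    gradient_norm: float | None = None
    n_zeros_excluded: int = 0

    @property
    def n_params(self) -> int:
        return _N_PARAMS[self.family]

    def frozen(self):
        """The scipy frozen distribution for these parameters."""
        return _frozen(self.family, self.params)


@dataclass
class FitComparison:
    """Converged fits sorted ascending by AIC (ties: fewer parameters first)."""

    fits: list[DistributionFit]

    @property
    def best(self) -> DistributionFit:
        return self.fits[0]

    @property
    def best_family(self) -> str:
        return self.fits[0].family


def _frozen(family: str, params: dict[str, float]):
    if family == "lognormal":
        return stats.lognorm(s=params["sigma"], scale=math.exp(params["mu"]))
    if family == "pareto":
        return stats.pareto(b=params["alpha"], scale=params["xmin"])
    if family == "loglogistic":
        return stats.fisk(c=params["shape"], scale=params["scale"])
    if family == "gamma":
        return stats.gamma(a=params["shape"], scale=params["scale"])
    if family == "weibull":
        return stats.weibull_min(c=params["shape"], scale=params["scale"])
    if family == "burr":
        return stats.burr12(c=params["c"], d=params["k"], scale=params["scale"])
    raise ValidationError(f"unknown distribution family: {family!r}")


def _positive_values(values, context: str) -> tuple[np.ndarray, int]:
    x = np.asarray(values, dtype=float).ravel()
    if np.any(~np.isfinite(x)) or np.any(x < 0):
        raise ValidationError(f"{context}: values must be finite and non-negative")
    n_zeros = int(np.sum(x == 0))
    x = x[x > 0]
    if x.size == 0:
        raise ValidationError(f"{context}: no positive values")
    return x, n_zeros


@dataclass
class ECDF:
    """Right-continuous empirical CDF reaching 1 at the sample maximum."""

    support: np.ndarray
    probabilities: np.ndarray
    n: int
    n_zeros_excluded: int = 0

    def __call__(self, q) -> np.ndarray | float:
        q = np.asarray(q, dtype=float)
        idx = np.searchsorted(self.support, q, side="right")
        out = np.where(idx == 0, 0.0, self.probabilities[np.maximum(idx - 1, 0)])
        return float(out) if out.ndim == 0 else out


def ecdf(values) -> ECDF:
    """Empirical CDF of the positive values (zeros dropped with a count)."""
    x, n_zeros = _positive_values(values, "ecdf")
    if x.size < 2:
        raise ValidationError("ecdf requires at least 2 positive values")
    support, counts = np.unique(x, return_counts=True)
    probs = np.cumsum(counts) / x.size
    return ECDF(support=support, probabilities=probs, n=int(x.size), n_zeros_excluded=n_zeros)


# ---------------------------------------------------------------------------
# Closed-form estimators
# ---------------------------------------------------------------------------

def _fit_lognormal_closed(x: np.ndarray) -> tuple[dict[str, float], float, bool]:
    logs = np.log(x)
    mu = float(logs.mean())
    sigma = float(logs.std(ddof=0))  # ML uses the population sd
    if sigma == 0.0:
        # Degenerate: all values identical; the likelihood is unbounded.
        return {"mu": mu, "sigma": 0.0}, math.inf, False
    loglik = float(stats.lognorm(s=sigma, scale=math.exp(mu)).logpdf(x).sum())
    return {"mu": mu, "sigma": sigma}, loglik, True


def _fit_pareto_closed(x: np.ndarray) -> tuple[dict[str, float], float, bool]:
    xmin = float(x.min())
    denom = float(np.log(x / xmin).sum())
    if denom == 0.0:
        return {"alpha": math.inf, "xmin": xmin}, math.inf, False
    alpha = x.size / denom
    loglik = float(stats.pareto(b=alpha, scale=xmin).logpdf(x).sum())
    return {"alpha": float(alpha), "xmin": xmin}, loglik, True


# ---------------------------------------------------------------------------
# Numerical MLE: multi-start L-BFGS-B in unconstrained (mostly log) space
# ---------------------------------------------------------------------------

# Each entry: (param names, to_params(z), to_z(params), heuristic start in z)
def _heuristic_start(family: str, x: np.ndarray) -> np.ndarray:
    logs = np.log(x)
    m, s = float(logs.mean()), float(max(logs.std(ddof=0), 1e-3))
    if family == "lognormal":
        return np.array([m, math.log(s)])
    if family == "pareto":
        xmin = float(x.min())
        denom = max(float(np.log(x / xmin).sum()), 1e-9)
        return np.array([math.log(max(x.size / denom, 1e-6))])
    if family == "loglogistic":
        # logistic sd in log space = (pi / sqrt(3)) / c
        c = (math.pi / math.sqrt(3.0)) / s
        return np.array([math.log(c), m])
    if family == "gamma":
        mean, var = float(x.mean()), float(max(x.var(ddof=0), 1e-12))
        shape = max(mean * mean / var, 1e-3)
        return np.array([math.log(shape), math.log(mean / shape)])
    if family == "weibull":
        # sd of log Weibull = (pi / sqrt(6)) / shape; mean = log(scale) - gamma/shape
        shape = (math.pi / math.sqrt(6.0)) / s
        return np.array([math.log(shape), m + 0.5772156649 / shape])
    if family == "burr":
        c = (math.pi / math.sqrt(3.0)) / s
        return np.array([math.log(c), 0.0, m])  # k starts at 1 (loglogistic)
    raise ValidationError(f"unknown distribution family: {family!r}")


def _exp(v: float) -> float:
    # np.exp never raises; overflow becomes inf and is penalized in _nll
    with np.errstate(over="ignore"):
        return float(np.exp(v))


def _z_to_params(family: str, z: np.ndarray) -> dict[str, float]:
    if family == "lognormal":
        return {"mu": float(z[0]), "sigma": _exp(z[1])}
    if family == "pareto":
        return {"alpha": _exp(z[0]), "xmin": float("nan")}  # filled later
    if family == "loglogistic":
        return {"shape": _exp(z[0]), "scale": _exp(z[1])}
    if family == "gamma":
        return {"shape": _exp(z[0]), "scale": _exp(z[1])}
    if family == "weibull":
        return {"shape": _exp(z[0]), "scale": _exp(z[1])}
    if family == "burr":
        return {"c": _exp(z[0]), "k": _exp(z[1]), "scale": _exp(z[2])}
    raise ValidationError(f"unknown distribution family: {family!r}")


def _nll(family: str, z: np.ndarray, x: np.ndarray, xmin: float) -> float:
    params = _z_to_params(family, z)
    if family == "pareto":
        params["xmin"] = xmin
    vals = [v for k, v in params.items() if k != "xmin"]
    if not all(np.isfinite(vals)) or any(v > 1e12 for v in vals):
        return 1e12
    with np.errstate(all="ignore"):
        lp = _frozen(family, params).logpdf(x)
    if not np.all(np.isfinite(lp)):
        return 1e12
    return float(-lp.sum())


def _fit_numeric(family: str, x: np.ndarray) -> tuple[dict[str, float], float, bool, float]:
    xmin = float(x.min())
    z0 = _heuristic_start(family, x)
    starts = [z0, z0 + 0.5, z0 - 0.5]
    best = None
    for start in starts:
        res = optimize.minimize(
            lambda z: _nll(family, z, x, xmin),
            start,
            method="L-BFGS-B",
            options={"ftol": 1e-15, "gtol": _OPT_TOL, "maxiter": 1000},
        )
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    params = _z_to_params(family, best.x)
    if family == "pareto":
        params["xmin"] = xmin
    grad_norm = float(np.linalg.norm(np.atleast_1d(best.jac)))
    converged = bool(best.fun < 1e11) and (bool(best.success) or grad_norm < 1e-1)
    return params, float(-best.fun), converged, grad_norm


def fit_family(values, family: str, method: str = "auto") -> DistributionFit:
    """Fit one family by maximum likelihood.

    ``method``: "auto" uses closed forms where available (lognormal, Pareto)
    and numerical optimization otherwise; "closed" forces the closed form
    (error if none exists); "numeric" forces the optimizer.
    """
    if family not in FAMILIES:
        raise ValidationError(
            f"unknown distribution family: {family!r}; choose from {', '.join(FAMILIES)}"
        )
    if method not in ("auto", "closed", "numeric"):
        raise ValidationError(f"unknown fit method: {method!r}")
    x, n_zeros = _positive_values(values, f"fit_family({family})")
    if x.size < 30:
        warnings.warn(
            f"fitting {family} with only {x.size} positive values; "
            "estimates may be unstable",
            stacklevel=2,
        )

    grad_norm: float | None = None
    if method in ("auto", "closed") and family in ("lognormal", "pareto"):
        if family == "lognormal":
            params, loglik, converged = _fit_lognormal_closed(x)
        else:
            params, loglik, converged = _fit_pareto_closed(x)
    elif method == "closed":
        raise ValidationError(f"no closed-form estimator for family {family!r}")
    else:
        params, loglik, converged, grad_norm = _fit_numeric(family, x)

    k = _N_PARAMS[family]
    aic = 2.0 * k - 2.0 * loglik
    return DistributionFit(
        family=family,
        params=params,
        loglik=loglik,
        aic=aic,
        n=int(x.size),
        converged=converged,
        gradient_norm=grad_norm,
        n_zeros_excluded=n_zeros,
    )


def compare_fits(values, families=None) -> FitComparison:
    """Fit the requested families and rank the converged ones by AIC.

    Ties in AIC rank the family with fewer free parameters first.
    Non-converged fits are excluded; if none converge, an error is raised.
    """
    families = list(families) if families is not None else list(FAMILIES)
    for fam in families:
        if fam not in FAMILIES:
            raise ValidationError(f"unknown distribution family: {fam!r}")
    fits = [fit_family(values, fam) for fam in families]
    converged = [f for f in fits if f.converged]
    if not converged:
        raise ValidationError("no distribution family converged")
    converged.sort(key=lambda f: (f.aic, f.n_params, f.family))
    return FitComparison(fits=converged)


@dataclass
class CutoffReport:
    """Fraction of values below a low-expression threshold, plus the Pareto
    fit to the values at or above it."""

    threshold: float
    n_total: int
    n_below: int
    fraction_below: float
    fit_above: DistributionFit
    n_zeros_excluded: int = 0


def powerlaw_cutoff(values, threshold: float = 10.0) -> CutoffReport:
    """Report how much of the sample falls strictly below ``threshold`` and
    fit a Pareto tail to the rest (default threshold 10, in FPKM units)."""
    x, n_zeros = _positive_values(values, "powerlaw_cutoff")
    if threshold > x.max():
        raise ValidationError(
            f"threshold {threshold} exceeds the maximum value {x.max()}"
        )
    n_below = int(np.sum(x < threshold))
    tail = x[x >= threshold]
    fit = fit_family(tail, "pareto")
    return CutoffReport(
        threshold=float(threshold),
        n_total=int(x.size),
        n_below=n_below,
        fraction_below=n_below / x.size,
        fit_above=fit,
        n_zeros_excluded=n_zeros,
    )
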