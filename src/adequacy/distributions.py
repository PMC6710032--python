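"""Lifetime distribution specifications and the two built-in families.

A :class:`DistributionSpec` bundles a pdf/cdf pair with its support and an
optional parameter box, which is everything the fitting machinery needs.
Two families ship built in:

* the exponentiated Weibull, cdf ``F(x; alpha, beta, a) =
  {1 - exp[-(alpha x)^beta]}^a`` on (0, inf), parameter order
  (alpha, beta, a);
* the Kumaraswamy-beta, cdf ``F(x) = 1 - {1 - I_x(alpha, beta)^a}^b`` on
  (0, 1) with ``I_x`` the regularized incomplete beta function, parameter
  order (beta, a, alpha, b).

The parameter orders match the vectors the fitting reports print, so a
reported MLE aligns index-by-index with the family definition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Tuple

import numpy as np
from scipy import integrate, optimize, stats

__all__ = [
    "DistributionSpec",
    "exp_weibull_pdf",
    "exp_weibull_cdf",
    "exp_weibull_quantile",
    "kw_beta_pdf",
    "kw_beta_cdf",
    "hazard",
    "sample",
    "validate_spec",
    "ValidationReport",
    "get_distribution",
    "BUILTIN_DISTRIBUTIONS",
]


@dataclass(frozen=True)
class DistributionSpec:
    """A univariate family: pdf/cdf callables, support and parameter box.

    ``pdf`` and ``cdf`` have signature ``(params, x)`` and must be
    vectorized over ``x``. ``support`` is an open interval; the default
    (0, inf) suits lifetime data. ``quantile`` is optional; when absent,
    sampling inverts the cdf numerically.
    """

    name: str
    n_params: int
    pdf: Callable
    cdf: Callable
    support: Tuple[float, float] = (0.0, math.inf)
    param_lower: Optional[np.ndarray] = None
    param_upper: Optional[np.ndarray] = None
    quantile: Optional[Callable] = None

    def in_support(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        lo, hi = self.support
        return (x > lo) & (x < hi)


def _check_params(params, k: int, name: str) -> np.ndarray:
    params = np.asarray(params, dtype=float).ravel()
    if params.size != k:
        raise ValueError(f"{name} takes {k} parameters, got {params.size}")
    if not np.all(np.isfinite(params)) or np.any(params <= 0):
        raise ValueError(f"{name} parameters must be positive and finite")
    return params


def exp_weibull_pdf(params, x):
    """Exponentiated Weibull density, params (alpha, beta, a), x > 0."""
    alpha, beta, a = _check_params(params, 3, "exp_weibull")
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("exp_weibull support is (0, inf)")
    z = (alpha * x) ** beta
    return alpha * beta * a * np.exp(-z) * (alpha * x) ** (beta - 1.0) * (
        1.0 - np.exp(-z)
    ) ** (a - 1.0)


def exp_weibull_cdf(params, x):
    """Exponentiated Weibull cdf {1 - exp[-(alpha x)^beta]}^a."""
    alpha, beta, a = _check_params(params, 3, "exp_weibull")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("exp_weibull support is (0, inf)")
    return (1.0 - np.exp(-((alpha * x) ** beta))) ** a


def exp_weibull_quantile(params, u):
    """Closed-form quantile x = (1/alpha) * [-ln(1 - u^(1/a))]^(1/beta)."""
    alpha, beta, a = _check_params(params, 3, "exp_weibull")
    u = np.asarray(u, dtype=float)
    return (1.0 / alpha) * (-np.log1p(-(u ** (1.0 / a)))) ** (1.0 / beta)


def kw_beta_pdf(params, x):
    """Kumaraswamy-beta density, params (beta, a, alpha, b), x in (0, 1).

    pdf = a b g(x; alpha, beta) G^(a-1) (1 - G^a)^(b-1) with G the
    beta(alpha, beta) cdf and g its density.
    """
    beta_p, a, alpha, b = _check_params(params, 4, "kw_beta")
    x = np.asarray(x, dtype=float)
    if np.any((x <= 0) | (x >= 1)):
        raise ValueError("kw_beta support is (0, 1)")
    # log-space evaluation: near the endpoints the direct product is a 0*inf
    # indeterminate even though the density limit is finite
    logG = stats.beta.logcdf(x, alpha, beta_p)
    logsf = stats.beta.logsf(x, alpha, beta_p)
    t = a * logG
    with np.errstate(divide="ignore", invalid="ignore"):
        # log(1 - G^a): -expm1 form away from G=1, a*(1-G) expansion at G=1
        safe_t = np.where(t < -1e-8, t, -1.0)
        log1mGa = np.where(
            t < -1e-8, np.log(-np.expm1(safe_t)), np.log(a) + logsf
        )
        logpdf = (
            np.log(a)
            + np.log(b)
            + stats.beta.logpdf(x, alpha, beta_p)
            + (a - 1.0) * logG
            + (b - 1.0) * log1mGa
        )
        out = np.exp(logpdf)
    return np.where(np.isnan(out), 0.0, out)


def kw_beta_cdf(params, x):
    """Kumaraswamy-beta cdf 1 - {1 - I_x(alpha, beta)^a}^b."""
    beta_p, a, alpha, b = _check_params(params, 4, "kw_beta")
    x = np.asarray(x, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("kw_beta support is (0, 1)")
    G = stats.beta.cdf(x, alpha, beta_p)
    return 1.0 - (1.0 - G**a) ** b


def hazard(dist: DistributionSpec, params, x):
    """Hazard rate h(x) = f(x) / (1 - F(x)); +inf where F(x) reaches 1."""
    f = np.asarray(dist.pdf(params, x), dtype=float)
    F = np.asarray(dist.cdf(params, x), dtype=float)
    surv = 1.0 - F
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(surv > 0.0, f / np.where(surv > 0.0, surv, 1.0), np.inf)
    return h


def _invert_cdf_scalar(cdf_x, u, support, tol=1e-12):
    lo, hi = support
    # establish a finite bracket inside the open support
    left = lo + 1e-12 if np.isfinite(lo) else -1.0
    right = hi - 1e-12 if np.isfinite(hi) else 1.0
    while not np.isfinite(lo) and cdf_x(left) > u:
        left *= 2.0
    while not np.isfinite(hi) and cdf_x(right) < u:
        right *= 2.0
        if right > 1e300:
            raise ValueError("cdf inversion failed: flat or non-invertible cdf")
    if np.isfinite(hi) and cdf_x(right) < u:
        raise ValueError("cdf inversion failed: cdf does not reach u on support")
    return optimize.brentq(lambda t: cdf_x(t) - u, left, right, xtol=tol)


def sample(
    dist: DistributionSpec,
    params,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw n values by inverse-cdf sampling.

    Uses the closed-form quantile when the spec provides one; otherwise each
    uniform draw is inverted through the cdf by bracketed root finding.
    """
    u = rng.uniform(size=n)
    if dist.quantile is not None:
        return np.asarray(dist.quantile(params, u), dtype=float)
    cdf_x = lambda t: float(dist.cdf(params, t))
    return np.array([_invert_cdf_scalar(cdf_x, ui, dist.support) for ui in u])


@dataclass
class ValidationReport:
    passed: bool
    messages: List[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.passed


def validate_spec(
    dist: DistributionSpec,
    params,
    integral_tol: float = 1e-3,
    grid_size: int = 200,
) -> ValidationReport:
    """Check that the supplied pdf/cdf pair is a genuine distribution.

    Verifies, at the given parameter values: the pdf integrates to one over
    the support (adaptive quadrature, tolerance ``integral_tol``); the cdf
    is non-decreasing on a grid with limits 0 and 1 at the support
    endpoints; and the numerical derivative of the cdf agrees with the pdf.
    Returns a report rather than raising, so callers can surface messages.
    """
    messages: List[str] = []
    lo, hi = dist.support

    total, _ = integrate.quad(
        lambda t: float(dist.pdf(params, t)), lo, hi, limit=200
    )
    if abs(total - 1.0) > integral_tol:
        messages.append(
            f"pdf does not integrate to one over the support (got {total:.6g})"
        )

    # probe the bulk of the distribution through cdf levels
    right = hi
    if not np.isfinite(hi):
        right = 1.0
        while float(dist.cdf(params, right)) < 0.999 and right < 1e6:
            right *= 2.0
    left = lo if np.isfinite(lo) else -right
    grid = np.linspace(left + 1e-9 * (right - left), right, grid_size)
    F = np.asarray(dist.cdf(params, grid), dtype=float)
    if np.any(np.diff(F) < -1e-12):
        messages.append("cdf is not non-decreasing")
    if np.any((F < -1e-12) | (F > 1 + 1e-12)):
        messages.append("cdf leaves [0, 1]")

    h = (grid[-1] - grid[0]) / (10.0 * grid_size)
    mid = grid[1:-1]
    dF = (
        np.asarray(dist.cdf(params, mid + h), dtype=float)
        - np.asarray(dist.cdf(params, mid - h), dtype=float)
    ) / (2.0 * h)
    f = np.asarray(dist.pdf(params, mid), dtype=float)
    if np.max(np.abs(dF - f)) > 1e-3 * max(1.0, float(np.max(np.abs(f)))):
        messages.append("numerical derivative of cdf does not match pdf")

    F_hi = float(dist.cdf(params, right))
    if np.isfinite(hi) and abs(F_hi - 1.0) > 1e-6:
        messages.append("cdf does not reach 1 at the upper support endpoint")

    return ValidationReport(passed=not messages, messages=messages)


BUILTIN_DISTRIBUTIONS = {
    "exp_weibull": DistributionSpec(
        name="exp_weibull",
        n_params=3,
        pdf=exp_weibull_pdf,
        cdf=exp_weibull_cdf,
        support=(0.0, math.inf),
        quantile=exp_weibull_quantile,
    ),
    "kw_beta": DistributionSpec(
        name="kw_beta",
        n_params=4,
        pdf=kw_beta_pdf,
        cdf=kw_beta_cdf,
        support=(0.0, 1.0),
    ),
}


def get_distribution(name: str) -> DistributionSpec:
    try:
        return BUILTIN_DISTRIBUTIONS[name]
    except KeyError:
        raise KeyError(
            f"unknown distribution {name!r}; "
            f"choose from {sorted(BUILTIN_DISTRIBUTIONS)}"
        ) from None
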