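"""Corrected Cramér-von Mises / Anderson-Darling statistics and friends.

The corrected statistics W* and A* assess how well a fitted continuous cdf
F(.; theta_hat) explains a sample. The probability transform runs in three
steps: v_i = F(x_(i); theta_hat) at the sorted data, y_i = Phi^{-1}(v_i),
then u_i = Phi((y_i - ybar)/s_y) with the sample mean and standard
deviation of the y_i. On the u_i,

    W^2 = sum_i [u_i - (2i-1)/(2n)]^2 + 1/(12n)
    A^2 = -n - (1/n) sum_i [(2i-1) ln u_i + (2n+1-2i) ln(1-u_i)]

and the small-sample corrections are W* = W^2 (1 + 0.5/n) and
A* = A^2 (1 + 0.75/n + 2.25/n^2). Lower values indicate a better fit.

The module also provides the AIC/CAIC/BIC/HQIC information criteria, the
one-sample Kolmogorov-Smirnov test against the fitted cdf, and standard
errors from the inverse numerical Hessian of the negative log-likelihood.
Note that KS p-values computed against a cdf with estimated parameters are
anti-conservative; they are reported as-is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, NamedTuple, Optional, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "GofInput",
    "compute_u",
    "cramer_von_mises",
    "anderson_darling",
    "InformationCriteria",
    "information_criteria",
    "ks_test",
    "numerical_hessian",
    "standard_errors",
]

_CLAMP = 1e-10


@dataclass(frozen=True)
class GofInput:
    """Probability-transformed sample used by W*/A*."""

    data: np.ndarray  # sorted ascending
    cdf_values: np.ndarray  # v_i = F(x_(i))
    normal_scores: np.ndarray  # y_i = Phi^{-1}(v_i)
    u_values: np.ndarray  # u_i = Phi((y_i - ybar)/s_y)
    n: int


def compute_u(data, cdf_at_mle: Callable) -> GofInput:
    """Sort the data and apply the v -> y -> u probability transform.

    cdf values outside (0, 1) are clamped to [1e-10, 1 - 1e-10] with a
    warning before the normal quantile is taken. Requires n >= 2 (the
    transform standardizes by the sample standard deviation of the y_i).
    """
    data = np.sort(np.asarray(data, dtype=float))
    n = data.size
    if n < 2:
        raise ValueError("at least two observations are required")
    v = np.asarray(cdf_at_mle(data), dtype=float)
    if np.any((v <= 0.0) | (v >= 1.0)):
        warnings.warn(
            "fitted cdf values outside (0, 1) were clamped", RuntimeWarning
        )
        v = np.clip(v, _CLAMP, 1.0 - _CLAMP)
    y = stats.norm.ppf(v)
    s_y = float(np.std(y, ddof=1))
    if s_y == 0.0:
        raise ValueError("degenerate probability transform: s_y = 0")
    u = stats.norm.cdf((y - y.mean()) / s_y)
    u = np.clip(u, _CLAMP, 1.0 - _CLAMP)
    return GofInput(data=data, cdf_values=v, normal_scores=y, u_values=u, n=n)


def cramer_von_mises(u) -> Tuple[float, float]:
    """Return (W^2, W*) from the transformed sample u (sorted internally)."""
    u = np.sort(np.asarray(u, dtype=float))
    n = u.size
    i = np.arange(1, n + 1)
    W2 = float(np.sum((u - (2.0 * i - 1.0) / (2.0 * n)) ** 2) + 1.0 / (12.0 * n))
    W_star = W2 * (1.0 + 0.5 / n)
    return W2, W_star


def anderson_darling(u) -> Tuple[float, float]:
    """Return (A^2, A*) from the transformed sample u (sorted internally)."""
    u = np.sort(np.asarray(u, dtype=float))
    n = u.size
    if np.any((u <= 0.0) | (u >= 1.0)):
        raise ValueError("degenerate probability transform: u at 0 or 1")
    i = np.arange(1, n + 1)
    A2 = float(
        -n
        - np.sum((2.0 * i - 1.0) * np.log(u) + (2.0 * n + 1.0 - 2.0 * i) * np.log1p(-u))
        / n
    )
    A_star = A2 * (1.0 + 0.75 / n + 2.25 / n**2)
    return A2, A_star


class InformationCriteria(NamedTuple):
    aic: float
    caic: float
    bic: float
    hqic: float


def information_criteria(
    neg_loglik_min: float, k: int, n: int
) -> InformationCriteria:
    """AIC, CAIC (small-sample corrected), BIC and HQIC from min(-log L).

    With ell = min(-log L): AIC = 2k + 2 ell, CAIC = AIC + 2k(k+1)/(n-k-1),
    BIC = k ln n + 2 ell, HQIC = 2k ln(ln n) + 2 ell. CAIC is NaN (with a
    warning) when n <= k + 1.
    """
    ell = float(neg_loglik_min)
    aic = 2.0 * k + 2.0 * ell
    if n > k + 1:
        caic = aic + 2.0 * k * (k + 1.0) / (n - k - 1.0)
    else:
        warnings.warn("CAIC undefined for n <= k + 1", RuntimeWarning)
        caic = float("nan")
    bic = k * np.log(n) + 2.0 * ell
    hqic = 2.0 * k * np.log(np.log(n)) + 2.0 * ell if n >= 3 else float("nan")
    return InformationCriteria(aic, caic, bic, float(hqic))


def ks_test(data, cdf_at_mle: Callable) -> Tuple[float, float]:
    """Two-sided one-sample Kolmogorov-Smirnov test against a fitted cdf.

    Returns (D, p). With ties in the data the exact p-value is invalid and
    the asymptotic one is used, with a warning.
    """
    data = np.asarray(data, dtype=float)
    mode = "auto"
    if np.unique(data).size < data.size:
        warnings.warn(
            "ties in data: Kolmogorov-Smirnov p-value is approximate",
            RuntimeWarning,
        )
        mode = "asymp"
    res = stats.kstest(data, cdf_at_mle, mode=mode)
    return float(res.statistic), float(res.pvalue)


def numerical_hessian(
    f: Callable, x, step: Optional[np.ndarray] = None
) -> np.ndarray:
    """Central-difference Hessian of a scalar function at x.

    Per-parameter step defaults to max(1e-5, 1e-4 |x_j|).
    """
    x = np.asarray(x, dtype=float)
    k = x.size
    if step is None:
        step = np.maximum(1e-5, 1e-4 * np.abs(x))
    else:
        step = np.broadcast_to(np.asarray(step, dtype=float), (k,)).copy()
    H = np.empty((k, k))
    f0 = float(f(x))
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = step[i]
        H[i, i] = (float(f(x + ei)) - 2.0 * f0 + float(f(x - ei))) / step[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = step[j]
            H[i, j] = H[j, i] = (
                float(f(x + ei + ej))
                - float(f(x + ei - ej))
                - float(f(x - ei + ej))
                + float(f(x - ei - ej))
            ) / (4.0 * step[i] * step[j])
    return H


def standard_errors(neg_loglik: Callable, mle) -> np.ndarray:
    """Standard errors as sqrt(diag(H^-1)) of the Hessian of -log L at the MLE.

    Components whose inverse-Hessian diagonal entry is non-positive (the
    Hessian is not positive definite there) come back as NaN with a warning.
    """
    mle = np.asarray(mle, dtype=float)
    H = numerical_hessian(neg_loglik, mle)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        warnings.warn("singular Hessian: standard errors unavailable", RuntimeWarning)
        return np.full(mle.size, np.nan)
    diag = np.diag(cov)
    if np.any(diag <= 0):
        warnings.warn(
            "Hessian not positive definite: some standard errors undefined",
            RuntimeWarning,
        )
    with np.errstate(invalid="ignore"):
        return np.where(diag > 0, np.sqrt(np.abs(diag)), np.nan)
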