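"""Maximum-likelihood fitting of lifetime distributions with adequacy checks.

The central objects follow the Model/Results convention of the statistical
modelling stack: :class:`LifetimeModel` is built from a sample and a
:class:`~adequacy.distributions.DistributionSpec`; its :meth:`fit` minimizes
the negative log-likelihood — by the box-constrained particle swarm
optimizer (default) or a classical local method — and returns a
:class:`LifetimeFitResults` carrying the MLEs, standard errors from the
inverse numerical Hessian, the corrected Cramér-von Mises and
Anderson-Darling statistics, the Kolmogorov-Smirnov test and the four
information criteria, with a ``summary()`` table.

Standard errors are not computed after a swarm fit by default (the swarm
returns no curvature information; errors can still be requested
explicitly), mirroring the usual practice for heuristic optimizers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy import optimize

from . import gof
from .distributions import DistributionSpec, get_distribution, sample
from .pso import Bounds, PSOConfig, PSOResult, pso

__all__ = [
    "LifetimeModel",
    "LifetimeFitResults",
    "neg_log_likelihood",
    "fit_distribution",
    "METHOD_ALIASES",
]

METHOD_ALIASES = {
    "P": "PSO",
    "PSO": "PSO",
    "B": "BFGS",
    "BFGS": "BFGS",
    "N": "Nelder-Mead",
    "NELDER-MEAD": "Nelder-Mead",
    "S": "SANN",
    "SANN": "SANN",
    "C": "CG",
    "CG": "CG",
}


def neg_log_likelihood(dist: DistributionSpec, params, data) -> float:
    """-sum(log f(x_i; params)); +inf for infeasible parameter vectors.

    Data outside the declared support is an error (the fit must not
    silently drop points); parameter vectors where the density is zero,
    negative or undefined signal infeasibility to the optimizer via +inf.
    """
    data = np.asarray(data, dtype=float)
    inside = dist.in_support(data)
    if not np.all(inside):
        idx = int(np.argmin(inside))
        raise ValueError(
            f"observation at index {idx} ({data[idx]!r}) is outside the "
            f"support {dist.support}"
        )
    try:
        with np.errstate(all="ignore"):
            f = np.asarray(dist.pdf(params, data), dtype=float)
    except (ValueError, FloatingPointError):
        return float("inf")
    if np.any(~np.isfinite(f)) or np.any(f <= 0.0):
        return float("inf")
    return float(-np.sum(np.log(f)))


@dataclass
class LifetimeFitResults:
    """Estimates and adequacy statistics from a :class:`LifetimeModel` fit.

    Attributes mirror the usual goodness-of-fit report: ``params`` (MLEs in
    the family's declared order), ``bse`` (standard errors, may be None),
    ``w_star``/``a_star`` (corrected Cramér-von Mises and Anderson-Darling),
    ``ks_stat``/``ks_pvalue``, the four information criteria, and
    ``neg_loglik`` (the minimized -log L).
    """

    model: "LifetimeModel"
    params: np.ndarray
    bse: Optional[np.ndarray]
    w_star: float
    a_star: float
    ks_stat: float
    ks_pvalue: float
    aic: float
    caic: float
    bic: float
    hqic: float
    neg_loglik: float
    converged: bool
    method: str
    optimizer_result: object = None

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def k_params(self) -> int:
        return self.model.dist.n_params

    def simulate(self, n: int, rng=None) -> np.ndarray:
        """Draw a synthetic sample of size n from the fitted distribution."""
        if rng is None:
            rng = np.random.default_rng()
        return sample(self.model.dist, self.params, n, rng)

    def to_dict(self) -> dict:
        """Serializable report; key names follow the classic output block."""
        return {
            "W": self.w_star,
            "A": self.a_star,
            "KS": {"D": self.ks_stat, "p_value": self.ks_pvalue},
            "mle": list(map(float, self.params)),
            "AIC": self.aic,
            "CAIC": self.caic,
            "BIC": self.bic,
            "HQIC": self.hqic,
            "Erro": None if self.bse is None else list(map(float, self.bse)),
            "Value": self.neg_loglik,
            "Convergence": 0 if self.converged else 1,
        }

    def summary(self) -> str:
        lines = [
            f"Lifetime distribution fit: {self.model.dist.name}",
            "=" * 58,
            f"Method: {self.method:<22} N obs: {self.nobs}",
            f"Converged: {str(self.converged):<19} min(-log L): "
            f"{self.neg_loglik:.6g}",
            "-" * 58,
            f"{'param':>8} {'estimate':>14} {'std err':>14}",
        ]
        for j, val in enumerate(self.params):
            se = "-" if self.bse is None else f"{self.bse[j]:14.6g}"
            lines.append(f"{f'theta_{j + 1}':>8} {val:14.6g} {se:>14}")
        lines += [
            "-" * 58,
            f"W* = {self.w_star:.6g}    A* = {self.a_star:.6g}",
            f"KS D = {self.ks_stat:.6g} (p = {self.ks_pvalue:.4g})",
            f"AIC = {self.aic:.6g}  CAIC = {self.caic:.6g}  "
            f"BIC = {self.bic:.6g}  HQIC = {self.hqic:.6g}",
            "=" * 58,
        ]
        return "\n".join(lines)

    def plot_fit(self, ax=None, bins="auto"):
        """Histogram of the data with the fitted density overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        data = self.model.data
        ax.hist(data, bins=bins, density=True, alpha=0.5, label="data")
        pad = 0.05 * (data.max() - data.min())
        lo = max(self.model.dist.support[0] + 1e-9, data.min() - pad)
        hi = min(self.model.dist.support[1] - 1e-9, data.max() + pad)
        grid = np.linspace(lo, hi, 400)
        ax.plot(grid, self.model.dist.pdf(self.params, grid),
                label=self.model.dist.name)
        ax.set_xlabel("x")
        ax.set_ylabel("density")
        ax.legend()
        return ax


class LifetimeModel:
    """Maximum-likelihood model for a univariate lifetime sample.

    Parameters
    ----------
    data : array-like
        Observations; every value must lie inside the distribution's
        support.
    dist : DistributionSpec or str
        The family to fit, either a spec object or the name of a built-in
        ("exp_weibull", "kw_beta").
    """

    def __init__(self, data, dist: Union[DistributionSpec, str]):
        if isinstance(dist, str):
            dist = get_distribution(dist)
        self.dist = dist
        self.data = np.asarray(data, dtype=float)
        if self.data.ndim != 1 or self.data.size == 0:
            raise ValueError("data must be a non-empty 1-D sample")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data must be finite")
        inside = dist.in_support(self.data)
        if not np.all(inside):
            idx = int(np.argmin(inside))
            raise ValueError(
                f"observation at index {idx} ({self.data[idx]!r}) is outside "
                f"the support {dist.support}"
            )

    @classmethod
    def from_dataframe(cls, frame, column: str, dist) -> "LifetimeModel":
        return cls(np.asarray(frame[column], dtype=float), dist)

    @property
    def nobs(self) -> int:
        return self.data.size

    def nloglike(self, params) -> float:
        return neg_log_likelihood(self.dist, params, self.data)

    def fit(
        self,
        method: str = "PSO",
        starts: Optional[Sequence[float]] = None,
        param_bounds: Optional[Bounds] = None,
        pso_config: Optional[PSOConfig] = None,
        known_mle: Optional[Sequence[float]] = None,
        compute_se: Optional[bool] = None,
        seed: Optional[int] = None,
    ) -> LifetimeFitResults:
        """Minimize -log L and assemble the adequacy report.

        Parameters
        ----------
        method : str
            "PSO" (default), "BFGS", "Nelder-Mead", "SANN", "CG", or their
            initial letters. Local methods require ``starts``; the swarm
            requires an explicit ``param_bounds`` box.
        known_mle : array-like, optional
            Skip optimization and evaluate the report at these parameters.
        compute_se : bool, optional
            Defaults to True for local methods and False after a swarm fit.
        seed : int, optional
            Seed for the swarm (and SANN) random stream.
        """
        key = METHOD_ALIASES.get(str(method).upper())
        if key is None:
            raise ValueError(f"unknown method {method!r}")
        method = key

        opt_result = None
        if known_mle is not None:
            mle = np.asarray(known_mle, dtype=float)
            if mle.size != self.dist.n_params:
                raise ValueError("known_mle has wrong length")
            converged = True
            method = "provided MLE"
        elif method == "PSO":
            if param_bounds is None:
                if self.dist.param_lower is None or self.dist.param_upper is None:
                    raise ValueError(
                        "PSO fitting requires an explicit parameter box "
                        "(param_bounds)"
                    )
                param_bounds = Bounds(self.dist.param_lower, self.dist.param_upper)
            elif not isinstance(param_bounds, Bounds):
                param_bounds = Bounds(*param_bounds)
            if pso_config is None:
                pso_config = PSOConfig(seed=seed)
            elif seed is not None:
                pso_config.seed = seed

            def objective(params, data):
                return neg_log_likelihood(self.dist, params, data)

            opt_result = pso(objective, param_bounds, pso_config, data=self.data)
            mle = opt_result.best_position
            converged = opt_result.converged
        else:
            if starts is None:
                raise ValueError(f"method {method!r} requires starting values")
            starts = np.asarray(starts, dtype=float)
            nll = self.nloglike
            if method == "SANN":
                rng = np.random.default_rng(seed)
                opt_result = optimize.basinhopping(
                    nll,
                    starts,
                    niter=100,
                    minimizer_kwargs={"method": "Nelder-Mead"},
                    seed=rng,
                )
                mle = np.asarray(opt_result.x, dtype=float)
                converged = bool(
                    opt_result.lowest_optimization_result.success
                )
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    opt_result = optimize.minimize(nll, starts, method=method)
                mle = np.asarray(opt_result.x, dtype=float)
                converged = bool(opt_result.success)
            if self.nloglike(mle) > self.nloglike(starts):
                # never report a point worse than the starting values
                mle = starts
                converged = False

        if compute_se is None:
            compute_se = method != "PSO" and known_mle is None
        bse = gof.standard_errors(self.nloglike, mle) if compute_se else None

        cdf_at_mle = lambda x: self.dist.cdf(mle, x)
        gin = gof.compute_u(self.data, cdf_at_mle)
        _, w_star = gof.cramer_von_mises(gin.u_values)
        _, a_star = gof.anderson_darling(gin.u_values)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            D, p = gof.ks_test(self.data, cdf_at_mle)
        ell = self.nloglike(mle)
        ics = gof.information_criteria(ell, self.dist.n_params, self.nobs)

        return LifetimeFitResults(
            model=self,
            params=mle,
            bse=bse,
            w_star=w_star,
            a_star=a_star,
            ks_stat=D,
            ks_pvalue=p,
            aic=ics.aic,
            caic=ics.caic,
            bic=ics.bic,
            hqic=ics.hqic,
            neg_loglik=ell,
            converged=converged,
            method=method,
            optimizer_result=opt_result,
        )


def fit_distribution(data, dist, **fit_kwargs) -> LifetimeFitResults:
    """Convenience wrapper: ``LifetimeModel(data, dist).fit(**fit_kwargs)``."""
    return LifetimeModel(data, dist).fit(**fit_kwargs)
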