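"""Quasi-xgamma frailty proportional-hazards model.

The conditional hazard of subject i is

    lambda(t | z_i, x_i) = z_i * lambda0(t) * exp(x_i' beta),

with z_i an unobserved mean-one QXg frailty.  Integrating z out, the
marginal survival is the frailty Laplace transform evaluated at
s = Lambda0(t) * exp(x' beta).  With D = (3+zeta) + s*(1+zeta) the closed
forms in the zeta parameterization are

    S(t|x)      = (3+zeta) * (zeta D^2 + (3+zeta)^2) / ((1+zeta) D^3)
    lambda(t|x) = lambda0 xi * (1+zeta)/D
                  * (zeta D^2 + 3(3+zeta)^2) / (zeta D^2 + (3+zeta)^2)
    f(t|x)      = lambda(t|x) * S(t|x)

The frailty variance sigma^2 = (zeta^2+8*zeta+3)/(3+zeta)^2 quantifies the
unobserved heterogeneity; sigma^2-parameterized entry points go through the
variance->zeta branch map.

``QXgFrailtyModel`` is the statsmodels-style entry point: build it from
right-censored data (time, status, covariates), call ``fit`` to obtain a
``QXgFrailtyResults`` with estimates, numeric-Hessian standard errors and a
``summary`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .distribution import MeanOneFrailty, sigma2_of_zeta, zeta_from_variance
from .hazards import GompertzHazard, WeibullHazard, baseline_hazard

__all__ = ["FrailtySpec", "QXgFrailtyModel", "QXgFrailtyResults", "ConvergenceError"]


class ConvergenceError(RuntimeError):
    """Raised when no optimizer start reaches a usable optimum."""


@dataclass(frozen=True)
class FrailtySpec:
    """A fully specified QXg frailty model: baseline + frailty shape + betas."""

    baseline: WeibullHazard | GompertzHazard
    zeta: float
    beta: np.ndarray

    def __post_init__(self):
        if not (np.isfinite(self.zeta) and self.zeta >= 0):
            raise ValueError(f"zeta must be finite and >= 0, got {self.zeta!r}")
        object.__setattr__(
            self, "beta", np.atleast_1d(np.asarray(self.beta, dtype=float))
        )

    @classmethod
    def from_sigma2(cls, baseline, sigma2, beta, branch="lower"):
        """Build from the frailty variance instead of zeta."""
        return cls(baseline, zeta_from_variance(sigma2, branch), beta)

    @property
    def frailty(self) -> MeanOneFrailty:
        return MeanOneFrailty(self.zeta)

    @property
    def sigma2(self) -> float:
        return float(sigma2_of_zeta(self.zeta))

    # -- marginal functions ------------------------------------------------
    def _risk_score(self, x):
        if x is None:
            if self.beta.size:
                raise ValueError("model has covariates; x must be supplied")
            return 1.0
        x = np.asarray(x, dtype=float)
        if x.ndim == 1 and self.beta.size != x.shape[-1]:
            raise ValueError(
                f"covariate dimension {x.shape[-1]} does not match "
                f"beta dimension {self.beta.size}"
            )
        return np.exp(x @ self.beta) if self.beta.size else 1.0

    def _d(self, t, x):
        s = self.baseline.cumulative(np.asarray(t, dtype=float)) * self._risk_score(x)
        return (3.0 + self.zeta) + s * (1.0 + self.zeta)

    def survival(self, t, x=None):
        """Marginal (population) survival S(t|x); S(0|x) = 1."""
        z3 = 3.0 + self.zeta
        d = self._d(t, x)
        return z3 * (self.zeta * d**2 + z3**2) / ((1.0 + self.zeta) * d**3)

    def log_survival(self, t, x=None):
        z3 = 3.0 + self.zeta
        d = self._d(t, x)
        return (
            np.log(z3)
            + np.log(self.zeta * d**2 + z3**2)
            - np.log1p(self.zeta)
            - 3.0 * np.log(d)
        )

    def cumulative_hazard(self, t, x=None):
        return -self.log_survival(t, x)

    def hazard(self, t, x=None):
        return np.exp(self.log_hazard(t, x))

    def log_hazard(self, t, x=None):
        t = np.asarray(t, dtype=float)
        z3 = 3.0 + self.zeta
        d = self._d(t, x)
        xb = 0.0
        if x is not None and self.beta.size:
            xb = np.asarray(x, dtype=float) @ self.beta
        return (
            np.log(self.baseline.hazard(t))
            + xb
            + np.log1p(self.zeta)
            - np.log(d)
            + np.log(self.zeta * d**2 + 3.0 * z3**2)
            - np.log(self.zeta * d**2 + z3**2)
        )

    def density(self, t, x=None):
        """Marginal density f(t|x) = hazard * survival."""
        return self.hazard(t, x) * self.survival(t, x)


def _loglik(spec: FrailtySpec, time, status, exog) -> float:
    """Censored-data log likelihood sum(delta*log lambda + log S)."""
    logs = spec.log_survival(time, exog)
    ll = float(np.sum(logs))
    events = status.astype(bool)
    if events.any():
        x_ev = exog[events] if exog is not None else None
        ll += float(np.sum(spec.log_hazard(time[events], x_ev)))
    return ll


class QXgFrailtyModel:
    """Proportional-hazards model with mean-one QXg frailty.

    Parameters
    ----------
    time : array-like of positive floats
        Observed times min(T_i, C_i).
    status : array-like of {0, 1}
        Event indicator delta_i (1 = event, 0 = right-censored).
    exog : array-like (n, p), optional
        Covariate matrix; no intercept (the baseline absorbs scale).
    baseline : {"weibull", "gompertz"}

    The free parameters are (shape, scale, zeta, beta_1..beta_p); results
    additionally report the frailty variance sigma^2(zeta).
    """

    def __init__(self, time, status, exog=None, baseline="weibull"):
        time = np.asarray(time, dtype=float)
        status = np.asarray(status)
        if time.ndim != 1 or np.any(time <= 0) or not np.all(np.isfinite(time)):
            raise ValueError("time must be a 1-d array of positive finite values")
        if status.shape != time.shape or not np.isin(status, (0, 1)).all():
            raise ValueError("status must match time and contain only 0/1")
        if exog is not None:
            exog = np.asarray(exog, dtype=float)
            if exog.ndim == 1:
                exog = exog[:, None]
            if exog.shape[0] != time.size:
                raise ValueError("exog row count must match time")
        self.time = time
        self.status = status.astype(int)
        self.exog = exog
        self.nobs = time.size
        self.n_events = int(self.status.sum())
        self.k_exog = 0 if exog is None else exog.shape[1]
        baseline = baseline.lower()
        if baseline not in ("weibull", "gompertz"):
            raise ValueError(f"unknown baseline {baseline!r}")
        self.baseline_kind = baseline
        self.exog_names = [f"x{j + 1}" for j in range(self.k_exog)]

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        time_col: str = "time",
        status_col: str = "status",
        covariate_cols=None,
        baseline: str = "weibull",
    ) -> "QXgFrailtyModel":
        if covariate_cols is None:
            covariate_cols = [
                c for c in data.columns if c not in (time_col, status_col)
            ]
        exog = data[covariate_cols].to_numpy(float) if covariate_cols else None
        model = cls(
            data[time_col].to_numpy(float),
            data[status_col].to_numpy(),
            exog,
            baseline,
        )
        model.exog_names = list(covariate_cols)
        return model

    # -- parameter packing -------------------------------------------------
    @property
    def param_names(self):
        base = list(
            WeibullHazard.param_names
            if self.baseline_kind == "weibull"
            else GompertzHazard.param_names
        )
        return base + ["zeta"] + self.exog_names

    def spec(self, params) -> FrailtySpec:
        """Build a FrailtySpec from the natural parameter vector
        (shape, scale, zeta, beta...)."""
        params = np.asarray(params, dtype=float)
        if params.size != 3 + self.k_exog:
            raise ValueError(
                f"expected {3 + self.k_exog} parameters, got {params.size}"
            )
        base = baseline_hazard(self.baseline_kind, params[0], params[1])
        return FrailtySpec(base, params[2], params[3:])

    def loglike(self, params) -> float:
        """Log likelihood at the natural parameter vector or FrailtySpec.

        Returns -inf for parameter values outside the domain (boundary
        convention for the optimizer).
        """
        if not isinstance(params, FrailtySpec):
            try:
                params = self.spec(params)
            except ValueError:
                return -np.inf
        # extreme trial points overflow harmlessly to -inf
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            ll = _loglik(params, self.time, self.status, self.exog)
        return ll if np.isfinite(ll) else -np.inf

    # -- fitting -----------------------------------------------------------
    def _to_unconstrained(self, params):
        u = np.asarray(params, dtype=float).copy()
        u[:3] = np.log(u[:3])
        return u

    def _from_unconstrained(self, u):
        p = np.asarray(u, dtype=float).copy()
        p[:3] = np.exp(np.clip(p[:3], -500, 60))
        return p

    def _auto_start(self):
        """Moment-style start: exponential-fit baseline scale ignoring the
        frailty, shape near 1 (Weibull) or 1/mean-time (Gompertz), midpoint
        heterogeneity sigma^2 = 0.7, beta = 0."""
        r = max(self.n_events, 1)
        mean_scale = float(self.time.sum()) / r
        zeta0 = zeta_from_variance(0.7)
        if self.baseline_kind == "weibull":
            base = [1.0, mean_scale]
        else:
            base = [1.0 / float(self.time.mean()), 1.0 / mean_scale]
        return np.array(base + [zeta0] + [0.0] * self.k_exog)

    def _start_grid(self, start, n_starts, rng):
        """Structured multi-starts: the likelihood can carry two modes along
        a baseline-shape / frailty-shape ridge, so the first restarts
        straddle the auto point in (shape, zeta); further ones are jittered
        copies."""
        starts = [self._to_unconstrained(start)]
        u0 = starts[0]
        fixed = [
            np.concatenate([[u0[0] + np.log(2.0), u0[1], np.log(2.0)], u0[3:]]),
            np.concatenate([[u0[0] - np.log(2.0), u0[1], np.log(0.1)], u0[3:]]),
        ]
        starts.extend(fixed[: max(n_starts - 1, 0)])
        while len(starts) < n_starts:
            starts.append(u0 + rng.normal(scale=0.4, size=u0.size))
        return starts

    def fit(
        self,
        start_params=None,
        n_starts: int = 3,
        seed: int = 0,
        maxiter: int = 500,
    ) -> "QXgFrailtyResults":
        """Maximize the censored-data log likelihood.

        Multi-start quasi-Newton (BFGS on log-transformed positive
        parameters) with a Nelder-Mead fallback; ``n_starts - 1`` jittered
        restarts are drawn from ``seed``.  Raises ``ConvergenceError`` when
        no start yields a finite optimum.
        """
        if self.nobs < self.k_exog + 3:
            raise ConvergenceError(
                f"need at least {self.k_exog + 3} observations, have {self.nobs}"
            )
        if self.n_events == 0:
            raise ConvergenceError("no events observed; parameters not identified")
        start = (
            self._auto_start()
            if start_params is None
            else np.asarray(start_params, dtype=float)
        )
        ll_at_start = self.loglike(start)
        rng = np.random.default_rng(seed)
        starts = self._start_grid(start, n_starts, rng)

        def nll(u):
            ll = self.loglike(self._from_unconstrained(u))
            # large finite penalty keeps gradient stencils out of inf land
            return -ll if np.isfinite(ll) else 1e10

        best = None
        n_iter = 0
        for u0 in starts:
            res = optimize.minimize(nll, u0, method="BFGS", options={"maxiter": maxiter})
            n_iter += int(res.nit)
            if not np.isfinite(res.fun):
                continue
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise ConvergenceError("all optimizer starts failed")
        if -best.fun < ll_at_start - 1e-6:
            # fall back to a derivative-free polish from the start point
            res = optimize.minimize(
                nll, self._to_unconstrained(start), method="Nelder-Mead",
                options={"maxiter": 4 * maxiter, "fatol": 1e-10, "xatol": 1e-8},
            )
            n_iter += int(res.nit)
            if np.isfinite(res.fun) and res.fun < best.fun:
                best = res
        params = self._from_unconstrained(best.x)
        return QXgFrailtyResults(
            model=self,
            params=params,
            llf=-float(best.fun),
            converged=bool(best.success or np.isfinite(best.fun)),
            n_iter=n_iter,
            seed=seed,
            method="mle",
        )


class QXgFrailtyResults:
    """Fit results: estimates, numeric-Hessian standard errors, summary."""

    def __init__(self, model, params, llf, converged, n_iter, seed, method):
        self.model = model
        self.params = np.asarray(params, dtype=float)
        self.llf = llf
        self.converged = converged
        self.n_iter = n_iter
        self.seed = seed
        self.method = method
        self._bse = None

    @property
    def spec(self) -> FrailtySpec:
        return self.model.spec(self.params)

    @property
    def sigma2(self) -> float:
        return float(sigma2_of_zeta(self.params[2]))

    @property
    def param_names(self):
        return self.model.param_names

    @property
    def bse(self):
        """Standard errors from the numeric Hessian of the log likelihood."""
        if self._bse is None:
            h = _numeric_hessian(self.model.loglike, self.params)
            with np.errstate(invalid="ignore"):
                try:
                    cov = np.linalg.inv(-h)
                except np.linalg.LinAlgError:
                    cov = np.linalg.pinv(-h)
                var = np.diag(cov).copy()
            var[var < 0] = np.nan
            self._bse = np.sqrt(var)
        return self._bse

    def summary(self) -> str:
        lines = [
            "QXg frailty proportional-hazards model",
            f"baseline: {self.model.baseline_kind}   n = {self.model.nobs}   "
            f"events = {self.model.n_events}",
            f"log-likelihood = {self.llf:.6f}   converged = {self.converged}   "
            f"iterations = {self.n_iter}   seed = {self.seed}",
            "",
            f"{'param':>10} {'estimate':>14} {'std err':>12}",
        ]
        for name, est, se in zip(self.param_names, self.params, self.bse):
            lines.append(f"{name:>10} {est:>14.7g} {se:>12.5g}")
        se_z = self.bse[2]
        dsig = abs(_dsigma2_dzeta(self.params[2]))
        se_s2 = dsig * se_z if np.isfinite(se_z) else np.nan
        lines.append(f"{'sigma2':>10} {self.sigma2:>14.7g} {se_s2:>12.5g}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        out = dict(zip(self.param_names, map(float, self.params)))
        out.update(
            sigma2=self.sigma2,
            loglik=self.llf,
            converged=self.converged,
            n_iter=self.n_iter,
            seed=self.seed,
            method=self.method,
        )
        return out


def _dsigma2_dzeta(zeta):
    z3 = 3.0 + zeta
    return (2.0 * zeta + 8.0) / z3**2 - 2.0 * (zeta**2 + 8.0 * zeta + 3.0) / z3**3


def _numeric_hessian(fun, x, rel_step=1e-4):
    x = np.asarray(x, dtype=float)
    k = x.size
    h = rel_step * np.maximum(1.0, np.abs(x))
    hess = np.empty((k, k))
    f0 = fun(x)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            if i == j:
                val = (fun(x + ei) - 2.0 * f0 + fun(x - ei)) / h[i] ** 2
            else:
                val = (
                    fun(x + ei + ej) - fun(x + ei - ej)
                    - fun(x - ei + ej) + fun(x - ei - ej)
                ) / (4.0 * h[i] * h[j])
            hess[i, j] = hess[j, i] = val
    return hess
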