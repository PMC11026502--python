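"""Synthetic survival data from the QXg frailty model, and the Monte-Carlo
study drivers (estimator recovery, empirical test levels).

Event times are simulated exactly by inverse transform of the conditional
survival function: draw the frailty z from the mean-one QXg mixture, the
covariate x, and U ~ Uniform(0,1), then

    T = Lambda0^{-1}( -log U / (z * exp(x' beta)) ).

Right censoring uses an independent Uniform(0, c) censoring time whose
upper bound c is calibrated by bisection against a pilot sample so the
realized censoring fraction matches the target within 0.5%.

Default covariate design: a single x ~ Bernoulli(0.5), matching the single
regression coefficient used throughout the recovery studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .distribution import MeanOneFrailty, zeta_from_variance
from .gof import bagdonavicius_nikulin_test, rao_robson_test
from .hazards import baseline_hazard
from .model import ConvergenceError, FrailtySpec, QXgFrailtyModel
from .univariate import fit_qxg

__all__ = [
    "SimulationDesign",
    "simulate_survival_dataset",
    "calibrate_censoring",
    "bias_mse_study",
    "empirical_level_study",
    "WEIBULL_STUDY_DESIGN",
    "GOMPERTZ_STUDY_DESIGN",
]


@dataclass(frozen=True)
class SimulationDesign:
    """One Monte-Carlo design: true parameters, sizes, censoring target."""

    n: int
    baseline_kind: str = "weibull"
    shape: float = 0.8
    scale: float = 0.9
    sigma2: float = 0.6
    beta: tuple = (0.5,)
    censor_fraction: float = 0.0
    n_reps: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if not 0.0 <= self.censor_fraction < 1.0:
            raise ValueError("censor_fraction must lie in [0, 1)")

    @property
    def spec(self) -> FrailtySpec:
        base = baseline_hazard(self.baseline_kind, self.shape, self.scale)
        return FrailtySpec(base, zeta_from_variance(self.sigma2), np.asarray(self.beta))

    @property
    def true_params(self) -> np.ndarray:
        return np.concatenate(
            [[self.shape, self.scale, self.sigma2], np.asarray(self.beta)]
        )


#: The two recovery-study designs (sample sizes are set per run).
WEIBULL_STUDY_DESIGN = SimulationDesign(
    n=1000, baseline_kind="weibull", shape=0.8, scale=0.9, sigma2=0.6, beta=(0.5,)
)
GOMPERTZ_STUDY_DESIGN = SimulationDesign(
    n=1000, baseline_kind="gompertz", shape=1.07, scale=0.5, sigma2=0.7, beta=(0.3,)
)


def _draw_event_times(spec: FrailtySpec, n: int, rng) -> tuple:
    """Latent event times T and covariates x under the frailty model."""
    p = spec.beta.size
    x = rng.integers(0, 2, size=(n, p)).astype(float) if p else None
    z = MeanOneFrailty(spec.zeta).distribution.rvs(n, rng)
    xi = np.exp(x @ spec.beta) if p else 1.0
    u = rng.random(n)
    t = spec.baseline.inverse(-np.log(u) / (z * xi))
    return t, x


def simulate_survival_dataset(
    design: SimulationDesign, rng=None, censor_bound: float | None = None
) -> pd.DataFrame:
    """Simulate one right-censored dataset as a DataFrame
    (time, status, x1..xp).

    ``censor_bound`` overrides the calibrated Uniform(0, c) bound; with
    censor_fraction == 0 no censoring is applied and all status are 1.
    """
    rng = np.random.default_rng(design.seed) if rng is None else rng
    spec = design.spec
    t, x = _draw_event_times(spec, design.n, rng)
    if design.censor_fraction > 0:
        if censor_bound is None:
            censor_bound = calibrate_censoring(design)
        c = rng.uniform(0.0, censor_bound, size=design.n)
        status = (t <= c).astype(int)
        time = np.minimum(t, c)
    else:
        status = np.ones(design.n, dtype=int)
        time = t
    time = np.maximum(time, 1e-12)  # guard against degenerate 0 draws
    cols = {"time": time, "status": status}
    if x is not None:
        for j in range(x.shape[1]):
            cols[f"x{j + 1}"] = x[:, j]
    return pd.DataFrame(cols)


def calibrate_censoring(
    design: SimulationDesign, pilot: int = 100_000, tol: float = 0.005
) -> float:
    """Upper bound c of the Uniform(0, c) censoring law hitting the target.

    Uses a pilot sample of latent event times (seeded from the design) and
    the exact conditional censoring probability P(C < T | T) = min(T/c, 1),
    which is monotone in c, so plain bisection applies.
    """
    target = design.censor_fraction
    if target == 0:
        raise ValueError("no censoring requested; nothing to calibrate")
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 0xCA11]))
    t, _ = _draw_event_times(design.spec, pilot, rng)

    def frac(c):
        return float(np.mean(np.minimum(t / c, 1.0)))

    lo, hi = 1e-9, float(np.quantile(t, 0.999))
    while frac(hi) > target:
        hi *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        f = frac(mid)
        if abs(f - target) < tol * 0.2:
            return mid
        if f > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def bias_mse_study(
    design: SimulationDesign,
    censor_fractions=(0.0,),
    n_starts: int = 1,
) -> pd.DataFrame:
    """Monte-Carlo mean estimate and MSE of the MLEs per censoring level.

    Replicates whose fit fails are dropped and counted; the study is
    flagged invalid if more than 20% fail.
    """
    if design.n_reps < 1:
        raise ValueError("need at least one replicate")
    truth = design.true_params
    names = ["shape", "scale", "sigma2"] + [
        f"beta{j + 1}" for j in range(len(design.beta))
    ]
    rows = []
    for cf in censor_fractions:
        d = replace(design, censor_fraction=cf)
        bound = calibrate_censoring(d) if cf > 0 else None
        rng = np.random.default_rng(np.random.SeedSequence([design.seed, int(cf * 1000)]))
        ests, failures = [], 0
        for _ in range(design.n_reps):
            data = simulate_survival_dataset(d, rng, censor_bound=bound)
            model = QXgFrailtyModel.from_dataframe(data, baseline=d.baseline_kind)
            try:
                res = model.fit(n_starts=n_starts, seed=0)
            except ConvergenceError:
                failures += 1
                continue
            est = res.params.copy()
            est[2] = res.sigma2  # report the frailty variance, not zeta
            ests.append(est)
        ests = np.asarray(ests)
        valid = failures <= 0.2 * design.n_reps and ests.size
        for j, name in enumerate(names):
            rows.append(
                {
                    "censor_fraction": cf,
                    "parameter": name,
                    "truth": truth[j],
                    "mean_estimate": float(ests[:, j].mean()) if len(ests) else np.nan,
                    "mse": float(((ests[:, j] - truth[j]) ** 2).mean())
                    if len(ests)
                    else np.nan,
                    "n_reps": len(ests),
                    "n_failures": failures,
                    "valid": bool(valid),
                }
            )
    return pd.DataFrame(rows)


def empirical_level_study(
    test: str,
    n: int,
    eps_levels=(0.01, 0.02, 0.05, 0.1),
    n_reps: int = 2000,
    censor_fraction: float = 0.0,
    seed: int = 0,
    cells: int = 5,
    null_params=(0.5, 1.0),
    design: SimulationDesign | None = None,
) -> pd.DataFrame:
    """Non-rejection frequencies of a goodness-of-fit test under its null.

    ``test="nrr"``: complete QXg(zeta, theta) samples at ``null_params``,
    MLE refit per replicate, Rao-Robson-Nikulin statistic on ``cells``
    equiprobable cells.

    ``test="bnik"``: right-censored frailty-model datasets from ``design``
    (default: the Weibull recovery design) at ``censor_fraction``, full MLE
    refit, Bagdonavicius-Nikulin statistic on ``cells`` intervals.

    For each nominal level eps the reported frequency is the fraction of
    replicates with statistic <= upper-eps chi-squared quantile; under the
    null it approaches 1 - eps.
    """
    if test not in ("nrr", "bnik"):
        raise ValueError(f"unknown test {test!r}")
    rng = np.random.default_rng(seed)
    stats_out, dfs = [], []
    if test == "nrr":
        from .distribution import QuasiXGamma

        null = QuasiXGamma(*null_params)
        for _ in range(n_reps):
            sample = null.rvs(n, rng)
            fit = fit_qxg(sample, "maxle")
            res = rao_robson_test(sample, fit.distribution, cells)
            if np.isfinite(res.statistic):
                stats_out.append(res.statistic)
                dfs.append(res.df)
    else:
        base = design if design is not None else WEIBULL_STUDY_DESIGN
        d = replace(base, n=n, censor_fraction=censor_fraction, seed=seed)
        bound = calibrate_censoring(d) if censor_fraction > 0 else None
        for _ in range(n_reps):
            data = simulate_survival_dataset(d, rng, censor_bound=bound)
            model = QXgFrailtyModel.from_dataframe(data, baseline=d.baseline_kind)
            try:
                res_fit = model.fit(n_starts=1, seed=0)
            except ConvergenceError:
                continue
            res = bagdonavicius_nikulin_test(model, res_fit, cells)
            if np.isfinite(res.statistic):
                stats_out.append(res.statistic)
                dfs.append(res.df)
    stats_out = np.asarray(stats_out)
    dfs = np.asarray(dfs)
    rows = []
    for eps in eps_levels:
        crit = stats.chi2.ppf(1.0 - eps, dfs)
        rows.append(
            {
                "eps": eps,
                "nominal": 1.0 - eps,
                "non_rejection_freq": float(np.mean(stats_out <= crit)),
                "n_reps": stats_out.size,
            }
        )
    return pd.DataFrame(rows)
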