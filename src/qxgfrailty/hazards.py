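"""Parametric baseline hazards for the frailty model.

Each baseline supplies the triple (hazard lambda0, cumulative hazard
Lambda0, inverse cumulative hazard) used throughout the marginal model and
the inverse-transform simulator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["WeibullHazard", "GompertzHazard", "baseline_hazard"]


def _check_time(t, positive=True):
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("time must be finite")
    if positive and np.any(t <= 0):
        raise ValueError("time must be > 0")
    if not positive and np.any(t < 0):
        raise ValueError("time must be >= 0")
    return t


@dataclass(frozen=True)
class WeibullHazard:
    """Weibull baseline: lambda0(t) = (kappa/rho)(t/rho)^(kappa-1),
    Lambda0(t) = (t/rho)^kappa.

    The hazard decreases in t for kappa < 1, is constant (exponential) at
    kappa = 1, and increases for kappa > 1.
    """

    kappa: float
    rho: float
    kind = "weibull"

    def __post_init__(self):
        if not (np.isfinite(self.kappa) and self.kappa > 0):
            raise ValueError(f"kappa must be > 0, got {self.kappa!r}")
        if not (np.isfinite(self.rho) and self.rho > 0):
            raise ValueError(f"rho must be > 0, got {self.rho!r}")

    def hazard(self, t):
        t = _check_time(t)
        return (self.kappa / self.rho) * (t / self.rho) ** (self.kappa - 1.0)

    def cumulative(self, t):
        t = _check_time(t, positive=False)
        return (t / self.rho) ** self.kappa

    def inverse(self, h):
        h = np.asarray(h, dtype=float)
        if np.any(h < 0):
            raise ValueError("cumulative hazard must be >= 0")
        return self.rho * h ** (1.0 / self.kappa)

    @property
    def params(self):
        return np.array([self.kappa, self.rho])

    param_names = ("kappa", "rho")

    def replace(self, params):
        return WeibullHazard(float(params[0]), float(params[1]))


@dataclass(frozen=True)
class GompertzHazard:
    """Gompertz baseline: lambda0(t) = rho1*exp(kappa1*t),
    Lambda0(t) = (rho1/kappa1)(exp(kappa1*t) - 1).

    Only kappa1 > 0 is supported: for kappa1 < 0 the cumulative hazard is
    bounded and the model is improper (a cure fraction appears), which is
    outside this package's scope.  Near kappa1 = 0 the exponential limit
    Lambda0 = rho1*t is used (expm1/log1p keep the evaluation stable).
    """

    kappa1: float
    rho1: float
    kind = "gompertz"

    _LIMIT = 1e-8  # below this, use the exponential limit

    def __post_init__(self):
        if not (np.isfinite(self.kappa1) and self.kappa1 > 0):
            raise ValueError(
                f"kappa1 must be > 0 (kappa1 <= 0 yields an improper, "
                f"cure-fraction model), got {self.kappa1!r}"
            )
        if not (np.isfinite(self.rho1) and self.rho1 > 0):
            raise ValueError(f"rho1 must be > 0, got {self.rho1!r}")

    def hazard(self, t):
        t = _check_time(t)
        return self.rho1 * np.exp(self.kappa1 * t)

    def cumulative(self, t):
        t = _check_time(t, positive=False)
        if self.kappa1 < self._LIMIT:
            return self.rho1 * t
        return (self.rho1 / self.kappa1) * np.expm1(self.kappa1 * t)

    def inverse(self, h):
        h = np.asarray(h, dtype=float)
        if np.any(h < 0):
            raise ValueError("cumulative hazard must be >= 0")
        if self.kappa1 < self._LIMIT:
            return h / self.rho1
        return np.log1p(self.kappa1 * h / self.rho1) / self.kappa1

    @property
    def params(self):
        return np.array([self.kappa1, self.rho1])

    param_names = ("kappa1", "rho1")

    def replace(self, params):
        return GompertzHazard(float(params[0]), float(params[1]))


def baseline_hazard(kind: str, shape: float, scale: float):
    """Factory: ``baseline_hazard("weibull", kappa, rho)`` or
    ``baseline_hazard("gompertz", kappa1, rho1)``."""
    kind = kind.lower()
    if kind == "weibull":
        return WeibullHazard(shape, scale)
    if kind == "gompertz":
        return GompertzHazard(shape, scale)
    raise ValueError(f"unknown baseline kind {kind!r}")
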