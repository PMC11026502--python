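"""The quasi-xgamma (QXg) distribution and its mean-one frailty reparameterization.

The QXg law is a two-component mixture of an Exponential(theta) and a
Gamma(shape 3, rate theta) distribution with mixing weights zeta/(1+zeta)
and 1/(1+zeta):

    f(z) = theta/(1+zeta) * exp(-theta*z) * (zeta + theta^2 z^2 / 2),  z > 0.

``zeta`` is a dimensionless shape parameter (zeta=0 degenerates to
Gamma(3, theta); zeta -> inf approaches Exponential(theta)) and ``theta`` is
a rate.  The mixture representation gives closed forms for the CDF, the
Laplace transform, all partial moments (via upper incomplete gamma
functions) and an exact sampler, which this module exposes.

As a frailty law the distribution is rescaled to unit mean by fixing
``theta = (3+zeta)/(1+zeta)``; the frailty variance is then

    sigma^2 = (zeta^2 + 8 zeta + 3) / (3+zeta)^2,

which ranges over (1/3, 13/12], attains its maximum 13/12 at zeta=9, and
tends to 1 as zeta -> inf.  ``zeta_from_variance`` inverts this map on
either algebraic branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

__all__ = [
    "QuasiXGamma",
    "MeanOneFrailty",
    "mean_one",
    "zeta_from_variance",
    "sigma2_of_zeta",
]

#: Open lower / closed upper bound of the attainable frailty variance.
SIGMA2_MIN = 1.0 / 3.0
SIGMA2_MAX = 13.0 / 12.0


def sigma2_of_zeta(zeta):
    """Frailty variance of the mean-one law as a function of the shape zeta."""
    zeta = np.asarray(zeta, dtype=float)
    return (zeta**2 + 8.0 * zeta + 3.0) / (3.0 + zeta) ** 2


def zeta_from_variance(sigma2: float, branch: str = "lower") -> float:
    """Invert sigma^2(zeta) = (zeta^2+8*zeta+3)/(3+zeta)^2.

    The quadratic (sigma2-1) zeta^2 + (6 sigma2 - 8) zeta + 9 sigma2 - 3 = 0
    has discriminant 4*C with C = 13 - 12 sigma2 >= 0 iff sigma2 <= 13/12.
    The ``lower`` branch (zeta <= 9) exists for all sigma2 in (1/3, 13/12];
    the ``upper`` branch (zeta >= 9) only for sigma2 in (1, 13/12].  At
    sigma2 = 1 the lower branch is the continuity limit zeta = 3.
    """
    if not SIGMA2_MIN < sigma2 <= SIGMA2_MAX:
        raise ValueError(
            f"sigma2 must lie in (1/3, 13/12], got {sigma2!r}"
        )
    if branch not in ("lower", "upper"):
        raise ValueError(f"branch must be 'lower' or 'upper', got {branch!r}")
    c = 13.0 - 12.0 * sigma2
    sqrt_c = np.sqrt(max(c, 0.0))
    denom = sigma2 - 1.0
    if abs(denom) < 1e-12:
        if branch == "upper":
            raise ValueError("upper branch does not exist for sigma2 <= 1")
        return 3.0  # limit of the lower root as sigma2 -> 1
    if branch == "upper":
        if sigma2 <= 1.0:
            raise ValueError("upper branch does not exist for sigma2 <= 1")
        return (4.0 - 3.0 * sigma2 + sqrt_c) / denom
    # the "-sqrt(C)" root is the lower (zeta <= 9) branch on either side of
    # the sigma2 = 1 singularity (for sigma2 < 1 it is the only real root)
    return (4.0 - 3.0 * sigma2 - sqrt_c) / denom


@dataclass(frozen=True)
class QuasiXGamma:
    """Two-parameter quasi-xgamma distribution QXg(zeta, theta).

    Parameters
    ----------
    zeta : float
        Dimensionless shape, >= 0.  zeta = 0 is the Gamma(3, theta) boundary.
    theta : float
        Rate, > 0 (units 1/time).
    """

    zeta: float
    theta: float

    def __post_init__(self):
        if not np.isfinite(self.zeta) or self.zeta < 0:
            raise ValueError(f"zeta must be finite and >= 0, got {self.zeta!r}")
        if not np.isfinite(self.theta) or self.theta <= 0:
            raise ValueError(f"theta must be finite and > 0, got {self.theta!r}")

    # -- basic functions ---------------------------------------------------
    def pdf(self, z):
        z = self._check_support(z)
        th = self.theta
        return th / (1.0 + self.zeta) * np.exp(-th * z) * (
            self.zeta + 0.5 * (th * z) ** 2
        )

    def logpdf(self, z):
        z = self._check_support(z)
        th = self.theta
        return (
            np.log(th)
            - np.log1p(self.zeta)
            - th * z
            + np.log(self.zeta + 0.5 * (th * z) ** 2)
        )

    def sf(self, z):
        """Survival function; closed form from the mixture tails."""
        z = self._check_support(z)
        u = self.theta * z
        return np.exp(-u) * (1.0 + self.zeta + u + 0.5 * u**2) / (1.0 + self.zeta)

    def cdf(self, z):
        return 1.0 - self.sf(z)

    def ppf(self, q):
        """Quantile by bracketed root-finding on the closed-form CDF.

        The bracket starts at [0, mean + 50/theta] and doubles until it
        contains the root; tolerance 1e-10 on the CDF scale.
        """
        q_arr = np.asarray(q, dtype=float)
        if np.any((q_arr <= 0.0) | (q_arr >= 1.0)):
            raise ValueError("quantile level must lie strictly in (0, 1)")
        scalar = q_arr.ndim == 0
        out = np.empty(np.atleast_1d(q_arr).shape)
        for i, qi in enumerate(np.atleast_1d(q_arr)):
            hi = self.mean() + 50.0 / self.theta
            while self.cdf(hi) < qi:
                hi *= 2.0
            out[i] = optimize.brentq(
                lambda z: self.cdf(z) - qi, 0.0, hi, xtol=1e-14, rtol=8.9e-16
            )
        return float(out[0]) if scalar else out.reshape(q_arr.shape)

    # -- moments -----------------------------------------------------------
    def partial_moment(self, k: int, threshold: float = 0.0):
        """Upper partial moment E[Z^k 1{Z > threshold}] in closed form.

        Equals [zeta*Gu(k+1, theta*u) + Gu(k+3, theta*u)/2] / ((1+zeta) theta^k)
        with Gu the (non-regularized) upper incomplete gamma function; at
        threshold 0 this is the k-th raw moment.
        """
        if k < 0 or int(k) != k:
            raise ValueError("moment order k must be a nonnegative integer")
        if threshold < 0 or not np.isfinite(threshold):
            raise ValueError("threshold must be finite and >= 0")
        u = self.theta * threshold
        g1 = special.gammaincc(k + 1, u) * special.gamma(k + 1)
        g3 = special.gammaincc(k + 3, u) * special.gamma(k + 3)
        return (self.zeta * g1 + 0.5 * g3) / ((1.0 + self.zeta) * self.theta**k)

    def mean(self):
        return (self.zeta + 3.0) / (self.theta * (1.0 + self.zeta))

    def var(self):
        m1 = self.mean()
        return self.partial_moment(2) - m1 * m1

    # -- Laplace transform -------------------------------------------------
    def laplace(self, s):
        """Laplace transform L(s) = E[exp(-s Z)] and its derivative L'(s).

        Mixture form: L(s) = [zeta*theta/(theta+s) + theta^3/(theta+s)^3]
        / (1+zeta).  Returns the pair (L, dL/ds); L(0)=1 and -L'(0) is the
        mean.
        """
        s = np.asarray(s, dtype=float)
        if np.any(s < 0) or not np.all(np.isfinite(s)):
            raise ValueError("Laplace argument s must be finite and >= 0")
        th = self.theta
        r = th / (th + s)
        lap = (self.zeta * r + r**3) / (1.0 + self.zeta)
        dlap = -(self.zeta * r**2 + 3.0 * r**4) / ((1.0 + self.zeta) * th)
        return lap, dlap

    # -- sampling ----------------------------------------------------------
    def rvs(self, size: int, rng):
        """Exact sampling via the Exponential/Gamma(3) mixture.

        Parameters
        ----------
        size : int
            Number of draws, >= 1.
        rng : numpy.random.Generator or int
            Generator, or a seed used to build one.
        """
        if size < 1:
            raise ValueError("size must be >= 1")
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        w_exp = self.zeta / (1.0 + self.zeta)
        pick_exp = rng.random(size) < w_exp
        out = rng.gamma(3.0, 1.0 / self.theta, size=size)
        n_exp = int(pick_exp.sum())
        if n_exp:
            out[pick_exp] = rng.exponential(1.0 / self.theta, size=n_exp)
        return out

    @staticmethod
    def _check_support(z):
        z = np.asarray(z, dtype=float)
        if np.any(z < 0) or not np.all(np.isfinite(z)):
            raise ValueError("z must be finite and >= 0")
        return z


@dataclass(frozen=True)
class MeanOneFrailty:
    """Mean-one QXg frailty law, indexed by the single shape zeta.

    The rate is pinned at theta = (3+zeta)/(1+zeta) so that E[Z] = 1; the
    frailty variance sigma^2 and the auxiliary constant C = 13 - 12 sigma^2
    (the discriminant kernel of the variance->zeta inversion) are derived
    fields.
    """

    zeta: float
    theta_implied: float = field(init=False)
    sigma2: float = field(init=False)
    c_of_sigma2: float = field(init=False)

    def __post_init__(self):
        if not np.isfinite(self.zeta) or self.zeta < 0:
            raise ValueError(f"zeta must be finite and >= 0, got {self.zeta!r}")
        object.__setattr__(
            self, "theta_implied", (3.0 + self.zeta) / (1.0 + self.zeta)
        )
        object.__setattr__(self, "sigma2", float(sigma2_of_zeta(self.zeta)))
        object.__setattr__(self, "c_of_sigma2", 13.0 - 12.0 * self.sigma2)

    @property
    def distribution(self) -> QuasiXGamma:
        return QuasiXGamma(self.zeta, self.theta_implied)

    @classmethod
    def from_variance(cls, sigma2: float, branch: str = "lower") -> "MeanOneFrailty":
        return cls(zeta_from_variance(sigma2, branch))

    def laplace(self, s):
        """Laplace transform of the mean-one law; L(0)=1, L'(0)=-1."""
        return self.distribution.laplace(s)


def mean_one(zeta: float) -> MeanOneFrailty:
    """Mean-one reparameterization of QXg at shape zeta."""
    return MeanOneFrailty(zeta)
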