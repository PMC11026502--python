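"""Shared fixtures and independent numerical oracles.

The oracles here deliberately avoid the package's closed forms: they
integrate the mixture density directly (adaptive quadrature), so the tests
compare two independent routes to the same quantity.
"""

import numpy as np
import pytest
from scipy import integrate


def qxg_pdf_formula(z, zeta, theta):
    """The QXg density written out directly (oracle side)."""
    return theta / (1.0 + zeta) * np.exp(-theta * z) * (zeta + 0.5 * theta**2 * z**2)


def quad_cdf(z, zeta, theta):
    """CDF by adaptive quadrature of the density."""
    val, _ = integrate.quad(qxg_pdf_formula, 0.0, z, args=(zeta, theta))
    return val


def quad_partial_moment(k, threshold, zeta, theta):
    """E[Z^k 1{Z > threshold}] by adaptive quadrature."""
    val, _ = integrate.quad(
        lambda z: z**k * qxg_pdf_formula(z, zeta, theta),
        threshold, np.inf, limit=200,
    )
    return val


def meanone_pdf(z, zeta):
    """Mean-one frailty density (theta pinned at (3+zeta)/(1+zeta))."""
    return qxg_pdf_formula(z, zeta, (3.0 + zeta) / (1.0 + zeta))


def quad_laplace(s, zeta):
    """Laplace transform of the mean-one frailty law by quadrature."""
    val, _ = integrate.quad(
        lambda z: np.exp(-s * z) * meanone_pdf(z, zeta), 0.0, np.inf, limit=200
    )
    return val


def quad_marginal_survival(t, zeta, cum_hazard, risk_score=1.0):
    """Marginal survival by mixing the conditional survival over the
    frailty density: integral of exp(-z * Lambda0(t) * xi) f(z) dz."""
    s = cum_hazard(t) * risk_score
    return quad_laplace(s, zeta)


@pytest.fixture
def rng():
    return np.random.default_rng(20240418)


@pytest.fixture
def table5_params():
    """MaxLE point of the n=20 KRI table."""
    return 0.14107, 0.52017
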