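"""Generic Laplace approximation to marginal negative log likelihoods.

The joint estimator integrates spline random effects out of the likelihood
with a Laplace approximation evaluated at the conditional mode.  This module
provides a small, model-agnostic version of that operation,

``-log int exp(-f(u)) du  ~=  f(u_hat) + 0.5 log det H(u_hat) - (d/2) log 2pi``

used for cross-checking the approximation against adaptive quadrature on toy
models; the production inner solver in :mod:`icebears.joint` exploits the
model's analytic gradient and Hessian instead.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize


def numeric_hessian(f, x, step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian with relative steps."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    H = np.empty((n, n))
    h = step * np.maximum(1.0, np.abs(x))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej)
                - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h[i] * h[j])
    return H


def laplace_marginal_nll(f, x0, hess_step: float = 1e-4):
    """Laplace-approximate ``-log int exp(-f(u)) du`` over all of R^d.

    Returns ``(value, u_hat, H)``.  ``f`` must be smooth and grow at
    infinity; the mode is located with BFGS from ``x0``.
    """
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    res = optimize.minimize(f, x0, method="BFGS",
                            options={"gtol": 1e-10, "maxiter": 500})
    u_hat = res.x
    H = numeric_hessian(f, u_hat, step=hess_step)
    sign, logdet = np.linalg.slogdet(H)
    if sign <= 0:
        raise RuntimeError("Hessian at the mode is not positive definite")
    d = len(u_hat)
    value = float(res.fun + 0.5 * logdet - 0.5 * d * np.log(2 * np.pi))
    return value, u_hat, H
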