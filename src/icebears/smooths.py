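"""Penalized cubic spline bases for the abundance density surface.

Each abundance covariate (ice, RSF, easting, northing, distance to land) gets
a cubic B-spline basis with a maximum basis dimension of six and a smoothness
penalty equal to the integrated squared second derivative of the fitted
function.  A sum-to-zero constraint over all cell-days is absorbed into the
basis by a QR reparameterization (six columns become five), the standard GAM
identifiability device given that the occupancy linear predictor carries no
intercept.  The penalty matrices are computed exactly: the second derivative
of a cubic B-spline is piecewise linear, so two-point Gauss-Legendre
quadrature per knot span integrates the products without error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

_EIG_TOL = 1e-10


def cubic_basis(x: np.ndarray, k: int = 6):
    """Cubic B-spline basis with ``k`` columns and its curvature penalty.

    Knots: boundary knots at the data range, interior knots at quantiles.
    Returns ``(B, S, knots)`` where ``B`` is the (n, k) design, ``S`` the
    (k, k) penalty ``S_ij = int B_i'' B_j'' dx``, and ``knots`` the full knot
    vector.  A (numerically) constant covariate raises, with advice to drop
    it.
    """
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if hi - lo < 1e-12 * max(1.0, abs(hi)):
        raise ValueError(
            "covariate is constant; remove it from the smooth set")
    if k < 4:
        raise ValueError("cubic basis needs k >= 4")
    n_interior = k - 4
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(x, qs)
        # guard against ties collapsing the knot sequence
        interior = np.clip(interior, lo + 1e-9 * (hi - lo),
                           hi - 1e-9 * (hi - lo))
        interior = np.sort(interior)
        for i in range(1, len(interior)):
            if interior[i] <= interior[i - 1]:
                interior[i] = interior[i - 1] + 1e-9 * (hi - lo)
    else:
        interior = np.empty(0)
    knots = np.concatenate([[lo] * 4, interior, [hi] * 4])

    B = BSpline.design_matrix(np.clip(x, lo, hi), knots, 3).toarray()
    S = _curvature_penalty(knots, k)
    return B, S, knots


def _curvature_penalty(knots: np.ndarray, k: int) -> np.ndarray:
    """Exact Gram matrix of second derivatives over the knot range."""
    spans = np.unique(knots)
    # Gauss-Legendre order 2: exact for the quadratic products of the
    # piecewise-linear second derivatives
    gl_x = np.array([-1.0, 1.0]) / np.sqrt(3.0)
    S = np.zeros((k, k))
    eye = np.eye(k)
    d2 = [BSpline(knots, eye[i], 3).derivative(2) for i in range(k)]
    for a, b in zip(spans[:-1], spans[1:]):
        h = 0.5 * (b - a)
        pts = 0.5 * (a + b) + h * gl_x
        D = np.array([[f(p) for f in d2] for p in pts])
        S += h * (D.T @ D)
    return S


@dataclass
class Smooth:
    """One constrained smooth term."""

    name: str
    X: np.ndarray          # (n_rows, k-1) constrained basis
    S: np.ndarray          # (k-1, k-1) constrained penalty, symmetric PSD
    Zc: np.ndarray         # (k, k-1) constraint transform
    knots: np.ndarray
    rank: int
    log_pdet: float

    @property
    def n_coef(self) -> int:
        return self.X.shape[1]


@dataclass
class SmoothSpec:
    """Collection of constrained smooths sharing one row index (cell-day).

    ``X`` stacks the smooth bases column-wise; ``blocks`` gives the coefficient
    slice of each smooth.  Rows are in day-major order (day varies slowest),
    matching the package-wide flattening of (cell, day) arrays.
    """

    smooths: list[Smooth]

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.smooths]

    @property
    def X(self) -> np.ndarray:
        if not self.smooths:
            return np.empty((0, 0))
        return np.hstack([s.X for s in self.smooths])

    @property
    def blocks(self) -> list[slice]:
        out, start = [], 0
        for s in self.smooths:
            out.append(slice(start, start + s.n_coef))
            start += s.n_coef
        return out

    @property
    def n_coef(self) -> int:
        return sum(s.n_coef for s in self.smooths)

    def penalty(self, lam: np.ndarray) -> np.ndarray:
        """Block-diagonal precision ``blockdiag(lambda_i * S_i)``."""
        P = np.zeros((self.n_coef, self.n_coef))
        for lam_i, s, blk in zip(lam, self.smooths, self.blocks):
            P[blk, blk] += lam_i * s.S
        return P


def constrain_basis(B: np.ndarray, S: np.ndarray):
    """Absorb the sum-to-zero constraint ``1'B alpha = 0`` via QR.

    Returns ``(Xc, Sc, Zc)`` with one fewer column; the constrained columns
    each sum to zero over rows.
    """
    C = B.sum(axis=0, keepdims=True)
    Q, _ = np.linalg.qr(C.T, mode="complete")
    Zc = Q[:, 1:]
    return B @ Zc, Zc.T @ S @ Zc, Zc


def build_smooth(name: str, values: np.ndarray, k: int = 6) -> Smooth:
    B, S, knots = cubic_basis(values, k=k)
    Xc, Sc, Zc = constrain_basis(B, S)
    Sc = 0.5 * (Sc + Sc.T)
    eig = np.linalg.eigvalsh(Sc)
    pos = eig[eig > _EIG_TOL * max(eig.max(), 1.0)]
    return Smooth(name=name, X=Xc, S=Sc, Zc=Zc, knots=knots,
                  rank=len(pos), log_pdet=float(np.sum(np.log(pos))))


def build_smooths(cov, k: int = 6, covariates=None) -> SmoothSpec:
    """Build the abundance smooth set from a covariate field.

    ``covariates`` selects and orders the smooth terms (default: ice, rsf,
    easting, northing, dist_land).  Values are pooled over all cell-days when
    placing quantile knots; bases are evaluated per cell-day in day-major
    order.
    """
    fields = cov.smooth_covariates()
    if covariates is None:
        covariates = list(fields)
    smooths = []
    for name in covariates:
        if name not in fields:
            raise KeyError(f"unknown smooth covariate {name!r}")
        values = fields[name].T.ravel()  # day-major
        smooths.append(build_smooth(name, values, k=k))
    return SmoothSpec(smooths=smooths)
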