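"""Randomized quantile residuals and uniformity checks.

For discrete data, ordinary residuals clump at the support points; randomized
quantile residuals (RQRs) spread the probability mass of the observed value
uniformly, ``R = P(Y < y) + u P(Y = y)`` with ``u ~ Uniform(0,1)``, so that a
correctly specified model yields exactly Uniform(0,1) residuals.  Uniformity
is assessed with a chi-squared test over 10 equally sized bins, one panel per
submodel (US tracks, RU tracks, US counts, RU counts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class RQRSet:
    """Residuals for one submodel, with the seed that generated the
    randomization deviates (diagnostics are reproducible)."""

    residuals: np.ndarray
    submodel: str
    seed: int | None = None

    def __post_init__(self) -> None:
        self.residuals = np.asarray(self.residuals, dtype=float)
        if len(self.residuals) and (
                self.residuals.min() < 0 or self.residuals.max() > 1):
            raise ValueError("residuals must lie in [0, 1]")


def rqr(y, dist: str, u, mu=None, size=None, p=None) -> np.ndarray:
    """Randomized quantile residual(s) ``P(Y < y) + u * P(Y = y)``.

    ``dist`` is ``"poisson"`` (fitted mean ``mu``) or ``"binomial"`` (fitted
    ``size`` and ``p``).  Uses the lower-CDF convention so residuals are
    exactly uniform under the fitted model.
    """
    y = np.asarray(y)
    u = np.asarray(u, dtype=float)
    if np.any((u < 0) | (u > 1)):
        raise ValueError("uniform deviates must lie in [0, 1]")
    if dist == "poisson":
        if mu is None or np.any(np.asarray(mu) < 0):
            raise ValueError("poisson requires nonnegative fitted mean mu")
        lower = stats.poisson.cdf(y - 1, mu)
        mass = stats.poisson.pmf(y, mu)
    elif dist == "binomial":
        if size is None or p is None or np.any((np.asarray(p) < 0)
                                               | (np.asarray(p) > 1)):
            raise ValueError("binomial requires size and p in [0, 1]")
        lower = stats.binom.cdf(y - 1, size, p)
        mass = stats.binom.pmf(y, size, p)
    else:
        raise ValueError(f"unknown distribution {dist!r}")
    return lower + u * mass


def uniformity_chisq(residuals, bins: int = 10):
    """Chi-squared uniformity test with equally sized bins on [0, 1].

    Returns ``(statistic, p_value)`` with ``bins - 1`` degrees of freedom.
    """
    residuals = np.asarray(residuals, dtype=float)
    n = len(residuals)
    if n == 0:
        raise ValueError("no residuals to test")
    if n < bins:
        import warnings
        warnings.warn(f"only {n} residuals for {bins} bins; "
                      "test will have little power")
    observed, _ = np.histogram(residuals, bins=bins, range=(0.0, 1.0))
    expected = n / bins
    statistic = float(np.sum((observed - expected) ** 2 / expected))
    p_value = float(stats.chi2.sf(statistic, df=bins - 1))
    return statistic, p_value


def fit_residuals(fit, data, grid, cov, seed: int = 0) -> dict[str, RQRSet]:
    """RQRs of a joint fit, one set per submodel panel.

    Panels: ``us_tracks`` (binomial photo-track indicators), ``ru_tracks``
    (Poisson observer track counts), ``us_counts`` (thermal + auxiliary
    Poisson counts), ``ru_counts`` (visual Poisson counts).
    """
    from .detection import halfnormal_p
    from .joint import JointModel
    from .tracks import photo_track_prob

    rng = np.random.default_rng(seed)
    p = fit.params
    model = JointModel(data, grid, cov, None, g0=p.g0)
    # fitted surfaces from the fit object (S, T)
    Z = fit.Z_hat
    pi = fit.pi_hat
    out = {}

    us, ru = data.track.us, data.track.ru
    if len(us):
        s, t = us["cell_id"].to_numpy(), us["day"].to_numpy()
        phi = photo_track_prob(Z[s, t])
        u = rng.uniform(size=len(us))
        out["us_tracks"] = RQRSet(
            rqr(us["tracks"].to_numpy(), "binomial", u,
                size=us["photos"].to_numpy(), p=phi), "us_tracks", seed)
    if len(ru):
        s, t = ru["cell_id"].to_numpy(), ru["day"].to_numpy()
        lam = ru["length_km"].to_numpy() * p.eta * Z[s, t]
        u = rng.uniform(size=len(ru))
        out["ru_tracks"] = RQRSet(
            rqr(ru["tracks"].to_numpy(), "poisson", u, mu=lam),
            "ru_tracks", seed)

    if len(model.cnt):
        p_rus = halfnormal_p(p.sigma, data.w, p.g0)
        theta_row = np.array([p.p_us, p.xi * p.p_us, p_rus])
        mu = (p.N * model.cnt_a * theta_row[model.cnt_code]
              * pi.T.ravel()[model.cnt_idx])
        u = rng.uniform(size=len(model.cnt))
        res = rqr(model.cnt, "poisson", u, mu=mu)
        us_mask = model.cnt_code <= 1
        if us_mask.any():
            out["us_counts"] = RQRSet(res[us_mask], "us_counts", seed)
        if (~us_mask).any():
            out["ru_counts"] = RQRSet(res[~us_mask], "ru_counts", seed)
    return out


def residual_summary(residual_sets: dict[str, RQRSet],
                     bins: int = 10) -> pd.DataFrame:
    """Chi-squared uniformity table across submodel panels."""
    rows = []
    for name, rs in residual_sets.items():
        stat, pval = uniformity_chisq(rs.residuals, bins=bins)
        rows.append({"submodel": name, "n": len(rs.residuals),
                     "chisq": stat, "p_value": pval})
    return pd.DataFrame(rows)
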