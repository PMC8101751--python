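"""Joint spatio-temporal abundance model with Laplace-marginalized likelihood.

The estimator assumes a closed population of ``N`` polar bear groups that
redistributes itself across the survey grid each day: cell occupancy
probabilities follow an area-weighted softmax

``pi_st = A_s exp(nu_st) / sum_s A_s exp(nu_st)``

where ``A_s`` is the saltwater habitat of cell ``s`` and the linear predictor
``nu`` (no intercept) combines penalized spline smooths of habitat covariates,
a fixed -50 coefficient on the open-water indicator, and a linear effect of
the latent track intensity.  Observed group counts are Poisson-thinned,
``C_st ~ Poisson(N pi_st p_st)`` with compound detection ``p = theta * a``
(per-group detectability times fractional cell coverage); auxiliary visual
counts carry an extra relative-detectability scaling ``xi``.  Mean group size
``mu_g`` (shifted Poisson) converts group abundance to bears,
``N* = mu_g N``.

All data streams — tracks, counts, flyover trials, perpendicular distances,
group sizes — enter one joint likelihood.  Spline coefficients ``alpha`` are
random effects integrated out by a Laplace approximation at their conditional
mode (found by a damped Newton solver with analytic gradient and Hessian);
smoothing parameters ``lambda_i`` are optimized on the log scale alongside
the other fixed parameters, carrying Gamma(0.05, 0.005) log-priors
(empirical-Bayes treatment of the formal integral over lambda).  Standard
errors come from the numeric Hessian of the marginal negative log likelihood,
and intervals for abundance are 95% log-based (multiplicatively symmetric).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy.linalg import cho_factor as _cho_factor, cho_solve as _cho_solve

from .detection import (DistanceData, FlyoverTrials, distance_nll,
                        fit_distance, flyover_estimate, halfnormal_p)
from .laplace import numeric_hessian
from .smooths import SmoothSpec
from .tracks import (TRACK_DESIGN_COLUMNS, WATER99_COEF, TrackData,
                     TrackParams, build_track_design, fit_track, track_nll)

#: Fixed effective strip width of the visual platform (km): 0.6 km per side.
RU_STRIP_WIDTH_KM = 1.2

#: Gamma prior on smoothing parameters: shape, rate (mean = 10).
LAMBDA_PRIOR_SHAPE = 0.05
LAMBDA_PRIOR_RATE = 0.005

_COUNT_CODES = {("us", "thermal"): 0, ("us", "aux"): 1, ("ru", "visual"): 2}


# ---------------------------------------------------------------------------
# data containers


@dataclass
class SurveyData:
    """All survey observations on the grid x day index.

    ``counts`` rows: cell_id, day, platform ('us'/'ru'), kind
    ('thermal'/'aux'/'visual'), count.  ``effort`` rows: cell_id, day,
    platform, length_km (visual transect km), footprint_km2 (photographed
    area).  ``distances`` rows: cell_id, day, distance_m.
    """

    track: TrackData = field(default_factory=TrackData)
    counts: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["cell_id", "day", "platform", "kind", "count"]))
    effort: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["cell_id", "day", "platform", "length_km", "footprint_km2"]))
    distances: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["cell_id", "day", "distance_m"]))
    w: float = 600.0
    breakpoint: float = 350.0
    trials: FlyoverTrials | None = None
    group_sizes: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        self.group_sizes = np.asarray(self.group_sizes, dtype=int)

    @property
    def distance_data(self) -> DistanceData:
        return DistanceData(self.distances["distance_m"].to_numpy(dtype=float),
                            w=self.w, breakpoint=self.breakpoint)

    def validate(self) -> None:
        self.track.validate()
        if len(self.counts):
            if (self.counts["count"] < 0).any():
                raise ValueError("counts must be nonnegative")
        if len(self.group_sizes) and np.any(self.group_sizes < 1):
            raise ValueError("group sizes must be >= 1")


def coverage_fraction(length_km: float, footprint_km2: float, platform: str,
                      saltwater_area_km2: float) -> float:
    """Fraction of a cell's saltwater habitat covered by one day's effort.

    Visual platform: ``L * 1.2 / A`` (fixed 1.2-km strip); thermal platform:
    photographed footprint / A.  Clipped to [0, 1].
    """
    effortful = (length_km > 0) or (footprint_km2 > 0)
    if saltwater_area_km2 <= 0:
        if effortful:
            raise ValueError("nonzero effort in a cell without saltwater")
        return 0.0
    if platform == "ru":
        a = length_km * RU_STRIP_WIDTH_KM / saltwater_area_km2
    elif platform == "us":
        a = footprint_km2 / saltwater_area_km2
    else:
        raise ValueError(f"unknown platform {platform!r}")
    return float(np.clip(a, 0.0, 1.0))


# ---------------------------------------------------------------------------
# likelihood pieces (also usable standalone)


def cell_probs(A, nu=None, alpha=None, smooth_spec=None, t=None, offset=0.0):
    """Area-weighted softmax occupancy probabilities for one day.

    Either pass the linear predictor ``nu`` directly, or ``alpha`` +
    ``smooth_spec`` + day ``t`` (plus any fixed ``offset``, e.g. the open
    water gate and the track effect).  Cells with ``A = 0`` get probability
    exactly 0; the rest sum to 1.
    """
    A = np.asarray(A, dtype=float)
    if np.all(A <= 0):
        raise ValueError("no saltwater habitat anywhere")
    S = len(A)
    if nu is None:
        X = smooth_spec.X[t * S:(t + 1) * S]
        nu = X @ alpha + np.broadcast_to(offset, (S,))
    nu = np.asarray(nu, dtype=float)
    log_w = np.where(A > 0, np.log(np.where(A > 0, A, 1.0)), -np.inf)
    log_num = log_w + nu
    pi = np.exp(log_num - special.logsumexp(log_num))
    return pi


def alpha_prior_nll(alpha: np.ndarray, lam: np.ndarray,
                    smooth_spec: SmoothSpec) -> float:
    """Negative Gaussian log density of the spline coefficients.

    The precision is block-diagonal ``lambda_i S_i``; penalty null spaces are
    handled with the pseudo-determinant, i.e. the density is proper on the
    penalized subspace and flat along the (data-identified) null directions.
    """
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("smoothing parameters must be positive")
    quad = 0.0
    log_norm = 0.0
    total_rank = 0
    for lam_i, s, blk in zip(lam, smooth_spec.smooths, smooth_spec.blocks):
        a = alpha[blk]
        quad += lam_i * (a @ s.S @ a)
        log_norm += s.rank * np.log(lam_i) + s.log_pdet
        total_rank += s.rank
    return float(0.5 * quad - 0.5 * log_norm
                 + 0.5 * total_rank * np.log(2 * np.pi))


def lambda_prior_nll(lam: np.ndarray) -> float:
    """Negative log prior of smoothing parameters on the log scale.

    Gamma(0.05, 0.005) density on ``lambda`` plus the Jacobian of the
    log-scale parameterization.
    """
    lam = np.asarray(lam, dtype=float)
    a, b = LAMBDA_PRIOR_SHAPE, LAMBDA_PRIOR_RATE
    return float(np.sum(b * lam - a * np.log(lam)
                        - a * np.log(b) + special.gammaln(a)))


def count_nll(data: SurveyData, grid, N: float, pi: np.ndarray,
              p_us: float, p_rus: float, xi: float = 1.0) -> float:
    """Poisson negative log likelihood of all count streams.

    ``pi`` is the (S, T) occupancy surface.  Thermal rows have mean
    ``N pi p_us a``, auxiliary rows ``xi N pi p_us a``, visual rows
    ``N pi p_rus a``.
    """
    if not len(data.counts):
        return 0.0
    A = grid.saltwater_area
    eff = data.effort.set_index(["cell_id", "day", "platform"])
    nll = 0.0
    for row in data.counts.itertuples(index=False):
        e = eff.loc[(row.cell_id, row.day, row.platform)]
        a = coverage_fraction(float(e["length_km"]), float(e["footprint_km2"]),
                              row.platform, A[row.cell_id])
        theta = {"thermal": p_us, "aux": xi * p_us, "visual": p_rus}[row.kind]
        mu = N * pi[row.cell_id, row.day] * theta * a
        if mu == 0:
            if row.count > 0:
                raise ValueError("positive count with zero detection rate")
            continue
        nll -= row.count * np.log(mu) - mu - special.gammaln(row.count + 1)
    return float(nll)


def groupsize_nll(g: np.ndarray, mu_g: float) -> float:
    """Shifted-Poisson negative log likelihood of observed group sizes."""
    g = np.asarray(g, dtype=float)
    if np.any(g < 1):
        raise ValueError("group sizes must be >= 1")
    if not mu_g >= 1:
        raise ValueError("mean group size must be >= 1")
    if len(g) == 0:
        return 0.0
    gm1 = g - 1.0
    if mu_g == 1.0:
        return float(np.inf) if gm1.sum() > 0 else 0.0
    lam = mu_g - 1.0
    return float(np.sum(lam - gm1 * np.log(lam) + special.gammaln(g)))


def groupsize_mle(g: np.ndarray) -> float:
    """MLE of mean group size under the shifted Poisson: the sample mean."""
    g = np.asarray(g, dtype=float)
    if len(g) == 0:
        raise ValueError("no group sizes observed")
    if np.any(g < 1):
        raise ValueError("group sizes must be >= 1")
    return float(g.mean())


def flyover_nll(trials: FlyoverTrials, p_us: float) -> float:
    n, D = trials.n, trials.detected
    if p_us <= 0 or p_us >= 1:
        if (D > 0 and p_us <= 0) or (D < n and p_us >= 1):
            return float(np.inf)
        return 0.0
    return float(-(special.gammaln(n + 1) - special.gammaln(D + 1)
                   - special.gammaln(n - D + 1)
                   + D * np.log(p_us) + (n - D) * np.log1p(-p_us)))


# ---------------------------------------------------------------------------
# parameter containers


@dataclass
class AbundanceParams:
    """Fixed parameters of the joint model, on their working scales."""

    log_N: float
    beta: np.ndarray
    alpha_tracks: float = 0.0
    log_lambda: np.ndarray = field(default_factory=lambda: np.empty(0))
    log_eta: float = 0.0
    log_xi: float = 0.0
    log_sigma: float = float(np.log(250.0))
    logit_p_us: float = float(special.logit(0.67))
    log_mu_g_m1: float | None = float(np.log(0.4))
    g0: float = 1.0

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.log_lambda = np.asarray(self.log_lambda, dtype=float)

    @property
    def N(self) -> float:
        return float(np.exp(self.log_N))

    @property
    def lam(self) -> np.ndarray:
        return np.exp(self.log_lambda)

    @property
    def eta(self) -> float:
        return float(np.exp(self.log_eta))

    @property
    def xi(self) -> float:
        return float(np.exp(self.log_xi))

    @property
    def sigma(self) -> float:
        return float(np.exp(self.log_sigma))

    @property
    def p_us(self) -> float:
        return float(special.expit(self.logit_p_us))

    @property
    def mu_g(self) -> float:
        if self.log_mu_g_m1 is None:
            return 1.0
        return float(1.0 + np.exp(self.log_mu_g_m1))


@dataclass
class FitResult:
    """Joint-model fit: estimates, uncertainty, and predicted surfaces."""

    theta_names: list[str]
    theta: np.ndarray
    se: np.ndarray
    cov_matrix: np.ndarray
    params: AbundanceParams
    alpha: np.ndarray
    N_hat: float
    mu_g_hat: float
    N_star: float
    se_N_star: float
    ci_N_star: tuple[float, float]
    pi_hat: np.ndarray      # (S, T)
    N_surface: np.ndarray   # (S, T) expected bears per cell-day
    Z_hat: np.ndarray       # (S, T) track intensity
    convergence: dict

    def se_for(self, name: str) -> float:
        return float(self.se[self.theta_names.index(name)])

    def estimate_for(self, name: str) -> float:
        return float(self.theta[self.theta_names.index(name)])

    def ci_N(self) -> tuple[float, float]:
        """95% log-based CI for the number of groups N."""
        se_log = self.se_for("log_N")
        return lognormal_ci(self.N_hat, self.N_hat * se_log)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"parameter": self.theta_names,
                             "estimate": self.theta, "se": self.se})


def lognormal_ci(point: float, se: float,
                 z: float = 1.959963984540054) -> tuple[float, float]:
    """95% log-based interval ``point * exp(+-z sqrt(log(1+CV^2)))``."""
    if point <= 0 or not np.isfinite(se):
        return (np.nan, np.nan)
    cv = se / point
    half = np.exp(z * np.sqrt(np.log1p(cv * cv)))
    return (point / half, point * half)


# ---------------------------------------------------------------------------
# the fitting machine


class JointModel:
    """Precomputed designs and likelihood evaluation for one dataset.

    Day-major flattening throughout: row ``t * S + s`` holds cell ``s`` on
    day ``t``.
    """

    #: parameter names that always exist, in packing order (lambdas inserted)
    def __init__(self, data: SurveyData, grid, cov,
                 smooth_spec: SmoothSpec | None, g0: float = 1.0,
                 fix: dict | None = None, control: dict | None = None):
        data.validate()
        self.data = data
        self.grid = grid
        self.cov = cov
        self.spec = smooth_spec if smooth_spec is not None else SmoothSpec([])
        self.g0 = float(g0)
        self.control = {"inner_tol": 1e-8, "inner_maxiter": 100,
                        "jitter": 1e-6, "null_ridge": 1e-4}
        self.control.update(control or {})

        S, T = cov.n_cells, cov.n_days
        self.S, self.T = S, T
        self.Y = (self.spec.X if self.spec.n_coef else
                  np.empty((S * T, 0)))
        if self.Y.shape[0] not in (0, S * T):
            raise ValueError("smooth basis rows do not match grid x days")
        self.k_alpha = self.Y.shape[1]
        self.Y3 = self.Y.reshape(T, S, self.k_alpha)
        self.w99_flat = cov.water99.T.ravel()
        self.off_w99 = WATER99_COEF * self.w99_flat
        self.X_track = build_track_design(cov)
        A = grid.saltwater_area
        logA = np.where(A > 0, np.log(np.where(A > 0, A, 1.0)), -np.inf)
        self.logA_flat = np.tile(logA, T)

        # count rows joined with effort -> coverage fractions
        idx, cnt, acov, code = [], [], [], []
        if len(data.counts):
            eff = data.effort.groupby(
                ["cell_id", "day", "platform"], as_index=True).sum(
                numeric_only=True)
            for row in data.counts.itertuples(index=False):
                key = (row.cell_id, row.day, row.platform)
                if key not in eff.index:
                    if row.count > 0:
                        raise ValueError(
                            f"count without recorded effort at {key}")
                    continue
                e = eff.loc[key]
                a = coverage_fraction(float(e["length_km"]),
                                      float(e["footprint_km2"]),
                                      row.platform, A[row.cell_id])
                if a == 0:
                    if row.count > 0:
                        raise ValueError(
                            f"positive count with zero coverage at {key}")
                    continue
                idx.append(row.day * S + row.cell_id)
                cnt.append(row.count)
                acov.append(a)
                code.append(_COUNT_CODES[(row.platform, row.kind)])
        self.cnt_idx = np.asarray(idx, dtype=int)
        self.cnt = np.asarray(cnt, dtype=float)
        self.cnt_a = np.asarray(acov, dtype=float)
        self.cnt_code = np.asarray(code, dtype=int)
        self.cnt_day = self.cnt_idx // S
        self.cnt_lgamma = float(np.sum(special.gammaln(self.cnt + 1)))
        self.has_aux = bool(np.any(self.cnt_code == 1))

        # track rows
        us, ru = data.track.us, data.track.ru
        self.us_idx = (us["day"].to_numpy(int) * S
                       + us["cell_id"].to_numpy(int)) if len(us) else \
            np.empty(0, dtype=int)
        self.us_P = us["photos"].to_numpy(float) if len(us) else np.empty(0)
        self.us_y = us["tracks"].to_numpy(float) if len(us) else np.empty(0)
        self.ru_idx = (ru["day"].to_numpy(int) * S
                       + ru["cell_id"].to_numpy(int)) if len(ru) else \
            np.empty(0, dtype=int)
        self.ru_L = ru["length_km"].to_numpy(float) if len(ru) else np.empty(0)
        self.ru_y = ru["tracks"].to_numpy(float) if len(ru) else np.empty(0)
        self.has_tracks = len(us) + len(ru) > 0
        self._track_const = float(
            np.sum(special.gammaln(self.us_P + 1)
                   - special.gammaln(self.us_y + 1)
                   - special.gammaln(self.us_P - self.us_y + 1))
            - np.sum(special.gammaln(self.ru_y + 1)))

        # distances, groups, trials
        x = data.distances["distance_m"].to_numpy(dtype=float) \
            if len(data.distances) else np.empty(0)
        self.dist = DistanceData(x, w=data.w, breakpoint=data.breakpoint) \
            if len(x) else None
        g = data.group_sizes
        self.groups = g
        self.mu_g_fixed_one = len(g) == 0 or bool(np.all(g == 1))
        self.trials = data.trials

        # parameter layout
        names = ["log_N"]
        names += [f"beta_{c}" for c in TRACK_DESIGN_COLUMNS]
        names += ["alpha_tracks"]
        names += [f"log_lambda_{n}" for n in self.spec.names]
        names += ["log_eta", "log_xi", "log_sigma", "logit_p_us",
                  "log_mu_g_m1"]
        self.all_names = names
        defaults = {"log_N": np.log(100.0), "alpha_tracks": 0.0,
                    "log_eta": 0.0, "log_xi": 0.0,
                    "log_sigma": np.log(250.0),
                    "logit_p_us": float(special.logit(0.67)),
                    "log_mu_g_m1": np.log(0.4)}
        for c in TRACK_DESIGN_COLUMNS:
            defaults[f"beta_{c}"] = 0.0
        for n in self.spec.names:
            defaults[f"log_lambda_{n}"] = np.log(10.0)
        self.defaults = defaults

        fix = dict(fix or {})
        if not self.has_tracks:
            for c in TRACK_DESIGN_COLUMNS:
                fix.setdefault(f"beta_{c}", 0.0)
            fix.setdefault("log_eta", 0.0)
            fix.setdefault("alpha_tracks", 0.0)
        if not self.has_aux:
            fix.setdefault("log_xi", 0.0)
        if self.dist is None:
            fix.setdefault("log_sigma", np.log(250.0))
        if self.trials is None and not np.any(self.cnt_code <= 1):
            fix.setdefault("logit_p_us", float(special.logit(0.67)))
        if self.mu_g_fixed_one:
            fix["log_mu_g_m1"] = None  # mu_g pinned to 1
        self.fixed = fix
        self.free_names = [n for n in names if n not in fix]
        self._alpha_warm = np.zeros(self.k_alpha)
        self.n_inner_calls = 0

    # -- parameter plumbing -------------------------------------------------

    def full_theta(self, theta_free: np.ndarray) -> dict:
        out = {}
        it = iter(theta_free)
        for n in self.all_names:
            if n in self.fixed:
                out[n] = self.fixed[n]
            else:
                out[n] = float(next(it))
        return out

    def params_from(self, theta: dict) -> AbundanceParams:
        return AbundanceParams(
            log_N=theta["log_N"],
            beta=np.array([theta[f"beta_{c}"] for c in TRACK_DESIGN_COLUMNS]),
            alpha_tracks=theta["alpha_tracks"],
            log_lambda=np.array([theta[f"log_lambda_{n}"]
                                 for n in self.spec.names]),
            log_eta=theta["log_eta"], log_xi=theta["log_xi"],
            log_sigma=theta["log_sigma"], logit_p_us=theta["logit_p_us"],
            log_mu_g_m1=theta["log_mu_g_m1"], g0=self.g0)

    # -- likelihood evaluation ----------------------------------------------

    def _prepare(self, p: AbundanceParams) -> dict:
        logZ = self.X_track @ p.beta + self.off_w99
        Z = np.exp(logZ)
        Z_std = Z / Z.mean()
        offset = self.off_w99 + p.alpha_tracks * Z_std
        theta_log = np.empty(3)
        p_us = p.p_us
        p_rus = halfnormal_p(p.sigma, self.data.w, self.g0) \
            if (self.dist is not None or np.any(self.cnt_code == 2)) else 1.0
        with np.errstate(divide="ignore"):
            theta_log[0] = np.log(p_us) if p_us > 0 else -np.inf
            theta_log[1] = np.log(p.xi) + theta_log[0]
            theta_log[2] = np.log(p_rus)
        log_rf = (p.log_N + np.log(self.cnt_a)
                  + theta_log[self.cnt_code]) if len(self.cnt) else \
            np.empty(0)
        return {"logZ": logZ, "Z_std": Z_std, "offset": offset,
                "log_rf": log_rf, "p_rus": p_rus, "p": p}

    def _occupancy(self, alpha: np.ndarray, offset: np.ndarray):
        nu = (self.Y @ alpha if self.k_alpha else 0.0) + offset
        log_num = self.logA_flat + nu
        M = log_num.reshape(self.T, self.S)
        log_den = special.logsumexp(M, axis=1)
        log_pi = (M - log_den[:, None])
        with np.errstate(over="ignore"):
            pi = np.exp(log_pi)
        return log_pi.ravel(), pi  # flat day-major, and (T, S)

    def _count_terms(self, alpha, prep, want_derivs=False):
        log_pi_flat, pi_ts = self._occupancy(alpha, prep["offset"])
        log_mu = prep["log_rf"] + log_pi_flat[self.cnt_idx]
        mu = np.exp(log_mu)
        f = float(np.sum(mu) - np.sum(self.cnt * log_mu) + self.cnt_lgamma)
        if not want_derivs:
            return f, pi_ts
        r = mu - self.cnt
        Ybar = np.einsum("ts,tsk->tk", pi_ts, self.Y3)
        Yc_rows = self.Y[self.cnt_idx] - Ybar[self.cnt_day]
        G = Yc_rows.T @ r
        H_gn = (Yc_rows * mu[:, None]).T @ Yc_rows
        H = H_gn.copy()
        R_t = np.bincount(self.cnt_day, weights=r, minlength=self.T)
        for t in np.flatnonzero(np.abs(R_t) > 0):
            Yc_t = self.Y3[t] - Ybar[t]
            V_t = (Yc_t * pi_ts[t][:, None]).T @ Yc_t
            H -= R_t[t] * V_t
        return f, pi_ts, G, H, H_gn

    def inner_solve(self, prep, alpha0=None):
        """Conditional mode of the spline coefficients by damped Newton.

        Returns ``(alpha_hat, f_at_mode, H_at_mode, pi_ts, n_iter)`` where
        ``f`` includes the penalty quadratic form.
        """
        k = self.k_alpha
        p = prep["p"]
        if k == 0:
            f, pi_ts = self._count_terms(np.empty(0), prep)
            return np.empty(0), f, np.empty((0, 0)), pi_ts, 0
        # weak proper ridge on the coefficients keeps the Laplace curvature
        # positive definite along penalty-null directions the data barely see
        P = self.spec.penalty(p.lam) + self.control["null_ridge"] * np.eye(k)
        alpha = (self._alpha_warm if alpha0 is None else alpha0).copy()
        tol = self.control["inner_tol"]
        f, pi_ts, G, H, H_gn = self._count_terms(alpha, prep,
                                                 want_derivs=True)
        f += 0.5 * alpha @ P @ alpha
        G = G + P @ alpha
        eye = np.eye(k)
        it = 0
        for it in range(1, self.control["inner_maxiter"] + 1):
            if np.max(np.abs(G)) <= tol:
                break
            step = self._newton_step(H, H_gn, P, G, eye)
            dec = -(G @ step)  # Newton decrement
            if dec <= 1e-16 * (1.0 + abs(f)):
                break
            if dec <= 1e-3 * (1.0 + abs(f)):
                # quadratic regime: full undamped steps converge the mode to
                # near machine precision (the Laplace log-determinant is
                # first-order sensitive to residual mode error)
                cand = alpha + step
                fc, pc, Gc, Hc, Hgc = self._count_terms(cand, prep,
                                                        want_derivs=True)
                fc += 0.5 * cand @ P @ cand
                alpha, f, pi_ts = cand, fc, pc
                G, H, H_gn = Gc + P @ cand, Hc, Hgc
                continue
            t_ls = 1.0
            for _ in range(30):
                cand = alpha + t_ls * step
                fc, pc, Gc, Hc, Hgc = self._count_terms(cand, prep,
                                                        want_derivs=True)
                fc += 0.5 * cand @ P @ cand
                if fc <= f + 1e-4 * t_ls * (G @ step) or fc < f:
                    break
                t_ls *= 0.5
            else:
                break  # no descent found: accept current point
            alpha, f, pi_ts = cand, fc, pc
            G, H, H_gn = Gc + P @ cand, Hc, Hgc
        self._alpha_warm = alpha.copy()
        self.n_inner_calls += 1
        return alpha, f, H + P, pi_ts, it

    def _newton_step(self, H, H_gn, P, G, eye):
        """Descent direction: exact Newton if PD, else damped Gauss-Newton."""
        try:
            c, low = _cho_factor(H + P)
            return -_cho_solve((c, low), G)
        except np.linalg.LinAlgError:
            pass
        ridge = self.control["jitter"] * max(
            1.0, float(np.abs(np.diag(H_gn)).max(initial=1.0)))
        for _ in range(12):
            try:
                c, low = _cho_factor(H_gn + P + ridge * eye)
                return -_cho_solve((c, low), G)
            except np.linalg.LinAlgError:
                ridge *= 100.0
        return -G / max(1.0, float(np.linalg.norm(G)))

    def _theta_only_nll(self, prep) -> float:
        p = prep["p"]
        nll = 0.0
        if self.has_tracks:
            logZ = prep["logZ"]
            if len(self.us_idx):
                BZ = 0.012 * np.exp(logZ[self.us_idx])
                log_phi = np.log(-np.expm1(-np.clip(BZ, 1e-300, None)))
                nll -= float(np.sum(self.us_y * log_phi
                                    - (self.us_P - self.us_y) * BZ))
            if len(self.ru_idx):
                log_lam = (np.log(self.ru_L) + p.log_eta
                           + logZ[self.ru_idx])
                nll -= float(np.sum(self.ru_y * log_lam - np.exp(log_lam)))
            nll -= self._track_const
        if self.dist is not None:
            nll += distance_nll(p.sigma, self.dist, "halfnormal")
        if self.trials is not None:
            nll += flyover_nll(self.trials, p.p_us)
        if not self.mu_g_fixed_one:
            nll += groupsize_nll(self.groups, p.mu_g)
        if self.spec.n_coef:
            nll += lambda_prior_nll(p.lam)
        return nll

    def _alpha_prior_norm(self, lam) -> float:
        """Normalizing part of the alpha prior (quadratic lives inner).

        With the propriety ridge the prior precision ``P + eps I`` is full
        rank, so the exact Gaussian constant ``-1/2 log det(P + eps I) +
        (k/2) log 2 pi`` applies; without it, the pseudo-determinant over the
        penalized subspace is used.
        """
        if not self.spec.n_coef:
            return 0.0
        ridge = self.control["null_ridge"]
        if ridge > 0:
            P = (self.spec.penalty(np.asarray(lam))
                 + ridge * np.eye(self.k_alpha))
            sign, logdet = np.linalg.slogdet(P)
            return float(-0.5 * logdet
                         + 0.5 * self.k_alpha * np.log(2 * np.pi))
        log_norm = sum(s.rank * np.log(l) + s.log_pdet
                       for l, s in zip(lam, self.spec.smooths))
        total_rank = sum(s.rank for s in self.spec.smooths)
        return float(-0.5 * log_norm + 0.5 * total_rank * np.log(2 * np.pi))

    def marginal_nll(self, theta_free: np.ndarray) -> float:
        theta = self.full_theta(np.asarray(theta_free, dtype=float))
        p = self.params_from(theta)
        prep = self._prepare(p)
        alpha, f_inner, H, _, _ = self.inner_solve(prep)
        val = f_inner + self._alpha_prior_norm(p.lam)
        if self.k_alpha:
            sign, logdet = np.linalg.slogdet(H)
            if sign <= 0:
                H = H + (self.control["jitter"]
                         * max(1.0, np.abs(np.diag(H)).max())
                         * np.eye(self.k_alpha))
                sign, logdet = np.linalg.slogdet(H)
                if sign <= 0:
                    return 1e12
            val += 0.5 * logdet - 0.5 * self.k_alpha * np.log(2 * np.pi)
        val += self._theta_only_nll(prep)
        if not np.isfinite(val):
            return 1e12
        return float(val)

    def integrand_nll(self, params: AbundanceParams,
                      alpha: np.ndarray) -> float:
        """Joint negative log likelihood at given (theta, alpha): the
        integrand of the marginal likelihood, priors included."""
        prep = self._prepare(params)
        f, _ = self._count_terms(np.asarray(alpha, dtype=float), prep)
        if self.spec.n_coef:
            f += alpha_prior_nll(np.asarray(alpha, dtype=float),
                                 params.lam, self.spec)
        return float(f + self._theta_only_nll(prep))


def joint_nll(params: AbundanceParams, alpha: np.ndarray, data: SurveyData,
              grid, cov, smooth_spec: SmoothSpec | None = None,
              g0: float | None = None) -> float:
    """Joint negative log likelihood of all data streams plus priors.

    The integrand of the marginal likelihood, evaluated at fixed parameters
    and spline coefficients.  Differentiable in all continuous parameters.
    """
    model = JointModel(data, grid, cov, smooth_spec,
                       g0=params.g0 if g0 is None else g0)
    return model.integrand_nll(params, alpha)


# ---------------------------------------------------------------------------
# fitting


_BOUNDS = {
    "log_N": (-5.0, 25.0), "alpha_tracks": (-50.0, 50.0),
    "log_eta": (-20.0, 20.0), "log_xi": (-10.0, 10.0),
    "log_sigma": (0.0, 12.0), "logit_p_us": (-8.0, 8.0),
    "log_mu_g_m1": (-10.0, 5.0),
}


def _bound_for(name: str):
    if name.startswith("beta_"):
        return (-30.0, 30.0)
    if name.startswith("log_lambda_"):
        return (-20.0, 20.0)
    return _BOUNDS[name]


def _initial_theta(model: JointModel) -> dict:
    data, grid, cov = model.data, model.grid, model.cov
    theta = dict(model.defaults)
    if model.has_tracks:
        try:
            tp, _ = fit_track(data.track, cov)
            for c, b in zip(TRACK_DESIGN_COLUMNS, tp.beta):
                theta[f"beta_{c}"] = float(np.clip(b, -25, 25))
            theta["log_eta"] = float(np.clip(np.log(tp.eta), -18, 18))
        except Exception:  # fall back to defaults on degenerate track data
            pass
    if model.dist is not None and len(model.dist.distances) >= 2:
        sigma0, _, _ = fit_distance(model.dist, "halfnormal")
        theta["log_sigma"] = float(np.log(sigma0))
    if model.trials is not None and model.trials.n > 0:
        p0, _ = flyover_estimate(model.trials)
        theta["logit_p_us"] = float(special.logit(np.clip(p0, 0.05, 0.95)))
    if not model.mu_g_fixed_one:
        mu0 = groupsize_mle(model.groups)
        theta["log_mu_g_m1"] = float(np.log(max(mu0 - 1.0, 1e-3)))
    if model.has_aux:
        tot_thermal = model.cnt[model.cnt_code == 0].sum()
        tot_aux = model.cnt[model.cnt_code == 1].sum()
        theta["log_xi"] = float(np.clip(
            np.log((tot_aux + 0.5) / (tot_thermal + 0.5)), -3, 3))
    # moment-style N init: assume occupancy spread uniformly over iced cells
    if len(model.cnt):
        p = model.params_from(theta)
        prep = model._prepare(p)
        n_ice = max(int(np.sum(cov.ice.mean(axis=1) >= 0.01)), 1)
        denom = np.exp(prep["log_rf"] - p.log_N).sum() / n_ice
        n0 = model.cnt.sum() / max(denom, 1e-12)
        theta["log_N"] = float(np.clip(np.log(max(n0, 5.0)), 0.0, 20.0))
    return theta


def _fd_grad(f, x, step):
    n = len(x)
    g = np.empty(n)
    for i in range(n):
        e = np.zeros(n); e[i] = step
        g[i] = (f(x + e) - f(x - e)) / (2 * step)
    return g


def _fd_hess(f, x, step):
    n = len(x)
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = step
            ej = np.zeros(n); ej[j] = step
            H[i, j] = H[j, i] = (f(x + ei + ej) - f(x + ei - ej)
                                 - f(x - ei + ej) + f(x - ei - ej)) \
                / (4 * step * step)
    return H


def _regularized_solve(H, g):
    """Newton direction with eigenvalue flooring (saddle-safe)."""
    eig, V = np.linalg.eigh(0.5 * (H + H.T))
    floor = max(1e-8, 1e-8 * float(np.abs(eig).max()))
    eig_safe = np.where(np.abs(eig) < floor, floor, np.abs(eig))
    return -(V @ ((V.T @ g) / eig_safe))


def _newton_outer(f, x0, bounds, maxiter=30, grad_tol=1e-3):
    """Minimize a noisy-FD objective: preconditioned warmup + Newton polish.

    The objective is rescaled by the square root of its diagonal curvature so
    every direction has near-unit stiffness (track-likelihood directions are
    several orders stiffer than abundance directions), L-BFGS-B takes cheap
    descent steps, and damped Newton iterations with a finite-difference
    Hessian finish the job.  Returns the optimum, the gradient and Hessian in
    the preconditioned space, and the scaling used.
    """
    n = len(x0)
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    x = np.clip(np.asarray(x0, dtype=float), lo, hi)
    if n == 0:
        return x, f(x), np.empty(0), np.empty((0, 0)), np.empty(0), 0

    f0 = f(x)
    diag = np.empty(n)
    h0 = 1e-3 * np.maximum(1.0, np.abs(x))
    for i in range(n):
        e = np.zeros(n); e[i] = h0[i]
        diag[i] = (f(x + e) - 2 * f0 + f(x - e)) / (h0[i] * h0[i])
    scale = np.sqrt(np.clip(diag, 0.25, 1e10))

    x_ref = x.copy()

    def fz(z):
        xx = np.clip(x_ref + z / scale, lo, hi)
        return f(xx)

    res = optimize.minimize(
        fz, np.zeros(n), method="L-BFGS-B",
        bounds=list(zip((lo - x_ref) * scale, (hi - x_ref) * scale)),
        jac="2-point",
        options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-8, "eps": 1e-5})
    z, f_cur = res.x, float(res.fun)

    H_z = _fd_hess(fz, z, 1e-3)
    n_outer = 0
    stale = 0
    for n_outer in range(1, maxiter + 1):
        g = _fd_grad(fz, z, 1e-4)
        if np.max(np.abs(g)) <= grad_tol:
            break
        step = _regularized_solve(H_z, g)
        t = 1.0
        improved = False
        for _ in range(20):
            fc = fz(z + t * step)
            if fc < f_cur - 1e-12 * (1 + abs(f_cur)):
                improved = True
                break
            t *= 0.5
        if improved:
            z = z + t * step
            f_cur = fc
            stale += 1 if t < 0.26 else 0
        if (not improved) or stale >= 2:
            H_z = _fd_hess(fz, z, 1e-3)
            stale = 0
            if not improved:
                g2 = _fd_grad(fz, z, 1e-4)
                step = _regularized_solve(H_z, g2)
                t, improved = 1.0, False
                for _ in range(20):
                    fc = fz(z + t * step)
                    if fc < f_cur - 1e-12 * (1 + abs(f_cur)):
                        improved = True
                        break
                    t *= 0.5
                if improved:
                    z, f_cur = z + t * step, fc
                else:
                    break  # no further descent available
    else:
        g = _fd_grad(fz, z, 1e-4)

    H_z = _fd_hess(fz, z, 1e-3)
    g = _fd_grad(fz, z, 1e-4)
    x_hat = np.clip(x_ref + z / scale, lo, hi)
    return x_hat, f_cur, g, H_z, scale, n_outer


def laplace_fit(data: SurveyData, grid, cov,
                smooth_spec: SmoothSpec | None = None, g0: float = 1.0,
                init: dict | None = None, fix: dict | None = None,
                control: dict | None = None) -> FitResult:
    """Fit the joint model by maximizing the Laplace-marginal likelihood.

    Parameters with no informative data stream (e.g. ``xi`` without auxiliary
    counts) are frozen automatically; ``fix`` pins additional parameters by
    name.  Standard errors come from the numeric Hessian of the marginal
    negative log likelihood; a singular Hessian is reported in
    ``convergence`` and suppresses intervals rather than failing the fit.
    """
    control = dict(control or {})
    outer_maxiter = control.pop("outer_maxiter", 30)
    grad_tol = control.pop("outer_grad_tol", 1e-3)
    want_hessian = control.pop("hessian", True)

    model = JointModel(data, grid, cov, smooth_spec, g0=g0, fix=fix,
                       control=control)
    if len(model.cnt) == 0 or model.cnt.sum() == 0:
        raise ValueError("data are degenerate: no positive counts anywhere")

    theta = _initial_theta(model)
    theta.update(init or {})
    x0 = np.array([theta[n] for n in model.free_names])
    bounds = [_bound_for(n) for n in model.free_names]

    x_hat, f_hat, g_z, H_z, scale, n_outer = _newton_outer(
        model.marginal_nll, x0, bounds, maxiter=outer_maxiter,
        grad_tol=grad_tol)

    n_free = len(x_hat)
    se = np.full(n_free, np.nan)
    cov_matrix = np.full((n_free, n_free), np.nan)
    singular = False
    if want_hessian and n_free:
        # Hessian in the original parameterization from the preconditioned one
        D = np.diag(scale)
        H = D @ H_z @ D
        try:
            cov_matrix = np.linalg.inv(H)
            d = np.diag(cov_matrix)
            if np.any(d <= 0):
                raise np.linalg.LinAlgError("non-PD Hessian")
            se = np.sqrt(d)
        except np.linalg.LinAlgError:
            singular = True
            cov_matrix = np.linalg.pinv(H)
            d = np.diag(cov_matrix)
            se = np.where(d > 0, np.sqrt(np.abs(d)), np.nan)
        hess_cond = float(np.linalg.cond(H))
    else:
        H = None
        hess_cond = np.nan

    theta_hat = model.full_theta(x_hat)
    p_hat = model.params_from(theta_hat)
    prep = model._prepare(p_hat)
    alpha_hat, _, _, pi_ts, _ = model.inner_solve(prep)
    S, T = model.S, model.T
    pi_hat = pi_ts.T  # (S, T)
    N_hat = p_hat.N
    mu_g_hat = p_hat.mu_g
    N_star = mu_g_hat * N_hat

    # delta method for N* = exp(log_N) * (1 + exp(log_mu_g_m1))
    grad = np.zeros(n_free)
    if "log_N" in model.free_names:
        grad[model.free_names.index("log_N")] = N_star
    if "log_mu_g_m1" in model.free_names:
        grad[model.free_names.index("log_mu_g_m1")] = N_hat * (mu_g_hat - 1.0)
    var = float(grad @ cov_matrix @ grad) if n_free else np.nan
    se_N_star = float(np.sqrt(var)) if var >= 0 else np.nan
    if singular or not np.isfinite(se_N_star):
        ci = (np.nan, np.nan)
    else:
        ci = lognormal_ci(N_star, se_N_star)

    grad_norm = float(np.max(np.abs(g_z)))
    success = grad_norm <= 10 * grad_tol
    convergence = {"success": success,
                   "message": ("converged" if success else
                               f"gradient norm {grad_norm:.2e} above "
                               "tolerance"),
                   "n_outer_iter": int(n_outer), "grad_norm": grad_norm,
                   "hessian_singular": singular,
                   "hessian_condition": hess_cond,
                   "n_inner_solves": model.n_inner_calls,
                   "nll": float(f_hat)}
    if singular:
        warnings.warn("marginal Hessian is singular; intervals suppressed",
                      RuntimeWarning)

    Z_hat = np.exp(prep["logZ"]).reshape(T, S).T
    return FitResult(
        theta_names=list(model.free_names), theta=np.asarray(x_hat),
        se=se, cov_matrix=cov_matrix, params=p_hat, alpha=alpha_hat,
        N_hat=N_hat, mu_g_hat=mu_g_hat, N_star=N_star, se_N_star=se_N_star,
        ci_N_star=ci, pi_hat=pi_hat, N_surface=N_star * pi_hat, Z_hat=Z_hat,
        convergence=convergence)


def total_abundance(fit: FitResult) -> tuple[float, float, tuple[float, float]]:
    """Total bear abundance ``N* = mu_g N`` with SE and 95% log-based CI."""
    if not np.isfinite(fit.se_N_star):
        raise ValueError("SE unavailable (singular Hessian)")
    return fit.N_star, fit.se_N_star, fit.ci_N_star
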