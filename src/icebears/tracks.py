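"""Latent track-intensity submodel.

Polar bear tracks are recorded on two incommensurable scales: U.S. flights
systematically photograph the ice and each examined photograph either does or
does not contain tracks, while Russian observers report the number of distinct
tracks seen per surveyed grid cell.  Both are joined on a common latent track
intensity ``Z`` (expected track features per km^2) under a "blocky" Poisson
point-process approximation: within a surveyed cell-day the intensity is
constant, so a photograph of footprint ``B`` km^2 contains at least one track
with probability ``phi = 1 - exp(-B * Z)``, and an observer flying ``L`` km
reports ``Poisson(L * eta * Z)`` tracks, where ``eta`` absorbs the unknown
effective strip width for tracks and the observers' track-delineation rules.

Spatio-temporal variation enters through ``log Z = x'beta`` with a fixed
polynomial design (intercept, distance-to-land linear + quadratic, ice
concentration linear + quadratic, RSF linear).  Cells with essentially no ice
(ice < 1%) additionally receive a fixed -50 offset on the log scale so that no
tracks are predicted in open water.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

#: Average ground footprint of one examined photograph (km^2).
PHOTO_FOOTPRINT_KM2 = 0.012

#: Fixed log-scale offset applied where ice concentration is below 1%.
WATER99_COEF = -50.0

TRACK_DESIGN_COLUMNS = (
    "intercept",
    "dist_land",
    "dist_land_sq",
    "ice",
    "ice_sq",
    "rsf",
)


@dataclass
class TrackParams:
    """Parameters of the track-intensity submodel.

    Attributes
    ----------
    beta
        Coefficients of ``log Z`` on the polynomial design
        (:data:`TRACK_DESIGN_COLUMNS`).
    eta
        Positive scaling converting intensity to expected observer track
        counts per km flown.
    B
        Photograph ground footprint in km^2.
    """

    beta: np.ndarray
    eta: float = 1.0
    B: float = PHOTO_FOOTPRINT_KM2

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (len(TRACK_DESIGN_COLUMNS),):
            raise ValueError(
                f"beta must have {len(TRACK_DESIGN_COLUMNS)} entries, "
                f"got shape {self.beta.shape}"
            )
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("beta must be finite")
        if not self.eta > 0:
            raise ValueError("eta must be positive")
        if not self.B > 0:
            raise ValueError("photo footprint B must be positive")


@dataclass
class TrackData:
    """Track observations from both platforms.

    ``us`` has one row per photographed cell-day with columns
    ``cell_id, day, photos, tracks`` (photos examined, photos with >=1 track);
    ``ru`` has one row per visually surveyed cell-day with columns
    ``cell_id, day, length_km, tracks`` (km flown, number of tracks reported).
    """

    us: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["cell_id", "day", "photos", "tracks"]))
    ru: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["cell_id", "day", "length_km", "tracks"]))

    def validate(self) -> None:
        us, ru = self.us, self.ru
        if len(us):
            if (us["tracks"] < 0).any() or (us["tracks"] > us["photos"]).any():
                raise ValueError("US track rows require 0 <= tracks <= photos")
        if len(ru):
            if (ru["tracks"] < 0).any():
                raise ValueError("RU track counts must be nonnegative")
            if (ru["length_km"] < 0).any():
                raise ValueError("RU transect lengths must be nonnegative")


def build_track_design(cov, cell=None, day=None) -> np.ndarray:
    """Polynomial design row(s) ``[1, d, d^2, ice, ice^2, rsf]``.

    ``cov`` is a :class:`~icebears.synthetic.CovariateField`.  With ``cell``
    and ``day`` given, returns the single row for that cell-day; otherwise
    returns the full ``(S*T, 6)`` design in day-major order (day varying
    slowest), matching the flattening used throughout the package.

    ``d`` is the standardized distance-to-land covariate (divided by its
    grand mean so that it averages 1.0).
    """
    if (cell is None) != (day is None):
        raise ValueError("pass both cell and day, or neither")
    if cell is not None:
        if not (0 <= cell < cov.n_cells) or not (0 <= day < cov.n_days):
            raise KeyError(
                f"no covariates for cell {cell}, day {day} "
                f"(grid has {cov.n_cells} cells, {cov.n_days} days)")
        d = cov.dist_land_std[cell]
        ice = cov.ice[cell, day]
        rsf = cov.rsf[cell]
        row = np.array([1.0, d, d * d, ice, ice * ice, rsf])
        if not np.all(np.isfinite(row)):
            raise ValueError(f"missing covariate for cell {cell}, day {day}")
        return row

    S, T = cov.n_cells, cov.n_days
    d = np.tile(cov.dist_land_std, T)
    ice = cov.ice.T.ravel()  # day-major
    rsf = np.tile(cov.rsf, T)
    X = np.column_stack([np.ones(S * T), d, d * d, ice, ice * ice, rsf])
    if not np.all(np.isfinite(X)):
        bad = np.argwhere(~np.isfinite(X).all(axis=1))[0, 0]
        raise ValueError(
            f"missing covariate for cell {bad % S}, day {bad // S}")
    return X


def track_intensity(x: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Track intensity ``Z = exp(x'beta)`` (tracks per km^2)."""
    x = np.asarray(x, dtype=float)
    beta = np.asarray(beta, dtype=float)
    return np.exp(x @ beta)


def photo_track_prob(Z, B: float = PHOTO_FOOTPRINT_KM2):
    """Probability ``phi = 1 - exp(-B*Z)`` that a photograph shows tracks."""
    Z = np.asarray(Z, dtype=float)
    if np.any(Z < 0):
        raise ValueError("track intensity Z must be nonnegative")
    if not B > 0:
        raise ValueError("photo footprint B must be positive")
    # expm1 keeps precision for small B*Z
    return -np.expm1(-B * Z)


def _log_Z(data_idx_X, beta, offset):
    return data_idx_X @ beta + offset


def track_nll(data: TrackData, params: TrackParams, cov) -> float:
    """Joint negative log likelihood of both platforms' track data.

    US rows contribute Binomial(photos, phi) terms with
    ``phi = 1 - exp(-B*Z)``; RU rows contribute Poisson(L * eta * Z) terms.
    ``log Z = x'beta - 50 * water99`` with the design of
    :func:`build_track_design`.
    """
    data.validate()
    nll = 0.0
    if len(data.us):
        s = data.us["cell_id"].to_numpy()
        t = data.us["day"].to_numpy()
        X = _rows_design(cov, s, t)
        logZ = X @ params.beta + WATER99_COEF * cov.water99[s, t]
        # log(phi) computed stably: phi = 1 - exp(-BZ)
        BZ = params.B * np.exp(logZ)
        log_phi = np.log(-np.expm1(-np.clip(BZ, 1e-300, None)))
        log_1mphi = -BZ
        y = data.us["tracks"].to_numpy()
        n = data.us["photos"].to_numpy()
        ok = n > 0
        nll -= np.sum(
            special.gammaln(n[ok] + 1) - special.gammaln(y[ok] + 1)
            - special.gammaln(n[ok] - y[ok] + 1)
            + y[ok] * log_phi[ok] + (n[ok] - y[ok]) * log_1mphi[ok]
        )
    if len(data.ru):
        s = data.ru["cell_id"].to_numpy()
        t = data.ru["day"].to_numpy()
        X = _rows_design(cov, s, t)
        logZ = X @ params.beta + WATER99_COEF * cov.water99[s, t]
        L = data.ru["length_km"].to_numpy()
        y = data.ru["tracks"].to_numpy()
        ok = L > 0
        log_lam = np.log(L[ok]) + np.log(params.eta) + logZ[ok]
        nll -= np.sum(y[ok] * log_lam - np.exp(log_lam)
                      - special.gammaln(y[ok] + 1))
        if np.any(~ok & (y > 0)):
            raise ValueError("positive track count with zero effort")
    return float(nll)


def _rows_design(cov, s, t):
    d = cov.dist_land_std[s]
    ice = cov.ice[s, t]
    rsf = cov.rsf[s]
    return np.column_stack([np.ones(len(s)), d, d * d, ice, ice * ice, rsf])


def fit_track(data: TrackData, cov, beta0=None, eta0: float = 1.0):
    """Maximum-likelihood fit of the track submodel alone.

    Returns ``(TrackParams, result)`` where ``result`` carries the scipy
    optimizer output plus standard errors from the inverse numeric Hessian.
    Useful on its own and as the initializer for the joint fit.
    """
    k = len(TRACK_DESIGN_COLUMNS)
    if beta0 is None:
        beta0 = np.zeros(k)
        # crude intercept init from the overall track frequency
        if len(data.us) and data.us["photos"].sum() > 0:
            phi_bar = max(1e-4, data.us["tracks"].sum() / data.us["photos"].sum())
            beta0[0] = np.log(-np.log1p(-min(phi_bar, 0.999)) / PHOTO_FOOTPRINT_KM2)

    def nll_vec(v):
        params = TrackParams(beta=v[:k], eta=np.exp(v[k]))
        val = track_nll(data, params, cov)
        return val if np.isfinite(val) else 1e12

    x0 = np.concatenate([beta0, [np.log(eta0)]])
    res = optimize.minimize(nll_vec, x0, method="L-BFGS-B")
    H = _numeric_hessian(nll_vec, res.x)
    try:
        cov_mat = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov_mat), 0, None))
    except np.linalg.LinAlgError:
        cov_mat = np.full((k + 1, k + 1), np.nan)
        se = np.full(k + 1, np.nan)
    params = TrackParams(beta=res.x[:k], eta=float(np.exp(res.x[k])))
    info = {
        "opt": res,
        "se_beta": se[:k],
        "se_log_eta": se[k],
        "cov": cov_mat,
        "nll": float(res.fun),
    }
    return params, info


def _numeric_hessian(f, x, eps: float = 1e-4):
    n = len(x)
    H = np.empty((n, n))
    f0 = f(x)
    step = eps * np.maximum(1.0, np.abs(x))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = step[i]
            ej = np.zeros(n); ej[j] = step[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * step[i] * step[j])
    return H
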