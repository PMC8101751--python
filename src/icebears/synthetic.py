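"""Synthetic study grids, covariates, and survey data.

The generator emulates a springtime dual-platform aerial survey over sea ice:
a planar equal-area lattice of ~25-km cells with a land edge along the
southern boundary, smoothly varying ice concentration that declines (melts)
over the survey window, a telemetry-style relative-use (RSF) field, and two
survey platforms flying parallel north--south transects — a thermal/photo
platform in the eastern ("US") region and a visual/photographic platform in
the western ("RU") region.

Every observation stream is drawn from exactly the distributions the
estimation model assumes: log-linear latent track intensity, binomial
photo-track indicators, Poisson observer track counts, a closed population of
``N`` groups redistributed by a fresh multinomial draw each day with
area-weighted softmax probabilities, Poisson-thinned group counts with
compound detection ``p = theta * a``, truncated half-normal perpendicular
distances, shifted-Poisson group sizes, and binomial flyover trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import special

from .detection import (DEFAULT_BREAKPOINT_M, DEFAULT_TRUNCATION_M,
                        FlyoverTrials, halfnormal_p)
from .joint import RU_STRIP_WIDTH_KM, SurveyData
from .tracks import (PHOTO_FOOTPRINT_KM2, WATER99_COEF, TrackData,
                     build_track_design)

#: Ice concentration below this fraction marks a cell as open water.
WATER99_THRESHOLD = 0.01


@dataclass
class StudyGrid:
    """Regular lattice of survey cells on a planar equal-area convention.

    ``cells`` has one row per cell: ``cell_id`` (0-based), ``easting`` /
    ``northing`` centroid coordinates (km), ``area`` (km^2), ``saltwater_prop``
    (fraction of the cell that is saltwater habitat rather than land), and one
    boolean ``region_<label>`` column per region flag.  Region flags may
    overlap; every cell belongs to the full-grid region ``"all"``.
    """

    cells: pd.DataFrame
    nx: int
    ny: int
    cell_km: float

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def region_labels(self) -> list[str]:
        return [c[len("region_"):] for c in self.cells.columns
                if c.startswith("region_")]

    def region_mask(self, label: str) -> np.ndarray:
        col = f"region_{label}"
        if col not in self.cells.columns:
            raise KeyError(f"unknown region label {label!r}; "
                           f"known: {self.region_labels}")
        return self.cells[col].to_numpy(dtype=bool)

    @property
    def saltwater_area(self) -> np.ndarray:
        """Saltwater habitat area per cell (km^2)."""
        return (self.cells["area"] * self.cells["saltwater_prop"]).to_numpy()

    def validate(self) -> None:
        c = self.cells
        if c["cell_id"].duplicated().any():
            raise ValueError("cell ids must be unique")
        if (c["area"] <= 0).any():
            raise ValueError("cell areas must be positive")
        if ((c["saltwater_prop"] < 0) | (c["saltwater_prop"] > 1)).any():
            raise ValueError("saltwater proportions must lie in [0, 1]")


@dataclass
class CovariateField:
    """Per-cell and per-cell-day covariates on a grid.

    ``ice`` is (S, T); the remaining fields are per-cell.  Distance to land,
    easting, and northing are standardized by division by their grand means
    (each standardized covariate averages 1.0); ice and RSF stay on their
    natural scales.  ``water99`` (ice < 1%) is derived, never stored
    independently.
    """

    ice: np.ndarray
    dist_land: np.ndarray
    rsf: np.ndarray
    easting: np.ndarray
    northing: np.ndarray

    def __post_init__(self) -> None:
        self.ice = np.atleast_2d(np.asarray(self.ice, dtype=float))
        for name in ("dist_land", "rsf", "easting", "northing"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.dist_land < 0):
            raise ValueError("dist_land must be nonnegative")
        if np.any(self.rsf < 0):
            raise ValueError("rsf must be nonnegative")
        if np.any((self.ice < 0) | (self.ice > 1)):
            raise ValueError("ice concentrations must lie in [0, 1]")

    @property
    def n_cells(self) -> int:
        return self.ice.shape[0]

    @property
    def n_days(self) -> int:
        return self.ice.shape[1]

    @property
    def water99(self) -> np.ndarray:
        return (self.ice < WATER99_THRESHOLD).astype(float)

    @property
    def dist_land_std(self) -> np.ndarray:
        return self.dist_land / self.dist_land.mean()

    @property
    def easting_std(self) -> np.ndarray:
        return self.easting / self.easting.mean()

    @property
    def northing_std(self) -> np.ndarray:
        return self.northing / self.northing.mean()

    def smooth_covariates(self) -> dict[str, np.ndarray]:
        """Covariates entering the abundance smooths, as (S, T) arrays."""
        T = self.n_days
        tile = lambda v: np.tile(v[:, None], (1, T))
        return {
            "ice": self.ice,
            "rsf": tile(self.rsf),
            "easting": tile(self.easting_std),
            "northing": tile(self.northing_std),
            "dist_land": tile(self.dist_land_std),
        }


@dataclass
class EffortConfig:
    """Survey effort layout (free knobs of the generator).

    Defaults mirror the reported survey scale: the visual platform flies long
    pre-planned transects (~1500 km/day -> 60 cells at 25 km each) while the
    thermal platform photographs ~10 km^2 per surveyed cell across ~30 cells
    per day.  Photos examined per cell-day is ``floor(footprint / 0.012)``.
    """

    ru_cells_per_day: int = 60
    us_cells_per_day: int = 30
    ru_length_km: float = 25.0
    us_footprint_km2: float = 10.0
    n_trials: int = 12
    w: float = DEFAULT_TRUNCATION_M
    breakpoint: float = DEFAULT_BREAKPOINT_M


@dataclass
class SimScenario:
    """Generating parameters for one synthetic survey.

    The defaults are the package's reference study conditions: 600 groups of
    mean size 1.4 on a 400-cell grid surveyed for 10 days.
    """

    T: int = 10
    true_N: int = 600
    true_mu_g: float = 1.4
    true_sigma: float = 250.0
    true_eta: float = 0.05
    true_xi: float = 1.5
    true_p_us: float = 0.67
    g0: float = 1.0
    true_beta: tuple = (2.0, -0.8, 0.1, 1.5, -0.75, 0.3)
    true_alpha: dict = field(default_factory=lambda: {
        "ice": 2.0, "rsf": 0.5, "dist_land": -0.5,
        "northing": -0.3, "easting": 0.0})
    true_alpha_tracks: float = 0.2
    effort: EffortConfig = field(default_factory=EffortConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if self.true_N < 0:
            raise ValueError("true_N must be nonnegative")
        if self.true_mu_g < 1:
            raise ValueError("mean group size must be >= 1")
        for name in ("true_sigma", "true_eta", "true_xi"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.true_p_us <= 1:
            raise ValueError("true_p_us must lie in [0, 1]")
        if not 0 < self.g0 <= 1:
            raise ValueError("g0 must lie in (0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


def make_grid(nx: int, ny: int, cell_km: float = 25.0,
              seed: int = 0) -> StudyGrid:
    """Build a regular ``nx`` x ``ny`` lattice of square cells.

    Land lies along the southern boundary (northing = 0): the first row of
    cells is partly land (reduced saltwater proportion), the second row
    slightly so.  Region flags: ``all`` (every cell), ``US`` (eastern ~40% of
    columns), ``RU`` (the rest), plus nested ``PBSG`` and ``Regehr``
    analogues (large and small sub-rectangles).
    """
    if nx < 1 or ny < 1:
        raise ValueError("grid dimensions must be >= 1")
    if not cell_km > 0:
        raise ValueError("cell size must be positive")
    rng = np.random.default_rng(seed)
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    ix, iy = ix.ravel(), iy.ravel()
    easting = (ix + 0.5) * cell_km
    northing = (iy + 0.5) * cell_km

    saltwater = np.ones(nx * ny)
    coastal = iy == 0
    saltwater[coastal] = rng.uniform(0.3, 0.9, size=coastal.sum())
    near = iy == 1
    saltwater[near] = rng.uniform(0.85, 1.0, size=near.sum())

    us = ix >= int(np.ceil(0.6 * nx)) if nx > 1 else ix >= 0
    cells = pd.DataFrame({
        "cell_id": np.arange(nx * ny),
        "easting": easting,
        "northing": northing,
        "area": np.full(nx * ny, cell_km * cell_km),
        "saltwater_prop": saltwater,
        "region_all": True,
        "region_US": us,
        "region_RU": ~us,
        # PBSG analogue: everything south of the top 20% of rows
        "region_PBSG": iy < max(1, int(np.ceil(0.8 * ny))),
        # Regehr analogue: small near-shore rectangle in the US region
        "region_Regehr": us & (iy < max(1, ny // 3)),
    })
    grid = StudyGrid(cells=cells, nx=nx, ny=ny, cell_km=cell_km)
    grid.validate()
    return grid


def _bump_field(rng, easting, northing, n_bumps=6):
    """Smooth random spatial field as a sum of radial Gaussian bumps."""
    ex = easting.max() - easting.min() + 1e-9
    ey = northing.max() - northing.min() + 1e-9
    f = np.zeros_like(easting, dtype=float)
    for _ in range(n_bumps):
        cx = rng.uniform(easting.min(), easting.max())
        cy = rng.uniform(northing.min(), northing.max())
        r = rng.uniform(0.2, 0.5) * max(ex, ey)
        wgt = rng.normal()
        f += wgt * np.exp(-((easting - cx) ** 2 + (northing - cy) ** 2)
                          / (2 * r * r))
    sd = f.std()
    return f / sd if sd > 0 else f


def idw_fill(easting, northing, values, missing, power: float = 2.0,
             k: int = 8) -> np.ndarray:
    """Fill missing entries by inverse-distance weighting.

    Stand-in for geostatistical kriging of unreliable coastal ice cells:
    each missing value becomes the IDW (power ``power``) average of its ``k``
    nearest non-missing neighbors.
    """
    values = np.asarray(values, dtype=float).copy()
    missing = np.asarray(missing, dtype=bool)
    if not missing.any():
        return values
    if missing.all():
        raise ValueError("cannot interpolate: all values missing")
    obs = ~missing
    eo, no_, vo = easting[obs], northing[obs], values[obs]
    for i in np.flatnonzero(missing):
        d2 = (eo - easting[i]) ** 2 + (no_ - northing[i]) ** 2
        idx = np.argsort(d2)[:k]
        d = np.sqrt(d2[idx])
        if d[0] == 0:
            values[i] = vo[idx[0]]
            continue
        wts = 1.0 / d ** power
        values[i] = np.sum(wts * vo[idx]) / np.sum(wts)
    return values


def make_covariates(grid: StudyGrid, T: int, seed: int = 0,
                    missing_frac: float = 0.05) -> CovariateField:
    """Draw smooth covariate fields for ``T`` survey days.

    Ice starts high nearly everywhere and melts over the survey window, most
    strongly near the southern land edge, so that late-season cells can drop
    below the 1% open-water threshold.  A fraction of coastal cells is marked
    missing each day and filled by inverse-distance interpolation, mimicking
    unreliable remotely sensed ice near land.  The RSF field is a positive
    smooth surface with mean 1.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = np.random.default_rng(seed)
    c = grid.cells
    easting = c["easting"].to_numpy()
    northing = c["northing"].to_numpy()
    # L-shaped coast: land along the whole southern edge plus the southern
    # 40% of the western edge, so distance-to-land correlates strongly but
    # not perfectly with northing (as for a real coastline)
    wall_n = 0.4 * (northing.max() + grid.cell_km / 2)
    d_west = np.where(northing <= wall_n, easting,
                      np.hypot(easting, northing - wall_n))
    dist_land = np.minimum(northing, d_west)

    base = np.clip(0.88 + 0.08 * _bump_field(rng, easting, northing), 0, 1)
    south = 1.0 - northing / (northing.max() + grid.cell_km)
    melt_field = 0.5 + 0.5 * np.clip(
        _bump_field(rng, easting, northing) * 0.3 + south, 0, 2)
    S = grid.n_cells
    ice = np.empty((S, T))
    coastal = northing <= 2.5 * grid.cell_km
    for t in range(T):
        m_t = 0.9 * t / max(T - 1, 1)
        day = np.clip(base - m_t * melt_field
                      + rng.normal(0, 0.01, size=S), 0, 1)
        if missing_frac > 0 and coastal.any():
            miss = coastal & (rng.uniform(size=S) < missing_frac)
            if miss.any() and not miss.all():
                day = idw_fill(easting, northing, np.where(miss, np.nan, day),
                               miss)
        ice[:, t] = np.clip(day, 0, 1)

    rsf = np.exp(0.5 * _bump_field(rng, easting, northing))
    rsf = rsf / rsf.mean()

    return CovariateField(ice=ice, dist_land=dist_land, rsf=rsf,
                          easting=easting, northing=northing)


def _transect_cells(rng, region_cells, col_of, n_cells):
    """Pick cells along randomly ordered parallel (N-S) transect columns."""
    cols = np.unique(col_of[region_cells])
    order = rng.permutation(cols)
    chosen = []
    for col in order:
        in_col = region_cells[col_of[region_cells] == col]
        chosen.extend(in_col.tolist())
        if len(chosen) >= n_cells:
            break
    return np.array(chosen[:n_cells], dtype=int)


def latent_surfaces(grid: StudyGrid, cov: CovariateField,
                    scenario: SimScenario):
    """Deterministic latent truth: track intensity Z and occupancy pi.

    Returns ``(Z, Z_std, pi)`` with shapes (S, T); ``pi`` columns each sum to
    one over cells with saltwater habitat.
    """
    S, T = cov.n_cells, cov.n_days
    X = build_track_design(cov)  # (S*T, 6), day-major
    w99_flat = cov.water99.T.ravel()
    logZ = X @ np.asarray(scenario.true_beta) + WATER99_COEF * w99_flat
    Z = np.exp(logZ).reshape(T, S).T
    Z_std = Z / Z.mean()

    sm = cov.smooth_covariates()
    nu = sum(coef * sm[name] for name, coef in scenario.true_alpha.items())
    nu = nu + scenario.true_alpha_tracks * Z_std + WATER99_COEF * cov.water99
    A = grid.saltwater_area
    log_w = np.where(A > 0, np.log(np.where(A > 0, A, 1.0)), -np.inf)
    log_num = log_w[:, None] + nu
    log_den = special.logsumexp(log_num, axis=0)
    pi = np.exp(log_num - log_den)
    return Z, Z_std, pi


def simulate_survey(grid: StudyGrid, cov: CovariateField,
                    scenario: SimScenario, return_truth: bool = False):
    """Simulate one complete dual-platform survey.

    Draws, in order: latent track intensity; US photo-track indicators; RU
    track counts; daily multinomial redistribution of the closed population;
    Poisson-thinned thermal, auxiliary, and visual counts; truncated
    half-normal perpendicular distances for visual detections; shifted-Poisson
    group sizes; and binomial flyover trials.  Identical scenarios (including
    the seed) give identical output.

    With ``return_truth=True`` also returns a dict of latent surfaces and
    closed-form expected totals for use as simulation oracles.
    """
    if cov.n_cells != grid.n_cells:
        raise ValueError("covariates do not match grid")
    if cov.n_days != scenario.T:
        raise ValueError("covariates do not match scenario day count")
    rng = np.random.default_rng(scenario.seed)
    S, T = grid.n_cells, scenario.T
    eff = scenario.effort

    Z, Z_std, pi = latent_surfaces(grid, cov, scenario)
    A = grid.saltwater_area
    p_rus = halfnormal_p(scenario.true_sigma, eff.w, scenario.g0)
    p_us = scenario.true_p_us

    col_of = np.asarray(
        np.round((grid.cells["easting"] / grid.cell_km) - 0.5), dtype=int)
    cells_us = np.flatnonzero(grid.region_mask("US") & (A > 0))
    cells_ru = np.flatnonzero(grid.region_mask("RU") & (A > 0))

    # daily redistribution of the closed population (conservation: sums to N)
    placements = np.empty((S, T), dtype=int)
    for t in range(T):
        placements[:, t] = rng.multinomial(scenario.true_N, pi[:, t])

    photos_per_cell = int(np.floor(eff.us_footprint_km2 / PHOTO_FOOTPRINT_KM2))
    us_track_rows, ru_track_rows = [], []
    count_rows, dist_rows = [], []
    effort_rows = []
    expected = {"thermal": 0.0, "aux": 0.0, "visual": 0.0}

    for t in range(T):
        su = (_transect_cells(rng, cells_us, col_of, eff.us_cells_per_day)
              if len(cells_us) else np.empty(0, dtype=int))
        sr = (_transect_cells(rng, cells_ru, col_of, eff.ru_cells_per_day)
              if len(cells_ru) else np.empty(0, dtype=int))

        # --- US platform: photographs -> tracks, thermal + auxiliary counts
        if len(su):
            phi = -np.expm1(-PHOTO_FOOTPRINT_KM2 * Z[su, t])
            t_us = rng.binomial(photos_per_cell, phi)
            a_us = np.clip(eff.us_footprint_km2 / A[su], 0, 1)
            mu_c = scenario.true_N * pi[su, t] * p_us * a_us
            mu_u = scenario.true_xi * mu_c
            if np.any(mu_c < 0) or not np.all(np.isfinite(mu_c)):
                raise ValueError("mis-scaled scenario: invalid thermal mean")
            c_us = rng.poisson(mu_c)
            u_us = rng.poisson(mu_u)
            expected["thermal"] += mu_c.sum()
            expected["aux"] += mu_u.sum()
            for j, s in enumerate(su):
                us_track_rows.append((s, t, photos_per_cell, t_us[j]))
                count_rows.append((s, t, "us", "thermal", c_us[j]))
                count_rows.append((s, t, "us", "aux", u_us[j]))
                effort_rows.append((s, t, "us", 0.0, eff.us_footprint_km2))

        # --- RU platform: observer tracks, visual counts, distances
        if len(sr):
            lam_track = eff.ru_length_km * scenario.true_eta * Z[sr, t]
            t_ru = rng.poisson(lam_track)
            a_ru = np.clip(eff.ru_length_km * RU_STRIP_WIDTH_KM / A[sr], 0, 1)
            mu_r = scenario.true_N * pi[sr, t] * p_rus * a_ru
            if np.any(mu_r < 0) or not np.all(np.isfinite(mu_r)):
                raise ValueError("mis-scaled scenario: invalid visual mean")
            c_ru = rng.poisson(mu_r)
            expected["visual"] += mu_r.sum()
            for j, s in enumerate(sr):
                ru_track_rows.append((s, t, eff.ru_length_km, t_ru[j]))
                count_rows.append((s, t, "ru", "visual", c_ru[j]))
                effort_rows.append((s, t, "ru", eff.ru_length_km, 0.0))
                if c_ru[j] > 0:
                    x = _truncated_halfnormal(rng, scenario.true_sigma,
                                              eff.w, c_ru[j])
                    dist_rows.extend((s, t, xi_) for xi_ in x)

    n_groups = sum(r[4] for r in count_rows)
    group_sizes = 1 + rng.poisson(scenario.true_mu_g - 1.0, size=n_groups)
    trials = FlyoverTrials(n=eff.n_trials,
                           detected=int(rng.binomial(eff.n_trials, p_us)))

    data = SurveyData(
        track=TrackData(
            us=pd.DataFrame(us_track_rows,
                            columns=["cell_id", "day", "photos", "tracks"]),
            ru=pd.DataFrame(ru_track_rows,
                            columns=["cell_id", "day", "length_km", "tracks"]),
        ),
        counts=pd.DataFrame(
            count_rows, columns=["cell_id", "day", "platform", "kind",
                                 "count"]),
        effort=pd.DataFrame(
            effort_rows, columns=["cell_id", "day", "platform", "length_km",
                                  "footprint_km2"]),
        distances=pd.DataFrame(dist_rows,
                               columns=["cell_id", "day", "distance_m"]),
        w=eff.w,
        breakpoint=eff.breakpoint,
        trials=trials,
        group_sizes=np.asarray(group_sizes, dtype=int),
    )
    if not return_truth:
        return data
    truth = {
        "Z": Z, "Z_std": Z_std, "pi": pi, "placements": placements,
        "expected_counts": expected, "p_rus": p_rus,
    }
    return data, truth


def _truncated_halfnormal(rng, sigma, w, n):
    """Inverse-CDF draws from the half-normal truncated to [0, w]."""
    u = rng.uniform(size=n)
    cap = special.erf(w / (sigma * np.sqrt(2.0)))
    return sigma * np.sqrt(2.0) * special.erfinv(u * cap)
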