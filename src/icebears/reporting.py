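"""Results-layer computations: surfaces, regional totals, densities.

The fitted model predicts an expected-bears surface
``N_hat_{s,t} = N_hat * pi_hat_{s,t} * mu_g_hat``; regional abundance is the
time average of the surface summed over the cells whose centroids fall in a
region, and density per unit sea-ice habitat divides total abundance by the
concentration-weighted ice area.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def abundance_surface(fit) -> np.ndarray:
    """Expected bears per cell-day, ``(S, T)``: ``N pi mu_g``."""
    return fit.N_surface


def region_abundance(surface: np.ndarray, grid, region_label: str) -> float:
    """Time-averaged abundance in a region (cells by centroid membership).

    ``mean_t sum_{s in region} N_hat_{s,t}``; for the full-grid region this
    equals total abundance ``N_hat * mu_g_hat`` exactly, by conservation.
    """
    mask = grid.region_mask(region_label)
    if surface.shape[0] != len(mask):
        raise ValueError("surface does not match grid")
    return float(surface[mask].sum(axis=0).mean()) if mask.any() else 0.0


def region_table(fit, grid, g0: float,
                 labels=None) -> pd.DataFrame:
    """Abundance-by-region table with log-based 95% intervals.

    Regional intervals rescale the total-abundance interval by the region's
    share of the time-averaged surface (point estimates are exact; interval
    endpoints inherit the total's CV).
    """
    from .joint import lognormal_ci

    surface = fit.N_surface
    labels = labels if labels is not None else grid.region_labels
    rows = []
    total = fit.N_star
    for label in labels:
        est = region_abundance(surface, grid, label)
        if np.isfinite(fit.se_N_star) and total > 0 and est > 0:
            lo, hi = lognormal_ci(est, fit.se_N_star * est / total)
        else:
            lo = hi = np.nan
        rows.append({"region": label, "g0": g0, "estimate": est,
                     "lower": lo, "upper": hi})
    return pd.DataFrame(rows)


def ice_area(cov, grid, t: int) -> float:
    """Concentration-weighted sea-ice area (km^2) on day ``t``."""
    return float(np.sum(cov.ice[:, t] * grid.saltwater_area))


def density_per_ice(N_star: float, ice_area_km2: float) -> float:
    """Bears per km^2 of sea-ice habitat, rounded to 3 decimals."""
    if not ice_area_km2 > 0:
        raise ValueError("ice area must be positive")
    return round(N_star / ice_area_km2, 3)


def surface_correlation(surface_a: np.ndarray,
                        surface_b: np.ndarray) -> float:
    """Pearson correlation between two cell-day surfaces."""
    a = np.asarray(surface_a, dtype=float).ravel()
    b = np.asarray(surface_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("surfaces must have matching shapes")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("constant surface has no defined correlation")
    return float(np.corrcoef(a, b)[0, 1])


def surface_frame(surface: np.ndarray, grid) -> pd.DataFrame:
    """Long-format (cell_id, day, value) frame for a (S, T) surface."""
    S, T = surface.shape
    return pd.DataFrame({
        "cell_id": np.tile(np.arange(S), T),
        "day": np.repeat(np.arange(T), S),
        "value": surface.T.ravel(),
    })
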