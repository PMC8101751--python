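"""Delimited-text input/output for the survey tables.

All tables are UTF-8 CSV with a header row.  Schemas:

* ``grid.csv`` — cell_id, easting, northing, area, saltwater_prop,
  region_<label> (one boolean column per region flag)
* ``covariates.csv`` — cell_id, day, ice, dist_land, rsf, easting, northing
  (per-cell fields repeated across days)
* ``effort.csv`` — cell_id, day, platform, length_km, footprint_km2
* ``tracks.csv`` — cell_id, day, platform, photos, tracks, length_km
  (photos for 'us' rows, length_km for 'ru' rows)
* ``counts.csv`` — cell_id, day, platform, kind, count
* ``distances.csv`` — cell_id, day, distance_m
* ``trials.csv`` — n, detected (single row)
* ``groups.csv`` — size (one row per detected group)
* ``scenario.yaml`` — generating parameters of a synthetic survey
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import yaml

from .detection import FlyoverTrials
from .joint import SurveyData
from .synthetic import CovariateField, EffortConfig, SimScenario, StudyGrid
from .tracks import TrackData


def write_grid(grid: StudyGrid, path: str) -> None:
    grid.cells.to_csv(path, index=False)


def read_grid(path: str) -> StudyGrid:
    cells = pd.read_csv(path)
    nx = cells["easting"].nunique()
    ny = cells["northing"].nunique()
    es = np.sort(cells["easting"].unique())
    cell_km = float(es[1] - es[0]) if len(es) > 1 else float(2 * es[0])
    grid = StudyGrid(cells=cells, nx=nx, ny=ny, cell_km=cell_km)
    grid.validate()
    return grid


def write_covariates(cov: CovariateField, path: str) -> None:
    S, T = cov.n_cells, cov.n_days
    frame = pd.DataFrame({
        "cell_id": np.tile(np.arange(S), T),
        "day": np.repeat(np.arange(T), S),
        "ice": cov.ice.T.ravel(),
        "dist_land": np.tile(cov.dist_land, T),
        "rsf": np.tile(cov.rsf, T),
        "easting": np.tile(cov.easting, T),
        "northing": np.tile(cov.northing, T),
    })
    frame.to_csv(path, index=False)


def read_covariates(path: str) -> CovariateField:
    frame = pd.read_csv(path)
    S = frame["cell_id"].nunique()
    T = frame["day"].nunique()
    frame = frame.sort_values(["day", "cell_id"])
    ice = frame["ice"].to_numpy().reshape(T, S).T
    first = frame.iloc[:S]
    return CovariateField(
        ice=ice,
        dist_land=first["dist_land"].to_numpy(),
        rsf=first["rsf"].to_numpy(),
        easting=first["easting"].to_numpy(),
        northing=first["northing"].to_numpy(),
    )


def write_survey(data: SurveyData, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    us = data.track.us.assign(platform="us", length_km=np.nan)
    ru = data.track.ru.assign(platform="ru", photos=np.nan)
    tracks = pd.concat([us, ru], ignore_index=True)[
        ["cell_id", "day", "platform", "photos", "tracks", "length_km"]]
    tracks.to_csv(os.path.join(out_dir, "tracks.csv"), index=False)
    data.counts.to_csv(os.path.join(out_dir, "counts.csv"), index=False)
    data.effort.to_csv(os.path.join(out_dir, "effort.csv"), index=False)
    data.distances.to_csv(os.path.join(out_dir, "distances.csv"), index=False)
    if data.trials is not None:
        pd.DataFrame([{"n": data.trials.n,
                       "detected": data.trials.detected}]).to_csv(
            os.path.join(out_dir, "trials.csv"), index=False)
    pd.DataFrame({"size": data.group_sizes}).to_csv(
        os.path.join(out_dir, "groups.csv"), index=False)


def read_survey(tracks: str, counts: str, effort: str, distances: str,
                trials: str | None = None, groups: str | None = None,
                w: float = 600.0, breakpoint: float = 350.0) -> SurveyData:
    tr = pd.read_csv(tracks)
    us = tr[tr["platform"] == "us"][
        ["cell_id", "day", "photos", "tracks"]].astype(
        {"photos": int, "tracks": int}).reset_index(drop=True)
    ru = tr[tr["platform"] == "ru"][
        ["cell_id", "day", "length_km", "tracks"]].astype(
        {"tracks": int}).reset_index(drop=True)
    trials_obj = None
    if trials is not None and os.path.exists(trials):
        trow = pd.read_csv(trials).iloc[0]
        trials_obj = FlyoverTrials(n=int(trow["n"]),
                                   detected=int(trow["detected"]))
    sizes = np.empty(0, dtype=int)
    if groups is not None and os.path.exists(groups):
        gf = pd.read_csv(groups)
        sizes = gf["size"].to_numpy(dtype=int) if len(gf) else sizes
    return SurveyData(
        track=TrackData(us=us, ru=ru),
        counts=pd.read_csv(counts),
        effort=pd.read_csv(effort),
        distances=pd.read_csv(distances),
        w=w, breakpoint=breakpoint,
        trials=trials_obj, group_sizes=sizes)


def write_scenario(scenario: SimScenario, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scenario.to_dict(), fh, sort_keys=False)


def read_scenario(path: str) -> SimScenario:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    raw["effort"] = EffortConfig(**raw.get("effort", {}))
    raw["true_beta"] = tuple(raw.get("true_beta", ()))
    return SimScenario(**raw)


def grid_geojson(grid: StudyGrid) -> dict:
    """Grid cells as GeoJSON square polygons (planar km coordinates)."""
    half = grid.cell_km / 2.0
    features = []
    for row in grid.cells.itertuples(index=False):
        e, n = row.easting, row.northing
        ring = [[e - half, n - half], [e + half, n - half],
                [e + half, n + half], [e - half, n + half],
                [e - half, n - half]]
        features.append({
            "type": "Feature",
            "properties": {"cell_id": int(row.cell_id),
                           "area": float(row.area),
                           "saltwater_prop": float(row.saltwater_prop)},
            "geometry": {"type": "Polygon", "coordinates": [ring]},
        })
    return {"type": "FeatureCollection", "features": features}
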