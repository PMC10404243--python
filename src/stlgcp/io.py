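"""File formats: events CSV, boundary GeoJSON, covariates CSV, results CSV/JSON.

Core code works in planar km coordinates; longitude/latitude input is
converted on read with a sinusoidal equal-area projection (adequate for the
regional windows this package targets; the projection is confined to this
module and the core stays projection-agnostic).
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import Polygon, shape

from .errors import SchemaError
from .mesh import Mesh
from .model import CovariateDesign
from .spde import MaternParams

EARTH_RADIUS_KM = 6371.0088
FLOAT_FMT = "%.6g"

__all__ = [
    "read_boundary",
    "lonlat_to_planar",
    "read_events",
    "read_node_covariates",
    "write_mesh",
    "write_fit_result",
    "load_scenario",
    "save_scenario",
]


def read_boundary(path) -> Polygon:
    """Read an observation-window polygon from GeoJSON.

    Accepts a bare Polygon geometry, a Feature, or a FeatureCollection whose
    first feature is a Polygon; the first ring is the exterior.
    """
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        gj = gj["features"][0]
    if gj.get("type") == "Feature":
        gj = gj["geometry"]
    geom = shape(gj)
    if not isinstance(geom, Polygon):
        raise SchemaError(f"boundary must be a GeoJSON Polygon, got {gj.get('type')}")
    return geom


def lonlat_to_planar(lon, lat, lon0: float | None = None, lat0: float | None = None):
    """Sinusoidal equal-area projection to planar km.

    x = R (λ−λ₀) cos φ, y = R (φ−φ₀), with the reference point defaulting to
    the centroid of the input.  Equal-area by construction, which is what the
    intensity quadrature cares about.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    lon0 = float(np.mean(lon)) if lon0 is None else lon0
    lat0 = float(np.mean(lat)) if lat0 is None else lat0
    lam = np.radians(lon - lon0)
    phi = np.radians(lat)
    x = EARTH_RADIUS_KM * lam * np.cos(phi)
    y = EARTH_RADIUS_KM * (phi - np.radians(lat0))
    return x, y


def read_events(path, max_bad_fraction: float = 0.01) -> pd.DataFrame:
    """Read an events CSV with columns x,y,date (planar) or lon,lat,date.

    The coordinate system is detected from the column names; lon/lat input is
    projected to planar km.

    Malformed dates are rejected row by row (1-based data line numbers in the
    error); the run aborts if more than ``max_bad_fraction`` of rows fail.
    """
    df = pd.read_csv(path)
    cols = set(df.columns)
    if {"x", "y", "date"} <= cols:
        planar = True
    elif {"lon", "lat", "date"} <= cols:
        planar = False
    else:
        raise SchemaError(
            f"{path}: expected columns x,y,date or lon,lat,date; got {sorted(cols)}"
        )
    dates = pd.to_datetime(df["date"], errors="coerce", format="ISO8601")
    bad = np.where(dates.isna())[0]
    if len(bad):
        lines = (bad + 2).tolist()  # header is line 1
        if len(bad) > max_bad_fraction * len(df):
            raise SchemaError(
                f"{path}: {len(bad)} unparseable dates (lines {lines[:10]}...); aborting"
            )
        df = df[~dates.isna()].copy()
        dates = dates[~dates.isna()]
    out = pd.DataFrame({"date": dates.to_numpy()})
    if planar:
        out["x"] = df["x"].to_numpy(dtype=float)
        out["y"] = df["y"].to_numpy(dtype=float)
    else:
        x, y = lonlat_to_planar(df["lon"].to_numpy(), df["lat"].to_numpy())
        out["x"], out["y"] = x, y
    if "weight" in cols:
        out["weight"] = df["weight"].to_numpy(dtype=float)
    return out[["x", "y", "date"] + (["weight"] if "weight" in cols else [])]


def read_node_covariates(path, N: int, T: int) -> CovariateDesign:
    """Read a long-format node covariate CSV: node_id, period, name, value."""
    df = pd.read_csv(path)
    required = {"node_id", "period", "name", "value"}
    if not required <= set(df.columns):
        raise SchemaError(f"{path}: expected columns {sorted(required)}")
    names = sorted(df["name"].unique())
    arr = np.zeros((T, N, len(names)))
    for j, name in enumerate(names):
        sub = df[df["name"] == name]
        t = sub["period"].to_numpy(dtype=int) - 1
        k = sub["node_id"].to_numpy(dtype=int)
        if t.min() < 0 or t.max() >= T or k.min() < 0 or k.max() >= N:
            raise SchemaError(f"{path}: node_id/period out of range for {name}")
        arr[t, k, j] = sub["value"].to_numpy(dtype=float)
    return CovariateDesign(node_values=arr, names=names)


def write_mesh(mesh: Mesh, outdir) -> None:
    """Export the mesh as vertices.csv (id,x,y,interior) and triangles.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "id": np.arange(mesh.n_vertices),
            "x": mesh.vertices[:, 0],
            "y": mesh.vertices[:, 1],
            "interior": mesh.interior_mask.astype(int),
        }
    ).to_csv(outdir / "vertices.csv", index=False, float_format=FLOAT_FMT)
    pd.DataFrame(
        {
            "id": np.arange(mesh.n_triangles),
            "v1": mesh.triangles[:, 0],
            "v2": mesh.triangles[:, 1],
            "v3": mesh.triangles[:, 2],
        }
    ).to_csv(outdir / "triangles.csv", index=False)


def write_fit_result(result, outdir, meta: dict | None = None) -> None:
    """Serialise a FitResult as a CSV set plus JSON run metadata."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.hyperparameters.to_csv(
        outdir / "hyperparameters.csv", index_label="parameter", float_format=FLOAT_FMT
    )
    result.fixed_effects.to_csv(
        outdir / "fixed_effects.csv", index_label="effect", float_format=FLOAT_FMT
    )
    result.components.to_csv(outdir / "components.csv", index=False, float_format=FLOAT_FMT)
    result.field.to_csv(outdir / "spatial_field.csv", index=False, float_format=FLOAT_FMT)
    result.intensity.to_csv(outdir / "intensity.csv", index=False, float_format=FLOAT_FMT)
    result.totals.to_csv(outdir / "totals.csv", index=False, float_format=FLOAT_FMT)
    info = {
        "seed": result.seed,
        "strategy": result.strategy,
        "converged": bool(result.converged),
        "n_outer_iter": int(result.n_outer_iter),
        "log_evidence": float(result.log_evidence),
        "theta_mode": [float(v) for v in result.theta_mode],
    }
    if meta:
        info["config"] = meta
    with open(outdir / "run_meta.json", "w") as fh:
        json.dump(info, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# scenario YAML
# ---------------------------------------------------------------------------


def _plain(obj):
    """Recursively convert numpy scalars/arrays to plain Python types."""
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


def scenario_to_dict(scenario) -> dict:
    d = asdict(scenario)
    d["window"] = np.asarray(scenario.window.exterior.coords).tolist()
    if scenario.matern is not None:
        d["matern"] = {"sigma": float(scenario.matern.sigma),
                       "rho": float(scenario.matern.rho)}
    return _plain(d)


def scenario_from_dict(d: dict):
    from .simulate import SimulationScenario

    d = dict(d)
    d["window"] = Polygon(d["window"])
    if d.get("matern"):
        m = d["matern"]
        d["matern"] = MaternParams.from_sigma_rho(m["sigma"], m["rho"])
    for key in ("trend_path", "seasonal_path", "cycle_path", "seasonal_init", "polyline"):
        if d.get(key) is not None:
            d[key] = np.asarray(d[key], dtype=float)
    if d.get("cycle_pacf") is not None:
        d["cycle_pacf"] = tuple(d["cycle_pacf"])
    d["beta"] = tuple(d.get("beta", ()))
    d["trend_init"] = tuple(d.get("trend_init", (0.0, 0.0)))
    return SimulationScenario(**d)


def save_scenario(scenario, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scenario_to_dict(scenario), fh, sort_keys=True)


def load_scenario(path):
    with open(path) as fh:
        return scenario_from_dict(yaml.safe_load(fh))
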