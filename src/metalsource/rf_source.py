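"""Random-forest source apportionment.

Each metal's plant concentration is regressed on source-proximity
features — one per candidate source, encoded as exp(-d/lambda) with d
the Euclidean distance (km) from the sample to the source point or the
nearest point of the source polyline — so that impurity-based feature
importances read directly as source influence. Model quality is
summarized by R^2, RMSE, MAE and the residual prediction deviation
RPD = sd(observed)/RMSE on a held-out split, plus the out-of-bag R^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import train_test_split

from .io_core import ConcentrationTable

DEFAULT_DECAY_KM = 10.0


def read_sources(path: str | Path) -> pd.DataFrame:
    """Read a source table (CSV with columns ``name`` and ``wkt``).

    Geometries are WKT points or linestrings in the survey's planar km
    frame; the parsed geometry is attached as a ``geometry`` column.
    """
    df = pd.read_csv(path)
    for col in ("name", "wkt"):
        if col not in df.columns:
            raise ValueError(f"source table lacks a {col!r} column")
    df = df.copy()
    df["geometry"] = df["wkt"].map(shapely.from_wkt)
    return df


def proximity(x, y, geometry, decay_km: float = DEFAULT_DECAY_KM):
    """exp(-d/lambda) for the distance from (x, y) to a geometry."""
    if decay_km <= 0:
        raise ValueError("decay length must be > 0")
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    d = np.array([geometry.distance(Point(px, py)) for px, py in zip(x, y)])
    return np.exp(-d / decay_km)


def build_feature_matrix(
    samples: ConcentrationTable,
    sources: pd.DataFrame,
    decay_km: float = DEFAULT_DECAY_KM,
) -> pd.DataFrame:
    """Proximity features (sample x source), aligned with the table rows."""
    if not samples.has_coordinates:
        raise ValueError(
            f"samples lack coordinates: {samples.sample_ids.tolist()}")
    coords = samples.coordinates()
    if "geometry" not in sources.columns:
        sources = sources.assign(geometry=sources["wkt"].map(shapely.from_wkt))
    feats = {
        row["name"]: proximity(coords["x"], coords["y"], row["geometry"], decay_km)
        for _, row in sources.iterrows()
    }
    return pd.DataFrame(feats, index=coords.index)


def evaluate(obs, pred) -> dict[str, float]:
    """R^2, RMSE, MAE and RPD for a prediction vector.

    RPD = sd(obs, n-1)/RMSE; a perfect fit yields RPD = inf.
    """
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1 or obs.size < 2:
        raise ValueError("obs and pred must be equal-length vectors of size >= 2")
    if np.ptp(obs) == 0:
        raise ValueError("observed values are constant; R^2 undefined")
    resid = obs - pred
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    sd = float(np.std(obs, ddof=1))
    rpd = np.inf if rmse == 0 else sd / rmse
    return {"r2": 1.0 - ss_res / ss_tot, "rmse": rmse, "mae": mae, "rpd": rpd}


@dataclass
class RfApportionment:
    """Fitted-forest summary for one metal."""

    metal: str
    metrics: pd.DataFrame            # index: split (train/test); r2, rmse, mae, rpd
    oob_r2: float
    importance_shares: pd.Series     # percent per source, sums to 100
    seed: int
    test_fraction: float
    model: RandomForestRegressor = field(repr=False, default=None)


def importance_shares(forest: RandomForestRegressor, feature_names) -> pd.Series:
    """Impurity-based feature importances normalized to percent."""
    imp = np.asarray(forest.feature_importances_, dtype=float)
    total = imp.sum()
    if total == 0:  # fully uninformative forest: spread evenly
        imp = np.full_like(imp, 1.0 / len(imp))
        total = 1.0
    return pd.Series(100.0 * imp / total, index=list(feature_names))


def fit_rf(
    features: pd.DataFrame,
    y: pd.Series | np.ndarray,
    metal: str = "",
    species: pd.Series | None = None,
    seed: int = 42,
    test_fraction: float = 0.3,
    n_trees: int = 500,
    max_features: str | float = "sqrt",
) -> RfApportionment:
    """Train a bagged regression forest on a 70/30 train/test split
    (stratified by species when given) and report both-split metrics,
    the OOB R^2, and normalized importance shares."""
    y = np.asarray(y, dtype=float)
    if len(features) != len(y):
        raise ValueError("features and target length mismatch")
    if len(y) < 20:
        raise ValueError("need at least 20 samples for a meaningful split")
    if np.ptp(y) == 0:
        raise ValueError(f"constant target for metal {metal!r}; R^2 undefined")
    x = features.to_numpy(dtype=float)
    strat = None if species is None else np.asarray(species)
    x_tr, x_te, y_tr, y_te = train_test_split(
        x, y, test_size=test_fraction, random_state=seed, stratify=strat)
    forest = RandomForestRegressor(
        n_estimators=n_trees, max_features=max_features,
        oob_score=True, bootstrap=True, random_state=seed, n_jobs=1)
    forest.fit(x_tr, y_tr)
    metrics = pd.DataFrame({
        "train": evaluate(y_tr, forest.predict(x_tr)),
        "test": evaluate(y_te, forest.predict(x_te)),
    }).T
    return RfApportionment(
        metal=metal, metrics=metrics, oob_r2=float(forest.oob_score_),
        importance_shares=importance_shares(forest, features.columns),
        seed=seed, test_fraction=test_fraction, model=forest)


def apportion_all(
    plants: ConcentrationTable,
    sources: pd.DataFrame,
    decay_km: float = DEFAULT_DECAY_KM,
    seed: int = 42,
    **rf_kwargs,
) -> dict[str, RfApportionment]:
    """Fit one forest per metal on source-proximity features."""
    feats = build_feature_matrix(plants, sources, decay_km)
    conc = plants.concentrations()
    species = plants.data.set_index("sample_id").loc[conc.index, "species"] \
        if plants.species is not None else None
    return {
        m: fit_rf(feats, conc[m], metal=m, species=species, seed=seed, **rf_kwargs)
        for m in plants.metals
    }
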