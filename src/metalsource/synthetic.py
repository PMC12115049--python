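"""Synthetic paired soil-plant surveys with known source structure.

Soil concentrations are generated as a geogenic background plus
distance-decaying contributions from named point/line sources, under
multiplicative log-normal noise; plant concentrations follow from
species-specific soil-to-plant transfer factors plus an optional
additive atmospheric deposition term (for metals, like Hg, whose
above-ground plant content is partly decoupled from soil), again under
log-normal noise:

    soil_i(m)  = [bg_draw_i(m) + sum_s E_s(m) exp(-d_is / lambda_s)] * eps
    plant_i(m) = [tf(species_i, m) * soil_i(m) + atm(m)] * eps'

Ground-truth per-metal source shares are defined on the noise-free
mixture (the estimand the apportionment methods target): the share of
source s is the mean of its term over samples divided by the mean
total, with the background counted as its own (geogenic) share.

The default preset emulates a 36-sample arid-steppe survey: four
shrub/semi-shrub species, seven metals, two factories loading
Cr/Cu/Zn/Cd (plus Hg on one), and three traffic corridors (a railway
and two highways) loading Pb and secondarily As/Cu/Zn.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point
from shapely.geometry.base import BaseGeometry

from .io_core import METALS, ConcentrationTable, ReferenceSet

FACTORY = "factory"
ROAD = "road"


@dataclass(frozen=True)
class PollutionSource:
    """A named emission source with a spatial footprint.

    ``emissions[m]`` is the concentration increment E (mg/kg) a sample
    located on the source would receive for metal m; the increment
    decays as exp(-d/decay_km) with distance d (km) to the point or to
    the nearest point of the polyline.
    """

    name: str
    geometry: BaseGeometry
    family: str                      # "factory" or "road"
    emissions: dict[str, float]
    decay_km: float

    def term(self, x: np.ndarray, y: np.ndarray, metal: str) -> np.ndarray:
        e = self.emissions.get(metal, 0.0)
        if e == 0.0:
            return np.zeros_like(np.asarray(x, dtype=float))
        d = np.array([self.geometry.distance(Point(px, py)) for px, py in zip(x, y)])
        return e * np.exp(-d / self.decay_km)


@dataclass
class SourceScenario:
    """Fully specified synthetic survey design."""

    n_samples: int
    extent_km: tuple[float, float]
    species_counts: dict[str, int]
    transfer: dict[str, dict[str, float]]         # species -> metal -> true BCF
    sources: list[PollutionSource]
    background_mean: dict[str, float]             # mg/kg
    background_sd: dict[str, float]               # log-scale sd
    noise_soil: float = 0.2                       # log-scale sd
    noise_plant: float = 0.2
    atmospheric: dict[str, float] = field(default_factory=dict)   # mg/kg, plants
    metals: tuple[str, ...] = METALS
    seed: int = 0
    coordinates: np.ndarray | None = None         # optional fixed n x 2 layout

    def __post_init__(self) -> None:
        if sum(self.species_counts.values()) != self.n_samples:
            raise ValueError(
                f"species counts sum to {sum(self.species_counts.values())}, "
                f"not n_samples={self.n_samples}")
        for src in self.sources:
            if src.decay_km <= 0:
                raise ValueError(f"source {src.name!r}: decay length must be > 0")
            if any(e < 0 for e in src.emissions.values()):
                raise ValueError(f"source {src.name!r}: emissions must be >= 0")
        for name, vals in (("background_mean", self.background_mean),
                           ("background_sd", self.background_sd)):
            for m in self.metals:
                if m not in vals:
                    raise ValueError(f"{name} lacks metal {m!r}")
        if self.noise_soil < 0 or self.noise_plant < 0:
            raise ValueError("noise sds must be >= 0")
        for sp, tf in self.transfer.items():
            if any(v < 0 for v in tf.values()):
                raise ValueError(f"transfer factors for {sp!r} must be >= 0")


SPECIES = (
    "Anabasis aphylla",
    "Alhagi camelorum",
    "Reaumuria songonica",
    "Haloxylon ammodendron",
)

_PRESET_TRANSFER = {
    # per-metal true BCF by species (order as SPECIES)
    "Cr": (7.303, 1.78, 2.60, 1.45),
    "Cu": (0.31, 0.18, 0.28, 0.18),
    "Zn": (0.21, 0.09, 0.15, 0.13),
    "Cd": (1.424, 0.71, 0.71, 0.84),
    "Pb": (0.125, 0.125, 0.125, 0.125),
    "Hg": (0.60, 0.65, 0.55, 0.40),
    "As": (0.15, 0.10, 0.14, 0.11),
}


def _kalamaili_like(seed: int) -> SourceScenario:
    sources = [
        PollutionSource("factory_1", Point(6.0, 10.0), FACTORY,
                        {"Cr": 60.0, "Cu": 40.0, "Zn": 70.0, "Cd": 0.30,
                         "Hg": 0.02, "As": 8.0}, decay_km=8.0),
        PollutionSource("factory_2", Point(6.0, 26.0), FACTORY,
                        {"Cr": 35.0, "Cu": 22.0, "Zn": 45.0, "Cd": 0.20,
                         "As": 5.0}, decay_km=8.0),
        PollutionSource("railway", LineString([(0.0, 30.0), (36.0, 31.0)]), ROAD,
                        {"Pb": 3.0, "Zn": 8.0, "Cu": 3.0}, decay_km=6.0),
        PollutionSource("G216", LineString([(0.0, 22.0), (36.0, 23.0)]), ROAD,
                        {"Pb": 6.0}, decay_km=6.0),
        PollutionSource("S11", LineString([(0.0, 13.0), (36.0, 15.0)]), ROAD,
                        {"Pb": 30.0, "Cu": 3.0}, decay_km=6.0),
    ]
    transfer = {
        sp: {m: vals[i] for m, vals in _PRESET_TRANSFER.items()}
        for i, sp in enumerate(SPECIES)
    }
    return SourceScenario(
        n_samples=36,
        extent_km=(36.0, 36.0),
        species_counts={SPECIES[0]: 9, SPECIES[1]: 7, SPECIES[2]: 6, SPECIES[3]: 14},
        transfer=transfer,
        sources=sources,
        background_mean={"Cr": 29.0, "Cu": 10.0, "Zn": 32.0, "Cd": 0.05,
                         "Pb": 8.5, "Hg": 0.0055, "As": 4.2},
        background_sd={"Cr": 0.15, "Cu": 0.12, "Zn": 0.10, "Cd": 0.12,
                       "Pb": 0.05, "Hg": 0.15, "As": 0.15},
        noise_soil=0.2,
        noise_plant=0.2,
        atmospheric={"Hg": 0.005},
        seed=seed,
    )


PRESETS = {"kalamaili-like": _kalamaili_like}


def make_scenario(preset: str = "kalamaili-like", seed: int = 0, **overrides) -> SourceScenario:
    """Build a scenario from a named preset, optionally overriding
    individual fields (``noise_soil=0`` etc.)."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; available: {sorted(PRESETS)}")
    scenario = PRESETS[preset](seed)
    return replace(scenario, **overrides) if overrides else scenario


def _lognormal_factor(rng: np.random.Generator, sd: float, size) -> np.ndarray:
    """Mean-one multiplicative log-normal noise."""
    if sd == 0:
        return np.ones(size)
    return np.exp(sd * rng.standard_normal(size) - sd**2 / 2.0)


def _coords(scenario: SourceScenario, rng: np.random.Generator) -> np.ndarray:
    if scenario.coordinates is not None:
        coords = np.asarray(scenario.coordinates, dtype=float)
        if coords.shape != (scenario.n_samples, 2):
            raise ValueError("coordinates must have shape (n_samples, 2)")
        return coords
    xmax, ymax = scenario.extent_km
    return rng.uniform([0, 0], [xmax, ymax], size=(scenario.n_samples, 2))


def simulate_soil(scenario: SourceScenario) -> tuple[ConcentrationTable, dict]:
    """Simulate the soil table and its ground truth.

    Returns ``(table, truth)`` where truth holds the sample layout, the
    per-source noise-free contribution matrices, the per-metal percent
    shares (background included) and each metal's dominant named source.
    """
    rng = np.random.default_rng([scenario.seed, 0])
    coords = _coords(scenario, rng)
    x, y = coords[:, 0], coords[:, 1]
    n, metals = scenario.n_samples, scenario.metals

    bg_draw = pd.DataFrame({
        m: scenario.background_mean[m]
        * _lognormal_factor(rng, scenario.background_sd[m], n)
        for m in metals})
    contributions: dict[str, pd.DataFrame] = {
        "background": pd.DataFrame({m: np.full(n, scenario.background_mean[m])
                                    for m in metals}),
    }
    for src in scenario.sources:
        contributions[src.name] = pd.DataFrame({m: src.term(x, y, m) for m in metals})

    noise = pd.DataFrame(
        {m: _lognormal_factor(rng, scenario.noise_soil, n) for m in metals})
    source_total = sum(contributions[s.name] for s in scenario.sources)
    soil = (bg_draw + source_total) * noise

    mean_terms = pd.DataFrame({name: c.mean() for name, c in contributions.items()})
    shares = 100.0 * mean_terms.div(mean_terms.sum(axis=1), axis=0)  # metal x source
    named = shares.drop(columns="background")
    dominant = {
        m: (named.loc[m].idxmax() if named.loc[m].notna().any() and named.loc[m].max() > 0
            else None)
        for m in named.index
    }
    truth = {
        "coords": coords,
        "contributions": contributions,
        "shares": shares,
        "dominant_source": dominant,
        "family": {s.name: s.family for s in scenario.sources},
    }
    sample_ids = [f"S{i + 1:02d}" for i in range(n)]
    data = pd.DataFrame({"sample_id": sample_ids, "x": x, "y": y})
    table = ConcentrationTable(pd.concat([data, soil], axis=1), metals=metals)
    return table, truth


def simulate_plants(scenario: SourceScenario, soil: ConcentrationTable) -> ConcentrationTable:
    """Simulate the paired plant table from a simulated soil table."""
    rng = np.random.default_rng([scenario.seed, 1])
    n = len(soil)
    labels = np.repeat(
        list(scenario.species_counts), list(scenario.species_counts.values()))
    species = rng.permutation(labels)
    conc = soil.concentrations().reset_index(drop=True)
    tf = pd.DataFrame([scenario.transfer[sp] for sp in species])[list(scenario.metals)]
    atm = pd.Series({m: scenario.atmospheric.get(m, 0.0) for m in scenario.metals})
    noise = pd.DataFrame({m: _lognormal_factor(rng, scenario.noise_plant, n)
                          for m in scenario.metals})
    plant = (tf.to_numpy() * conc.to_numpy() + atm.to_numpy()) * noise.to_numpy()
    data = soil.data[["sample_id", "x", "y"]].copy()
    data["species"] = species
    data = pd.concat(
        [data, pd.DataFrame(plant, columns=list(scenario.metals))], axis=1)
    return ConcentrationTable(data, metals=scenario.metals)


def simulate_survey(scenario: SourceScenario) -> tuple[ConcentrationTable, ConcentrationTable, dict]:
    """Simulate soil and plants in one call."""
    soil, truth = simulate_soil(scenario)
    plants = simulate_plants(scenario, soil)
    return soil, plants, truth


# -- recovery helpers ------------------------------------------------------

def family_signals(scenario: SourceScenario, coords: np.ndarray) -> pd.DataFrame:
    """Per-sample noise-free source-family intensities.

    For each family, the sum over its sources of the emission profile
    scaled by the per-metal background mean (so metals combine on a
    comparable scale) times the distance-decay factor. Used to map
    anonymous receptor-model components back to the known families.
    """
    x, y = coords[:, 0], coords[:, 1]
    out: dict[str, np.ndarray] = {}
    for src in scenario.sources:
        weight = sum(src.emissions.get(m, 0.0) / scenario.background_mean[m]
                     for m in scenario.metals)
        d = np.array([src.geometry.distance(Point(px, py)) for px, py in zip(x, y)])
        sig = weight * np.exp(-d / src.decay_km)
        out[src.family] = out.get(src.family, 0.0) + sig
    return pd.DataFrame(out)


def assign_component_families(
    apcs: pd.DataFrame,
    signals: pd.DataFrame,
    min_abs_r: float = 0.3,
    min_margin: float = 0.1,
) -> dict[str, str | None]:
    """Map each receptor-model component to the source family whose
    true intensity field its scores track best (|Pearson r|).

    A component stays unassigned (None) when no family reaches
    ``min_abs_r`` or when the best family does not beat the runner-up
    by ``min_margin`` — e.g. a species-uptake or noise component, or a
    general component mixing both families.
    """
    out: dict[str, str | None] = {}
    for comp in apcs.columns:
        scores = apcs[comp].to_numpy(dtype=float)
        rs = {
            fam: abs(float(np.corrcoef(scores, signals[fam].to_numpy(dtype=float))[0, 1]))
            for fam in signals.columns
        }
        ranked = sorted(rs, key=rs.get, reverse=True)
        best = ranked[0]
        clear = rs[best] >= min_abs_r and (
            len(ranked) == 1 or rs[best] - rs[ranked[1]] >= min_margin)
        out[comp] = best if clear else None
    return out


def family_shares(contributions: pd.DataFrame, assignment: dict[str, str | None]) -> pd.DataFrame:
    """Aggregate per-component percent shares into per-family shares."""
    families = sorted({f for f in assignment.values() if f is not None})
    out = pd.DataFrame(0.0, index=contributions.index, columns=families)
    for comp, fam in assignment.items():
        if fam is not None and comp in contributions.columns:
            out[fam] += contributions[comp]
    return out


# -- serialization ---------------------------------------------------------

def sources_frame(scenario: SourceScenario) -> pd.DataFrame:
    """Source table (name, family, wkt) as consumed by rf_source."""
    return pd.DataFrame({
        "name": [s.name for s in scenario.sources],
        "family": [s.family for s in scenario.sources],
        "wkt": [s.geometry.wkt for s in scenario.sources],
    })


def write_survey(scenario: SourceScenario, outdir: str | Path) -> dict[str, Path]:
    """Write soil.csv, plants.csv, sources.csv, refs.yaml and truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    soil, plants, truth = simulate_survey(scenario)
    paths = {
        "soil": outdir / "soil.csv",
        "plants": outdir / "plants.csv",
        "sources": outdir / "sources.csv",
        "refs": outdir / "refs.yaml",
        "truth": outdir / "truth.json",
    }
    soil.to_csv(paths["soil"])
    plants.to_csv(paths["plants"])
    sources_frame(scenario).to_csv(paths["sources"], index=False)
    ReferenceSet().to_yaml(paths["refs"])
    payload = {
        "seed": scenario.seed,
        "shares_percent": {m: truth["shares"].loc[m].round(6).to_dict()
                           for m in scenario.metals},
        "dominant_source": truth["dominant_source"],
        "family": truth["family"],
    }
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
    return paths
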