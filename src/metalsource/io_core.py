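"""Data model and I/O for paired soil-plant heavy-metal surveys.

A survey consists of a soil table and a plant table, paired by
``sample_id``, each holding one concentration column (mg/kg dry weight)
per metal, plus a :class:`ReferenceSet` of per-metal reference values:
regional geochemical background, plant standard limits, Hakanson
toxicity coefficients, and risk-screening values.

Tables travel as plain CSV (comma-separated, UTF-8, header row,
decimal point); reference sets as YAML. Coordinates, when present, are
planar kilometres in a projected frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("metalsource")

#: The seven metals of the survey design, in reporting order.
METALS: tuple[str, ...] = ("Cr", "Cu", "Zn", "Cd", "Pb", "Hg", "As")

#: Regional geochemical background values for Xinjiang topsoil (mg/kg).
XINJIANG_BACKGROUND: dict[str, float] = {
    "Cr": 49.30, "Cu": 26.70, "Zn": 68.80, "Cd": 0.12,
    "Pb": 19.40, "Hg": 0.02, "As": 11.20,
}

#: National soil risk-screening values, GB 15618-2018 (mg/kg).
SCREENING_VALUES: dict[str, float] = {
    "Cr": 250.0, "Cu": 100.0, "Zn": 300.0, "Cd": 0.60,
    "Pb": 170.0, "Hg": 3.40, "As": 25.0,
}

#: Standard limits for plant tissue (mg/kg dry weight).
PLANT_LIMITS: dict[str, float] = {
    "Cr": 2.00, "Cu": 45.80, "Zn": 100.0, "Cd": 0.20,
    "Pb": 3.00, "Hg": 0.01, "As": 5.00,
}

#: Hakanson toxicity coefficients (dimensionless).
TOXICITY_COEFFICIENTS: dict[str, float] = {
    "Cr": 2.0, "Cu": 5.0, "Zn": 1.0, "Cd": 30.0,
    "Pb": 5.0, "Hg": 40.0, "As": 10.0,
}

# Class schemes: ordered (upper bound, label) pairs; the final bound is inf.
# Nemerow intervals are right-closed (value <= bound), Hakanson intervals
# right-open (value < bound).
NIPI_CLASSES: tuple[tuple[float, str], ...] = (
    (0.7, "Safe"),
    (1.0, "Alert"),
    (2.0, "Light Pollution"),
    (3.0, "Moderate Pollution"),
    (np.inf, "Heavy Pollution"),
)
ER_CLASSES: tuple[tuple[float, str], ...] = (
    (40.0, "Low Risk"),
    (80.0, "Moderate Risk"),
    (160.0, "Considerable Risk"),
    (320.0, "High Risk"),
    (np.inf, "Very High Risk"),
)
RI_CLASSES: tuple[tuple[float, str], ...] = (
    (150.0, "Low Risk"),
    (300.0, "Moderate Risk"),
    (600.0, "High Risk"),
    (np.inf, "Very High Risk"),
)


class SurveyValidationError(ValueError):
    """Raised when a concentration table or reference set is malformed."""


@dataclass
class ConcentrationTable:
    """Per-sample metal concentrations for one medium (soil or plant).

    Parameters
    ----------
    data:
        DataFrame with a ``sample_id`` column, optional ``species``
        (plant tables), optional planar coordinates ``x``/``y`` (km),
        and one concentration column (mg/kg) per metal.
    metals:
        Metal column names; defaults to the seven survey metals.
    """

    data: pd.DataFrame
    metals: tuple[str, ...] = METALS

    def __post_init__(self) -> None:
        df = self.data
        if "sample_id" not in df.columns:
            raise SurveyValidationError("table lacks a 'sample_id' column")
        missing = [m for m in self.metals if m not in df.columns]
        if missing:
            raise SurveyValidationError(f"missing metal column(s): {', '.join(missing)}")
        if df["sample_id"].duplicated().any():
            dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise SurveyValidationError(f"duplicate sample_id(s): {dupes}")
        conc = df[list(self.metals)].to_numpy(dtype=float)
        if not np.isfinite(conc).all():
            raise SurveyValidationError("non-finite concentration encountered")
        if (conc < 0).any():
            rows, cols = np.nonzero(conc < 0)
            sid = df["sample_id"].iloc[rows[0]]
            raise SurveyValidationError(
                f"negative {self.metals[cols[0]]} concentration in sample {sid!r}"
            )
        self.data = df.reset_index(drop=True)

    # -- accessors ---------------------------------------------------------
    @property
    def sample_ids(self) -> pd.Series:
        return self.data["sample_id"]

    @property
    def species(self) -> pd.Series | None:
        return self.data["species"] if "species" in self.data.columns else None

    @property
    def has_coordinates(self) -> bool:
        return {"x", "y"}.issubset(self.data.columns)

    def concentrations(self) -> pd.DataFrame:
        """Metal concentrations indexed by sample_id (metals as columns)."""
        return self.data.set_index("sample_id")[list(self.metals)].astype(float)

    def coordinates(self) -> pd.DataFrame:
        if not self.has_coordinates:
            raise SurveyValidationError("table has no x/y coordinate columns")
        return self.data.set_index("sample_id")[["x", "y"]].astype(float)

    def __len__(self) -> int:
        return len(self.data)

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_csv(cls, path: str | Path, metals: tuple[str, ...] = METALS) -> "ConcentrationTable":
        return cls(pd.read_csv(path), metals=metals)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


@dataclass
class ReferenceSet:
    """Per-metal reference values and classification schemes."""

    background: dict[str, float] = field(default_factory=lambda: dict(XINJIANG_BACKGROUND))
    plant_limit: dict[str, float] = field(default_factory=lambda: dict(PLANT_LIMITS))
    toxicity: dict[str, float] = field(default_factory=lambda: dict(TOXICITY_COEFFICIENTS))
    screening: dict[str, float] = field(default_factory=lambda: dict(SCREENING_VALUES))
    nipi_classes: tuple[tuple[float, str], ...] = NIPI_CLASSES
    er_classes: tuple[tuple[float, str], ...] = ER_CLASSES
    ri_classes: tuple[tuple[float, str], ...] = RI_CLASSES

    def __post_init__(self) -> None:
        for name in ("background", "plant_limit", "toxicity", "screening"):
            vals = getattr(self, name)
            for metal, v in vals.items():
                if not (np.isfinite(v) and v > 0):
                    raise SurveyValidationError(f"{name}[{metal}] must be positive, got {v}")
        for name in ("nipi_classes", "er_classes", "ri_classes"):
            bounds = [b for b, _ in getattr(self, name)]
            if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
                raise SurveyValidationError(f"{name} thresholds must be strictly increasing")

    def require(self, metals: tuple[str, ...], tables: tuple[str, ...] = ("background", "plant_limit", "toxicity")) -> None:
        """Check every metal has an entry in the named reference tables."""
        for name in tables:
            vals = getattr(self, name)
            for metal in metals:
                if metal not in vals:
                    raise SurveyValidationError(f"reference table {name!r} lacks an entry for {metal!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ReferenceSet":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in ("background", "plant_limit", "toxicity", "screening"):
            if key in raw:
                kwargs[key] = {str(k): float(v) for k, v in raw[key].items()}
        for key in ("nipi_classes", "er_classes", "ri_classes"):
            if key in raw:
                kwargs[key] = tuple(
                    (np.inf if b in ("inf", ".inf", None) else float(b), str(lab))
                    for b, lab in raw[key]
                )
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "background": self.background,
            "plant_limit": self.plant_limit,
            "toxicity": self.toxicity,
            "screening": self.screening,
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


def classify(value: float, scheme: tuple[tuple[float, str], ...], right_closed: bool) -> str:
    """Map a nonnegative index value onto an ordered class scheme.

    ``right_closed`` selects the interval convention: ``True`` means a
    value equal to an upper bound takes that bin's label (Nemerow),
    ``False`` pushes it into the next bin (Hakanson).
    """
    if not np.isfinite(value) or value < 0:
        raise ValueError(f"index value must be finite and >= 0, got {value}")
    for bound, label in scheme:
        if (value <= bound) if right_closed else (value < bound):
            return label
    return scheme[-1][1]  # pragma: no cover - inf bound always matches


def read_survey(
    soil_path: str | Path,
    plant_path: str | Path,
    refs_path: str | Path | None = None,
    metals: tuple[str, ...] = METALS,
) -> tuple[ConcentrationTable, ConcentrationTable, ReferenceSet]:
    """Read and validate a paired soil-plant survey.

    Plant rows whose ``sample_id`` has no soil counterpart are dropped
    with a logged warning; a missing metal column or a negative
    concentration is a hard error.
    """
    soil = ConcentrationTable.from_csv(soil_path, metals=metals)
    plants = ConcentrationTable.from_csv(plant_path, metals=metals)
    unpaired = ~plants.sample_ids.isin(soil.sample_ids)
    if unpaired.any():
        dropped = plants.sample_ids[unpaired].tolist()
        logger.warning("dropping %d unpaired plant sample(s): %s", len(dropped), dropped)
        plants = ConcentrationTable(plants.data.loc[~unpaired], metals=metals)
    refs = ReferenceSet.from_yaml(refs_path) if refs_path is not None else ReferenceSet()
    refs.require(metals)
    return soil, plants, refs


def describe(table: ConcentrationTable) -> pd.DataFrame:
    """Descriptive statistics per metal.

    Returns a DataFrame indexed by metal with columns ``max``, ``min``,
    ``median``, ``mean``, ``sd``, ``cv_percent``, ``kurtosis``,
    ``skewness``. The sd uses the n-1 denominator, ``cv_percent`` is
    100*sd/mean, kurtosis is excess kurtosis and skewness the adjusted
    Fisher-Pearson coefficient (ordinary stats-package defaults).
    """
    if len(table) < 2:
        raise ValueError("descriptive statistics need at least 2 samples (sd undefined)")
    conc = table.concentrations()
    out = pd.DataFrame(index=list(table.metals))
    out["max"] = conc.max()
    out["min"] = conc.min()
    out["median"] = conc.median()
    out["mean"] = conc.mean()
    out["sd"] = conc.std(ddof=1)
    mean = out["mean"]
    out["cv_percent"] = np.where(mean > 0, 100.0 * out["sd"] / mean, np.nan)
    out["kurtosis"] = conc.kurt()
    out["skewness"] = conc.skew()
    return out
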