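"""Soil pollution indices: single-factor, Nemerow, and Hakanson risk.

The single-factor index Pi = Ci/Bi compares a measured concentration
with the regional geochemical background Bi. The Nemerow composite
index NIPI = sqrt((Pave^2 + Pmax^2)/2) blends the survey-average and
survey-maximum single-factor indices, weighting the worst pollutant.
The Hakanson single-metal risk Er = Tr * Pi scales Pi by a per-metal
toxicity coefficient, and RI sums Er values into a composite potential
ecological risk score.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_core import ConcentrationTable, ReferenceSet, classify


def single_factor_index(c, b):
    """Single-factor pollution index Pi = Ci/Bi (element-wise)."""
    c = np.asarray(c, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(b <= 0):
        raise ValueError("background value must be > 0")
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    out = c / b
    return out.item() if out.ndim == 0 else out


def nemerow_index(p_ave, p_max):
    """Nemerow composite index: quadratic mean of Pave and Pmax."""
    p_ave = np.asarray(p_ave, dtype=float)
    p_max = np.asarray(p_max, dtype=float)
    if np.any(p_ave < 0) or np.any(p_max < 0):
        raise ValueError("single-factor indices must be >= 0")
    out = np.sqrt((p_ave**2 + p_max**2) / 2.0)
    return out.item() if out.ndim == 0 else out


def ecological_risk(pi, tr):
    """Hakanson single-metal potential ecological risk Er = Tr * Pi."""
    pi = np.asarray(pi, dtype=float)
    tr = np.asarray(tr, dtype=float)
    if np.any(pi < 0):
        raise ValueError("single-factor index must be >= 0")
    if np.any(tr <= 0):
        raise ValueError("toxicity coefficient must be > 0")
    out = tr * pi
    return out.item() if out.ndim == 0 else out


def aggregate_ri(er) -> float:
    """Sum Er values into a composite RI.

    The caller chooses the aggregation axis: across metals for a
    sample's composite risk, or across samples for a per-metal total.
    """
    er = np.asarray(er, dtype=float).ravel()
    if er.size == 0:
        raise ValueError("cannot aggregate an empty Er vector")
    if np.any(er < 0):
        raise ValueError("Er values must be >= 0")
    return float(er.sum())


def classify_nipi(nipi: float, refs: ReferenceSet | None = None) -> str:
    """Label a Nemerow index (right-closed intervals)."""
    scheme = (refs or ReferenceSet()).nipi_classes
    return classify(nipi, scheme, right_closed=True)


def classify_er(er: float, refs: ReferenceSet | None = None) -> str:
    """Label a single-metal Er value (right-open intervals)."""
    scheme = (refs or ReferenceSet()).er_classes
    return classify(er, scheme, right_closed=False)


def classify_ri(ri: float, refs: ReferenceSet | None = None) -> str:
    """Label a composite RI value (right-open intervals)."""
    scheme = (refs or ReferenceSet()).ri_classes
    return classify(ri, scheme, right_closed=False)


def index_report(soil: ConcentrationTable, refs: ReferenceSet | None = None) -> pd.DataFrame:
    """Per-metal pollution-index summary for a soil survey.

    For each metal: Pave and Pmax from the survey mean and maximum
    concentration, the Nemerow index and its class, the per-metal RI
    (sum of per-sample Er over all samples) and its risk class.
    """
    refs = refs or ReferenceSet()
    refs.require(soil.metals, tables=("background", "toxicity"))
    conc = soil.concentrations()
    rows = []
    for metal in soil.metals:
        b = refs.background[metal]
        tr = refs.toxicity[metal]
        pi = single_factor_index(conc[metal].to_numpy(), b)
        p_ave = single_factor_index(float(conc[metal].mean()), b)
        p_max = single_factor_index(float(conc[metal].max()), b)
        nipi = nemerow_index(p_ave, p_max)
        ri = aggregate_ri(ecological_risk(pi, tr))
        rows.append({
            "metal": metal,
            "p_ave": p_ave,
            "p_max": p_max,
            "nipi": nipi,
            "nipi_level": classify_nipi(nipi, refs),
            "mean_er": ri / len(pi),
            "ri": ri,
            "risk_level": classify_ri(ri, refs),
        })
    return pd.DataFrame(rows).set_index("metal")


def sample_ri(soil: ConcentrationTable, refs: ReferenceSet | None = None) -> pd.Series:
    """Composite RI per sample: sum of Er over the seven metals."""
    refs = refs or ReferenceSet()
    conc = soil.concentrations()
    er = pd.DataFrame({
        m: ecological_risk(single_factor_index(conc[m].to_numpy(), refs.background[m]),
                           refs.toxicity[m])
        for m in soil.metals
    }, index=conc.index)
    return er.sum(axis=1)
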