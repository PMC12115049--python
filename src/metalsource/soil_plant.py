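"""Soil-plant transfer: bioconcentration factors, exceedance folds,
correlation matrices, and nonparametric group-difference tests.

The bioconcentration factor BCF = Cp/Cs is the ratio of a plant-tissue
concentration to the paired topsoil concentration; BCF > 1 marks a
metal the species actively accumulates. Species summaries average
per-sample BCFs within species, and the cross-species mean is the
unweighted mean of the species means.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import ConcentrationTable, ReferenceSet

logger = logging.getLogger("metalsource")


def bcf(cp, cs):
    """Bioconcentration factor BCF = Cp/Cs (element-wise)."""
    cp = np.asarray(cp, dtype=float)
    cs = np.asarray(cs, dtype=float)
    if np.any(cs <= 0):
        raise ValueError("soil concentration must be > 0 to form a BCF")
    if np.any(cp < 0):
        raise ValueError("plant concentration must be >= 0")
    out = cp / cs
    return out.item() if out.ndim == 0 else out


def exceedance_fold(mean_c, limit):
    """How many times a mean concentration exceeds a standard limit."""
    mean_c = np.asarray(mean_c, dtype=float)
    limit = np.asarray(limit, dtype=float)
    if np.any(limit <= 0):
        raise ValueError("standard limit must be > 0")
    out = mean_c / limit
    return out.item() if out.ndim == 0 else out


def cross_species_mean(species_means) -> float:
    """Unweighted mean of species-mean BCFs (not the pooled mean)."""
    vals = np.asarray(species_means, dtype=float)
    if vals.size == 0:
        raise ValueError("no species means supplied")
    return float(vals.mean())


@dataclass
class BcfReport:
    """Per-sample, per-species, and cross-species BCF summaries."""

    per_sample: pd.DataFrame       # columns: sample_id, species, metal, bcf
    species_means: pd.DataFrame    # species x metal
    cross_species: pd.Series       # per metal

    def to_long(self) -> pd.DataFrame:
        long = self.species_means.reset_index().melt(
            id_vars="species", var_name="metal", value_name="mean_bcf")
        n = (self.per_sample.groupby(["species", "metal"]).size()
             .rename("n").reset_index())
        return long.merge(n, on=["species", "metal"])


def _paired(plants: ConcentrationTable, soil: ConcentrationTable):
    """Align plant rows with their soil counterparts by sample_id."""
    pc = plants.concentrations()
    sc = soil.concentrations()
    common = pc.index.intersection(sc.index)
    if len(common) == 0:
        raise ValueError("no paired sample_ids between plant and soil tables")
    if plants.species is None:
        raise ValueError("plant table lacks a 'species' column")
    species = plants.data.set_index("sample_id").loc[common, "species"]
    return pc.loc[common], sc.loc[common], species


def species_bcf_summary(plants: ConcentrationTable, soil: ConcentrationTable) -> BcfReport:
    """BCFs on matched pairs, averaged by species then across species.

    Pairs with a zero soil concentration are excluded with a warning;
    species left with no pairs are omitted with a warning.
    """
    pc, sc, species = _paired(plants, soil)
    records = []
    for metal in plants.metals:
        cs = sc[metal].to_numpy()
        cp = pc[metal].to_numpy()
        ok = cs > 0
        if not ok.all():
            bad = pc.index[~ok].tolist()
            logger.warning("excluding %d pair(s) with zero soil %s: %s", (~ok).sum(), metal, bad)
        records.append(pd.DataFrame({
            "sample_id": pc.index[ok],
            "species": species.to_numpy()[ok],
            "metal": metal,
            "bcf": bcf(cp[ok], cs[ok]),
        }))
    per_sample = pd.concat(records, ignore_index=True)
    present = per_sample["species"].unique()
    for sp in species.unique():
        if sp not in present:
            logger.warning("species %r has no usable pairs; omitted", sp)
    species_means = (per_sample.pivot_table(index="species", columns="metal",
                                            values="bcf", aggfunc="mean")
                     [list(plants.metals)])
    species_means.columns.name = None
    cross = species_means.mean(axis=0).rename("cross_species_bcf")
    return BcfReport(per_sample=per_sample, species_means=species_means, cross_species=cross)


def exceedance_table(plants: ConcentrationTable, refs: ReferenceSet | None = None) -> pd.DataFrame:
    """Species-mean exceedance folds against the plant standard limits."""
    refs = refs or ReferenceSet()
    refs.require(plants.metals, tables=("plant_limit",))
    if plants.species is None:
        raise ValueError("plant table lacks a 'species' column")
    means = plants.data.groupby("species")[list(plants.metals)].mean()
    limits = pd.Series({m: refs.plant_limit[m] for m in plants.metals})
    return means / limits


def soil_plant_correlations(
    plants: ConcentrationTable, soil: ConcentrationTable, min_pairs: int = 3
) -> dict[str, pd.DataFrame]:
    """Per-species Pearson r between plant-metal and soil-metal columns.

    Returns one (plant metal x soil metal) matrix per species, computed
    over that species' paired samples only. A zero-variance column
    yields NaN entries with a warning.
    """
    pc, sc, species = _paired(plants, soil)
    out: dict[str, pd.DataFrame] = {}
    for sp in pd.unique(species):
        idx = species[species == sp].index
        if len(idx) < min_pairs:
            logger.warning("species %r has %d < %d pairs; skipped", sp, len(idx), min_pairs)
            continue
        p = pc.loc[idx].to_numpy(dtype=float)
        s = sc.loc[idx].to_numpy(dtype=float)
        mat = np.full((p.shape[1], s.shape[1]), np.nan)
        for i in range(p.shape[1]):
            for j in range(s.shape[1]):
                if p[:, i].std() == 0 or s[:, j].std() == 0:
                    logger.warning(
                        "zero-variance column for species %r (%s/%s); r undefined",
                        sp, plants.metals[i], soil.metals[j])
                    continue
                mat[i, j] = stats.pearsonr(p[:, i], s[:, j])[0]
        out[sp] = pd.DataFrame(mat, index=list(plants.metals), columns=list(soil.metals))
    return out


def group_difference_tests(
    plants: ConcentrationTable, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Kruskal-Wallis omnibus test per metal across species, with
    pairwise Mann-Whitney follow-ups (Bonferroni-adjusted) whenever the
    omnibus p-value falls below ``alpha``.

    Returns ``(omnibus, pairwise)`` frames. Species groups with fewer
    than 2 observations are excluded with a warning; a metal whose
    values are all identical is reported with p = 1.
    """
    if plants.species is None:
        raise ValueError("plant table lacks a 'species' column")
    df = plants.data
    counts = df.groupby("species").size()
    keep = counts[counts >= 2].index
    for sp in counts[counts < 2].index:
        logger.warning("species %r has < 2 observations; excluded from tests", sp)
    df = df[df["species"].isin(keep)]
    if df["species"].nunique() < 2:
        raise ValueError("need at least 2 species groups with >= 2 observations")

    omnibus_rows, pair_rows = [], []
    groups = {sp: g for sp, g in df.groupby("species")}
    for metal in plants.metals:
        samples = [g[metal].to_numpy(dtype=float) for g in groups.values()]
        pooled = np.concatenate(samples)
        if np.ptp(pooled) == 0:
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.kruskal(*samples)
        omnibus_rows.append({"metal": metal, "statistic": stat, "omnibus_p": p})
        if p < alpha:
            pairs = list(itertools.combinations(groups, 2))
            for a, b in pairs:
                xa = groups[a][metal].to_numpy(dtype=float)
                xb = groups[b][metal].to_numpy(dtype=float)
                if np.ptp(np.concatenate([xa, xb])) == 0:
                    raw = 1.0
                else:
                    raw = stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue
                pair_rows.append({
                    "metal": metal, "group_a": a, "group_b": b,
                    "raw_p": raw, "adjusted_p": min(1.0, raw * len(pairs)),
                })
    omnibus = pd.DataFrame(omnibus_rows).set_index("metal")
    pairwise = pd.DataFrame(pair_rows, columns=["metal", "group_a", "group_b", "raw_p", "adjusted_p"])
    return omnibus, pairwise


def compare_to_reference(
    table: ConcentrationTable, refs: ReferenceSet | None = None, which: str = "background"
) -> pd.DataFrame:
    """One-sample Wilcoxon signed-rank test of each metal against a
    reference value (two-sided). ``which`` selects the reference table
    (``background``, ``plant_limit`` or ``screening``)."""
    refs = refs or ReferenceSet()
    ref_vals = getattr(refs, which)
    conc = table.concentrations()
    rows = []
    for metal in table.metals:
        diffs = conc[metal].to_numpy(dtype=float) - ref_vals[metal]
        if np.all(diffs == 0):
            p = 1.0
        else:
            p = stats.wilcoxon(diffs).pvalue
        rows.append({"metal": metal, "reference": ref_vals[metal], "p": p})
    return pd.DataFrame(rows).set_index("metal")
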