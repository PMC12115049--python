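"""Bioconcentration, exceedance, correlation, and group-difference tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from metalsource.io_core import METALS, ConcentrationTable
from metalsource.soil_plant import (
    bcf,
    cross_species_mean,
    exceedance_fold,
    group_difference_tests,
    soil_plant_correlations,
    species_bcf_summary,
)
from tests.conftest import random_table


def make_pair(rng, n=12, n_species=3):
    soil = random_table(rng, n=n)
    plants = random_table(rng, n=n, species=False)
    plants.data.insert(1, "species", [f"sp_{i % n_species}" for i in range(n)])
    return soil, ConcentrationTable(plants.data)


class TestBcf:
    @pytest.mark.parametrize("cp,cs,want", [
        (294.24, 44.38, 6.6300),   # ratio of survey means; differs from the per-sample-mean convention
        (5.0, 5.0, 1.0),
        (0.0, 5.0, 0.0),
    ])
    def test_examples(self, cp, cs, want):
        assert bcf(cp, cs) == pytest.approx(want, abs=1e-4)

    def test_zero_soil_rejected(self):
        with pytest.raises(ValueError):
            bcf(1.0, 0.0)


class TestExceedance:
    @pytest.mark.parametrize("mean_c,limit,want", [
        (294.24, 2.00, 147.12),
        (115.46, 2.00, 57.73),
        (3.0, 3.0, 1.0),
    ])
    def test_examples(self, mean_c, limit, want):
        assert exceedance_fold(mean_c, limit) == pytest.approx(want)


class TestSpeciesBcfSummary:
    def test_cross_species_mean_is_mean_of_species_means(self):
        # The published cross-species values are only reproducible when
        # species means are averaged unweighted (not pooled per sample).
        assert cross_species_mean([7.303, 1.78, 2.60, 1.45]) == pytest.approx(3.28, abs=5e-3)
        assert cross_species_mean([1.35, 1.46, 1.26, 0.82]) == pytest.approx(1.22, abs=5e-3)
        assert cross_species_mean([1.424, 0.71, 0.71, 0.84]) == pytest.approx(0.92, abs=5e-3)

    def test_summary_on_constructed_pairs(self, rng):
        # plant = known factor * soil, unequal group sizes
        soil = random_table(rng, n=9)
        factors = {"a": 2.0, "b": 0.5, "c": 1.0}
        species = ["a"] * 2 + ["b"] * 3 + ["c"] * 4
        pdata = soil.data.copy()
        pdata.insert(1, "species", species)
        for m in METALS:
            pdata[m] = pdata[m] * [factors[s] for s in species]
        report = species_bcf_summary(ConcentrationTable(pdata), soil)
        for sp, f in factors.items():
            assert report.species_means.loc[sp, "Cd"] == pytest.approx(f, rel=1e-12)
        assert report.cross_species["Cd"] == pytest.approx(np.mean(list(factors.values())), rel=1e-12)

    def test_single_pair_species(self, rng):
        soil = random_table(rng, n=1)
        pdata = soil.data.copy()
        pdata.insert(1, "species", ["only"])
        for m in METALS:
            pdata[m] = soil.data[m] * 2.0
        report = species_bcf_summary(ConcentrationTable(pdata), soil)
        assert report.species_means.loc["only", "Pb"] == pytest.approx(2.0)

    def test_permutation_invariance(self, rng):
        soil, plants = make_pair(rng, n=12)
        base = species_bcf_summary(plants, soil).species_means
        perm = rng.permutation(len(plants.data))
        shuffled = species_bcf_summary(
            ConcentrationTable(plants.data.iloc[perm]),
            ConcentrationTable(soil.data.iloc[rng.permutation(len(soil.data))]))
        pd.testing.assert_frame_equal(base.sort_index(), shuffled.species_means.sort_index())


class TestCorrelations:
    def test_identical_and_reflected_columns(self, rng):
        soil = random_table(rng, n=8)
        pdata = soil.data.copy()
        pdata.insert(1, "species", ["one"] * 8)
        pdata["Cr"] = soil.data["Cr"]                   # identical -> r = 1
        pdata["Pb"] = -soil.data["Pb"] + 100.0          # reflected -> r = -1
        mats = soil_plant_correlations(ConcentrationTable(pdata), soil)
        assert mats["one"].loc["Cr", "Cr"] == pytest.approx(1.0)
        assert mats["one"].loc["Pb", "Pb"] == pytest.approx(-1.0)

    def test_five_point_hand_example(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 5])
        num = float(np.sum((x - x.mean()) * (y - y.mean())))
        den = float(np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)))
        assert num / den == pytest.approx(0.8)
        assert sps.pearsonr(x, y)[0] == pytest.approx(0.8)

    def test_matches_brute_force_oracle(self, rng):
        soil, plants = make_pair(rng, n=15, n_species=1)
        mats = soil_plant_correlations(plants, soil)
        pc, sc = plants.concentrations(), soil.concentrations()
        for pm in METALS:
            for sm in METALS:
                x, y = pc[pm].to_numpy(), sc[sm].to_numpy()
                num = sum((xi - x.mean()) * (yi - y.mean()) for xi, yi in zip(x, y))
                den = (sum((xi - x.mean()) ** 2 for xi in x)
                       * sum((yi - y.mean()) ** 2 for yi in y)) ** 0.5
                assert mats["sp_0"].loc[pm, sm] == pytest.approx(num / den, rel=1e-12)

    def test_zero_variance_reported_missing(self, rng, caplog):
        soil, plants = make_pair(rng, n=8, n_species=1)
        plants.data["Hg"] = 3.0
        import logging
        with caplog.at_level(logging.WARNING, logger="metalsource"):
            mats = soil_plant_correlations(plants, soil)
        assert mats["sp_0"].loc["Hg"].isna().all()


class TestGroupDifferences:
    def test_identical_groups_give_p_one(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        data = pd.DataFrame({
            "sample_id": range(8),
            "species": ["a"] * 4 + ["b"] * 4,
            **{m: vals + vals for m in METALS},
        })
        omnibus, pairwise = group_difference_tests(ConcentrationTable(data))
        assert np.allclose(omnibus["omnibus_p"], 1.0)
        assert pairwise.empty

    def test_shifted_groups_detected(self, rng):
        # 3-sd shift between groups of 12: both Kruskal-Wallis and a
        # 10,000-draw permutation oracle of its H statistic agree p < 0.01
        a = rng.normal(0, 1, 12)
        b = rng.normal(3, 1, 12)
        data = pd.DataFrame({
            "sample_id": range(24),
            "species": ["a"] * 12 + ["b"] * 12,
            **{m: np.abs(np.concatenate([a, b])) + 10 for m in METALS},
        })
        omnibus, pairwise = group_difference_tests(ConcentrationTable(data))
        assert (omnibus["omnibus_p"] < 0.01).all()
        pooled = np.concatenate([a, b])
        h_obs = sps.kruskal(a, b).statistic
        count = 0
        n_perm = 10_000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            if sps.kruskal(perm[:12], perm[12:]).statistic >= h_obs:
                count += 1
        assert (count + 1) / (n_perm + 1) < 0.01
        assert not pairwise.empty
        assert (pairwise["adjusted_p"] >= pairwise["raw_p"] - 1e-15).all()

    def test_constant_groups_handled(self):
        data = pd.DataFrame({
            "sample_id": range(20),
            "species": np.repeat(["a", "b", "c", "d"], 5),
            **{m: np.repeat([1.0, 2.0, 3.0, 4.0], 5) for m in METALS},
        })
        omnibus, _ = group_difference_tests(ConcentrationTable(data))
        assert np.isfinite(omnibus["omnibus_p"]).all()
        assert (omnibus["omnibus_p"] < 0.05).all()

    def test_small_group_excluded(self, caplog):
        import logging
        data = pd.DataFrame({
            "sample_id": range(7),
            "species": ["a"] * 3 + ["b"] * 3 + ["lone"],
            **{m: np.arange(7, dtype=float) + 1 for m in METALS},
        })
        with caplog.at_level(logging.WARNING, logger="metalsource"):
            omnibus, _ = group_difference_tests(ConcentrationTable(data))
        assert any("lone" in r.message for r in caplog.records)
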