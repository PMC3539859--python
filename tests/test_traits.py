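import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aflpop import (
    DistanceMatrix,
    correlation_suite,
    geo_genetic_correlation,
    mantel_spearman,
    mutant_flower_frequency,
    mutant_fraction,
    pollen_ovule_ratio,
    pollen_total,
    seed_summaries,
    spearman,
)
from aflpop.io import ConfigError, FormatError, TraitTable
from aflpop.traits import bud_summaries


class TestMutantFlowers:
    def test_worked_fraction(self):
        assert round(100 * mutant_fraction(47, 103), 2) == 45.63

    def test_zero_mutants(self):
        assert mutant_fraction(0, 54) == 0.0

    def test_more_mutants_than_flowers_rejected(self):
        with pytest.raises(FormatError):
            mutant_fraction(10, 5)

    def test_complete_area_separation_significant(self):
        counts = pd.DataFrame(
            {
                "population": [f"p{i}" for i in range(14)],
                "n_mutant": [30 + i for i in range(7)] + [0, 1, 0, 2, 1, 0, 1],
                "n_total": [100] * 14,
            }
        )
        area = {f"p{i}": ("introduced" if i < 7 else "native") for i in range(14)}
        table, cmp = mutant_flower_frequency(counts, area)
        assert cmp["p_value"] < 0.05
        assert table["mutant_fraction"].iloc[0] == pytest.approx(0.30)


class TestPollenAndOvules:
    def test_constant_aliquots(self):
        assert pollen_total([5] * 10) == 5000.0

    def test_mean_of_one_to_ten(self):
        assert pollen_total(range(1, 11)) == 5500.0

    def test_all_zero_counts(self):
        assert pollen_total([0] * 10) == 0.0

    def test_wrong_aliquot_count_rejected(self):
        with pytest.raises(FormatError):
            pollen_total([1] * 9)

    def test_ratio(self):
        assert pollen_ovule_ratio(5000, 10) == 500.0
        assert pollen_ovule_ratio(0, 8) == 0.0

    def test_zero_ovules_rejected(self):
        with pytest.raises(ConfigError):
            pollen_ovule_ratio(100, 0)

    def test_population_po_decreases_with_planted_load(self, scenario):
        buds = bud_summaries(scenario.traits)
        po = buds.groupby("population")["pollen_ovule_ratio"].mean()
        load = scenario.truth.populations.set_index("population")["mean_load"]
        r, _ = stats.spearmanr(load.reindex(po.index), po)
        assert r < -0.5


class TestSeedSummaries:
    def test_per_capsule_mean_width(self):
        traits = TraitTable(
            seeds=pd.DataFrame(
                [
                    {"population": "P", "capsule_id": "c1", "width_mm": 0.5,
                     "viability": "viable"},
                    {"population": "P", "capsule_id": "c1", "width_mm": 0.7,
                     "viability": "dead"},
                ]
            )
        )
        out = seed_summaries(traits)
        assert out["capsule_mean_width_mm"].iloc[0] == pytest.approx(0.6)

    def test_viability_fraction_with_provenance(self):
        seeds = pd.DataFrame(
            [{"population": "P", "capsule_id": f"c{i}", "width_mm": 0.5,
              "viability": ("viable" if i < 33 else "dead")} for i in range(150)]
        )
        out = seed_summaries(TraitTable(seeds=seeds))
        assert out["viable_fraction"].iloc[0] == pytest.approx(0.22)
        assert out["n_viable"].iloc[0] == 33
        assert out["n_viability_tested"].iloc[0] == 150

    def test_empty_group_reported_missing(self):
        traits = TraitTable(
            capsules=pd.DataFrame(
                [{"population": "P", "capsule_id": "c1", "seed_count": 3}]
            )
        )
        out = seed_summaries(traits)
        assert out["n_capsules"].iloc[0] == 1
        assert "viable_fraction" not in out.columns or out.get("n_viability_tested", pd.Series([0])).iloc[0] == 0


class TestSpearman:
    def test_monotone_extremes(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40]).r == pytest.approx(1.0)
        assert spearman([1, 2, 3, 4], [4, 3, 2, 1]).r == pytest.approx(-1.0)

    def test_tied_data_matches_rank_formula(self):
        x = [1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 5.0, 9.0]
        y = [2.0, 1.0, 4.0, 4.0, 6.0, 8.0, 7.0, 7.0]
        res = spearman(x, y)
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert res.r == pytest.approx(expected)

    def test_permutation_p_reproducible(self):
        x = np.arange(10.0)
        y = x + np.random.default_rng(0).normal(0, 3, 10)
        p1 = spearman(x, y, n_perm=499, seed=11).p_value
        p2 = spearman(x, y, n_perm=499, seed=11).p_value
        assert p1 == p2

    def test_length_mismatch_rejected(self):
        with pytest.raises(ConfigError):
            spearman([1, 2, 3], [1, 2])


def _dm(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"p{i}" for i in range(len(values))]
    return DistanceMatrix(ids, values, "geographic")


def _random_euclidean_dm(rng, n, ids=None):
    from scipy.spatial.distance import pdist, squareform

    pts = rng.normal(size=(n, 2))
    return _dm(squareform(pdist(pts)), ids)


class TestMantel:
    def test_monotone_relation_maximal(self):
        rng = np.random.default_rng(1)
        geo = _random_euclidean_dm(rng, 8)
        gen = _dm(np.sqrt(geo.values))
        res = mantel_spearman(geo, gen, n_perm=199, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 200)

    def test_twenty_populations_use_190_pairs(self):
        rng = np.random.default_rng(2)
        geo = _random_euclidean_dm(rng, 20)
        gen = _random_euclidean_dm(rng, 20, ids=geo.ids)
        res = geo_genetic_correlation(geo, gen, n_perm=99, seed=0)
        assert res.n == 190

    def test_population_set_mismatch_rejected(self):
        rng = np.random.default_rng(3)
        geo = _random_euclidean_dm(rng, 5)
        gen = _random_euclidean_dm(rng, 5, ids=[f"z{i}" for i in range(5)])
        with pytest.raises(ConfigError):
            geo_genetic_correlation(geo, gen)

    def test_id_order_aligned_before_correlation(self):
        rng = np.random.default_rng(4)
        geo = _random_euclidean_dm(rng, 6)
        gen = _dm(np.sqrt(geo.values), ids=geo.ids)
        perm = [3, 1, 0, 5, 2, 4]
        gen_shuffled = _dm(
            gen.values[np.ix_(perm, perm)], ids=[gen.ids[i] for i in perm]
        )
        res = geo_genetic_correlation(geo, gen_shuffled, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)


class TestCorrelationSuite:
    def test_constant_vector_skipped_with_warning(self):
        table = pd.DataFrame(
            {
                "pollen_per_flower": [1.0, 2.0, 3.0, 4.0],
                "frag_polymorphic": [5.0, 5.0, 5.0, 5.0],
            },
            index=[f"p{i}" for i in range(4)],
        )
        with pytest.warns(UserWarning, match="constant"):
            out = correlation_suite(table, pairs=[("pollen_per_flower", "frag_polymorphic")])
        assert len(out) == 0

    def test_too_few_shared_populations_skipped(self):
        table = pd.DataFrame(
            {"a": [1.0, 2.0, np.nan], "b": [2.0, 1.0, 3.0]}, index=list("xyz")
        )
        with pytest.warns(UserWarning, match="< 3"):
            out = correlation_suite(table, pairs=[("a", "b")])
        assert len(out) == 0

    def test_holm_column_present_and_no_smaller_than_raw(self):
        rng = np.random.default_rng(5)
        table = pd.DataFrame(
            rng.normal(size=(12, 4)), columns=["pollen_per_flower", "hj",
                                               "frag_polymorphic", "mutant_fraction"],
            index=[f"p{i}" for i in range(12)],
        )
        out = correlation_suite(
            table,
            pairs=[("pollen_per_flower", "hj"), ("pollen_per_flower", "frag_polymorphic"),
                   ("mutant_fraction", "pollen_per_flower")],
        )
        assert (out["p_holm"] >= out["p_value"] - 1e-12).all()

    def test_planted_ratchet_sign_pattern(self, scenario):
        """A strong planted ratchet yields the expected sign structure:
        pollen rises with polymorphism and falls with fixation and
        clonality; mutant flowers fall with pollen; diversity rises with
        the non-clonal fraction."""
        from aflpop import call_clones, pairwise_mismatch, replicate_error_rate
        from aflpop.pipeline import population_summary_table, primary_matrix

        prim = primary_matrix(scenario.marker, scenario.samples)
        err = replicate_error_rate(scenario.marker, scenario.samples.replicate_pairs())
        part = call_clones(pairwise_mismatch(prim), err)
        table = population_summary_table(
            prim, scenario.samples, part, scenario.traits, seed=0
        )
        suite = correlation_suite(table).set_index(["x", "y"])
        assert suite.loc[("pollen_per_flower", "frag_polymorphic"), "r"] > 0
        assert suite.loc[("pollen_per_flower", "frag_fixed"), "r"] < 0
        assert suite.loc[("mutant_fraction", "pollen_per_flower"), "r"] < 0
        assert suite.loc[("hj", "nonclonal_fraction"), "r"] > 0
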