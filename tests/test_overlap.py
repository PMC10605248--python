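"""Hypergeometric overlap: exact tails, sweep nulls, set trajectories."""

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom, spearmanr

import lenscope as L
from lenscope.errors import InputError
from lenscope.expression import EnrichmentRanking, cpm, enrichment_ranking
from _helpers import mc_null_overlap


def ranking_from_scores(scores: dict) -> EnrichmentRanking:
    s = pd.Series(scores)
    s.index.name = "gene"
    ordered = s.sort_index().sort_values(ascending=False, kind="mergesort")
    rank = pd.Series(np.arange(1, len(ordered) + 1), index=ordered.index)
    return EnrichmentRanking(
        table=pd.DataFrame({"score": s, "rank": rank.reindex(s.index)})
    )


def random_ranking(n, rng) -> EnrichmentRanking:
    return ranking_from_scores(
        {f"g{i:05d}": v for i, v in enumerate(rng.normal(size=n))}
    )


def exact_tail_fraction(observed, k_a, k_b, n, convention="greater"):
    """Exact rational tail probability by direct pmf summation."""
    start = observed + 1 if convention == "greater" else observed
    total = Fraction(0)
    for k in range(start, min(k_a, k_b) + 1):
        total += Fraction(comb(k_a, k) * comb(n - k_a, k_b - k), comb(n, k_b))
    return total


class TestTopFractionSet:
    def test_published_set_sizes(self):
        rng = np.random.default_rng(0)
        ranking = random_ranking(10320, rng)
        assert len(L.top_fraction_set(ranking, 0.10)) == 1032
        assert len(L.top_fraction_set(ranking, 0.01)) == 103
        assert len(L.top_fraction_set(ranking, 1.0)) == 10320

    def test_out_of_range_fraction_rejected(self):
        ranking = random_ranking(10, np.random.default_rng(0))
        for x in (0.0, -0.1, 1.5):
            with pytest.raises(InputError):
                L.top_fraction_set(ranking, x)


class TestHypergeomTail:
    def test_zero_overlap_geq_is_one(self):
        assert L.hypergeom_overlap_pvalue(0, 10, 10, 100,
                                          "greater_or_equal") == 1.0

    def test_published_overlap_probability(self):
        # 198 shared among two 1032-gene top sets from 10,320 genes
        p_greater = L.hypergeom_overlap_pvalue(198, 1032, 1032, 10320, "greater")
        assert p_greater == pytest.approx(8.7e-22, rel=0.05)
        p_geq = L.hypergeom_overlap_pvalue(198, 1032, 1032, 10320,
                                           "greater_or_equal")
        assert p_geq == pytest.approx(2.1e-21, rel=0.05)

    def test_convention_identity_exact(self):
        # P(X >= O) == P(X > O - 1) exactly, across counts
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(5, 200))
            k_a = int(rng.integers(1, n + 1))
            k_b = int(rng.integers(1, n + 1))
            o = int(rng.integers(1, min(k_a, k_b) + 1))
            assert L.hypergeom_overlap_pvalue(o, k_a, k_b, n, "greater_or_equal") \
                == L.hypergeom_overlap_pvalue(o - 1, k_a, k_b, n, "greater")

    def test_enumeration_of_subset_pairs_small_n(self):
        # full enumeration of independent subset pairs, N <= 12
        n, k_a, k_b = 10, 4, 3
        universe = range(n)
        total = hits_ge2 = 0
        for sa in combinations(universe, k_a):
            for sb in combinations(universe, k_b):
                total += 1
                if len(set(sa) & set(sb)) >= 2:
                    hits_ge2 += 1
        enumerated = hits_ge2 / total
        assert L.hypergeom_overlap_pvalue(2, k_a, k_b, n, "greater_or_equal") \
            == pytest.approx(enumerated, rel=1e-12)

    def test_exact_rational_summation_medium_n(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            n = int(rng.integers(20, 500))
            k_a = int(rng.integers(1, n // 2))
            k_b = int(rng.integers(1, n // 2))
            o = int(rng.integers(0, min(k_a, k_b)))
            for convention in ("greater", "greater_or_equal"):
                exact = float(exact_tail_fraction(o, k_a, k_b, n, convention))
                got = L.hypergeom_overlap_pvalue(o, k_a, k_b, n, convention)
                if exact == 0.0:
                    assert got == 0.0
                else:
                    assert got == pytest.approx(exact, rel=1e-10)

    def test_agrees_with_scipy_survival_function(self):
        # independent implementation cross-check at extreme tails
        p = L.hypergeom_overlap_pvalue(198, 1032, 1032, 10320, "greater")
        assert p == pytest.approx(hypergeom.sf(198, 10320, 1032, 1032), rel=1e-9)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(InputError, match="inconsistent"):
            L.hypergeom_overlap_pvalue(11, 10, 10, 100)


class TestOverlapSweep:
    def test_identical_rankings_full_overlap(self):
        ranking = random_ranking(500, np.random.default_rng(1))
        sweep = L.overlap_sweep(ranking, ranking, [0.02, 0.1, 0.5])
        assert (sweep.table["observed"] == sweep.table["set_size"]).all()

    def test_expected_curve_is_k_squared_over_n(self):
        ranking = random_ranking(10320, np.random.default_rng(2))
        sweep = L.overlap_sweep(ranking, ranking, [0.01, 0.10])
        expected = sweep.table.set_index("x")["expected"]
        assert expected[0.01] == pytest.approx(103**2 / 10320)
        assert round(expected[0.01]) == 1  # one gene expected by chance at 1%
        assert expected[0.10] == pytest.approx(1032**2 / 10320)

    def test_null_mean_overlap_matches_expectation(self):
        # permuted rankings: MC mean within 3 standard errors of K^2/N
        rng = np.random.default_rng(42)
        n = 10320
        for x in (0.01, 0.02, 0.05, 0.10):
            k = int(np.floor(x * n))
            overlaps = mc_null_overlap(n, k, n_draws=200, rng=rng)
            se = overlaps.std(ddof=1) / np.sqrt(len(overlaps))
            assert abs(overlaps.mean() - k * k / n) <= 3 * se

    def test_observed_exceeds_expected_for_correlated_rankings(self):
        # planted shared enrichment (rho = 0.2) lifts O(x) above E(x)
        sim = L.simulate_counts(
            L.CountsSimConfig(shared_enriched_fraction_rho=0.2, seed=0)
        )
        m = sim.matrix
        mean_cpm = {g: cpm(m.subset_groups([g])).mean(axis=1)
                    for g in ("3D", "lens", "WB")}
        sweep = L.overlap_sweep(
            enrichment_ranking(mean_cpm["3D"], mean_cpm["WB"]),
            enrichment_ranking(mean_cpm["lens"], mean_cpm["WB"]),
        )
        t = sweep.table[sweep.table["x"] >= 0.01]  # where E(x) >= 1
        assert (t["observed"] >= t["expected"]).all()

    def test_observed_nondecreasing_in_x(self):
        rng = np.random.default_rng(6)
        sweep = L.overlap_sweep(random_ranking(800, rng),
                                random_ranking(800, rng))
        assert (np.diff(sweep.table["observed"]) >= 0).all()

    def test_mismatched_universes_rejected(self):
        a = random_ranking(50, np.random.default_rng(0))
        b = ranking_from_scores({f"h{i}": float(i) for i in range(50)})
        with pytest.raises(InputError, match="universe"):
            L.overlap_sweep(a, b)


class TestSetMeanTrajectory:
    def stage_table(self, values, genes):
        return pd.DataFrame(values, index=genes,
                            columns=[f"E{10 + 2 * i}.5" for i in
                                     range(np.shape(values)[1])])

    def test_single_gene_set_equals_its_row(self):
        table = self.stage_table([[1.0, 2.0, 3.0], [9.0, 9.0, 9.0]], ["ga", "gb"])
        out = L.set_mean_trajectory({"solo": ["ga"]}, table)
        np.testing.assert_allclose(out["mean"], [1.0, 2.0, 3.0])
        np.testing.assert_allclose(out["sd"], 0.0)

    def test_noiseless_planted_profile_recovered_exactly(self):
        table = self.stage_table([[1.0, 2.0, 3.0]] * 5, [f"g{i}" for i in range(5)])
        out = L.set_mean_trajectory({"up": [f"g{i}" for i in range(5)]}, table)
        np.testing.assert_allclose(out["mean"], [1.0, 2.0, 3.0])

    def test_monotone_profile_with_noise_yields_perfect_spearman(self):
        # 291 genes, increasing stage means + noise sd 0.2
        stages = np.arange(1, 7, dtype=float)
        hits = 0
        n_runs = 100
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            values = stages[None, :] + rng.normal(0, 0.2, size=(291, 6))
            table = self.stage_table(values, [f"g{i}" for i in range(291)])
            out = L.set_mean_trajectory({"3D": list(table.index)}, table)
            if spearmanr(stages, out["mean"]).statistic == 1.0:
                hits += 1
        assert hits / n_runs >= 0.95

    def test_unknown_genes_warned_and_dropped(self):
        table = self.stage_table([[1.0, 2.0]], ["ga"])
        with pytest.warns(UserWarning, match="dropped"):
            out = L.set_mean_trajectory({"s": ["ga", "gz"]}, table)
        assert (out["n_dropped"] == 1).all()
        np.testing.assert_allclose(out["mean"], [1.0, 2.0])
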