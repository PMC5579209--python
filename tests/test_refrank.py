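import itertools
import math

import numpy as np
import pandas as pd
import pytest

from gravistab.matrixio import ValidationError
from gravistab.refrank import (
    bestkeeper_stats,
    coefficient_of_variation,
    delta_ct_stability,
    genorm_ranking,
    global_ranking,
    normfinder_stability,
    rank_table,
    reffinder_consensus,
    stable_reference_genes,
)
from gravistab.screen import ComparisonSpec

from conftest import make_matrix


def frame(values, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"r{i}" for i in range(values.shape[0])]
    return pd.DataFrame(values, index=genes,
                        columns=[f"s{j}" for j in range(values.shape[1])])


def brute_force_pairwise_sd(df):
    """Direct evaluation of the mean pairwise-difference SD definition."""
    out = {}
    for gi in df.index:
        sds = [
            (df.loc[gi] - df.loc[gj]).std(ddof=1)
            for gj in df.index
            if gj != gi
        ]
        out[gi] = np.mean(sds)
    return pd.Series(out)


class TestCoefficientOfVariation:
    def test_constant_vector_is_zero(self):
        assert coefficient_of_variation(frame([[3.0, 3.0, 3.0]]))["r0"] == 0.0

    def test_direct_formula(self):
        # sample SD 1, mean 2 -> 50%
        assert coefficient_of_variation(frame([[1.0, 2.0, 3.0]]))["r0"] == pytest.approx(50.0)

    def test_zero_mean_is_error(self):
        with pytest.raises(ValidationError, match="zero mean"):
            coefficient_of_variation(frame([[-1.0, 1.0]]))

    def test_linear_option_changes_scale(self):
        df = frame([[8.0, 8.5, 9.0]])
        log_cv = coefficient_of_variation(df)["r0"]
        lin_cv = coefficient_of_variation(df, linear=True)["r0"]
        assert lin_cv != pytest.approx(log_cv)


class TestDeltaCt:
    def test_constant_offset_genes_score_zero(self):
        df = frame([[5.0, 6.0, 7.0], [6.0, 7.0, 8.0]])
        scores = delta_ct_stability(df)
        assert scores["r0"] == pytest.approx(0.0, abs=1e-12)
        assert scores["r1"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force(self, rng):
        df = frame(rng.normal(8, 1, size=(3, 4)))
        pd.testing.assert_series_equal(
            delta_ct_stability(df), brute_force_pairwise_sd(df),
            check_names=False, atol=1e-12, rtol=0,
        )

    def test_shift_invariance(self, rng):
        df = frame(rng.normal(8, 1, size=(4, 5)))
        shifted = df + 3.7
        pd.testing.assert_series_equal(
            delta_ct_stability(df), delta_ct_stability(shifted), atol=1e-12, rtol=0
        )

    def test_needs_two_candidates(self):
        with pytest.raises(ValidationError):
            delta_ct_stability(frame([[1.0, 2.0]]))


class TestBestKeeper:
    def test_gene_identical_to_index_has_r_one(self):
        row = [5.0, 6.0, 7.0, 8.0]
        df = frame([row, row])  # index equals each gene
        stats = bestkeeper_stats(df)
        assert stats.loc["r0", "bk_r"] == pytest.approx(1.0)

    def test_anticorrelated_gene_has_r_minus_one(self):
        # index = [3, 2.5, 2] falls while r0 rises linearly -> r0 = -1, r1 = +1
        df = frame([[1.0, 2.0, 3.0], [5.0, 3.0, 1.0]])
        stats = bestkeeper_stats(df)
        assert stats.loc["r0", "bk_r"] == pytest.approx(-1.0)
        assert stats.loc["r1", "bk_r"] == pytest.approx(1.0)

    def test_toy_matches_hand_pearson(self, rng):
        df = frame(rng.normal(8, 1, size=(4, 5)))
        stats = bestkeeper_stats(df)
        index = df.mean(axis=0)
        for g in df.index:
            expected = np.corrcoef(df.loc[g], index)[0, 1]
            assert stats.loc[g, "bk_r"] == pytest.approx(expected, abs=1e-12)
            assert stats.loc[g, "bk_sd"] == pytest.approx(df.loc[g].std(ddof=1))

    def test_zero_variance_gene_r_flagged(self):
        df = frame([[1.0, 2.0, 3.0], [4.0, 4.0, 4.0]])
        stats = bestkeeper_stats(df)
        assert np.isnan(stats.loc["r1", "bk_r"])
        assert stats.loc["r1", "bk_sd"] == 0.0

    def test_needs_three_samples(self):
        with pytest.raises(ValidationError, match="3 samples"):
            bestkeeper_stats(frame([[1.0, 2.0], [3.0, 4.0]]))


class TestGeNorm:
    def test_m_equals_brute_force(self, rng):
        df = frame(rng.normal(8, 1, size=(4, 6)))
        result = genorm_ranking(df)
        pd.testing.assert_series_equal(
            result["genorm_m"], brute_force_pairwise_sd(df),
            check_names=False, atol=1e-12, rtol=0,
        )

    def test_m_identical_to_delta_ct_on_full_panel(self, rng):
        df = frame(rng.normal(8, 1, size=(6, 8)))
        np.testing.assert_allclose(
            genorm_ranking(df)["genorm_m"], delta_ct_stability(df), atol=1e-12
        )

    def test_covarying_pair_survives_to_final_pair(self, rng):
        base = rng.normal(8, 0.5, 6)
        df = frame(
            [base, base + 1.0, rng.normal(8, 2.0, 6), rng.normal(8, 2.0, 6)],
            genes=["a", "b", "noisy1", "noisy2"],
        )
        result = genorm_ranking(df)
        assert result.loc["a", "rank_genorm"] == 1.5
        assert result.loc["b", "rank_genorm"] == 1.5

    def test_permutation_invariance(self, rng):
        df = frame(rng.normal(8, 1, size=(5, 6)))
        shuffled = df.iloc[[3, 1, 4, 0, 2]]
        r1 = genorm_ranking(df)
        r2 = genorm_ranking(shuffled)
        pd.testing.assert_series_equal(
            r1["genorm_m"].sort_index(), r2["genorm_m"].sort_index(),
            atol=1e-12, rtol=0,
        )
        final1 = set(r1.index[r1["rank_genorm"] == 1.5])
        final2 = set(r2.index[r2["rank_genorm"] == 1.5])
        assert final1 == final2

    def test_needs_three_candidates(self):
        with pytest.raises(ValidationError):
            genorm_ranking(frame(np.ones((2, 4))))


class TestNormFinder:
    def test_zero_deviation_gene_scores_zero(self):
        # r2 equals the candidate mean shifted by a constant -> centered
        # profile is flat -> stability 0, best rank
        df = frame([[1.0, 2.0, 0.0, -1.0], [-1.0, -2.0, 0.0, 1.0],
                    [0.0, 0.0, 0.0, 0.0]])
        s = normfinder_stability(df)
        assert s["r2"] == pytest.approx(0.0, abs=1e-12)
        assert s["r2"] == s.min()

    def test_ungrouped_equals_sd_of_centered_values(self, rng):
        df = frame(rng.normal(8, 1, size=(3, 4)))
        z = df - df.mean(axis=0)
        np.testing.assert_allclose(
            normfinder_stability(df), z.std(axis=1, ddof=1), atol=1e-12
        )

    def test_grouped_matches_hand_formula(self, rng):
        df = frame(rng.normal(8, 1, size=(4, 6)))
        groups = {"a": ["s0", "s1", "s2"], "b": ["s3", "s4", "s5"]}
        s = normfinder_stability(df, groups=groups)
        z = df - df.mean(axis=0)
        for g in df.index:
            m = np.array([z.loc[g, ids].mean() for ids in groups.values()])
            v = np.array([z.loc[g, ids].var(ddof=1) for ids in groups.values()])
            n = np.array([len(ids) for ids in groups.values()])
            d = m - m.mean()
            expected = np.abs(d).mean() + np.sqrt(v / n).mean()
            assert s[g] == pytest.approx(expected, abs=1e-12)

    def test_inflating_noise_increases_score(self, rng):
        base = rng.normal(8, 0.2, size=(4, 8))
        df = frame(base)
        noisy = base.copy()
        noisy[0] = noisy[0] + rng.normal(0, 1.5, 8)
        df_noisy = frame(noisy)
        assert normfinder_stability(df_noisy)["r0"] > normfinder_stability(df)["r0"]

    def test_small_group_is_error(self):
        df = frame(np.arange(12.0).reshape(3, 4))
        with pytest.raises(ValidationError, match="need >= 2"):
            normfinder_stability(df, groups={"a": ["s0"], "b": ["s1", "s2", "s3"]})


class TestConsensus:
    def test_geometric_mean_values(self):
        ranks = pd.DataFrame(
            {"m1": [1.0, 1.0], "m2": [1.0, 2.0], "m3": [1.0, 4.0], "m4": [1.0, 8.0]},
            index=["best", "other"],
        )
        result = reffinder_consensus(ranks)
        assert result.loc["best", "consensus_score"] == pytest.approx(1.0)
        assert result.loc["other", "consensus_score"] == pytest.approx(64 ** 0.25)

    def test_symmetric_in_method_order(self, rng):
        ranks = pd.DataFrame(
            rng.permuted(np.tile(np.arange(1.0, 6.0), (4, 1)).T, axis=0),
            columns=["m1", "m2", "m3", "m4"],
        )
        base = reffinder_consensus(ranks)["consensus_score"]
        for perm in itertools.permutations(ranks.columns):
            alt = reffinder_consensus(ranks[list(perm)])["consensus_score"]
            np.testing.assert_allclose(alt, base, atol=1e-12)

    def test_mismatched_candidate_sets_rejected(self):
        ranks = pd.DataFrame(
            {"m1": [1.0, 2.0], "m2": [2.0, 1.0], "m3": [1.0, 2.0],
             "m4": [np.nan, 1.0]}
        )
        with pytest.raises(ValidationError, match="different candidate"):
            reffinder_consensus(ranks)

    def test_invariant_to_monotone_score_transforms(self, rng):
        """Only ranks enter the consensus, so any strictly monotone rescaling
        of a method's raw scores leaves the consensus ordering unchanged."""
        values = rng.normal(8, 0.5, size=(6, 10))
        m = make_matrix(values, gene_ids=[f"r{i}" for i in range(6)])
        base = rank_table(m, [f"r{i}" for i in range(6)])
        # recompute ranks from monotonically transformed scores
        from scipy.stats import rankdata

        transformed = {
            "rank_dct": rankdata(np.exp(base["delta_ct"])),
            "rank_bk": rankdata(base["bk_sd"] ** 3),
            "rank_gn": base["rank_gn"],
            "rank_nf": rankdata(10 + 5 * base["normfinder_s"]),
        }
        alt = reffinder_consensus(pd.DataFrame(transformed, index=base.index))
        np.testing.assert_allclose(
            alt["consensus_rank"], base["consensus_rank"], atol=1e-12
        )


class TestGlobalRanking:
    def test_geometric_mean_across_platforms(self):
        consensus = {
            "PFC": pd.Series({"g": 1.0, "h": 2.0}),
            "TX": pd.Series({"g": 2.0, "h": 2.0}),
            "GBF": pd.Series({"g": 4.0, "h": 2.0}),
        }
        table = global_ranking(consensus)
        assert table.loc["g", "global_score"] == pytest.approx(2.0)
        assert table.loc["h", "global_score"] == pytest.approx(2.0)

    def test_all_rank_one_everywhere(self):
        table = global_ranking({"a": pd.Series({"g": 1.0}), "b": pd.Series({"g": 1.0})})
        assert table.loc["g", "global_score"] == 1.0

    def test_tied_platform_is_neutral(self):
        base = {"PFC": pd.Series({"g": 1.0, "h": 3.0})}
        with_tie = dict(base)
        with_tie["extra"] = pd.Series({"g": 2.0, "h": 2.0})
        order1 = list(global_ranking(base).index)
        order2 = list(global_ranking(with_tie).index)
        assert order1 == order2

    def test_missing_gene_is_error(self):
        with pytest.raises(ValidationError, match="missing"):
            global_ranking(
                {"a": pd.Series({"g": 1.0, "h": 2.0}), "b": pd.Series({"g": 1.0})}
            )


class TestRankTable:
    def test_shift_invariance_of_all_scores_except_cv(self, rng):
        genes = [f"r{i}" for i in range(5)]
        values = rng.normal(8, 0.5, size=(5, 12))
        base = rank_table(make_matrix(values, gene_ids=genes), genes)
        shifted = rank_table(make_matrix(values + 2.5, gene_ids=genes), genes)
        for col in ("delta_ct", "bk_sd", "genorm_m", "normfinder_s"):
            np.testing.assert_allclose(shifted[col], base[col], atol=1e-10)
        assert not np.allclose(shifted["cv_percent"], base["cv_percent"])

    def test_noisiest_candidate_ranked_last_by_every_method(self, rng):
        genes = [f"r{i}" for i in range(6)]
        values = rng.normal(8, 0.1, size=(6, 12))
        values[0] += rng.normal(0, 1.0, 12)  # 10x the noise SD of the rest
        table = rank_table(make_matrix(values, gene_ids=genes), genes)
        n = len(genes)
        for col in ("rank_dct", "rank_bk", "rank_gn", "rank_nf"):
            assert table.loc["r0", col] == n, col
        assert table.loc["r0", "consensus_rank"] == n

    def test_panel_gene_missing_from_matrix_is_named(self, rng):
        m = make_matrix(rng.normal(8, 1, (3, 4)), gene_ids=["a", "b", "c"])
        with pytest.raises(ValidationError, match="ghost"):
            rank_table(m, ["a", "b", "ghost"])


class TestStableReferenceGenes:
    def _tables(self, flags):
        out = {}
        for platform, by_spec in flags.items():
            tables = {}
            for spec_name, stable_map in by_spec.items():
                spec = ComparisonSpec(platform, spec_name, "ref")
                tables[spec] = pd.DataFrame(
                    {"is_stable": pd.Series(stable_map)}
                )
            out[platform] = tables
        return out

    def test_grid_and_survivors(self):
        tables = self._tables(
            {
                "PFC": {"ug": {"GAPDH": True, "TUBA1A": True}},
                "TX": {"ug": {"GAPDH": True, "TUBA1A": False}},
            }
        )
        survivors, grid = stable_reference_genes(tables, ["GAPDH", "TUBA1A"])
        assert survivors == ["GAPDH"]
        assert grid.loc["TUBA1A", "TX:ug_vs_ref"] == "altered"
        assert grid.loc["GAPDH", "PFC:ug_vs_ref"] == "stable"

    def test_empty_panel_gives_empty_result(self):
        tables = self._tables({"PFC": {"ug": {"GAPDH": True}}})
        survivors, grid = stable_reference_genes(tables, [])
        assert survivors == []
        assert grid.empty

    def test_missing_panel_gene_is_error(self):
        tables = self._tables({"PFC": {"ug": {"GAPDH": True}}})
        with pytest.raises(ValidationError, match="ABCA5"):
            stable_reference_genes(tables, ["ABCA5"])
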