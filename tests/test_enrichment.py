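"""Filtering, signal-to-noise ranking and the enrichment score machinery."""

import itertools

import numpy as np
import pandas as pd
import pytest

from hypoflow import (
    CountSimConfig,
    ExpressionMatrix,
    GeneSet,
    enrichment_score,
    filter_expressed,
    gen_rnaseq_counts,
    gsea_permutation,
    log_fold_change,
    rank_signal_to_noise,
)
from hypoflow.enrichment import _es_from_positions
from .conftest import brute_force_es


def counts_matrix(rows: dict, groups=("h", "h", "h", "n", "n", "n")) -> ExpressionMatrix:
    cols = [f"s{i}" for i in range(len(groups))]
    return ExpressionMatrix(
        values=pd.DataFrame(rows, index=cols).T,
        groups=pd.Series(groups, index=cols),
        mode="counts",
    )


def ranked_from_scores(scores) -> "RankedList":
    """RankedList with given descending scores and genes g0, g1, ..."""
    from hypoflow.enrichment import RankedList

    scores = np.asarray(scores, float)
    table = pd.DataFrame(
        {
            "gene": [f"g{i}" for i in range(len(scores))],
            "score": scores,
            "mean1": 0.0, "mean2": 0.0, "sd1": 1.0, "sd2": 1.0,
        }
    )
    return RankedList(table=table, group1="a", group2="b", n1=3, n2=3)


class TestFilterExpressed:
    def test_keeps_only_genes_above_threshold_in_every_sample(self):
        m = counts_matrix(
            {"geneA": (12, 15, 10, 11, 30, 10), "geneB": (12, 15, 9, 11, 30, 10)}
        )
        out = filter_expressed(m, 10)
        assert list(out.values.index) == ["geneA"]

    def test_zero_threshold_is_identity(self):
        m = counts_matrix({"a": (0, 1, 2, 3, 4, 5), "b": (9, 9, 9, 9, 9, 9)})
        assert list(filter_expressed(m, 0).values.index) == ["a", "b"]

    def test_stricter_threshold_gives_subset(self):
        matrix, _ = gen_rnaseq_counts(CountSimConfig(n_genes=500), seed=0)
        g10 = set(filter_expressed(matrix, 10).values.index)
        g20 = set(filter_expressed(matrix, 20).values.index)
        assert g20 <= g10

    def test_result_independent_of_sample_column_order(self):
        matrix, _ = gen_rnaseq_counts(CountSimConfig(n_genes=300), seed=1)
        shuffled = ExpressionMatrix(
            values=matrix.values[list(matrix.values.columns[::-1])],
            groups=matrix.groups,
            mode="counts",
        )
        assert list(filter_expressed(matrix, 10).values.index) == list(
            filter_expressed(shuffled, 10).values.index
        )

    def test_log_mode_rejected(self):
        m = counts_matrix({"a": (1, 2, 3, 4, 5, 6)})
        m_log = ExpressionMatrix(m.values.astype(float), m.groups, mode="log")
        with pytest.raises(ValueError, match="counts"):
            filter_expressed(m_log, 10)


class TestSignalToNoise:
    def test_hand_example_without_floor(self):
        cols = ["a1", "a2", "a3", "b1", "b2", "b3"]
        m = ExpressionMatrix(
            values=pd.DataFrame([[3, 4, 5, 1, 2, 3]], index=["g"], columns=cols),
            groups=pd.Series(["g1"] * 3 + ["g2"] * 3, index=cols),
            mode="log",
        )
        ranked = rank_signal_to_noise(m, "g1", "g2")
        # means (4, 2), sds (1, 1): floors 0.8 and 0.4 are inactive
        assert ranked.table["score"].iloc[0] == pytest.approx(1.0)

    def test_identical_groups_score_zero(self):
        cols = [f"s{i}" for i in range(6)]
        vals = np.tile(np.array([[5.0, 7.0, 9.0]]), (4, 2))
        m = ExpressionMatrix(
            values=pd.DataFrame(vals, index=list("abcd"), columns=cols),
            groups=pd.Series(["x"] * 3 + ["y"] * 3, index=cols),
            mode="log",
        )
        ranked = rank_signal_to_noise(m, "x", "y")
        np.testing.assert_allclose(ranked.table["score"], 0.0)

    def test_group_swap_negates_scores_and_reverses_order(self):
        matrix, _ = gen_rnaseq_counts(
            CountSimConfig(n_genes=200, de_fraction=0.2), seed=3
        )
        fwd = rank_signal_to_noise(matrix, "hypoxia", "normoxia")
        rev = rank_signal_to_noise(matrix, "normoxia", "hypoxia")
        merged = fwd.table.merge(rev.table, on="gene", suffixes=("_f", "_r"))
        np.testing.assert_allclose(merged["score_f"], -merged["score_r"], atol=1e-12)
        if fwd.table["score"].nunique() == len(fwd.table):
            assert fwd.table["gene"].tolist() == rev.table["gene"].tolist()[::-1]

    def test_printed_denominator_audit_mode(self):
        cols = ["a1", "a2", "a3", "b1", "b2", "b3"]
        m = ExpressionMatrix(
            values=pd.DataFrame([[1.0, 3, 5, 0.5, 1.0, 1.5]], index=["g"], columns=cols),
            groups=pd.Series(["g1"] * 3 + ["g2"] * 3, index=cols),
            mode="log",
        )
        audit = rank_signal_to_noise(m, "g1", "g2", denominator="difference")
        # means (3, 1), sds (2, 0.5), floors inactive: (3-1)/(2-0.5) = 4/3
        assert audit.table["score"].iloc[0] == pytest.approx(4 / 3)

    def test_overlapping_groups_rejected(self):
        cols = ["s0", "s1", "s2", "s3"]
        m = ExpressionMatrix(
            values=pd.DataFrame([[1.0, 2, 3, 4]], index=["g"], columns=cols),
            groups=pd.Series(["x", "x", "x", "x"], index=cols),
            mode="log",
        )
        with pytest.raises(ValueError, match="overlap"):
            rank_signal_to_noise(m, "x", "x")


class TestLogFoldChange:
    def test_equal_means_give_zero(self):
        m = counts_matrix({"a": (7, 7, 7, 7, 7, 7)})
        assert log_fold_change(m, "h", "n")["a"] == pytest.approx(0.0)

    def test_counts_arithmetic_with_pseudocount(self):
        # equal library sizes so normalisation is the identity
        m = counts_matrix(
            {"a": (40, 40, 40, 10, 10, 10), "b": (10, 10, 10, 40, 40, 40)}
        )
        lfc = log_fold_change(m, "h", "n", pseudocount=1.0)
        assert lfc["a"] == pytest.approx(np.log2(41 / 11))
        assert lfc["b"] == pytest.approx(np.log2(11 / 41))

    def test_antisymmetric_under_group_swap(self):
        matrix, _ = gen_rnaseq_counts(CountSimConfig(n_genes=100), seed=4)
        fwd = log_fold_change(matrix, "hypoxia", "normoxia")
        rev = log_fold_change(matrix, "normoxia", "hypoxia")
        np.testing.assert_allclose(fwd, -rev, atol=1e-12)

    def test_nonpositive_pseudocount_rejected_in_counts_mode(self):
        m = counts_matrix({"a": (1, 2, 3, 4, 5, 6)})
        with pytest.raises(ValueError, match="pseudocount"):
            log_fold_change(m, "h", "n", pseudocount=0.0)


class TestEnrichmentScore:
    def test_top_ranked_singleton_scores_plus_one(self):
        ranked = ranked_from_scores([4, 3, 2, 1])
        res = enrichment_score(ranked, GeneSet("s", ("g0",)))
        assert res.es == pytest.approx(1.0)
        assert res.leading_edge == ["g0"]

    def test_bottom_ranked_singleton_scores_minus_one(self):
        ranked = ranked_from_scores([4, 3, 2, 1])
        res = enrichment_score(ranked, GeneSet("s", ("g3",)))
        assert res.es == pytest.approx(-1.0)
        np.testing.assert_allclose(
            res.running_sum, [-1 / 3, -2 / 3, -1.0, 0.0], atol=1e-12
        )
        assert res.leading_edge == ["g3"]

    def test_exhaustive_agreement_with_bruteforce_oracle(self):
        for n in range(2, 9):
            scores = np.linspace(2.0, -1.0, n)
            ranked = ranked_from_scores(scores)
            for r in range(1, n):
                for subset in itertools.combinations(range(n), r):
                    member = np.zeros(n, bool)
                    member[list(subset)] = True
                    gs = GeneSet("s", tuple(f"g{i}" for i in subset))
                    got = enrichment_score(ranked, gs).es
                    want = brute_force_es(scores, member)
                    assert got == pytest.approx(want, abs=1e-12), (n, subset)

    def test_bounded_for_random_sets(self):
        rng = np.random.default_rng(0)
        scores = np.sort(rng.standard_normal(200))[::-1]
        w = np.abs(scores)
        pos = np.argpartition(rng.random((1000, 200)), 20, axis=1)[:, :20]
        es = _es_from_positions(w, pos, 200)
        assert np.all(np.abs(es) <= 1.0 + 1e-12)

    def test_fast_position_path_matches_full_walk(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(10, 120))
            k = int(rng.integers(1, n - 1))
            scores = np.sort(rng.standard_normal(n))[::-1]
            ranked = ranked_from_scores(scores)
            subset = rng.choice(n, size=k, replace=False)
            gs = GeneSet("s", tuple(f"g{i}" for i in subset))
            full = enrichment_score(ranked, gs).es
            fast = _es_from_positions(np.abs(scores), subset[None, :], n)[0]
            assert fast == pytest.approx(full, abs=1e-12)

    def test_empty_intersection_and_full_list_rejected(self):
        ranked = ranked_from_scores([3, 2, 1])
        with pytest.raises(ValueError, match="no member"):
            enrichment_score(ranked, GeneSet("s", ("nope",)))
        with pytest.raises(ValueError, match="whole list"):
            enrichment_score(ranked, GeneSet("s", ("g0", "g1", "g2")))


class TestPermutation:
    @staticmethod
    def _planted():
        matrix, truth = gen_rnaseq_counts(
            CountSimConfig(n_genes=1000, de_fraction=0.05, logfc_magnitude=2.0),
            seed=0,
        )
        filt = filter_expressed(matrix, 10)
        ranked = rank_signal_to_noise(filt, "hypoxia", "normoxia")
        present = set(ranked.genes)
        up = [g for g in truth.index[truth["log2fc"] > 0] if g in present]
        return ranked, GeneSet("planted_up", tuple(up))

    def test_planted_set_attains_minimum_p(self):
        ranked, gs = self._planted()
        res = gsea_permutation(ranked, [gs], n_perm=200, seed=0)
        row = res.iloc[0]
        assert row["ES"] > 0.5
        assert row["p"] >= 1 / 201  # attainable floor of the add-one rule
        assert row["p"] < 0.05

    def test_same_seed_reproduces_p_nes_fdr(self):
        ranked, gs = self._planted()
        r1 = gsea_permutation(ranked, [gs], n_perm=100, seed=5)
        r2 = gsea_permutation(ranked, [gs], n_perm=100, seed=5)
        pd.testing.assert_frame_equal(r1, r2)

    def test_planted_upregulated_set_detected_in_most_runs(self):
        detected = 0
        for seed in range(50):
            matrix, truth = gen_rnaseq_counts(
                CountSimConfig(n_genes=2000, de_fraction=0.025, logfc_magnitude=2.0),
                seed=seed,
            )
            filt = filter_expressed(matrix, 10)
            ranked = rank_signal_to_noise(filt, "hypoxia", "normoxia")
            present = set(ranked.genes)
            up = [g for g in truth.index[truth["log2fc"] > 0] if g in present]
            gs = GeneSet("planted", tuple(up))
            res = gsea_permutation(ranked, [gs], n_perm=200, seed=seed).iloc[0]
            detected += (res["ES"] > 0) and (res["p"] <= 0.05)
        assert detected >= 45

    def test_phenotype_mode_with_small_groups_falls_back(self):
        ranked, gs = self._planted()
        matrix, _ = gen_rnaseq_counts(CountSimConfig(n_genes=1000), seed=0)
        with pytest.warns(UserWarning, match="falling back"):
            res = gsea_permutation(
                ranked, [gs], n_perm=50, mode="phenotype", seed=0, matrix=matrix
            )
        assert len(res) == 1

    def test_bh_fdr_is_monotone_adjustment_of_p(self):
        rng = np.random.default_rng(2)
        scores = np.sort(rng.standard_normal(300))[::-1]
        ranked = ranked_from_scores(scores)
        sets = [
            GeneSet(f"s{i}", tuple(f"g{j}" for j in rng.choice(300, 15, replace=False)))
            for i in range(10)
        ]
        res = gsea_permutation(ranked, sets, n_perm=100, seed=3)
        assert (res["FDR"] >= res["p"] - 1e-12).all()
        assert (res["FDR"] <= 1.0 + 1e-12).all()
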