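"""Permutation enrichment engines, overlap pruning, and q-values."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from sweepset import (
    ValidationError,
    add_qvalues,
    candidate_gsea,
    compute_qvalues,
    gene_scores_from_snps,
    prune_overlapping_genes,
    sumscore_gsea,
)


def gene_table(scores, n_snps=None):
    genes = [f"g{i}" for i in range(len(scores))]
    return pd.DataFrame(
        {
            "score": np.asarray(scores, dtype=float),
            "n_snps": n_snps if n_snps is not None else np.ones(len(scores), int),
        },
        index=pd.Index(genes, name="gene"),
    )


class TestGeneScores:
    def test_max_abs_snp_score(self):
        snp_scores = pd.Series({"s1": -3.0, "s2": 1.0, "s3": 2.0})
        out = gene_scores_from_snps(snp_scores, {"gA": ["s1", "s2"], "gB": ["s3"]})
        assert out.loc["gA", "score"] == 3.0
        assert out.loc["gA", "n_snps"] == 2
        assert out.loc["gB", "score"] == 2.0

    def test_unscored_genes_omitted(self):
        snp_scores = pd.Series({"s1": 1.0})
        out = gene_scores_from_snps(snp_scores, {"gA": ["s1"], "gB": []})
        assert list(out.index) == ["gA"]


class TestSumEngine:
    def test_exhaustive_matches_itertools_enumeration(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=10)
        table = gene_table(scores)
        top3 = set(table["score"].nlargest(3).index)
        res = sumscore_gsea(table, {"T": top3}, null="exhaustive")
        # independent oracle: direct enumeration over all C(10,3) subsets
        s_obs = sum(sorted(scores)[-3:])
        hits = sum(
            1
            for comb in combinations(scores, 3)
            if sum(comb) >= s_obs - 1e-12
        )
        assert res["p"].iloc[0] == pytest.approx(hits / 120)
        assert res["p"].iloc[0] == pytest.approx(1 / 120)

    def test_permutation_converges_to_exhaustive(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=10)
        table = gene_table(scores)
        test_set = set(table.index[:3])
        exact = sumscore_gsea(table, {"T": test_set}, null="exhaustive")
        B = 20_000
        perm = sumscore_gsea(
            table, {"T": test_set}, n_permutations=B, seed=2
        )
        p0 = exact["p"].iloc[0]
        se = np.sqrt(p0 * (1 - p0) / B)
        assert abs(perm["p"].iloc[0] - p0) < 4 * se + 2 / B

    def test_all_equal_scores_give_p_one(self):
        table = gene_table(np.full(12, 2.5))
        res = sumscore_gsea(
            table, {"T": {"g0", "g1", "g2"}}, n_permutations=500, seed=0
        )
        assert res["p"].iloc[0] == 1.0

    def test_binning_preserves_snp_count_composition(self):
        # genes with huge SNP counts get large scores; a null ignoring bins
        # would call the set significant, the matched null must not
        rng = np.random.default_rng(3)
        n_snps = np.concatenate([np.full(30, 1), np.full(30, 100)])
        scores = np.concatenate(
            [rng.normal(0, 1, 30), rng.normal(0, 1, 30) + 3]
        )
        table = gene_table(scores, n_snps=n_snps)
        long_genes = set(table.index[30:42])
        res = sumscore_gsea(
            table, {"L": long_genes}, n_bins=2, n_permutations=2000, seed=4
        )
        assert res["p"].iloc[0] > 0.05

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(5)
        table = gene_table(rng.normal(size=40))
        sets = {"A": set(table.index[:12]), "B": set(table.index[5:20])}
        a = sumscore_gsea(table, sets, n_permutations=500, seed=7)
        b = sumscore_gsea(table, sets, n_permutations=500, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_missing_gene_scores_rejected(self):
        table = gene_table([1.0, 2.0])
        with pytest.raises(ValidationError):
            sumscore_gsea(table, {"T": {"g0", "nope"}}, n_permutations=100)


class TestPruning:
    def test_identical_sets_worse_one_dropped(self):
        rng = np.random.default_rng(6)
        table = gene_table(rng.normal(size=40))
        members = set(table.index[:12])
        sets = {"A": members, "B": set(members)}
        res = sumscore_gsea(table, sets, n_permutations=300, seed=1)
        pruned = prune_overlapping_genes(
            res, sets, table, n_permutations=300, seed=1
        )
        statuses = dict(zip(pruned["set"], pruned["status"]))
        assert sorted(statuses.values()) == ["dropped_overlap", "kept"]

    def test_disjoint_sets_untouched(self):
        rng = np.random.default_rng(7)
        table = gene_table(rng.normal(size=40))
        sets = {"A": set(table.index[:12]), "B": set(table.index[12:24])}
        res = sumscore_gsea(table, sets, n_permutations=300, seed=2)
        pruned = prune_overlapping_genes(
            res, sets, table, n_permutations=300, seed=2
        )
        assert (pruned["status"] == "kept").all()
        merged = res.merge(pruned, on="set")
        np.testing.assert_allclose(merged["p_x"], merged["p_y"])

    def test_superset_loses_signal_genes_and_p_increases(self):
        # B holds all the signal; A = B plus noise genes ranks worse, and
        # after losing B's genes its re-tested p must increase
        scores = np.zeros(60)
        scores[:10] = 8.0
        table = gene_table(scores)
        b_set = set(table.index[:10])
        a_set = set(table.index[:24])
        sets = {"Asuper": a_set, "Bcore": b_set}
        res = sumscore_gsea(table, sets, n_permutations=2000, seed=3)
        by_set = res.set_index("set")
        # both may hit the permutation floor; ranking then prefers the
        # smaller (more concentrated) set
        assert by_set.loc["Bcore", "p"] <= by_set.loc["Asuper", "p"]
        pruned = prune_overlapping_genes(
            res, sets, table, n_permutations=2000, seed=3
        ).set_index("set")
        assert pruned.loc["Asuper", "status"] == "pruned_retested"
        assert pruned.loc["Asuper", "p"] > by_set.loc["Asuper", "p"]
        assert pruned.loc["Asuper", "n_genes"] == 14


class TestCandidateEngine:
    def test_converges_to_hypergeometric_one_snp_per_gene(self):
        # 100 genes x 1 SNP, 10 candidates, set of 20 genes: the permutation
        # p must approach the closed-form hypergeometric tail
        rng = np.random.default_rng(8)
        snps = [f"s{i}" for i in range(100)]
        scores = pd.Series(rng.normal(size=100), index=snps)
        snp_to_genes = {s: [f"g{i}"] for i, s in enumerate(snps)}
        collection = {"T": {f"g{i}" for i in range(20)}}
        B = 20_000
        res = candidate_gsea(
            scores, snp_to_genes, collection, percentile=10.0,
            n_permutations=B, seed=9,
        )
        count_obs = res["stat"].iloc[0]
        p_exact = float(hypergeom.sf(count_obs - 1, 100, 20, 10))
        se = np.sqrt(p_exact * (1 - p_exact) / B)
        assert abs(res["p"].iloc[0] - p_exact) < 4 * se + 2 / B

    def test_saturation_gives_p_one(self):
        snps = [f"s{i}" for i in range(50)]
        scores = pd.Series(np.ones(50), index=snps)  # all tied at the cutoff
        snp_to_genes = {s: [f"g{i % 10}"] for i, s in enumerate(snps)}
        res = candidate_gsea(
            scores, snp_to_genes, {"T": {f"g{i}" for i in range(5)}},
            percentile=5.0, n_permutations=200, seed=0,
        )
        assert res["p"].iloc[0] == 1.0

    def test_snp_mode_counts_snps(self):
        snps = [f"s{i}" for i in range(40)]
        vals = np.zeros(40)
        vals[:4] = 5.0  # four clear candidates
        scores = pd.Series(vals, index=snps)
        snp_to_genes = {s: ["hot" if i < 4 else f"g{i}"] for i, s in enumerate(snps)}
        res = candidate_gsea(
            scores, snp_to_genes, {"T": {"hot"}}, percentile=10.0,
            n_permutations=300, seed=1, mode="snp",
        )
        assert res["stat"].iloc[0] == 4

    def test_invalid_percentile_rejected(self):
        scores = pd.Series([1.0], index=["s0"])
        with pytest.raises(ValidationError):
            candidate_gsea(scores, {"s0": ["g"]}, {"T": {"g"}}, percentile=60)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(10)
        snps = [f"s{i}" for i in range(60)]
        scores = pd.Series(rng.normal(size=60), index=snps)
        snp_to_genes = {s: [f"g{i % 15}"] for i, s in enumerate(snps)}
        collection = {"A": {f"g{i}" for i in range(5)}}
        a = candidate_gsea(scores, snp_to_genes, collection, percentile=10,
                           n_permutations=500, seed=3)
        b = candidate_gsea(scores, snp_to_genes, collection, percentile=10,
                           n_permutations=500, seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestQValues:
    def test_hand_bh_example(self):
        q = compute_qvalues(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        assert compute_qvalues(np.array([0.5]))[0] == 0.5

    def test_all_ones(self):
        np.testing.assert_allclose(compute_qvalues(np.ones(5)), 1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            compute_qvalues(np.array([]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            compute_qvalues(np.array([0.0, 0.5]))

    def test_qvalues_monotone_in_sorted_p(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(1e-6, 1, 50)
        q = compute_qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q >= p - 1e-12)

    def test_add_qvalues_flags_at_009(self):
        res = pd.DataFrame(
            {"set": ["a", "b", "c"], "p": [0.001, 0.5, np.nan]}
        )
        out = add_qvalues(res)
        assert bool(out.loc[0, "significant"])
        assert not bool(out.loc[1, "significant"])
        assert not bool(out.loc[2, "significant"])
        assert np.isnan(out.loc[2, "q"])
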