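"""Bipartite graph construction, bicluster search and permutation test."""

import itertools

import numpy as np
import pytest
from scipy import stats

from mirmod.bicluster import (BipartiteGraph, PermutationConfig,
                              SambaBiclustering, _score_submatrix,
                              build_bipartite_graph, find_biclusters,
                              module_avg_pcc, permutation_pvalue)
from mirmod.preprocess import zscore_rows
from mirmod.types import GeneSampleModule
from tests.conftest import expr


class TestBuildGraph:
    def test_edges_thresholded_with_weight_and_sign(self):
        z = expr([[2.0, 0.1, -1.6], [0.2, 0.3, 1.4], [0.0, 1.5, -0.2]])
        g = build_bipartite_graph(z, z_threshold=1.5)
        assert g.n_edges == 3
        assert g.mask[0, 0] and g.mask[0, 2] and g.mask[2, 1]
        assert g.weights[0, 2] == pytest.approx(1.6)
        assert g.signs[0, 2] == -1 and g.signs[0, 0] == 1

    def test_infinite_threshold_empty(self):
        z = expr([[3.0, -3.0]])
        assert build_bipartite_graph(z, np.inf).n_edges == 0

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            build_bipartite_graph(expr([[1.0]]), 0.0)


class TestModuleAvgPCC:
    def test_identical_rows_give_one(self):
        z = expr([[1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0]])
        m = GeneSampleModule("M", {"g0", "g1"}, {"s0", "s1", "s2", "s3"})
        assert module_avg_pcc(m, z) == pytest.approx(1.0)

    def test_anticorrelated_rows_give_minus_one(self):
        z = expr([[1.0, 2.0, 3.0], [-1.0, -2.0, -3.0]])
        m = GeneSampleModule("M", {"g0", "g1"}, {"s0", "s1", "s2"})
        assert module_avg_pcc(m, z) == pytest.approx(-1.0)

    def test_hand_computed_three_genes(self):
        rows = np.array([[1.0, 2.0, 3.0, 4.0],
                         [2.0, 1.0, 4.0, 3.0],
                         [4.0, 3.0, 2.0, 1.0]])
        z = expr(rows)
        m = GeneSampleModule("M", {"g0", "g1", "g2"},
                             {"s0", "s1", "s2", "s3"})
        expected = np.mean([stats.pearsonr(rows[i], rows[j]).statistic
                            for i, j in [(0, 1), (0, 2), (1, 2)]])
        assert module_avg_pcc(m, z) == pytest.approx(expected)

    def test_bounded(self, rng):
        z = expr(rng.normal(size=(5, 8)))
        m = GeneSampleModule("M", {f"g{i}" for i in range(5)},
                             {f"s{j}" for j in range(8)})
        assert -1.0 <= module_avg_pcc(m, z) <= 1.0

    def test_zero_variance_gene_excluded(self, caplog):
        z = expr([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        m = GeneSampleModule("M", {"g0", "g1", "g2"}, {"s0", "s1", "s2"})
        with caplog.at_level("INFO"):
            avg = module_avg_pcc(m, z)
        assert avg == pytest.approx(-1.0)  # only the g1-g2 pair remains
        assert "zero-variance" in caplog.text


def exhaustive_best_score(graph, min_genes, min_samples, lam=1.0):
    n_g, n_s = graph.mask.shape
    best = -np.inf
    for k in range(min_genes, n_g + 1):
        for gs in itertools.combinations(range(n_g), k):
            for ks in range(min_samples, n_s + 1):
                for ss in itertools.combinations(range(n_s), ks):
                    sc = _score_submatrix(graph, np.array(gs),
                                          np.array(ss), lam)
                    best = max(best, sc)
    return best


class TestFindBiclusters:
    def test_empty_graph_returns_empty(self):
        z = expr([[0.1, -0.2], [0.3, 0.0]])
        g = build_bipartite_graph(z, 1.5)
        assert find_biclusters(g) == []

    def test_invalid_overlap_factor(self):
        z = expr([[2.0, 2.0], [2.0, 2.0]])
        g = build_bipartite_graph(z, 1.5)
        with pytest.raises(ValueError):
            find_biclusters(g, overlap_factor=1.5)

    def test_planted_block_recovered(self, rng):
        noise = rng.normal(0, 1, (40, 30))
        noise[:8, :6] = rng.normal(4.0, 0.3, (8, 6))
        z = zscore_rows(expr(noise))
        g = build_bipartite_graph(z, 1.5)
        mods = find_biclusters(g, min_genes=4, min_samples=4, seed=0)
        assert mods
        planted = {f"g{i}" for i in range(8)}
        top = mods[0]
        assert len(top.genes & planted) >= 7

    def test_two_disjoint_blocks_with_overlap_control(self, rng):
        noise = rng.normal(0, 1, (40, 40))
        noise[:8, :8] = rng.normal(4.0, 0.3, (8, 8))
        noise[10:18, 20:28] = rng.normal(-4.0, 0.3, (8, 8))
        z = zscore_rows(expr(noise))
        g = build_bipartite_graph(z, 1.5)
        mods = find_biclusters(g, min_genes=4, min_samples=4,
                               overlap_factor=0.5, seed=0)
        assert len(mods) >= 2
        b1 = {f"g{i}" for i in range(8)}
        b2 = {f"g{i}" for i in range(10, 18)}
        hits1 = max(len(m.genes & b1) for m in mods[:2])
        hits2 = max(len(m.genes & b2) for m in mods[:2])
        assert hits1 >= 7 and hits2 >= 7
        inter = mods[0].genes & mods[1].genes
        union = mods[0].genes | mods[1].genes
        assert len(inter) / len(union) <= 0.5

    def test_top_score_matches_exhaustive_enumeration(self, rng):
        # the search is exact on small matrices: verify against the
        # brute-force optimum over all gene/sample subsets
        for trial in range(6):
            vals = rng.normal(0, 1.2, (6, 5))
            if trial % 2 == 0:
                vals[:3, :3] += 2.5
            z = expr(vals)
            g = build_bipartite_graph(z, 1.0)
            if g.n_edges == 0:
                continue
            mods = find_biclusters(g, min_genes=2, min_samples=2, seed=0)
            expected = exhaustive_best_score(g, 2, 2)
            if not mods:
                assert expected <= 0
            else:
                assert mods[0].score == pytest.approx(expected)

    def test_greedy_matches_exact_on_planted_small_matrix(self, rng):
        vals = rng.normal(0, 1.0, (7, 6))
        vals[:4, :4] += 3.0
        z = expr(vals)
        g = build_bipartite_graph(z, 1.0)
        exact = find_biclusters(g, min_genes=2, min_samples=2,
                                method="exact")
        greedy = find_biclusters(g, min_genes=2, min_samples=2,
                                 method="greedy")
        assert greedy and exact
        assert greedy[0].score == pytest.approx(exact[0].score)


class TestPermutationPvalue:
    def test_perfect_module_p_zero(self, rng):
        vals = rng.normal(0, 1, (30, 20))
        base = rng.normal(0, 1, 20)
        for i in range(4):
            vals[i] = base * (i + 1) + 0.5  # positive affine copies
        z = expr(vals)
        m = GeneSampleModule("M", {f"g{i}" for i in range(4)},
                             {f"s{j}" for j in range(10)})
        m.module_avg = module_avg_pcc(m, z)
        cfg = PermutationConfig(N=50, seed=1, overlap_matched=False)
        assert permutation_pvalue(m, z, cfg) == 0.0

    def test_null_module_pvalues_roughly_uniform(self, rng):
        z = expr(rng.normal(0, 1, (60, 30)))
        cfg = PermutationConfig(N=200, seed=5, overlap_matched=False)
        ps = []
        for rep in range(50):
            genes = set(rng.choice(z.feature_ids, 6, replace=False))
            samples = set(rng.choice(z.sample_ids, 8, replace=False))
            m = GeneSampleModule(f"M{rep}", genes, samples)
            m.module_avg = module_avg_pcc(m, z)
            ps.append(permutation_pvalue(m, z, cfg))
        assert 0.4 <= np.mean(ps) <= 0.6

    def test_n_one_and_strict_inequality(self):
        z = expr([[1.0, 2.0, 3.0], [1.1, 2.1, 3.1],
                  [3.0, 1.0, 2.0], [2.0, 3.0, 1.0]])
        m = GeneSampleModule("M", {"g2", "g3"}, {"s0", "s1", "s2"})
        m.module_avg = module_avg_pcc(m, z)  # negative correlation
        cfg = PermutationConfig(N=1, seed=0, overlap_matched=False)
        p = permutation_pvalue(m, z, cfg)
        assert p in (0.0, 1.0)

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            PermutationConfig(N=0)

    def test_monotone_in_module_avg(self, rng):
        # lowering the observed average can only raise the p-value
        z = expr(rng.normal(0, 1, (40, 20)))
        genes = set(rng.choice(z.feature_ids, 5, replace=False))
        samples = set(rng.choice(z.sample_ids, 8, replace=False))
        cfg = PermutationConfig(N=100, seed=7, overlap_matched=False)
        ps = []
        for fake_avg in (0.9, 0.5, 0.1, -0.5):
            m = GeneSampleModule("M", set(genes), set(samples))
            m.module_avg = fake_avg
            ps.append(permutation_pvalue(m, z, cfg))
        assert all(a <= b for a, b in zip(ps, ps[1:]))

    def test_overlap_matched_cohort_respects_sizes(self, rng):
        z = expr(rng.normal(0, 1, (50, 20)))
        m1 = GeneSampleModule("A", {f"g{i}" for i in range(8)},
                              {f"s{j}" for j in range(6)})
        m2 = GeneSampleModule("B", {f"g{i}" for i in range(4, 12)},
                              {f"s{j}" for j in range(6)})
        for m in (m1, m2):
            m.module_avg = module_avg_pcc(m, z)
        cfg = PermutationConfig(N=20, seed=3, overlap_matched=True)
        p = permutation_pvalue(m1, z, cfg, cohort=[m1, m2])
        assert 0.0 <= p <= 1.0


class TestEstimator:
    def test_sklearn_params_round_trip(self):
        est = SambaBiclustering(z_threshold=2.0)
        params = est.get_params()
        assert params["z_threshold"] == 2.0
        est.set_params(max_modules=7)
        assert est.max_modules == 7

    def test_fit_filters_by_q(self, rng):
        vals = rng.normal(0, 1, (40, 30))
        shared = rng.normal(0, 1.0, 6)  # per-sample signal -> correlated
        vals[:8, :6] = 4.0 + shared[None, :] + rng.normal(0, 0.3, (8, 6))
        z = zscore_rows(expr(vals))
        est = SambaBiclustering(min_genes=4, min_samples=4,
                                n_permutations=100, random_state=0)
        est.fit(z)
        assert est.modules_
        assert all(m.q_value < 0.05 for m in est.modules_)
        assert all(np.isfinite(m.p_value) for m in est.all_modules_)
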