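"""Enrichment statistics, evidence cases and overlap/ratio summaries."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirmod.bicluster import bh_qvalues
from mirmod.types import (GeneMiRNAModule, GeneSampleModule,
                          GeneSetCollection, RegulationEvidence, TargetTable,
                          TFRelationTable)
from mirmod.validate import (cancer_annotation_ratios,
                             direct_regulation_evidence,
                             explained_module_summary, hypergeom_enrich,
                             mirna_via_tf_evidence, overlap_ratio,
                             pathway_enrichment, tf_coregulation_evidence)
from tests.conftest import expr


def brute_force_hypergeom_p(N, m, k, x):
    """P(X >= x) by direct enumeration over all C(N, k) draws."""
    total = math.comb(N, k)
    favorable = sum(math.comb(m, i) * math.comb(N - m, k - i)
                    for i in range(x, min(m, k) + 1))
    return favorable / total


class TestHypergeom:
    def test_matches_enumeration_small_universes(self):
        for N in range(2, 12):
            universe = {f"g{i}" for i in range(N)}
            ordered = sorted(universe)
            for m, k in itertools.product(range(0, N + 1), repeat=2):
                subject = set(ordered[:m])
                module = set(ordered[N - k:])
                res = hypergeom_enrich(module, subject, universe)
                expected = brute_force_hypergeom_p(N, m, k, res.x)
                assert res.p == pytest.approx(expected, rel=1e-10)

    def test_known_draw(self):
        # N=10, m=5, k=4, all 4 drawn from the subject set: 5/210
        universe = {f"g{i}" for i in range(10)}
        subject = {"g0", "g1", "g2", "g3", "g4"}
        module = {"g0", "g1", "g2", "g3"}
        res = hypergeom_enrich(module, subject, universe)
        assert res.p == pytest.approx(5 / 210, rel=1e-12)

    def test_zero_overlap_gives_one(self):
        universe = {f"g{i}" for i in range(20)}
        res = hypergeom_enrich({"g0", "g1"}, {"g10", "g11"}, universe)
        assert res.p == pytest.approx(1.0)

    def test_monotone_in_overlap(self):
        # p non-increasing in x for fixed N, m, k
        N, m, k = 40, 12, 8
        ps = [brute_force_hypergeom_p(N, m, k, x) for x in range(0, 9)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            hypergeom_enrich({"a"}, {"a"}, set())

    def test_genes_outside_universe_dropped(self, caplog):
        universe = {"g0", "g1", "g2", "g3"}
        with caplog.at_level("INFO"):
            res = hypergeom_enrich({"g0", "gX"}, {"g0"}, universe)
        assert res.k == 1 and res.x == 1
        assert "outside universe" in caplog.text


class TestBH:
    def brute(self, p):
        p = np.asarray(p, float)
        n = len(p)
        order = np.argsort(p, kind="stable")
        q = np.empty(n)
        prev = 1.0
        for rank_from_end, idx in enumerate(order[::-1]):
            rank = n - rank_from_end
            val = min(prev, p[idx] * n / rank)
            q[idx] = val
            prev = val
        return q

    def test_hand_example(self):
        np.testing.assert_allclose(bh_qvalues([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_single_and_degenerate(self):
        np.testing.assert_allclose(bh_qvalues([0.2]), [0.2])
        np.testing.assert_allclose(bh_qvalues([1.0, 1.0, 1.0]), [1, 1, 1])

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(bh_qvalues(p), self.brute(p),
                                       atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_qvalues([0.5, 1.5])


class TestOverlapRatio:
    def test_basics(self):
        assert overlap_ratio({"a"}, {"a"}) == 1.0
        assert overlap_ratio({"a"}, {"b"}) == 0.0
        assert overlap_ratio({"a", "b", "c"}, {"b", "c", "d"}) == 0.5
        assert overlap_ratio(set(), set()) == 0.0

    @settings(deadline=None, max_examples=50)
    @given(a=st.sets(st.integers(0, 20)), b=st.sets(st.integers(0, 20)))
    def test_symmetric_and_bounded(self, a, b):
        r = overlap_ratio(a, b)
        assert r == overlap_ratio(b, a)
        assert 0.0 <= r <= 1.0


def _make_gm_module(genes, samples, mirnas):
    base = GeneSampleModule("M1", set(genes), set(samples))
    return GeneMiRNAModule(base=base, mirnas=list(mirnas),
                           bic_trajectory=list(range(len(mirnas))))


class TestDirectEvidence:
    def _setup(self, rng):
        samples = [f"s{i}" for i in range(30)]
        u = rng.normal(0, 1, 30)
        gene_rows = [u + rng.normal(0, 0.2, 30) for _ in range(6)]
        gene_rows += [rng.normal(0, 1, 30) for _ in range(44)]
        genes = [f"g{i}" for i in range(50)]
        gene_expr = expr(np.array(gene_rows), genes=genes, samples=samples)
        mirna_expr = expr(np.array([-u + rng.normal(0, 0.2, 30),
                                    rng.normal(0, 1, 30)]),
                          genes=["mirA", "mirB"], samples=samples,
                          kind="miRNA")
        module = _make_gm_module(genes[:6], samples, ["mirA", "mirB"])
        return gene_expr, mirna_expr, module, set(genes)

    def test_planted_targets_enriched(self, rng):
        gene_expr, mirna_expr, module, universe = self._setup(rng)
        targets = TargetTable(pd.DataFrame(
            {"mirna": ["mirA"] * 5, "gene": [f"g{i}" for i in range(5)],
             "evidence": ["predicted"] * 5}))
        evs = direct_regulation_evidence(module, targets, gene_expr,
                                        mirna_expr, universe)
        pred = [e for e in evs if e.case == "direct_predicted"]
        assert len(pred) == 1
        assert pred[0].statistics["p"] < 0.05

    def test_positive_pcc_pairs_excluded_from_predicted_set(self, rng):
        gene_expr, mirna_expr, module, universe = self._setup(rng)
        # g40 is noise: its correlation sign is arbitrary; force positive by
        # using the miRNA itself as a target row
        targets = TargetTable(pd.DataFrame(
            {"mirna": ["mirA"], "gene": ["g40"], "evidence": ["predicted"]}))
        g40 = mirna_expr.values.loc["mirA"].to_numpy()
        gene_expr.values.loc["g40"] = g40  # perfectly positively correlated
        evs = direct_regulation_evidence(module, targets, gene_expr,
                                        mirna_expr, universe)
        assert not [e for e in evs if e.case == "direct_predicted"]

    def test_experimental_pairs_reported(self, rng):
        gene_expr, mirna_expr, module, universe = self._setup(rng)
        targets = TargetTable(pd.DataFrame(
            {"mirna": ["mirA", "mirA"], "gene": ["g0", "g45"],
             "evidence": ["direct", "direct"]}))
        evs = direct_regulation_evidence(module, targets, gene_expr,
                                        mirna_expr, universe)
        exp = [e for e in evs if e.case == "direct_experimental"]
        # only the in-module pair (g0) is evidence; g45 is outside
        assert len(exp) == 1
        assert exp[0].participants["gene"] == "g0"

    def test_mirna_without_entries_gives_nothing(self, rng):
        gene_expr, mirna_expr, module, universe = self._setup(rng)
        targets = TargetTable(pd.DataFrame(
            {"mirna": [], "gene": [], "evidence": []}, dtype=str))
        assert direct_regulation_evidence(module, targets, gene_expr,
                                          mirna_expr, universe) == []


class TestTFEvidence:
    def _setup(self, rng, tf_drives_mirna_sign):
        samples = [f"s{i}" for i in range(30)]
        t = rng.normal(0, 1, 30)
        gene_rows = [t + rng.normal(0, 0.2, 30) for _ in range(6)]
        gene_rows += [rng.normal(0, 1, 30) for _ in range(44)]
        genes = [f"g{i}" for i in range(50)]
        gene_expr = expr(np.array(gene_rows), genes=genes, samples=samples)
        mirna_expr = expr(
            np.array([tf_drives_mirna_sign * t + rng.normal(0, 0.2, 30)]),
            genes=["mirA"], samples=samples, kind="miRNA")
        tf_expr = expr(np.array([t]), genes=["TF1"], samples=samples)
        module = _make_gm_module(genes[:6], samples, ["mirA", "mirA2"])
        module.mirnas = ["mirA"]  # bypass >=2 rule for the fixture
        return gene_expr, mirna_expr, tf_expr, module, set(genes)

    def _table(self, direction):
        return TFRelationTable(
            pd.DataFrame({"tf": ["TF1"] * 6,
                          "gene": [f"g{i}" for i in range(6)]}),
            pd.DataFrame({"tf": ["TF1"], "mirna": ["mirA"],
                          "direction": [direction], "provenance": [""]}))

    def test_coregulation_same_sign_detected(self, rng):
        ge, me, te, module, universe = self._setup(rng, +1)
        evs = tf_coregulation_evidence(module, self._table(
            "TF_regulates_miRNA"), ge, me, te, universe)
        assert len(evs) == 1
        assert evs[0].statistics["tf_mirna_pcc"] > 0
        assert evs[0].statistics["p"] < 0.05

    def test_coregulation_sign_mismatch_excluded(self, rng):
        ge, me, te, module, universe = self._setup(rng, -1)
        evs = tf_coregulation_evidence(module, self._table(
            "TF_regulates_miRNA"), ge, me, te, universe)
        assert evs == []

    def test_mirna_via_tf_requires_negative_pcc(self, rng):
        ge, me, te, module, universe = self._setup(rng, -1)
        evs = mirna_via_tf_evidence(module, self._table(
            "miRNA_regulates_TF"), ge, me, te, universe)
        assert len(evs) == 1
        assert evs[0].statistics["mirna_tf_pcc"] < 0

        ge, me, te, module, universe = self._setup(rng, +1)
        evs = mirna_via_tf_evidence(module, self._table(
            "miRNA_regulates_TF"), ge, me, te, universe)
        assert evs == []

    def test_tf_without_expression_skipped(self, rng, caplog):
        ge, me, te, module, universe = self._setup(rng, +1)
        table = TFRelationTable(
            pd.DataFrame({"tf": ["TFmissing"] * 3,
                          "gene": ["g0", "g1", "g2"]}),
            pd.DataFrame({"tf": ["TFmissing"], "mirna": ["mirA"],
                          "direction": ["TF_regulates_miRNA"],
                          "provenance": [""]}))
        with caplog.at_level("INFO"):
            evs = tf_coregulation_evidence(module, table, ge, me, te,
                                           universe)
        assert evs == []
        assert "lacks expression" in caplog.text


class TestPathwayEnrichment:
    def test_oversized_sets_excluded_and_module_pathway_detected(self, rng):
        universe = {f"g{i}" for i in range(1000)}
        module = GeneSampleModule("M1", {f"g{i}" for i in range(20)},
                                  {"s1", "s2"})
        pathways = GeneSetCollection({
            "hit": {f"g{i}" for i in range(20)},
            "toobig": {f"g{i}" for i in range(301)},
        })
        results, summary = pathway_enrichment([module], pathways, universe)
        names = {r.subject.split(":", 1)[1] for r in results}
        assert names == {"hit"}
        assert results[0].q < 1e-10
        assert summary["fraction_enriched_modules"] == 1.0

    def test_null_false_positive_control(self, rng):
        universe = [f"g{i}" for i in range(300)]
        n_sig = 0
        n_total = 0
        for rep in range(100):
            module = GeneSampleModule(
                f"M{rep}", set(rng.choice(universe, 20, replace=False)),
                {"s1", "s2"})
            pathways = GeneSetCollection({
                f"p{j}": set(rng.choice(universe, 25, replace=False))
                for j in range(10)})
            results, _ = pathway_enrichment([module], pathways,
                                            set(universe))
            n_sig += len(results)
            n_total += 10
        # BH at q<0.05 on null data: false positive rate well below 0.05+3SE
        se = math.sqrt(0.05 * 0.95 / n_total)
        assert n_sig / n_total <= 0.05 + 3 * se


class TestSummaries:
    def test_cancer_ratios(self):
        gm = _make_gm_module([f"g{i}" for i in range(10)], ["s1", "s2"],
                             ["m1", "m2", "m3", "m4"])
        gene_lists = GeneSetCollection({"onco": {"g0", "g1", "gX"}})
        mirna_lists = GeneSetCollection({"cmir": {"m1", "mZ"}})
        ratios = cancer_annotation_ratios(gm, gene_lists, mirna_lists)
        assert ratios["gene:onco"] == pytest.approx(2 / 10)
        assert ratios["mirna:cmir"] == pytest.approx(1 / 4)
        disjoint = GeneSetCollection({"none": {"zz"}})
        assert cancer_annotation_ratios(gm, disjoint, None)["gene:none"] == 0

    def test_explained_summary(self):
        ev = RegulationEvidence("A", "direct_predicted", {})
        df = explained_module_summary({"A": [ev], "B": []})
        assert bool(df.loc["A", "explained"])
        assert not df.loc["B", "explained"]
        assert df.attrs["fraction_explained"] == pytest.approx(0.5)
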