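"""Correlation, soft thresholding, TOM, module detection, eigengenes,
module-trait selection, hubs."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from phytonet import coexpression as cx
from phytonet.reference import ip_module_records
from phytonet.synthetic import ModuleSpec, SyntheticDesign, gen_expression_with_modules


def tom_oracle(a: np.ndarray) -> np.ndarray:
    """Triple-loop reference implementation of unsigned topological overlap."""
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    n = a.shape[0]
    k = a.sum(axis=1)
    t = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n))
            t[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return t


def _frame(x):
    return pd.DataFrame(x, index=[f"g{i}" for i in range(x.shape[0])],
                        columns=[f"g{i}" for i in range(x.shape[0])])


class TestCorrelation:
    def test_monotone_invariance_of_spearman(self):
        x = np.linspace(-2, 2, 10)
        vals = pd.DataFrame([x, np.exp(x), -x], index=["x", "expx", "negx"])
        corr = cx.correlation_matrix(vals, method="spearman")
        assert corr.loc["x", "expx"] == pytest.approx(1.0)
        assert corr.loc["x", "negx"] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(5)
        vals = pd.DataFrame(rng.normal(size=(10, 20)))
        mine = cx.correlation_matrix(vals, method="spearman").to_numpy()
        oracle = np.corrcoef(stats.rankdata(vals.to_numpy(), axis=1))
        assert np.max(np.abs(mine - oracle)) < 1e-12

    def test_blockwise_equals_whole_matrix(self):
        rng = np.random.default_rng(7)
        vals = pd.DataFrame(rng.normal(size=(50, 12)))
        whole = cx.correlation_matrix(vals, max_block_size=3500)
        blocked = cx.correlation_matrix(vals, max_block_size=7)
        assert np.allclose(whole.to_numpy(), blocked.to_numpy(), atol=1e-12)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            cx.correlation_matrix(pd.DataFrame(np.ones((3, 3))))


class TestSoftThreshold:
    def test_beta_monotonically_weakens_adjacency(self):
        rng = np.random.default_rng(3)
        corr = cx.correlation_matrix(pd.DataFrame(rng.normal(size=(20, 10))))
        prev = None
        for beta in (1, 2, 4, 8):
            a = cx.soft_threshold_adjacency(corr, beta).to_numpy()
            off = a[~np.eye(len(a), dtype=bool)]
            if prev is not None:
                assert np.all(off <= prev + 1e-12)
            prev = off

    def test_selected_beta_is_minimal_over_candidates(self):
        design = SyntheticDesign(
            replicates=2, n_background_genes=100, seed=2,
            modules=[ModuleSpec(f"M{i}", 30, 0.9) for i in range(5)])
        expr, _ = gen_expression_with_modules(design)
        corr = cx.correlation_matrix(expr.values)
        beta = cx.select_soft_threshold(corr)
        if beta != 6:  # not the fallback: verify minimality exhaustively
            for smaller in range(1, beta):
                a = cx.soft_threshold_adjacency(corr, smaller).to_numpy()
                np.fill_diagonal(a, 0.0)
                r2 = cx.scale_free_fit(a.sum(axis=1))
                assert not (np.isfinite(r2) and r2 >= 0.8)

    def test_pure_noise_falls_back(self):
        rng = np.random.default_rng(1)
        corr = cx.correlation_matrix(pd.DataFrame(rng.normal(size=(30, 8))))
        assert cx.select_soft_threshold(corr, candidate_betas=[4]) in (4, 6)

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            cx.select_soft_threshold(pd.DataFrame(np.eye(3)), candidate_betas=[])


class TestTOM:
    def test_complete_graph_saturates(self):
        a = _frame(np.ones((4, 4)))
        tom = cx.compute_tom(a).to_numpy()
        assert np.allclose(tom, 1.0)

    def test_unconnected_without_shared_neighbors_is_zero(self):
        a = np.zeros((4, 4))
        a[0, 1] = a[1, 0] = 1.0  # g2, g3 isolated from g0
        a[2, 3] = a[3, 2] = 1.0
        tom = cx.compute_tom(_frame(a)).to_numpy()
        assert tom[0, 2] == 0.0

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(size=(8, 8))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        mine = cx.compute_tom(_frame(a)).to_numpy()
        assert np.max(np.abs(mine - tom_oracle(a))) < 1e-12

    def test_rejects_out_of_range_adjacency(self):
        with pytest.raises(ValueError):
            cx.compute_tom(_frame(np.full((3, 3), 1.5)))


class TestModules:
    def test_two_planted_blocks_recovered_exactly(self):
        design = SyntheticDesign(
            genotypes=("A", "B"), stages=tuple(f"s{i}" for i in range(5)),
            replicates=2, n_background_genes=400, seed=1,
            modules=[ModuleSpec("M1", 50, 0.9), ModuleSpec("M2", 50, 0.9)])
        expr, truth = gen_expression_with_modules(design)
        corr = cx.correlation_matrix(expr.values)
        tom = cx.compute_tom(cx.soft_threshold_adjacency(corr, 6))
        modules = cx.detect_modules(tom)
        assert set(modules.unique()) - {"grey"} == {"turquoise", "blue"}
        planted = [g for g, m in truth.module_of.items() if m != "background"]
        ari = adjusted_rand_score([truth.module_of[g] for g in planted],
                                  modules[planted])
        assert ari == pytest.approx(1.0)

    def test_independent_genes_form_no_modules(self):
        rng = np.random.default_rng(9)
        vals = pd.DataFrame(rng.normal(size=(120, 20)),
                            index=[f"g{i}" for i in range(120)])
        tom = cx.compute_tom(cx.soft_threshold_adjacency(
            cx.correlation_matrix(vals), 6))
        modules = cx.detect_modules(tom)
        assert set(modules.unique()) == {"grey"}

    def test_undersized_block_stays_grey(self):
        design = SyntheticDesign(
            genotypes=("A", "B"), stages=tuple(f"s{i}" for i in range(5)),
            replicates=2, n_background_genes=0, seed=4,
            modules=[ModuleSpec("M1", 29, 0.9)])  # min_module_size - 1
        expr, truth = gen_expression_with_modules(design)
        tom = cx.compute_tom(cx.soft_threshold_adjacency(
            cx.correlation_matrix(expr.values), 6))
        modules = cx.detect_modules(tom, min_module_size=30)
        block = [g for g, m in truth.module_of.items() if m == "M1"]
        assert set(modules[block]) == {"grey"}


class TestEigengenes:
    def test_identical_profiles_give_their_own_profile(self):
        profile = np.sin(np.linspace(0, 3, 12))
        vals = pd.DataFrame([profile * s for s in (1.0, 2.0, 5.0)],
                            index=["a", "b", "c"])
        modules = pd.Series("turquoise", index=vals.index)
        eig = cx.module_eigengenes(vals, modules)
        r = np.corrcoef(eig.loc["turquoise"], profile)[0, 1]
        assert r == pytest.approx(1.0)

    def test_factor_recovery_and_sign_orientation(self):
        design = SyntheticDesign(
            genotypes=("A", "B"), stages=tuple(f"s{i}" for i in range(5)),
            replicates=3, n_background_genes=0, seed=4,
            modules=[ModuleSpec("M1", 40, 0.9)])
        expr, truth = gen_expression_with_modules(design)
        modules = pd.Series("turquoise", index=expr.values.index)
        eig = cx.module_eigengenes(expr.values, modules)
        r = abs(np.corrcoef(eig.loc["turquoise"], truth.factors["M1"])[0, 1])
        assert r >= 0.9
        mean_profile = ((expr.values.sub(expr.values.mean(axis=1), axis=0))
                        .div(expr.values.std(axis=1, ddof=1), axis=0)).mean(axis=0)
        assert np.corrcoef(eig.loc["turquoise"], mean_profile)[0, 1] >= 0


class TestModuleTrait:
    def _eigengenes(self):
        rng = np.random.default_rng(9)
        samples = [f"s{i}" for i in range(20)]
        return pd.DataFrame(rng.normal(size=(2, 20)),
                            index=["turquoise", "blue"], columns=samples)

    def test_metabolite_equal_to_eigengene_is_selected(self):
        eig = self._eigengenes()
        met = pd.DataFrame([eig.loc["turquoise"]], index=["IP6"])
        recs = cx.module_trait_correlations(eig, met)
        rec = next(r for r in recs if r.module == "turquoise")
        assert rec.r == pytest.approx(1.0) and rec.selected

    def test_exact_threshold_not_selected(self):
        assert cx.select_significant_modules(
            [cx.ModuleTraitRecord("m", "IP1", 0.8, 1e-5, False)]) == []
        assert cx.select_significant_modules(
            [cx.ModuleTraitRecord("m", "IP1", 0.79, 1e-5, False)]) == []

    def test_sample_mismatch_rejected(self):
        eig = self._eigengenes()
        met = pd.DataFrame(np.zeros((1, 20)), index=["IP1"],
                           columns=[f"t{i}" for i in range(20)])
        with pytest.raises(ValueError, match="sample ids"):
            cx.module_trait_correlations(eig, met)

    def test_printed_records_give_six_distinct_modules(self):
        records = ip_module_records()
        selected = cx.select_significant_modules(records)
        assert len(selected) == 6
        assert set(selected) == {"dodgerblue4", "salmon1", "burlywood2",
                                 "magenta2", "cornsilk", "steelblue4"}
        # idempotent and order-stable
        assert cx.select_significant_modules(records) == selected


class TestHubs:
    def test_star_center_ranks_first_under_both_methods(self):
        edges = [("c", f"l{i}") for i in range(6)] + [("l0", "l1")]
        for method in ("degree", "mcc"):
            assert cx.hub_genes(edges, method=method, top_k=3)[0] == "c"

    def test_mcc_prefers_clique_members_over_pendant(self):
        # 4-clique abcd (+pendant p on a): MCC(clique member) >= 3! = 6,
        # MCC(p) = 1! = 1
        clique = [("a", "b"), ("a", "c"), ("a", "d"), ("b", "c"), ("b", "d"),
                  ("c", "d"), ("a", "p")]
        ranked = cx.hub_genes(clique, method="mcc", top_k=5)
        assert ranked.index("p") == len(ranked) - 1

    def test_top_k_larger_than_graph_returns_all(self):
        assert len(cx.hub_genes([("a", "b")], top_k=10)) == 2
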