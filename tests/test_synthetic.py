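"""Generator contracts: planted structure, determinism, truth sufficiency."""

import numpy as np
import pandas as pd
import pytest

from phytonet import synthetic as syn
from phytonet.coexpression import correlation_matrix
from phytonet.expression import ExpressionMatrix, filter_genes


def _design(**kw):
    base = dict(genotypes=("A", "B"), stages=tuple(f"s{i}" for i in range(5)),
                replicates=2, n_background_genes=20, seed=1,
                modules=[syn.ModuleSpec("M1", 50, 0.9), syn.ModuleSpec("M2", 50, 0.9)])
    base.update(kw)
    return syn.SyntheticDesign(**base)


class TestExpressionGenerator:
    def test_within_module_correlation_reflects_loading(self):
        expr, truth = syn.gen_expression_with_modules(_design())
        corr = correlation_matrix(expr.values, method="spearman")
        for module in ("M1", "M2"):
            genes = [g for g, m in truth.module_of.items() if m == module]
            sub = corr.loc[genes, genes].to_numpy()
            iu = np.triu_indices_from(sub, 1)
            assert np.abs(sub[iu]).mean() >= 0.6

    def test_loading_one_gives_perfect_correlation(self):
        design = _design(modules=[syn.ModuleSpec("M1", 5, 1.0)],
                         n_background_genes=0)
        expr, truth = syn.gen_expression_with_modules(design)
        genes = list(expr.values.index)
        c = np.corrcoef(expr.values.to_numpy())
        assert np.allclose(np.abs(c), 1.0)

    def test_seeded_determinism(self):
        e1, _ = syn.gen_expression_with_modules(_design())
        e2, _ = syn.gen_expression_with_modules(_design())
        assert e1.values.equals(e2.values)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            syn.gen_expression_with_modules(
                _design(genotypes=("A",), stages=("s",), replicates=3))

    def test_output_passes_gene_filter_and_metadata_aligned(self):
        expr, _ = syn.gen_expression_with_modules(_design())
        assert len(filter_genes(expr).values) == len(expr.values)
        assert set(expr.sample_meta.index) == set(expr.values.columns)
        assert set(expr.sample_meta.columns) == {"genotype", "stage", "replicate"}


class TestMetaboliteGenerator:
    def test_r0_one_reproduces_the_factor(self):
        expr, truth = syn.gen_expression_with_modules(_design())
        met = syn.gen_metabolite_profiles(truth, {"IP1": ("M1", 1.0)}, seed=2)
        r = np.corrcoef(met.loc["IP1"], truth.factors["M1"])[0, 1]
        assert r == pytest.approx(1.0)

    def test_strong_negative_r0_lands_in_band(self):
        design = _design(genotypes=("A", "B", "C"), replicates=1,
                         stages=tuple(f"s{i}" for i in range(10)))  # n = 30
        expr, truth = syn.gen_expression_with_modules(design)
        met = syn.gen_metabolite_profiles(truth, {"IP2": ("M1", -0.95)}, seed=7)
        r = np.corrcoef(met.loc["IP2"], truth.factors["M1"])[0, 1]
        assert -1.0 <= r <= -0.8

    def test_independent_metabolite_within_null_band(self):
        design = _design(genotypes=("A", "B", "C"), replicates=1,
                         stages=tuple(f"s{i}" for i in range(10)))
        expr, truth = syn.gen_expression_with_modules(design)
        met = syn.gen_metabolite_profiles(truth, {"IP6": ("M1", 0.0)}, seed=7)
        r = np.corrcoef(met.loc["IP6"], truth.factors["M1"])[0, 1]
        assert abs(r) < 0.4  # 95% Fisher-z band at n = 30

    def test_unknown_module_named_in_error(self):
        _, truth = syn.gen_expression_with_modules(_design())
        with pytest.raises(ValueError, match="M9"):
            syn.gen_metabolite_profiles(truth, {"IP1": ("M9", 0.5)}, seed=1)


class TestCountGenerator:
    def test_zero_de_fraction_has_empty_truth(self):
        _, truth = syn.gen_count_table(100, 3, de_fraction=0.0, seed=1)
        assert truth.de_genes == {}

    def test_zero_dispersion_is_poisson_like(self):
        table, _ = syn.gen_count_table(2000, 10, dispersion=0.0, seed=2)
        counts = table.counts.to_numpy(dtype=float)
        ratio = counts.var(axis=1, ddof=1) / counts.mean(axis=1)
        # variance/mean concentrates around 1 for Poisson
        assert 0.8 < np.median(ratio) < 1.2

    def test_requires_two_per_group(self):
        with pytest.raises(ValueError):
            syn.gen_count_table(10, 1, seed=0)

    def test_determinism(self):
        t1, _ = syn.gen_count_table(50, 3, de_fraction=0.1, seed=5)
        t2, _ = syn.gen_count_table(50, 3, de_fraction=0.1, seed=5)
        assert t1.counts.equals(t2.counts)


class TestGermplasmGenerator:
    def test_planted_q_in_expected_band(self):
        panel, truth = syn.gen_germplasm_panel(6, 3, [(2.0, 0.01)], seed=1)
        hi, lo, _ = truth.germplasm_pairs[0]
        q = np.abs(np.log2(panel.content.loc[hi] / panel.content.loc[lo]))
        assert np.all((q >= 0.9) & (q <= 1.1))

    def test_unit_ratio_gives_near_zero_q(self):
        panel, truth = syn.gen_germplasm_panel(6, 3, [(1.0, 0.01)], seed=2)
        hi, lo, _ = truth.germplasm_pairs[0]
        q = np.abs(np.log2(panel.content.loc[hi] / panel.content.loc[lo]))
        assert np.all(q < 0.1)

    def test_contents_positive_and_deterministic(self):
        p1, _ = syn.gen_germplasm_panel(12, 3, [(2.0, 0.02)], seed=3)
        p2, _ = syn.gen_germplasm_panel(12, 3, [(2.0, 0.02)], seed=3)
        assert (p1.content.to_numpy() > 0).all()
        assert p1.content.equals(p2.content)

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError):
            syn.gen_germplasm_panel(6, 3, [(-1.0, 0.01)], seed=1)


class TestCandidateBenchmark:
    def test_truth_names_one_candidate_and_ten_decoys(self):
        _, _, _, _, truth = syn.gen_candidate_benchmark(seed=1)
        roles = list(truth.candidate_roles.values())
        assert roles.count("true_candidate") == 1
        assert sum(r.startswith("decoy") for r in roles) == 10

    def test_relabeling_changes_ids_not_topology(self):
        e1, _, _, _, _ = syn.gen_candidate_benchmark(seed=1)
        e2, _, _, _, _ = syn.gen_candidate_benchmark(seed=2)
        assert len(e1) == len(e2)
        assert set(e1.gene_a) != set(e2.gene_a) or set(e1.gene_b) != set(e2.gene_b)


def test_truth_round_trips_through_json(tmp_path):
    expr, truth = syn.gen_expression_with_modules(_design())
    syn.gen_metabolite_profiles(truth, {"IP1": ("M1", 0.9)}, seed=2)
    path = tmp_path / "truth.json"
    truth.to_json(path)
    import json
    data = json.loads(path.read_text())
    assert data["metabolite_targets"]["IP1"] == ["M1", 0.9]
    assert set(data["module_of"]) == set(truth.module_of)
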