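"""RPKM normalization, gene filtering, BH adjustment, DE calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phytonet.expression import (
    CountTable,
    ExpressionMatrix,
    bh_fdr,
    call_degs,
    compute_rpkm,
    filter_genes,
)
from phytonet.synthetic import count_group_labels, gen_count_table


def _table(counts, lengths, mapped):
    genes = [f"g{i}" for i in range(len(lengths))]
    samples = [f"s{i}" for i in range(len(mapped))]
    return CountTable(
        counts=pd.DataFrame(counts, index=genes, columns=samples),
        exon_length_kb=pd.Series(lengths, index=genes),
        mapped_reads_millions=pd.Series(mapped, index=samples),
    )


@pytest.mark.parametrize(
    "count, mapped, length, expected",
    [(10, 1.0, 1.0, 10.0), (0, 1.0, 1.0, 0.0), (200, 2.5, 0.8, 100.0)],
)
def test_rpkm_formula(count, mapped, length, expected):
    table = _table([[count]], [length], [mapped])
    assert compute_rpkm(table).values.iloc[0, 0] == pytest.approx(expected)


def test_rpkm_linear_in_library_split():
    # splitting reads across two half-size libraries and averaging the two
    # RPKM columns reproduces the single-library RPKM
    table = _table([[100], [40]], [2.0, 0.5], [4.0])
    split = _table([[60, 40], [24, 16]], [2.0, 0.5], [2.4, 1.6])
    whole = compute_rpkm(table).values.iloc[:, 0]
    halves = compute_rpkm(split).values.mean(axis=1)
    assert np.allclose(whole, halves)


def test_rpkm_rejects_bad_length():
    with pytest.raises(ValueError, match="g0"):
        _table([[1]], [0.0], [1.0])


def test_gene_filter_boundary():
    vals = pd.DataFrame(
        {
            "four_zeros": [0, 0, 0, 0] + [1.0] * 8,
            "three_zeros": [0, 0, 0] + [1.0] * 9,
            "with_nan": [np.nan, 0, 0, 0] + [1.0] * 8,
            "clean": [1.0] * 12,
        },
        index=[f"s{i}" for i in range(12)],
    ).T
    kept = filter_genes(ExpressionMatrix(values=vals))
    assert list(kept.values.index) == ["three_zeros", "clean"]


def test_gene_filter_keeps_all_positive_matrix():
    vals = pd.DataFrame(np.ones((5, 6)) * 2.0,
                        index=[f"g{i}" for i in range(5)])
    out = filter_genes(ExpressionMatrix(values=vals))
    assert out.values.equals(vals)


def test_bh_fdr_hand_computed_stepup():
    out = bh_fdr([0.004, 0.02, 0.03, 0.04])
    assert np.allclose(out, [0.016, 0.04, 0.04, 0.04])
    assert bh_fdr([0.01]) == pytest.approx([0.01])


def test_bh_fdr_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.2])


@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
@settings(max_examples=100, derandomize=True)
def test_bh_fdr_properties(ps):
    out = bh_fdr(ps)
    assert np.all((out >= 0) & (out <= 1))
    # rank order preserved: sorting inputs sorts outputs
    order = np.argsort(ps, kind="stable")
    assert np.all(np.diff(out[order]) >= -1e-12)
    # permutation equivariance
    perm = list(reversed(range(len(ps))))
    assert np.allclose(bh_fdr(np.asarray(ps)[perm]), out[perm])


def test_identical_groups_give_zero_fold_change():
    counts = np.tile([[10], [100], [1000]], (1, 6))
    table = _table(counts, [1.0] * 3, [1.0] * 6)
    res = call_degs(table, ["A"] * 3 + ["B"] * 3)
    assert all(r.log2_fc == 0 for r in res)
    assert not any(r.is_de for r in res)


def test_fold_change_gate_blocks_significant_small_changes():
    # strong signal but FC < 2 must not be called DE
    rng = np.random.default_rng(0)
    stable = rng.poisson(500, (200, 6))
    shifted = np.concatenate([rng.poisson(1000, (20, 3)),
                              rng.poisson(1900, (20, 3))], axis=1)
    counts = np.vstack([stable, shifted])
    table = _table(counts, [1.0] * 220, [1.0] * 6)
    res = call_degs(table, ["A"] * 3 + ["B"] * 3)
    blocked = [r for r in res if abs(r.log2_fc) < 1 and r.fdr < 0.01]
    assert blocked, "expected significant genes below the FC gate"
    assert not any(r.is_de for r in blocked)


def test_group_swap_negates_fold_changes():
    table, _ = gen_count_table(50, 3, de_fraction=0.2, fold_change=3.0, seed=4)
    labels = count_group_labels(table)
    fwd = call_degs(table, labels)
    # swap group identities
    swapped = labels.map({"A": "Z", "B": "A"}).map(lambda x: {"Z": "B"}.get(x, x))
    rev = call_degs(table, swapped)
    assert np.allclose([r.log2_fc for r in fwd], [-r.log2_fc for r in rev])


def test_planted_fold_change_recovered_in_generated_counts():
    table, truth = gen_count_table(500, 3, de_fraction=0.2, fold_change=4.0,
                                   dispersion=0.05, seed=11)
    planted = list(truth.de_genes)
    mean_a = table.counts[[c for c in table.counts if c.startswith("A")]].mean(axis=1)
    mean_b = table.counts[[c for c in table.counts if c.startswith("B")]].mean(axis=1)
    ratio = (mean_b[planted] / mean_a[planted]).mean()
    assert 3.0 <= ratio <= 5.0


def test_call_degs_requires_two_per_group():
    table = _table([[1, 2, 3]], [1.0], [1.0] * 3)
    with pytest.raises(ValueError):
        call_degs(table, ["A", "B", "B"])
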