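"""Count normalization (RPKM), gene filtering, and differential expression.

Differential expression follows the screening rule used throughout the
pipeline: a gene is differentially expressed when its fold change is at
least 2 (|log2 FC| >= 1) and its Benjamini-Hochberg FDR is below 0.01.
P-values come from a two-sided exact negative-binomial test on group count
sums with a method-of-moments gene-wise dispersion — a deliberately simple,
fully documented test standing in for heavier DE machinery; the FC/FDR gate
is the decision rule, the test only supplies calibrated p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

DISPERSION_FLOOR = 1e-8
PSEUDO_COUNT = 0.5


@dataclass
class CountTable:
    """Genes x samples read counts with exon lengths and library sizes.

    ``exon_length_kb`` is per-gene exon length in kilobases;
    ``mapped_reads_millions`` is the per-sample total mapped reads in
    millions (the RPKM denominator).
    """

    counts: pd.DataFrame  # genes x samples, non-negative integers
    exon_length_kb: pd.Series  # indexed by gene_id
    mapped_reads_millions: pd.Series  # indexed by sample_id

    def __post_init__(self) -> None:
        bad_len = self.exon_length_kb[self.exon_length_kb <= 0]
        if len(bad_len):
            raise ValueError(f"non-positive exon length for gene(s) {list(bad_len.index)[:5]}")
        bad_lib = self.mapped_reads_millions[self.mapped_reads_millions <= 0]
        if len(bad_lib):
            raise ValueError(f"non-positive library size for sample(s) {list(bad_lib.index)[:5]}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_tsv(cls, path, mapped_reads_millions: pd.Series | None = None) -> "CountTable":
        """Read a counts TSV: gene_id, length_kb, then one column per sample.

        When library sizes are not given they default to the per-sample
        column totals divided by 1e6.
        """
        df = pd.read_csv(path, sep="\t", index_col=0)
        length = df["length_kb"].astype(float)
        counts = df.drop(columns=["length_kb"])
        if mapped_reads_millions is None:
            mapped_reads_millions = counts.sum(axis=0) / 1e6
        return cls(counts=counts, exon_length_kb=length,
                   mapped_reads_millions=mapped_reads_millions)

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.insert(0, "length_kb", self.exon_length_kb)
        out.to_csv(path, sep="\t")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values plus per-sample design metadata."""

    values: pd.DataFrame  # genes x samples
    sample_meta: pd.DataFrame | None = None  # indexed by sample_id

    def __post_init__(self) -> None:
        if (self.values.to_numpy(dtype=float) < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.sample_meta is not None:
            missing = set(self.values.columns) - set(self.sample_meta.index)
            if missing:
                raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @classmethod
    def from_tsv(cls, path, meta_path=None) -> "ExpressionMatrix":
        values = pd.read_csv(path, sep="\t", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t", index_col=0) if meta_path else None
        return cls(values=values, sample_meta=meta)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t")


def compute_rpkm(table: CountTable) -> ExpressionMatrix:
    """RPKM = exon reads / [mapped reads (millions) x exon length (kb)]."""
    denom = np.outer(table.exon_length_kb.to_numpy(dtype=float),
                     table.mapped_reads_millions.reindex(table.counts.columns).to_numpy(dtype=float))
    rpkm = table.counts.to_numpy(dtype=float) / denom
    return ExpressionMatrix(
        values=pd.DataFrame(rpkm, index=table.counts.index, columns=table.counts.columns)
    )


def filter_genes(expr: ExpressionMatrix, max_bad: int = 3) -> ExpressionMatrix:
    """Drop genes with more than ``max_bad`` missing-or-zero entries.

    Missing (NaN) cells and zeros count identically; genes with exactly
    ``max_bad`` bad entries are retained (strict >). Gene order is preserved.
    """
    vals = expr.values
    n_bad = (vals.isna() | (vals == 0)).sum(axis=1)
    keep = n_bad <= max_bad
    if not keep.any():
        log.warning("gene filter removed every gene")
    return ExpressionMatrix(values=vals.loc[keep], sample_meta=expr.sample_meta)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DEResult:
    gene_id: str
    log2_fc: float
    p_value: float
    fdr: float = float("nan")
    is_de: bool = False


def _nb_params(mean: float, var: float) -> tuple[float, float]:
    """scipy (n, p) parametrization from a mean/variance pair.

    Variance at or below the mean degenerates to (effectively) Poisson;
    a very large ``n`` approximates it within the NB family.
    """
    if var <= mean:
        n = 1e8
    else:
        n = mean * mean / (var - mean)
    p = n / (n + mean)
    return n, p


def _exact_nb_pvalue(k_a: int, k_b: int, mean_a: float, var_a: float,
                     mean_b: float, var_b: float) -> float:
    """Two-sided exact test: conditional on k_a + k_b, sum the probabilities
    of all splits no more likely than the observed one."""
    k = k_a + k_b
    if k == 0:
        return 1.0
    n_a, p_a = _nb_params(mean_a, var_a)
    n_b, p_b = _nb_params(mean_b, var_b)
    a = np.arange(k + 1)
    with np.errstate(divide="ignore"):
        logp = stats.nbinom.logpmf(a, n_a, p_a) + stats.nbinom.logpmf(k - a, n_b, p_b)
    logp -= logp.max()
    probs = np.exp(logp)
    total = probs.sum()
    if total <= 0 or not np.isfinite(total):
        return 1.0
    obs = probs[k_a]
    # 1+1e-7 relative tolerance keeps the observed split and its exact ties in
    return float(probs[probs <= obs * (1 + 1e-7)].sum() / total)


def call_degs(
    table: CountTable,
    group_labels,
    fc_min: float = 2.0,
    fdr_max: float = 0.01,
) -> list[DEResult]:
    """Call differential expression between the two groups in ``group_labels``.

    ``group_labels`` maps each sample (in column order, or by sample id via a
    dict/Series) to one of exactly two labels; fold changes are group2 vs
    group1 in sorted label order. Library sizes are normalized by total
    counts; a pseudo-count of 0.5 is added to both normalized group means
    for the fold change.
    """
    counts = table.counts
    if isinstance(group_labels, (dict, pd.Series)):
        labels = pd.Series(group_labels).reindex(counts.columns)
    else:
        labels = pd.Series(list(group_labels), index=counts.columns)
    groups = sorted(labels.dropna().unique())
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {groups}")
    idx_a = labels[labels == groups[0]].index
    idx_b = labels[labels == groups[1]].index
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValueError("each group needs at least 2 samples")

    totals = counts.sum(axis=0).astype(float)
    size = (totals / totals.mean()).to_numpy()
    s = pd.Series(size, index=counts.columns)
    s_a, s_b = s[idx_a].to_numpy(), s[idx_b].to_numpy()

    raw_a = counts[idx_a].to_numpy(dtype=float)
    raw_b = counts[idx_b].to_numpy(dtype=float)
    norm_a = raw_a / s_a
    norm_b = raw_b / s_b

    mean_a = norm_a.mean(axis=1)
    mean_b = norm_b.mean(axis=1)
    log2_fc = np.log2((mean_b + PSEUDO_COUNT) / (mean_a + PSEUDO_COUNT))

    # method-of-moments gene-wise dispersion: per group against its own
    # mean (variance = mu + disp * mu^2), averaged across the two groups
    mu0 = np.concatenate([norm_a, norm_b], axis=1).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp_a = (norm_a.var(axis=1, ddof=1) - mean_a) / np.where(mean_a > 0, mean_a**2, 1.0)
        disp_b = (norm_b.var(axis=1, ddof=1) - mean_b) / np.where(mean_b > 0, mean_b**2, 1.0)
    disp = np.clip(np.nan_to_num((disp_a + disp_b) / 2.0), DISPERSION_FLOOR, None)

    k_a = raw_a.sum(axis=1).round().astype(int)
    k_b = raw_b.sum(axis=1).round().astype(int)
    # null mean/variance of the raw group sums given shared normalized mean mu0
    m_a = mu0 * s_a.sum()
    v_a = (mu0[:, None] * s_a[None, :] + disp[:, None] * (mu0[:, None] * s_a[None, :]) ** 2).sum(axis=1)
    m_b = mu0 * s_b.sum()
    v_b = (mu0[:, None] * s_b[None, :] + disp[:, None] * (mu0[:, None] * s_b[None, :]) ** 2).sum(axis=1)

    pvals = np.ones(len(counts))
    for i in range(len(counts)):
        if mu0[i] <= 0:
            continue
        pvals[i] = _exact_nb_pvalue(k_a[i], k_b[i], m_a[i], v_a[i], m_b[i], v_b[i])

    fdr = bh_fdr(pvals)
    lfc_min = np.log2(fc_min)
    results = []
    for i, gene in enumerate(counts.index):
        is_de = bool(abs(log2_fc[i]) >= lfc_min and fdr[i] < fdr_max)
        results.append(DEResult(gene, float(log2_fc[i]), float(pvals[i]), float(fdr[i]), is_de))
    return results


def de_results_frame(results: list[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"gene_id": r.gene_id, "log2_fc": r.log2_fc, "p_value": r.p_value,
          "fdr": r.fdr, "is_de": r.is_de} for r in results]
    ).set_index("gene_id")
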