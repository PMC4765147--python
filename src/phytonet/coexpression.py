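"""Weighted gene co-expression network construction and module analysis.

The chain is the classic weighted-correlation-network recipe: a (Spearman)
correlation matrix over genes, soft-thresholded into an adjacency
a_ij = |rho_ij|^beta, converted to a topological overlap matrix (TOM) that
rewards shared neighborhoods, clustered by average linkage on 1 - TOM with
a static height cut, and summarized per module by an eigengene (first
principal component of the standardized module expression). Module
eigengenes are then correlated with metabolite abundances; modules with
|r| > 0.8 and p < 0.01 are the metabolite-associated modules carried
forward to compression and candidate screening.

The static height cut with a minimum module size is a deterministic
simplification of dynamic tree cutting, adequate for well-separated
modules.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

log = logging.getLogger(__name__)

#: module color vocabulary, assigned to detected modules in decreasing size
#: order; "grey" is reserved for unassigned genes. The list follows the
#: extended R color vocabulary conventional for co-expression modules.
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta", "sienna3",
    "yellowgreen", "skyblue3", "plum1", "orangered4", "mediumpurple3",
    "lightsteelblue1", "lightcyan1", "ivory", "floralwhite", "darkorange2",
    "brown4", "bisque4", "darkslateblue", "plum2", "thistle2", "thistle1",
    "salmon4", "palevioletred3", "navajowhite2", "maroon", "lightpink4",
    "lavenderblush3", "honeydew1", "darkseagreen4", "coral1",
    "antiquewhite4", "coral2", "mediumorchid", "skyblue2", "yellow4",
    "skyblue1", "plum", "orangered3", "mediumpurple2", "lightsteelblue",
    "lightskyblue4", "lightcoral", "indianred4", "firebrick4",
    "darkolivegreen4", "brown2", "blue2", "darkviolet", "plum3", "thistle3",
    "thistle", "salmon2", "palevioletred2", "navajowhite1", "magenta4",
    "lightpink3", "lavenderblush2", "honeydew", "darkseagreen3", "coral",
    "antiquewhite2", "dodgerblue4", "salmon1", "burlywood2", "magenta2",
    "cornsilk", "steelblue4",
]

GREY = "grey"


@dataclass
class NetworkParams:
    """Tunable knobs of the network construction."""

    correlation: str = "spearman"  # or "pearson"
    signed: bool = False
    beta: int | None = None  # None = choose by scale-free fit
    max_block_size: int = 3500
    export_threshold: float = 0.5
    min_module_size: int = 30
    cut_height: float = 0.99

    def __post_init__(self) -> None:
        if self.correlation not in ("spearman", "pearson"):
            raise ValueError(f"unknown correlation method {self.correlation!r}")
        if self.beta is not None and self.beta < 1:
            raise ValueError("beta must be >= 1")
        if not 0 <= self.export_threshold <= 1:
            raise ValueError("export_threshold must lie in [0, 1]")
        if not 0 <= self.cut_height <= 1:
            raise ValueError("cut_height must lie in [0, 1]")


@dataclass
class ModuleTraitRecord:
    module: str
    metabolite: str
    r: float
    p: float
    selected: bool


@dataclass
class CoexpressionResult:
    adjacency: pd.DataFrame
    tom: pd.DataFrame
    module_of: pd.Series  # gene -> color label
    eigengenes: pd.DataFrame  # modules x samples
    params: NetworkParams
    beta_used: int = 0
    correlation: pd.DataFrame | None = None
    trait_records: list[ModuleTraitRecord] = field(default_factory=list)


def correlation_matrix(
    values: pd.DataFrame,
    method: str = "spearman",
    max_block_size: int = 3500,
) -> pd.DataFrame:
    """Gene-gene correlation matrix (genes x genes).

    Spearman is Pearson on within-gene ranks (average ranks on ties).
    Genes with zero variance carry no correlation signal and are excluded
    with a warning. Computation runs blockwise in row blocks of at most
    ``max_block_size`` genes; the result is identical to the whole-matrix
    computation.
    """
    if values.shape[1] < 4:
        raise ValueError("at least 4 samples are required for correlation")
    x = values.to_numpy(dtype=float)
    if method == "spearman":
        x = stats.rankdata(x, axis=1)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    sd = x.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        log.warning("excluding %d zero-variance genes", int(degenerate.sum()))
        values = values.loc[~degenerate]
        x = x[~degenerate]
        sd = sd[~degenerate]
    z = (x - x.mean(axis=1, keepdims=True)) / (sd[:, None] * math.sqrt(x.shape[1]))
    n = z.shape[0]
    corr = np.empty((n, n))
    for start in range(0, n, max_block_size):
        stop = min(start + max_block_size, n)
        corr[start:stop] = z[start:stop] @ z.T
    np.clip(corr, -1.0, 1.0, out=corr)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=values.index, columns=values.index)


def soft_threshold_adjacency(corr: pd.DataFrame, beta: int, signed: bool = False) -> pd.DataFrame:
    """Adjacency a_ij = |rho_ij|^beta (unsigned) or ((1+rho)/2)^beta (signed)."""
    if signed:
        a = ((1.0 + corr.to_numpy()) / 2.0) ** beta
    else:
        a = np.abs(corr.to_numpy()) ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=corr.index, columns=corr.columns)


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of the log10 frequency vs log10 mean-connectivity regression."""
    k = np.asarray(connectivity, dtype=float)
    if k.max() == k.min():
        return float("nan")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    freqs, means = [], []
    for b in range(n_bins):
        mask = idx == b
        if mask.sum() > 0 and k[mask].mean() > 0:
            freqs.append(mask.mean())
            means.append(k[mask].mean())
    if len(freqs) < 3:
        return float("nan")
    res = stats.linregress(np.log10(means), np.log10(freqs))
    return float(res.rvalue**2)


def select_soft_threshold(
    corr: pd.DataFrame,
    candidate_betas=range(1, 21),
    target_r2: float = 0.8,
    signed: bool = False,
    fallback: int = 6,
) -> int:
    """Smallest beta whose scale-free fit R^2 reaches ``target_r2``.

    Falls back to ``fallback`` (with a warning) when no candidate fits or
    the connectivity distribution is degenerate.
    """
    candidates = sorted(candidate_betas)
    if not candidates:
        raise ValueError("candidate beta set is empty")
    for beta in candidates:
        a = soft_threshold_adjacency(corr, beta, signed=signed).to_numpy()
        np.fill_diagonal(a, 0.0)
        r2 = scale_free_fit(a.sum(axis=1))
        if np.isfinite(r2) and r2 >= target_r2:
            return beta
    log.warning("no candidate beta reached scale-free fit R^2 >= %.2f; falling back to %d",
                target_r2, fallback)
    return fallback


def compute_tom(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Unsigned topological overlap matrix.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) for
    i != j with the diagonal of ``adjacency`` forced to zero for the
    computation and k_i the node connectivity; TOM_ii = 1.
    """
    a = adjacency.to_numpy(dtype=float).copy()
    if (a < 0).any() or (a > 1).any():
        raise ValueError("adjacency entries must lie in [0, 1]")
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    if isinstance(adjacency, pd.DataFrame):
        return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)
    return pd.DataFrame(tom)


def detect_modules(
    tom: pd.DataFrame,
    min_module_size: int = 30,
    cut_height: float = 0.99,
) -> pd.Series:
    """Assign genes to color-named modules from the TOM.

    Average-linkage hierarchical clustering on the dissimilarity 1 - TOM;
    branches below ``cut_height`` with at least ``min_module_size`` members
    become modules, everything else is "grey". Colors go to modules in
    decreasing size order, ties broken by lowest gene index, so the result
    is deterministic.
    """
    genes = list(tom.index)
    d = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    z = linkage(squareform(d, checks=False), method="average")
    flat = fcluster(z, t=cut_height, criterion="distance")
    clusters: dict[int, list[int]] = {}
    for i, c in enumerate(flat):
        clusters.setdefault(int(c), []).append(i)
    keep = [idx for idx in clusters.values() if len(idx) >= min_module_size]
    keep.sort(key=lambda idx: (-len(idx), min(idx)))
    labels = pd.Series(GREY, index=genes, name="module")
    for rank, idx in enumerate(keep):
        color = MODULE_COLORS[rank % len(MODULE_COLORS)]
        labels.iloc[idx] = color
    return labels


def module_eigengenes(values: pd.DataFrame, module_of: pd.Series) -> pd.DataFrame:
    """First-principal-component summary profile per module (modules x samples).

    Each module's gene profiles are standardized across samples; the
    eigengene is the leading right singular vector of that submatrix, scaled
    to unit variance and sign-oriented so it correlates non-negatively with
    the module's mean expression profile.
    """
    out = {}
    for module in module_of.unique():
        if module == GREY:
            continue
        sub = values.loc[module_of[module_of == module].index].to_numpy(dtype=float)
        sd = sub.std(axis=1, ddof=1)
        sd[sd == 0] = 1.0
        z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
        if z.shape[0] == 1:
            log.warning("module %s has a single gene; using its standardized profile", module)
            eig = z[0]
        else:
            _, _, vt = np.linalg.svd(z, full_matrices=False)
            eig = vt[0]
        mean_profile = z.mean(axis=0)
        if np.std(mean_profile) > 0 and np.corrcoef(eig, mean_profile)[0, 1] < 0:
            eig = -eig
        eig = (eig - eig.mean()) / eig.std(ddof=1)
        out[module] = eig
    return pd.DataFrame(out, index=values.columns).T


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p from the t approximation t = r sqrt((n-2)/(1-r^2))."""
    if abs(r) >= 1.0:
        return 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def module_trait_correlations(
    eigengenes: pd.DataFrame,
    metabolites: pd.DataFrame,
    r_min: float = 0.8,
    p_max: float = 0.01,
) -> list[ModuleTraitRecord]:
    """Correlate each module eigengene with each metabolite profile.

    Both tables are entities x samples and must share sample ids; a record
    is ``selected`` when |r| > ``r_min`` (strict) and p < ``p_max``.
    """
    unmatched = set(eigengenes.columns) ^ set(metabolites.columns)
    if unmatched:
        raise ValueError(f"sample ids do not match: {sorted(unmatched)}")
    samples = list(eigengenes.columns)
    if len(samples) < 4:
        raise ValueError("at least 4 shared samples are required")
    met = metabolites[samples]
    records = []
    for module, eig in eigengenes.iterrows():
        for metabolite, vec in met.iterrows():
            r = float(np.corrcoef(eig.to_numpy(dtype=float), vec.to_numpy(dtype=float))[0, 1])
            p = correlation_pvalue(r, len(samples))
            records.append(ModuleTraitRecord(
                module=str(module), metabolite=str(metabolite), r=r, p=p,
                selected=bool(abs(r) > r_min and p < p_max),
            ))
    return records


def select_significant_modules(
    records: list[ModuleTraitRecord],
    r_min: float = 0.8,
    p_max: float = 0.01,
) -> list[str]:
    """Distinct modules with |r| > r_min and p < p_max, first-appearance order."""
    seen: list[str] = []
    for rec in records:
        if abs(rec.r) > r_min and rec.p < p_max and rec.module not in seen:
            seen.append(rec.module)
    return seen


def trait_records_frame(records: list[ModuleTraitRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"module": r.module, "metabolite": r.metabolite, "r": r.r, "p": r.p,
          "selected": r.selected} for r in records]
    )


def export_edges(weights: pd.DataFrame, threshold: float = 0.5) -> pd.DataFrame:
    """Edge list (gene_a, gene_b, weight) with weight > ``threshold``."""
    w = weights.to_numpy(dtype=float)
    iu, ju = np.triu_indices_from(w, k=1)
    keep = w[iu, ju] > threshold
    genes = np.asarray(weights.index)
    return pd.DataFrame({
        "gene_a": genes[iu[keep]],
        "gene_b": genes[ju[keep]],
        "weight": w[iu[keep], ju[keep]],
    })


def graph_from_edges(edge_list) -> nx.Graph:
    """Build an undirected graph from (a, b) or (a, b, weight) records or a frame."""
    g = nx.Graph()
    if isinstance(edge_list, pd.DataFrame):
        rows = edge_list.itertuples(index=False)
    else:
        rows = edge_list
    for row in rows:
        a, b = row[0], row[1]
        w = float(row[2]) if len(row) > 2 else 1.0
        g.add_edge(a, b, weight=w)
    return g


def hub_genes(edge_list, method: str = "degree", top_k: int = 10) -> list:
    """Rank network hubs by degree or Maximal Clique Centrality (MCC).

    MCC(v) = sum over maximal cliques C containing v of (|C| - 1)!.
    Ties are broken lexicographically by gene id; the ``top_k`` best are
    returned (all nodes when ``top_k`` exceeds the node count).
    """
    g = graph_from_edges(edge_list)
    if g.number_of_edges() == 0:
        raise ValueError("edge list is empty")
    if method == "degree":
        score = {v: g.degree(v) for v in g.nodes}
    elif method == "mcc":
        score = {v: 0.0 for v in g.nodes}
        for clique in nx.find_cliques(g):
            w = math.factorial(len(clique) - 1)
            for v in clique:
                score[v] += w
    else:
        raise ValueError(f"unknown hub method {method!r}")
    ranked = sorted(score, key=lambda v: (-score[v], str(v)))
    return ranked[:top_k]


def to_graphml(edge_list, module_of: pd.Series | None, path) -> None:
    g = graph_from_edges(edge_list)
    if module_of is not None:
        for v in g.nodes:
            g.nodes[v]["module"] = str(module_of.get(v, GREY))
    nx.write_graphml(g, path)
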