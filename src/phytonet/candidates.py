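"""Rule-based candidate-gene screening around guide genes.

A candidate must satisfy three mandatory principles on the co-expression
network: (1) it shares a key hub with a guide gene — some top-ranked hub is
adjacent both to the candidate and to a guide; (2) its shortest-path
distance to the nearest guide is below 4 hops; (3) it co-occurs in a power
node (or across one power edge) with at least one gene strongly correlated
with a guide. Passing genes are then ranked by preference criteria —
carrying a conserved inositol-pathway domain (carbohydrate kinase PfkB
IPR011611, P-loop IPR005337, P-loop NTPase IPR027417) and being
differentially expressed between the high- and low-phytic-acid lines —
then by guide distance, guide correlation, and gene id.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .coexpression import graph_from_edges, hub_genes
from .powergraph import PowerGraph

log = logging.getLogger(__name__)

PREFERRED_DOMAINS = frozenset({"IPR011611", "IPR005337", "IPR027417"})
DISTANCE_MAX = 4  # exclusive: guide distance must be < 4
#: description keywords that mark additional pathway-related genes
GUIDE_KEYWORDS = ("inositol", "phytic", "phytate", "phosphatidylinositol")


@dataclass
class AnnotationTable:
    """Total lookups: an unannotated gene has no domains and empty text."""

    domains: dict = field(default_factory=dict)  # gene -> set of InterPro ids
    tf_family: dict = field(default_factory=dict)
    description: dict = field(default_factory=dict)

    def domains_of(self, gene) -> set:
        return set(self.domains.get(gene, ()))

    @classmethod
    def from_tsv(cls, path) -> "AnnotationTable":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        domains, tf, desc = {}, {}, {}
        for row in df.itertuples(index=False):
            gid = row.gene_id
            if getattr(row, "interpro_ids", ""):
                domains[gid] = set(row.interpro_ids.split(";"))
            if getattr(row, "tf_family", ""):
                tf[gid] = row.tf_family
            if getattr(row, "description", ""):
                desc[gid] = row.description
        return cls(domains, tf, desc)

    def keyword_genes(self, keywords=GUIDE_KEYWORDS) -> set:
        hits = set()
        for gene, text in self.description.items():
            low = text.lower()
            if any(k in low for k in keywords):
                hits.add(gene)
        return hits


@dataclass
class CandidateReport:
    gene: str
    min_guide_distance: float
    shared_hub: bool
    hub_id: str | None
    in_power_node_with_guide_correlates: bool
    preferred_domain_hits: tuple
    is_de: bool
    passes_mandatory: bool
    max_guide_correlation: float
    rank: int | None = None

    @property
    def bonus(self) -> int:
        return int(bool(self.preferred_domain_hits)) + int(self.is_de)


def graph_distances(edge_list, sources) -> dict:
    """Minimum hop distance from each gene to the nearest source gene.

    Unreachable genes map to ``math.inf``.
    """
    sources = list(sources)
    if not sources:
        raise ValueError("source gene set is empty")
    g = graph_from_edges(edge_list)
    present = [s for s in sources if s in g]
    dist = {v: math.inf for v in g.nodes}
    if present:
        for v, d in nx.multi_source_dijkstra_path_length(g, present, weight=None).items():
            dist[v] = float(d)
    return dist


def _guide_correlated(g: nx.Graph, guides: set, threshold: float) -> set:
    """Non-guide genes connected to a guide by an edge heavier than the
    network export threshold."""
    out = set()
    for guide in guides:
        if guide not in g:
            continue
        for nb, attrs in g[guide].items():
            if nb not in guides and attrs.get("weight", 1.0) > threshold:
                out.add(nb)
    return out


def screen_candidates(
    edge_list,
    pg: PowerGraph,
    guides,
    annotations: AnnotationTable | None = None,
    de_flags=None,
    hubs: list | None = None,
    preferred_domains=PREFERRED_DOMAINS,
    distance_max: float = DISTANCE_MAX,
    correlation_threshold: float = 0.5,
    top_hubs: int = 10,
    hub_method: str = "degree",
) -> list[CandidateReport]:
    """Screen every non-guide network gene against the three mandatory
    principles and rank the passing genes.

    ``guides`` is a mapping gene -> role (or an iterable of gene ids);
    ``de_flags`` maps gene -> bool; ``hubs`` is a precomputed ranked hub
    list (computed here with ``hub_method`` / ``top_hubs`` when omitted).
    Returned reports are ordered: ranked passing genes first (rank 1 is the
    best candidate), then non-passing genes by id.
    """
    g = graph_from_edges(edge_list)
    guide_set = set(guides)
    missing = guide_set - set(g.nodes)
    if missing:
        log.warning("guide genes absent from the network: %s", sorted(missing))
        guide_set -= missing
    if not guide_set:
        raise ValueError("no guide gene is present in the network")
    annotations = annotations or AnnotationTable()
    de_flags = dict(de_flags or {})

    for pid, members in pg.power_nodes.items():
        stray = set(members) - set(g.nodes)
        if stray:
            raise ValueError(
                f"power node {pid} contains genes absent from the edge list: {sorted(map(str, stray))[:5]}")

    if hubs is None:
        hubs = hub_genes(edge_list, method=hub_method, top_k=top_hubs)
    hub_set = [h for h in hubs]
    dist = graph_distances(edge_list, guide_set)
    correlated = _guide_correlated(g, guide_set, correlation_threshold)

    # power-node / power-edge co-membership pools
    pools: list[set] = [set(s) for s in pg.power_nodes.values() if len(s) > 1]
    for pa, pb in pg.power_edges:
        pools.append(set(pg.power_nodes[pa]) | set(pg.power_nodes[pb]))

    reports = []
    for gene in g.nodes:
        if gene in guide_set:
            continue
        hub_id = None
        for h in hub_set:
            if h in g and gene in g[h] and (h in guide_set or any(x in guide_set for x in g[h])):
                hub_id = h
                break
        shared_hub = hub_id is not None
        in_pn = any(gene in pool and (pool & correlated) - {gene} for pool in pools)
        d = dist.get(gene, math.inf)
        passes = bool(shared_hub and d < distance_max and in_pn)
        dom_hits = tuple(sorted(annotations.domains_of(gene) & set(preferred_domains)))
        max_corr = max(
            (g[gene][gu].get("weight", 1.0) for gu in guide_set if gu in g and gene in g[gu]),
            default=0.0,
        )
        reports.append(CandidateReport(
            gene=gene, min_guide_distance=d, shared_hub=shared_hub, hub_id=hub_id,
            in_power_node_with_guide_correlates=in_pn,
            preferred_domain_hits=dom_hits, is_de=bool(de_flags.get(gene, False)),
            passes_mandatory=passes, max_guide_correlation=float(max_corr),
        ))

    passing = [r for r in reports if r.passes_mandatory]
    passing.sort(key=lambda r: (-r.bonus, r.min_guide_distance, -r.max_guide_correlation, str(r.gene)))
    for i, r in enumerate(passing):
        r.rank = i + 1
    rest = sorted((r for r in reports if not r.passes_mandatory), key=lambda r: str(r.gene))
    return passing + rest


def reports_frame(reports: list[CandidateReport]) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene": r.gene, "rank": r.rank, "passes_mandatory": r.passes_mandatory,
        "min_guide_distance": r.min_guide_distance, "shared_hub": r.shared_hub,
        "hub_id": r.hub_id,
        "in_power_node_with_guide_correlates": r.in_power_node_with_guide_correlates,
        "preferred_domain_hits": ";".join(r.preferred_domain_hits),
        "is_de": r.is_de, "max_guide_correlation": r.max_guide_correlation,
    } for r in reports])
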