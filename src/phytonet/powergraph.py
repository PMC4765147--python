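"""Lossless power-graph compression of undirected networks.

A power graph abstracts a network by grouping nodes into *power nodes*
(node sets) and replacing all edges between two sets — or within one set,
a clique — by a single *power edge*. Decompression expands every power
edge back to the exact original edge set, so the abstraction is lossless;
the fraction of original edges eliminated is the compression ratio.

Compression here is a deterministic greedy edge-coverage heuristic:
candidate node sets come from average-linkage clustering of neighborhood
Jaccard similarity, and the candidate power edge abstracting the most
not-yet-covered edges is committed repeatedly (subject to laminarity of
the committed sets) until no candidate abstracts at least two edges.
Exact minimum power-graph construction is NP-hard; the greedy heuristic is
the standard practical choice.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform


def _edge(a, b) -> frozenset:
    if a == b:
        raise ValueError(f"self-loop on node {a!r} is not allowed")
    return frozenset((a, b))


def _set_key(s: frozenset) -> tuple:
    return tuple(sorted(str(x) for x in s))


@dataclass
class PowerGraph:
    """Power nodes (laminar family of node sets), power edges, residuals."""

    power_nodes: dict[str, frozenset] = field(default_factory=dict)
    power_edges: list[tuple[str, str]] = field(default_factory=list)
    residual_edges: list[tuple] = field(default_factory=list)
    n_original_edges: int = 0

    def node_set(self, pid: str) -> frozenset:
        return self.power_nodes[pid]

    def to_json(self, path) -> None:
        data = {
            "power_nodes": {pid: sorted(map(str, s)) for pid, s in self.power_nodes.items()},
            "power_edges": [list(e) for e in self.power_edges],
            "residual_edges": [sorted(map(str, e)) for e in self.residual_edges],
            "n_original_edges": self.n_original_edges,
            "compression_ratio": compression_ratio(self) if self.n_original_edges else None,
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PowerGraph":
        with open(path) as fh:
            data = json.load(fh)
        return cls(
            power_nodes={pid: frozenset(s) for pid, s in data["power_nodes"].items()},
            power_edges=[tuple(e) for e in data["power_edges"]],
            residual_edges=[tuple(e) for e in data["residual_edges"]],
            n_original_edges=int(data["n_original_edges"]),
        )


def _is_laminar(s: frozenset, committed: list[frozenset]) -> bool:
    for c in committed:
        inter = s & c
        if inter and not (s <= c or c <= s):
            return False
    return True


def _candidate_sets(nodes: list, adj: dict) -> list[frozenset]:
    """Singletons plus every average-linkage dendrogram branch under the
    Jaccard-of-neighborhoods distance (open and closed neighborhoods both
    considered, so clique members and biclique sides each look alike)."""
    candidates = [frozenset((v,)) for v in nodes]
    n = len(nodes)
    if n < 2:
        return candidates
    d = np.zeros((n, n))
    closed = {v: adj[v] | {v} for v in nodes}
    for i, j in itertools.combinations(range(n), 2):
        u, v = nodes[i], nodes[j]
        j_open = len(adj[u] & adj[v]) / len(adj[u] | adj[v]) if adj[u] | adj[v] else 0.0
        j_closed = len(closed[u] & closed[v]) / len(closed[u] | closed[v])
        d[i, j] = d[j, i] = 1.0 - max(j_open, j_closed)
    z = linkage(squareform(d, checks=False), method="average")
    members: dict[int, frozenset] = {i: frozenset((nodes[i],)) for i in range(n)}
    for step, (a, b, _, _) in enumerate(z):
        merged = members[int(a)] | members[int(b)]
        members[n + step] = merged
        candidates.append(merged)
    # dedupe preserving order
    seen, out = set(), []
    for s in candidates:
        if s not in seen:
            seen.add(s)
            out.append(s)
    return out


def _coverage(s: frozenset, t: frozenset, uncovered: set) -> list | None:
    """Edges a power edge (s, t) would abstract, or None when invalid."""
    if s is t or s == t:
        pairs = [frozenset(p) for p in itertools.combinations(s, 2)]
    else:
        if s & t:
            return None
        pairs = [frozenset((a, b)) for a in s for b in t]
    if len(pairs) < 2:
        return None
    for p in pairs:
        if p not in uncovered:
            return None
    return pairs


def compress(edge_list, min_degree: int = 0) -> PowerGraph:
    """Greedy lossless power-graph compression of a simple undirected graph.

    ``min_degree`` optionally removes low-connectivity nodes (degree below
    the cutoff) before compression. Deterministic: ties between equally
    covering candidate power edges break on the lexicographically smallest
    gene-set pair.
    """
    edges = []
    seen = set()
    for row in _iter_edges(edge_list):
        e = _edge(row[0], row[1])
        if e not in seen:
            seen.add(e)
            edges.append(e)
    if min_degree > 0:
        while True:
            deg: dict = {}
            for e in edges:
                for v in e:
                    deg[v] = deg.get(v, 0) + 1
            drop = {v for v, d in deg.items() if d < min_degree}
            if not drop:
                break
            edges = [e for e in edges if not (e & drop)]
    if not edges:
        return PowerGraph(n_original_edges=0)

    nodes = sorted({v for e in edges for v in e}, key=str)
    adj: dict = {v: set() for v in nodes}
    for e in edges:
        a, b = tuple(e)
        adj[a].add(b)
        adj[b].add(a)

    candidates = _candidate_sets(nodes, adj)
    uncovered = set(edges)
    committed_sets: list[frozenset] = []
    pg = PowerGraph(n_original_edges=len(edges))
    set_ids: dict[frozenset, str] = {}

    def get_id(s: frozenset) -> str:
        if s not in set_ids:
            set_ids[s] = f"P{len(set_ids)}"
            pg.power_nodes[set_ids[s]] = s
        return set_ids[s]

    while True:
        best = None  # (coverage_size, key, s, t, pairs)
        for i, s in enumerate(candidates):
            # clique power edge on s
            pairs = _coverage(s, s, uncovered)
            if pairs is not None and _is_laminar(s, committed_sets):
                cand = (len(pairs), (_set_key(s), _set_key(s)), s, s, pairs)
                if best is None or (-cand[0], cand[1]) < (-best[0], best[1]):
                    best = cand
            for t in candidates[i + 1:]:
                pairs = _coverage(s, t, uncovered)
                if pairs is None:
                    continue
                if not (_is_laminar(s, committed_sets) and _is_laminar(t, committed_sets)
                        and _is_laminar(s, [t])):
                    continue
                key = tuple(sorted((_set_key(s), _set_key(t))))
                cand = (len(pairs), key, s, t, pairs)
                if best is None or (-cand[0], cand[1]) < (-best[0], best[1]):
                    best = cand
        if best is None:
            break
        _, _, s, t, pairs = best
        for new in {s, t}:
            if new not in committed_sets:
                committed_sets.append(new)
        pg.power_edges.append((get_id(s), get_id(t)))
        uncovered -= set(pairs)

    pg.residual_edges = sorted((tuple(sorted(e, key=str)) for e in uncovered),
                               key=lambda e: (str(e[0]), str(e[1])))
    return pg


def _iter_edges(edge_list):
    try:
        import pandas as pd
        if isinstance(edge_list, pd.DataFrame):
            return list(edge_list.itertuples(index=False))
    except ImportError:  # pragma: no cover
        pass
    return list(edge_list)


def decompress(pg: PowerGraph) -> set:
    """Expand a power graph back to its plain edge set (of frozenset pairs)."""
    fam = list(pg.power_nodes.values())
    for a, b in itertools.combinations(fam, 2):
        if (a & b) and not (a <= b or b <= a):
            raise ValueError("power-node hierarchy is not laminar")
    edges: set = set()
    for pa, pb in pg.power_edges:
        s, t = pg.power_nodes[pa], pg.power_nodes[pb]
        if pa == pb or s == t:
            edges.update(frozenset(p) for p in itertools.combinations(s, 2))
        else:
            if s & t:
                raise ValueError(f"power edge ({pa}, {pb}) joins overlapping sets")
            edges.update(frozenset((a, b)) for a in s for b in t)
    edges.update(frozenset(e) for e in pg.residual_edges)
    return edges


def compression_ratio(pg: PowerGraph) -> float:
    """Fraction of original edges eliminated:
    1 - (#power edges + #residual edges) / #original edges."""
    if pg.n_original_edges == 0:
        raise ValueError("compression ratio undefined for an empty graph")
    return 1.0 - (len(pg.power_edges) + len(pg.residual_edges)) / pg.n_original_edges


def gene_power_nodes(pg: PowerGraph) -> dict:
    """gene -> list of power-node ids containing it."""
    out: dict = {}
    for pid, s in pg.power_nodes.items():
        for v in s:
            out.setdefault(v, []).append(pid)
    return out
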