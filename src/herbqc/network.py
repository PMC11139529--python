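"""Target intersection, PPI centralities, median screening, enrichment.

Six node-centrality measures are computed on an undirected simple graph:
degree (DC), closeness (CC), betweenness (BC), eigenvector (EC), local
average connectivity (LAC), and an edge-clustering-based network
centrality (NC).  Core nodes are those at or above the per-measure median
for every measure simultaneously.

A generic hypergeometric over-representation test with Benjamini-Hochberg
adjustment stands in for web-based enrichment services.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TargetSet",
    "InteractionNetwork",
    "CentralityTable",
    "intersect_targets",
    "centralities",
    "median_screen",
    "mean_degree",
    "ora_enrichment",
    "read_edge_list",
    "read_target_set",
    "read_gmt",
]

CENTRALITY_COLUMNS = ["DC", "CC", "BC", "EC", "LAC", "NC"]


@dataclass(frozen=True)
class TargetSet:
    """A labelled set of case-normalized gene/target symbols."""

    label: str
    ids: frozenset[str]

    @classmethod
    def from_iterable(cls, label: str, ids: Iterable[str]) -> "TargetSet":
        return cls(label, frozenset(str(i).strip().upper() for i in ids if str(i).strip()))

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class InteractionNetwork:
    """Undirected simple graph over target symbols."""

    nodes: set[str]
    edges: set[frozenset[str]]

    def __post_init__(self) -> None:
        clean: set[frozenset[str]] = set()
        for edge in self.edges:
            pair = frozenset(edge)
            if len(pair) != 2:
                raise ValueError(f"self-loop or malformed edge: {set(edge)}")
            if not pair <= self.nodes:
                raise ValueError(f"edge endpoint outside node set: {set(edge)}")
            clean.add(pair)
        self.edges = clean

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str]], nodes: Iterable[str] | None = None
    ) -> "InteractionNetwork":
        edge_set = {frozenset((str(a), str(b))) for a, b in edges}
        node_set = set(nodes) if nodes is not None else set()
        for edge in edge_set:
            node_set |= set(edge)
        return cls(node_set, edge_set)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        g.add_edges_from(tuple(sorted(e)) for e in self.edges)
        return g

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class CentralityTable:
    """Per-node centralities plus the per-measure median thresholds."""

    values: pd.DataFrame  # index: node, columns: CENTRALITY_COLUMNS
    medians: pd.Series

    def threshold_report(self) -> dict[str, float]:
        return {m: float(self.medians[m]) for m in CENTRALITY_COLUMNS}


def intersect_targets(a: TargetSet, b: TargetSet) -> TargetSet:
    """Shared symbols of two target sets."""
    return TargetSet(label=f"{a.label}&{b.label}", ids=a.ids & b.ids)


def mean_degree(net: InteractionNetwork) -> float:
    """Average node degree, 2|E| / |V|."""
    if net.n_nodes == 0:
        raise ValueError("empty graph")
    return 2.0 * net.n_edges / net.n_nodes


def _eigenvector_centrality(g: nx.Graph, order: list[str]) -> np.ndarray:
    # Power iteration on A + I from a uniform start: deterministic,
    # converges to a non-negative principal eigenvector (Perron vector on
    # connected graphs), unit Euclidean norm.
    a = nx.to_numpy_array(g, nodelist=order)
    n = len(order)
    if n == 0:
        raise ValueError("empty graph")
    shifted = a + np.eye(n)
    v = np.full(n, 1.0 / np.sqrt(n))
    for _ in range(10000):
        nxt = shifted @ v
        norm = np.linalg.norm(nxt)
        if norm == 0:
            break
        nxt /= norm
        if np.linalg.norm(nxt - v) < 1e-13:
            v = nxt
            break
        v = nxt
    return np.clip(v, 0.0, None) / np.linalg.norm(np.clip(v, 0.0, None))


def _lac(g: nx.Graph, node: str) -> float:
    neighbors = list(g.neighbors(node))
    if not neighbors:
        return 0.0
    sub = g.subgraph(neighbors)
    return sum(dict(sub.degree()).values()) / len(neighbors)


def _nc(g: nx.Graph, node: str) -> float:
    total = 0.0
    dv = g.degree(node)
    nv = set(g.neighbors(node))
    for u in nv:
        denom = min(dv - 1, g.degree(u) - 1)
        if denom <= 0:
            continue
        triangles = len(nv & set(g.neighbors(u)))
        total += triangles / denom
    return total


def centralities(net: InteractionNetwork) -> CentralityTable:
    """All six centrality measures for every node.

    Closeness is computed within each connected component with the
    (n_component - 1) convention; betweenness is unnormalized with each
    unordered pair counted once.
    """
    if net.n_nodes == 0:
        raise ValueError("empty graph")
    g = net.to_networkx()
    order = sorted(net.nodes)
    dc = dict(g.degree())
    cc = nx.closeness_centrality(g, wf_improved=False)
    bc = nx.betweenness_centrality(g, normalized=False)
    ec = dict(zip(order, _eigenvector_centrality(g, order)))
    table = pd.DataFrame(
        {
            "DC": [dc[n] for n in order],
            "CC": [cc[n] for n in order],
            "BC": [bc[n] for n in order],
            "EC": [ec[n] for n in order],
            "LAC": [_lac(g, n) for n in order],
            "NC": [_nc(g, n) for n in order],
        },
        index=pd.Index(order, name="node"),
    )
    return CentralityTable(values=table, medians=table.median())


def median_screen(
    table: CentralityTable, rounds: int = 1, net: InteractionNetwork | None = None
) -> set[str]:
    """Nodes at or above the median of every measure (inclusive).

    With ``rounds > 1`` the screen is re-applied to the induced subgraph of
    the survivors; that requires the originating network.
    """
    if len(table.values) < 2:
        raise ValueError("screening needs at least two nodes")
    survivors = set(
        table.values.index[(table.values >= table.medians).all(axis=1)]
    )
    if rounds > 1:
        if net is None:
            raise ValueError("iterated screening requires the network")
        for _ in range(rounds - 1):
            if len(survivors) < 2:
                break
            sub = InteractionNetwork(
                nodes=set(survivors),
                edges={e for e in net.edges if e <= survivors},
            )
            survivors = median_screen(centralities(sub))
    return survivors


def ora_enrichment(
    query: TargetSet | Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    The upper-tail p-value P(X >= overlap) is computed against a universe of
    size N with K = |set & universe| successes and n = |query| draws, then
    adjusted across sets by Benjamini-Hochberg.  Returns a frame with
    columns ``set, set_size, overlap, p_value, p_adjusted`` sorted by
    p-value.
    """
    universe_set = {str(u).strip().upper() for u in universe}
    if not universe_set:
        raise ValueError("empty universe")
    query_ids = query.ids if isinstance(query, TargetSet) else frozenset(
        str(q).strip().upper() for q in query
    )
    if not query_ids <= universe_set:
        raise ValueError("query contains symbols outside the universe")
    n_universe = len(universe_set)
    n_query = len(query_ids)
    rows = []
    for name, members in gene_sets.items():
        member_set = {str(m).strip().upper() for m in members} & universe_set
        if not member_set:
            raise ValueError(f"gene set {name!r} has no overlap with the universe")
        overlap = len(query_ids & member_set)
        p = float(
            stats.hypergeom.sf(overlap - 1, n_universe, len(member_set), n_query)
        )
        rows.append(
            {"set": name, "set_size": len(member_set), "overlap": overlap, "p_value": p}
        )
    frame = pd.DataFrame(rows)
    frame["p_adjusted"] = _benjamini_hochberg(frame["p_value"].to_numpy())
    return frame.sort_values("p_value", kind="stable").reset_index(drop=True)


def _benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    m = len(pvalues)
    order = np.argsort(pvalues)
    ranked = pvalues[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downward
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adjusted, 0.0, 1.0)
    return out


def read_edge_list(path) -> InteractionNetwork:
    """Two whitespace-separated symbols per line; '#' lines are comments."""
    edges = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"malformed edge line: {line!r}")
            edges.append((parts[0], parts[1]))
    return InteractionNetwork.from_edges(edges)


def read_target_set(path, label: str | None = None) -> TargetSet:
    """One symbol per line."""
    with open(path) as handle:
        ids = [line.strip() for line in handle if line.strip()]
    return TargetSet.from_iterable(label or str(path), ids)


def read_gmt(path) -> dict[str, set[str]]:
    """GMT format: name <TAB> description <TAB> gene symbols..."""
    sets: dict[str, set[str]] = {}
    with open(path) as handle:
        for line in handle:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = {g.strip().upper() for g in parts[2:] if g.strip()}
    return sets
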