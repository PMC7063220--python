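"""Tripartite herb-compound-target networks and centrality ranking.

One network is built per pathological module: herbs connect to the active
compounds attributed to them, compounds connect to the module's candidate
targets they act on.  Networks are undirected and unweighted.  Node
importance is ranked by degree (incident-edge count) and betweenness
(fraction of all-pairs shortest paths passing through the node, Brandes'
algorithm with fractional credit for tied paths).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

NODE_HERB = "herb"
NODE_COMPOUND = "compound"
NODE_TARGET = "target"
NODE_TYPES = (NODE_HERB, NODE_COMPOUND, NODE_TARGET)

#: column labels used by herb_contribution
HEMO = "hemorheology"
COAG = "coagulopathy"

#: edge types a tripartite herb-compound-target map may contain
_ALLOWED_EDGES = {
    frozenset({NODE_HERB, NODE_COMPOUND}),
    frozenset({NODE_COMPOUND, NODE_TARGET}),
}


class NetworkIntegrityError(ValueError):
    """An edge references an undeclared endpoint or violates tripartiteness."""


@dataclass
class ModuleNetwork:
    """Undirected tripartite graph for one pathological module."""

    module_name: str
    graph: nx.Graph

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes_of_type(self, node_type: str) -> list[str]:
        return sorted(
            n for n, t in self.graph.nodes(data="node_type") if t == node_type
        )

    def counts(self) -> dict[str, int]:
        out = {t: len(self.nodes_of_type(t)) for t in NODE_TYPES}
        out["nodes"] = self.n_nodes
        out["edges"] = self.n_edges
        return out


def build_network(
    module_name: str,
    herbs: Iterable[str],
    compounds: Iterable[str],
    targets: Iterable[str],
    attribution_edges: Iterable[tuple[str, str]],
    interaction_edges: Iterable[tuple[str, str]],
    prune_isolated: bool = False,
) -> ModuleNetwork:
    """Assemble a herb-compound-target network for one module.

    ``attribution_edges`` are (herb, compound) pairs, ``interaction_edges``
    are (compound, target) pairs.  Every endpoint must be declared in the
    corresponding node list; node identifiers must be unique across the
    three types.  With ``prune_isolated``, zero-degree nodes are dropped
    after assembly.
    """
    herbs, compounds, targets = list(herbs), list(compounds), list(targets)
    declared: dict[str, str] = {}
    for nodes, ntype in ((herbs, NODE_HERB), (compounds, NODE_COMPOUND), (targets, NODE_TARGET)):
        for n in nodes:
            if n in declared:
                raise NetworkIntegrityError(
                    f"node id {n!r} declared as both {declared[n]} and {ntype}"
                )
            declared[n] = ntype
    g = nx.Graph(module_name=module_name)
    for n, t in declared.items():
        g.add_node(n, node_type=t)
    for edges, expected in (
        (attribution_edges, (NODE_HERB, NODE_COMPOUND)),
        (interaction_edges, (NODE_COMPOUND, NODE_TARGET)),
    ):
        for u, v in edges:
            for endpoint in (u, v):
                if endpoint not in declared:
                    raise NetworkIntegrityError(f"edge endpoint {endpoint!r} not declared")
            if (declared[u], declared[v]) != expected:
                raise NetworkIntegrityError(
                    f"edge ({u!r}, {v!r}) has types ({declared[u]}, {declared[v]}); "
                    f"expected {expected}"
                )
            if frozenset({declared[u], declared[v]}) not in _ALLOWED_EDGES:
                raise NetworkIntegrityError(
                    f"forbidden edge type {declared[u]}-{declared[v]}"
                )
            g.add_edge(u, v)
    if prune_isolated:
        g.remove_nodes_from(list(nx.isolates(g)))
    return ModuleNetwork(module_name, g)


def centrality_table(net: ModuleNetwork, normalized: bool = True) -> pd.DataFrame:
    """Degree and betweenness centrality of every node.

    Columns: ``node``, ``node_type``, ``degree`` (all incident edges, i.e.
    for a compound its herb attributions plus target interactions),
    ``target_degree`` (neighbours of type target; the compound-only
    counting), ``betweenness``.  Normalized betweenness divides the raw
    Brandes accumulation by ``(n-1)(n-2)/2`` with n the node count of the
    whole network; unreachable pairs contribute zero.
    """
    g = net.graph
    bet = nx.betweenness_centrality(g, normalized=normalized)
    rows = []
    for n, ntype in g.nodes(data="node_type"):
        tdeg = sum(
            1 for nb in g.neighbors(n) if g.nodes[nb]["node_type"] == NODE_TARGET
        )
        rows.append(
            {
                "node": n,
                "node_type": ntype,
                "degree": g.degree(n),
                "target_degree": tdeg,
                "betweenness": bet[n],
            }
        )
    return pd.DataFrame(rows, columns=["node", "node_type", "degree", "target_degree", "betweenness"])


def degree_centrality(net: ModuleNetwork) -> pd.DataFrame:
    """Degree-only view of :func:`centrality_table` (handshake: sum = 2|E|)."""
    g = net.graph
    rows = [
        {"node": n, "node_type": t, "degree": g.degree(n)}
        for n, t in g.nodes(data="node_type")
    ]
    return pd.DataFrame(rows, columns=["node", "node_type", "degree"])


def betweenness_centrality(net: ModuleNetwork, normalized: bool = True) -> pd.DataFrame:
    """Betweenness-only view of :func:`centrality_table`."""
    bet = nx.betweenness_centrality(net.graph, normalized=normalized)
    rows = [
        {"node": n, "node_type": t, "betweenness": bet[n]}
        for n, t in net.graph.nodes(data="node_type")
    ]
    return pd.DataFrame(rows, columns=["node", "node_type", "betweenness"])


def rank_top_k(
    table: pd.DataFrame,
    metric: str = "degree",
    k: int = 10,
    node_type: str | None = None,
) -> pd.DataFrame:
    """Top-k nodes by a centrality metric with a deterministic tie rule.

    Sorts descending by ``metric``, breaking ties by the secondary metric
    (betweenness when ranking by degree and vice versa, if present)
    descending, then node id lexicographic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if metric not in table.columns:
        raise ValueError(f"metric {metric!r} not in table")
    df = table if node_type is None else table[table["node_type"] == node_type]
    if df.empty:
        return df.copy()
    secondary = {"degree": "betweenness", "betweenness": "degree"}.get(metric)
    by, asc = [metric], [False]
    if secondary and secondary in df.columns:
        by.append(secondary)
        asc.append(False)
    by.append("node")
    asc.append(True)
    return df.sort_values(by, ascending=asc, kind="mergesort").head(k).reset_index(drop=True)


@dataclass(frozen=True)
class OverlapSummary:
    """Inclusion-exclusion summary of two sets (e.g. the module target sets)."""

    size_a: int
    size_b: int
    size_union: int
    size_intersection: int
    members_intersection: frozenset[str] | None = None

    def __post_init__(self):
        ok = (
            self.size_intersection == self.size_a + self.size_b - self.size_union
            and 0 <= self.size_intersection <= min(self.size_a, self.size_b)
            and self.size_union >= max(self.size_a, self.size_b)
        )
        if not ok:
            raise ValueError(
                f"inconsistent overlap sizes: |A|={self.size_a}, |B|={self.size_b}, "
                f"|A∪B|={self.size_union}, |A∩B|={self.size_intersection}"
            )


def overlap(set_a, set_b, union_size: int | None = None) -> OverlapSummary:
    """Overlap of two collections, by membership or by size arithmetic.

    Membership mode: ``set_a``/``set_b`` are iterables of members; sizes and
    intersection members are computed directly.  Size-only mode: both
    arguments are integers and ``union_size`` (|A∪B|) is required; the
    intersection follows by inclusion-exclusion, and inconsistent sizes
    raise.
    """
    if isinstance(set_a, int) and isinstance(set_b, int):
        if union_size is None:
            raise ValueError("size-only mode requires union_size")
        inter = set_a + set_b - union_size
        return OverlapSummary(set_a, set_b, union_size, inter)
    a, b = frozenset(set_a), frozenset(set_b)
    inter = a & b
    return OverlapSummary(len(a), len(b), len(a | b), len(inter), inter)


def herb_contribution(
    net_hemo: ModuleNetwork,
    net_coag: ModuleNetwork,
    herb_ids_by_compound: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Per-herb counts of attributed active compounds, overall and per module.

    A compound attributed to m herbs counts once for each of them.  The
    module count of a herb is the number of its compounds present in that
    module's network, so it never exceeds the herb's total.
    """
    in_hemo = set(net_hemo.nodes_of_type(NODE_COMPOUND))
    in_coag = set(net_coag.nodes_of_type(NODE_COMPOUND))
    rows: dict[str, dict[str, int]] = {}
    for cid, herbs in herb_ids_by_compound.items():
        for h in herbs:
            row = rows.setdefault(h, {"total": 0, HEMO: 0, COAG: 0})
            row["total"] += 1
            if cid in in_hemo:
                row[HEMO] += 1
            if cid in in_coag:
                row[COAG] += 1
    df = pd.DataFrame(
        [
            {"herb": h, "total": r["total"], HEMO: r[HEMO], COAG: r[COAG]}
            for h, r in sorted(rows.items())
        ],
        columns=["herb", "total", HEMO, COAG],
    )
    return df


def export_sif(net: ModuleNetwork, path) -> None:
    """Write the network as SIF: ``nodeA<TAB>interaction<TAB>nodeB``."""
    g = net.graph
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in sorted(map(sorted, g.edges())):
            tu, tv = g.nodes[u]["node_type"], g.nodes[v]["node_type"]
            kind = "attribution" if NODE_HERB in (tu, tv) else "interaction"
            fh.write(f"{u}\t{kind}\t{v}\n")


def export_graphml(net: ModuleNetwork, path) -> None:
    """Write the network as GraphML with the node-type attribute."""
    nx.write_graphml(net.graph, path)
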