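"""Signed hooligan-network construction, layout, and export.

Nodes are clubs with at least one recorded incident against a head; node
size grows with total incidents.  Edges connect a head to each club it has
incidents with; edge strength grows with the incident sum and is rendered as
an inverse distance (hostile pairs sit close together).  Each head anchors a
cluster; a club belongs to the cluster of the head it co-occurs with most.
The per-edge *relevance score* is the head-conditional incident share: the
fraction of a head's incidents that involve this club, so a head's scores
sum to one and the largest score marks the opponent most likely to co-occur
in violence with that head.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .incidents import MatchIncidentRecord
from .relations import (
    ALLIANCE,
    CLASH,
    COUP,
    ENEMY,
    FRIEND,
    PEER,
    RIVALRY,
    SPLIT,
    UNDEFINED,
    AssumedRelation,
    UnderlyingRelation,
)


@dataclass(frozen=True)
class NodeScaling:
    """Affine map of log(1 + total incidents) onto a size range.

    The log keeps the heavy upper tail of incident totals from swamping the
    visual scale; only the ordering of sizes is contractual.
    """

    size_min: float = 1.0
    size_max: float = 10.0


@dataclass
class HooliganNetwork:
    """Signed incident network around a set of head clubs."""

    graph: nx.Graph
    heads: tuple[str, ...]
    partitions: dict[str, int]  # club -> 1-based cluster id
    assumed_relations: tuple[AssumedRelation, ...] = ()

    @property
    def clubs(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_non_head_nodes(self) -> int:
        return sum(1 for n in self.graph.nodes if n not in self.heads)


@dataclass(frozen=True)
class AffinitySubnetwork:
    head_a: str
    head_b: str
    affinity_class: str
    member_clubs: tuple[str, ...]
    provenance: str  # inferred | assumed


def build_network(
    records: Sequence[MatchIncidentRecord],
    heads: Sequence[str],
    relations: Mapping[tuple[str, str], UnderlyingRelation] | None = None,
    scaling: NodeScaling = NodeScaling(),
    assumed_relations: Sequence[AssumedRelation] = (),
) -> HooliganNetwork:
    """Build the incident network: an edge per (head, club) with >= 1 incident.

    Clubs whose matches against every head were incident-free contribute no
    node and no edge.  Node attributes: ``total_incidents``,
    ``n_matches_with_incidents``, ``size``.  Edge attributes:
    ``incident_sum``, ``match_count``, ``relevance``, ``length``.
    """
    heads = tuple(heads)
    head_set = set(heads)
    # (head, club) -> [incident_sum, match_count, matches_with_incidents]
    edge_stats: dict[tuple[str, str], list[int]] = {}
    for r in records:
        involved = head_set & {r.head_club, r.opponent_club}
        for head in involved:
            other = r.opponent_club if head == r.head_club else r.head_club
            if other in head_set and other < head:
                continue  # count each head-head pair once
            key = (head, other)
            st = edge_stats.setdefault(key, [0, 0, 0])
            st[0] += r.incident_count
            st[1] += 1
            st[2] += 1 if r.incident_count > 0 else 0

    g = nx.Graph()
    node_totals: dict[str, int] = {}
    node_hits: dict[str, int] = {}
    for (head, other), (inc, matches, hits) in edge_stats.items():
        if inc < 1:
            continue  # edges exist only where at least one incident occurred
        g.add_edge(head, other, incident_sum=inc, match_count=matches,
                   length=1.0 / (1.0 + inc))
        for club in (head, other):
            node_totals[club] = node_totals.get(club, 0) + inc
            node_hits[club] = node_hits.get(club, 0) + hits
    if not g.number_of_edges():
        import logging

        logging.getLogger(__name__).warning("no incidents: empty network")
    for club in g.nodes:
        g.nodes[club]["total_incidents"] = node_totals[club]
        g.nodes[club]["n_matches_with_incidents"] = node_hits[club]
        g.nodes[club]["is_head"] = club in head_set
    _apply_size_scale(g, scaling)

    head_totals = {
        h: sum(
            g.edges[h, nb]["incident_sum"] for nb in g.neighbors(h)
        )
        for h in heads
        if h in g
    }
    for h in heads:
        if h not in g:
            continue
        for nb in g.neighbors(h):
            g.edges[h, nb]["relevance_" + h] = relevance_score(
                g.edges[h, nb]["incident_sum"], head_totals[h]
            )

    partitions = _assign_partitions(g, heads)
    net = HooliganNetwork(
        graph=g,
        heads=heads,
        partitions=partitions,
        assumed_relations=tuple(assumed_relations),
    )
    if relations:
        for (h, k), rel in relations.items():
            if g.has_edge(h, k):
                g.edges[h, k]["relation_" + h] = rel.label
    return net


def _apply_size_scale(g: nx.Graph, scaling: NodeScaling) -> None:
    if not g.nodes:
        return
    logs = {n: math.log1p(g.nodes[n]["total_incidents"]) for n in g.nodes}
    lo, hi = min(logs.values()), max(logs.values())
    span = hi - lo
    for n in g.nodes:
        frac = 0.5 if span == 0 else (logs[n] - lo) / span
        g.nodes[n]["size"] = scaling.size_min + frac * (
            scaling.size_max - scaling.size_min
        )


def _assign_partitions(g: nx.Graph, heads: Sequence[str]) -> dict[str, int]:
    """Clusters: one per head (1-based, in head order); a club joins the
    cluster of the head it shares the most incidents with (ties: head order)."""
    cluster_of_head = {h: i + 1 for i, h in enumerate(heads)}
    partitions: dict[str, int] = {}
    for node in g.nodes:
        if node in cluster_of_head:
            partitions[node] = cluster_of_head[node]
            continue
        best, best_inc = None, -1
        for h in heads:
            if g.has_edge(h, node) and g.edges[h, node]["incident_sum"] > best_inc:
                best, best_inc = h, g.edges[h, node]["incident_sum"]
        partitions[node] = cluster_of_head[best] if best else 0
    return partitions


def relevance_score(edge_incidents: int, head_total: int) -> float:
    """Share of a head's incidents carried by one edge, in [0, 1]."""
    if head_total <= 0:
        raise ValueError("head total must be positive")
    return edge_incidents / head_total


def shared_enemy_clubs(
    relations: Mapping[tuple[str, str], UnderlyingRelation],
    head_a: str,
    head_b: str,
    network: HooliganNetwork | None = None,
) -> list[str]:
    """Clubs adjacent (hostile) to both heads — the shared-enemy count of a
    head pair.  With relation info, hostility means an inferred rivalry;
    otherwise adjacency in the network (>= 1 incident) is used."""
    if network is not None:
        g = network.graph
        if head_a not in g or head_b not in g:
            return []
        common = set(g.neighbors(head_a)) & set(g.neighbors(head_b))
        return sorted(c for c in common if c not in (head_a, head_b))
    enemies_a = {k for (h, k), r in relations.items()
                 if h == head_a and r.label == RIVALRY}
    enemies_b = {k for (h, k), r in relations.items()
                 if h == head_b and r.label == RIVALRY}
    return sorted((enemies_a & enemies_b) - {head_a, head_b})


# component-label requirements per affinity class (both components equal)
_CLASS_REQUIREMENTS = {
    COUP: (ALLIANCE, RIVALRY),
    PEER: (ALLIANCE, ALLIANCE),
    CLASH: (RIVALRY, RIVALRY),
    SPLIT: (RIVALRY, ALLIANCE),
}


def extract_affinity_subnetwork(
    network: HooliganNetwork,
    relations: Mapping[tuple[str, str], UnderlyingRelation],
    head_a: str,
    head_b: str,
    affinity_class: str,
    assumed_relation: AssumedRelation | None = None,
) -> AffinitySubnetwork:
    """Member clubs of a coup/peer/clash/split subnetwork for a head pair.

    The head-pair relation comes from ``relations`` unless an
    ``assumed_relation`` override is supplied (mandatory when the inferred
    relation is undefined but the requested class needs a definite one);
    provenance is marked accordingly.  Members are exactly the clubs
    adjacent to both heads whose two component relations carry the labels
    the class requires.
    """
    if affinity_class not in _CLASS_REQUIREMENTS:
        raise ValueError(f"unknown affinity class {affinity_class!r}")
    required_head, required_component = _CLASS_REQUIREMENTS[affinity_class]

    provenance = "inferred"
    head_label = UNDEFINED
    rel = relations.get((head_a, head_b)) or relations.get((head_b, head_a))
    if rel is not None:
        head_label = rel.label
    if assumed_relation is not None:
        if {assumed_relation.head_a, assumed_relation.head_b} != {head_a, head_b}:
            raise ValueError("assumed_relation names a different head pair")
        head_label = ALLIANCE if assumed_relation.relation == FRIEND else RIVALRY
        provenance = "assumed"
    if head_label != required_head:
        raise ValueError(
            f"{affinity_class} requires the heads to be in "
            f"{required_head}, but their relation is {head_label} "
            "(supply an assumed_relation override to proceed)"
        )

    g = network.graph
    candidates = (
        (set(g.neighbors(head_a)) & set(g.neighbors(head_b))) - {head_a, head_b}
        if head_a in g and head_b in g
        else set()
    )
    members = []
    for k in sorted(candidates):
        ra = relations.get((head_a, k))
        rb = relations.get((head_b, k))
        if ra is None or rb is None:
            continue
        if ra.label == required_component and rb.label == required_component:
            members.append(k)
    return AffinitySubnetwork(
        head_a=head_a,
        head_b=head_b,
        affinity_class=affinity_class,
        member_clubs=tuple(members),
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# Layout


def layout_circular(
    network: HooliganNetwork,
    relations: Mapping[tuple[str, str], UnderlyingRelation] | None = None,
    layers: int = 2,
    seed: int = 0,
) -> dict[str, tuple[float, float]]:
    """Deterministic circular two-layer placement.

    Heads sit on an inner circle; the angular gap between two heads shrinks
    with their rivalry grade (|statistic|), so strong rivals appear close.
    Each opponent is placed on one of ``layers`` outer rings at the angle of
    a softmax-weighted blend of its adjacent heads' positions, weighted by
    the affinity statistic: if A(a,k) > A(b,k) the club lands nearer head a,
    and equal statistics give an equidistant placement.  The same seed and
    network always give identical coordinates (the construction is in fact
    seed-free; the argument is accepted for interface stability).
    """
    g = network.graph
    if g.number_of_nodes() == 0:
        raise ValueError("cannot lay out an empty network")
    heads = [h for h in network.heads if h in g]
    coords: dict[str, tuple[float, float]] = {}
    r_head = 1.0

    # head angles: start from equal spacing, then shrink gaps between rivals
    m = max(len(heads), 1)
    base = {h: 2 * math.pi * i / m for i, h in enumerate(heads)}
    if relations and len(heads) >= 2:
        # gap between consecutive heads scaled by 1/(1+grade)
        grades = []
        for i, h in enumerate(heads):
            nxt = heads[(i + 1) % len(heads)]
            rel = relations.get((h, nxt)) or relations.get((nxt, h))
            stat = abs(rel.statistic) if rel and rel.statistic else 0.0
            grades.append(1.0 / (1.0 + stat))
        total = sum(grades)
        angle = 0.0
        for i, h in enumerate(heads):
            base[h] = angle
            angle += 2 * math.pi * grades[i] / total
    for h in heads:
        coords[h] = (r_head * math.cos(base[h]), r_head * math.sin(base[h]))

    others = sorted(n for n in g.nodes if n not in heads)
    for idx, club in enumerate(others):
        ring = 1.6 + 0.5 * (idx % max(layers, 1))
        adj = [h for h in heads if g.has_edge(h, club)]
        if not adj:
            theta = 2 * math.pi * idx / max(len(others), 1)
            coords[club] = (ring * math.cos(theta), ring * math.sin(theta))
            continue
        weights = _affinity_weights(club, adj, relations, g)
        px = sum(w * coords[h][0] for h, w in zip(adj, weights))
        py = sum(w * coords[h][1] for h, w in zip(adj, weights))
        norm = math.hypot(px, py)
        if norm < 1e-12:
            theta = sum(base[h] for h in adj) / len(adj)
            px, py = math.cos(theta), math.sin(theta)
            norm = 1.0
        coords[club] = (ring * px / norm, ring * py / norm)
    return coords


def _affinity_weights(club, adj_heads, relations, g) -> list[float]:
    """Softmax weights over adjacent heads from affinity statistics
    (falling back to incident sums when no relations are supplied)."""
    scores = []
    for h in adj_heads:
        rel = relations.get((h, club)) if relations else None
        if rel is not None and rel.statistic is not None:
            scores.append(rel.statistic)
        else:
            scores.append(math.log1p(g.edges[h, club]["incident_sum"]))
    mx = max(scores)
    exps = [math.exp(s - mx) for s in scores]
    total = sum(exps)
    return [e / total for e in exps]


# ---------------------------------------------------------------------------
# Export / import


def export_network(network: HooliganNetwork, fmt: str, path) -> list[str]:
    """Write the network to ``pajek_net_clu``, ``graphml`` or ``edge_csv``.

    Pajek export produces a ``.net`` (vertices with sizes, edges with
    weights; 1-based vertex numbering) plus a ``.clu`` partition file with
    1-based cluster ids.  Returns the paths written.
    """
    path = str(path)
    if fmt == "pajek_net_clu":
        net_path = path if path.endswith(".net") else path + ".net"
        clu_path = net_path[:-4] + ".clu"
        _write_pajek(network, net_path, clu_path)
        return [net_path, clu_path]
    if fmt == "graphml":
        g = network.graph.copy()
        for n in g.nodes:
            g.nodes[n]["cluster"] = network.partitions.get(n, 0)
        nx.write_graphml(g, path)
        return [path]
    if fmt == "edge_csv":
        rows = [
            {"club_a": u, "club_b": v, **{k: d[k] for k in sorted(d)}}
            for u, v, d in sorted(network.graph.edges(data=True))
        ]
        pd.DataFrame(rows).to_csv(path, index=False)
        return [path]
    raise ValueError(f"unknown export format {fmt!r}")


def _write_pajek(network: HooliganNetwork, net_path: str, clu_path: str) -> None:
    g = network.graph
    nodes = sorted(g.nodes)
    index = {n: i + 1 for i, n in enumerate(nodes)}
    with open(net_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("% hoolinet pajek dialect: vertex 'id \"label\" size', 1-based\n")
        fh.write(f"*Vertices {len(nodes)}\n")
        for n in nodes:
            fh.write(f'{index[n]} "{n}" {g.nodes[n]["size"]:.6f}\n')
        fh.write("*Edges\n")
        for u, v in sorted(
            (min(index[a], index[b]), max(index[a], index[b]))
            for a, b in g.edges
        ):
            w = g.edges[nodes[u - 1], nodes[v - 1]]["incident_sum"]
            fh.write(f"{u} {v} {w}\n")
    with open(clu_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("% 1-based cluster ids, vertex order as in the .net file\n")
        fh.write(f"*Vertices {len(nodes)}\n")
        for n in nodes:
            fh.write(f"{network.partitions.get(n, 0)}\n")


def import_pajek(net_path, clu_path=None) -> HooliganNetwork:
    """Re-import a Pajek export written by :func:`export_network`.

    Only the fields the dialect carries are restored (labels, sizes, edge
    incident sums, cluster ids); re-exporting gives byte-identical files.
    """
    g = nx.Graph()
    labels: dict[int, str] = {}
    with open(net_path, encoding="utf-8") as fh:
        mode = None
        for line in fh:
            line = line.strip()
            if not line or line.startswith("%"):
                continue
            if line.lower().startswith("*vertices"):
                mode = "vertices"
                continue
            if line.lower().startswith("*edges"):
                mode = "edges"
                continue
            if mode == "vertices":
                idx, rest = line.split(" ", 1)
                label, size = rest.rsplit(" ", 1)
                name = label.strip('"')
                labels[int(idx)] = name
                g.add_node(name, size=float(size))
            elif mode == "edges":
                u, v, w = line.split()
                g.add_edge(labels[int(u)], labels[int(v)],
                           incident_sum=int(w), length=1.0 / (1.0 + int(w)))
    partitions: dict[str, int] = {}
    if clu_path is not None:
        with open(clu_path, encoding="utf-8") as fh:
            ids = [
                int(line)
                for line in (l.strip() for l in fh)
                if line and not line.startswith(("%", "*"))
            ]
        ordered = sorted(g.nodes)
        partitions = dict(zip(ordered, ids))
    # head identity is not carried by the Pajek dialect
    return HooliganNetwork(graph=g, heads=(), partitions=partitions)
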