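"""Network construction, relevance, subnetworks, layout, and export."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from hoolinet import (
    AssumedRelation,
    MatchIncidentRecord,
    build_network,
    export_network,
    extract_affinity_subnetwork,
    import_pajek,
    layout_circular,
    relevance_score,
    shared_enemy_clubs,
)
from hoolinet.network import NodeScaling
from hoolinet.relations import ALLIANCE, CLASH, COUP, RIVALRY, UNDEFINED, UnderlyingRelation


def _rec(head, opp, count):
    return MatchIncidentRecord(head_club=head, opponent_club=opp,
                               incident_count=count)


def _rel(a, b, label, statistic=None):
    return UnderlyingRelation(
        head_a=a, head_b=b, statistic=statistic, df=None,
        p_value=0.01 if label != UNDEFINED else 0.5,
        label=label, tier="strong" if label != UNDEFINED else "none",
    )


@pytest.fixture()
def simple_records():
    return [
        _rec("H1", "H2", 3),
        _rec("H1", "X", 10),
        _rec("H1", "X", 0),
        _rec("H1", "Y", 1),
        _rec("H2", "X", 4),
        _rec("H2", "Z", 0),  # matches but no incidents: no node, no edge
    ]


@pytest.fixture()
def simple_network(simple_records):
    return build_network(simple_records, ("H1", "H2"))


class TestBuildNetwork:
    def test_edges_require_at_least_one_incident(self, simple_network):
        g = simple_network.graph
        assert "Z" not in g
        assert {tuple(sorted(e)) for e in g.edges} == {
            ("H1", "H2"), ("H1", "X"), ("H1", "Y"), ("H2", "X")
        }

    def test_edge_attributes(self, simple_network):
        e = simple_network.graph.edges["H1", "X"]
        assert e["incident_sum"] == 10
        assert e["match_count"] == 2
        assert e["length"] == 1.0 / 11

    def test_node_size_monotone_in_totals(self, simple_network):
        g = simple_network.graph
        totals = {n: g.nodes[n]["total_incidents"] for n in g.nodes}
        sizes = {n: g.nodes[n]["size"] for n in g.nodes}
        for a, b in itertools.combinations(g.nodes, 2):
            if totals[a] < totals[b]:
                assert sizes[a] < sizes[b]

    def test_doubling_counts_preserves_size_ordering(self, simple_records):
        doubled = [
            _rec(r.head_club, r.opponent_club, 2 * r.incident_count)
            for r in simple_records
        ]
        net1 = build_network(simple_records, ("H1", "H2"))
        net2 = build_network(doubled, ("H1", "H2"))
        order = lambda net: sorted(
            net.graph.nodes, key=lambda n: net.graph.nodes[n]["size"]
        )
        assert order(net1) == order(net2)

    def test_partitions_cover_all_nodes(self, simple_network):
        assert set(simple_network.partitions) == set(simple_network.graph.nodes)
        # X has more incidents with H1 (10) than H2 (4) -> H1's cluster
        assert simple_network.partitions["X"] == simple_network.partitions["H1"]

    def test_planted_club_count(self):
        """A fixture built with 72 opponents each having incidents against
        some head yields exactly 72 non-head nodes."""
        records = [
            _rec(f"H{1 + i % 3}", f"club_{i:02d}", 1 + i % 5)
            for i in range(72)
        ]
        net = build_network(records, ("H1", "H2", "H3"))
        assert net.n_non_head_nodes == 72

    def test_empty_network_warns_not_raises(self):
        net = build_network([_rec("H1", "X", 0)], ("H1",))
        assert net.graph.number_of_nodes() == 0


class TestRelevance:
    def test_share_definition(self):
        assert relevance_score(10, 100) == 0.1

    def test_single_edge_head_is_one(self):
        net = build_network([_rec("H1", "X", 7)], ("H1",))
        assert net.graph.edges["H1", "X"]["relevance_H1"] == 1.0

    def test_scores_per_head_sum_to_one(self, simple_network):
        g = simple_network.graph
        for h in ("H1", "H2"):
            total = sum(
                g.edges[h, nb]["relevance_" + h] for nb in g.neighbors(h)
            )
            assert abs(total - 1.0) < 1e-12

    def test_dominant_rival_ranks_first(self):
        records = (
            [_rec("H1", "big", 6)] * 10  # 60% of H1's incidents
            + [_rec("H1", "small_a", 20)]
            + [_rec("H1", "small_b", 20)]
        )
        net = build_network(records, ("H1",))
        g = net.graph
        ranked = sorted(
            g.neighbors("H1"),
            key=lambda nb: g.edges["H1", nb]["relevance_H1"],
            reverse=True,
        )
        assert ranked[0] == "big"


class TestSubnetworks:
    @pytest.fixture()
    def coup_setup(self):
        records = [_rec("H1", "H2", 1)]
        rels = {("H1", "H2"): _rel("H1", "H2", UNDEFINED)}
        for i in range(16):
            k = f"club_{i:02d}"
            records += [_rec("H1", k, 2), _rec("H2", k, 2)]
            rels[("H1", k)] = _rel("H1", k, RIVALRY)
            rels[("H2", k)] = _rel("H2", k, RIVALRY)
        # one club hostile to H1 only
        records.append(_rec("H1", "only_one", 3))
        rels[("H1", "only_one")] = _rel("H1", "only_one", RIVALRY)
        net = build_network(records, ("H1", "H2"), rels)
        return net, rels

    def test_coup_with_assumed_friendship(self, coup_setup):
        net, rels = coup_setup
        sub = extract_affinity_subnetwork(
            net, rels, "H1", "H2", COUP,
            assumed_relation=AssumedRelation("H1", "H2", "friend"),
        )
        assert len(sub.member_clubs) == 16
        assert sub.provenance == "assumed"
        assert "only_one" not in sub.member_clubs

    def test_coup_without_override_is_contract_error(self, coup_setup):
        net, rels = coup_setup
        with pytest.raises(ValueError, match="assumed_relation"):
            extract_affinity_subnetwork(net, rels, "H1", "H2", COUP)

    def test_club_hostile_to_one_head_excluded_from_clash(self):
        records = [_rec("H1", "H2", 5), _rec("H1", "k", 4), _rec("H2", "k", 1)]
        rels = {
            ("H1", "H2"): _rel("H1", "H2", RIVALRY),
            ("H1", "k"): _rel("H1", "k", RIVALRY),
            ("H2", "k"): _rel("H2", "k", UNDEFINED),
        }
        net = build_network(records, ("H1", "H2"), rels)
        sub = extract_affinity_subnetwork(net, rels, "H1", "H2", CLASH)
        assert sub.member_clubs == ()
        assert sub.provenance == "inferred"

    def test_membership_matches_truth_table_oracle(self):
        """Subnetwork membership equals a brute-force application of the
        affinity taxonomy to every club adjacent to both heads."""
        labels = (RIVALRY, ALLIANCE, UNDEFINED)
        records = [_rec("H1", "H2", 2)]
        rels = {("H1", "H2"): _rel("H1", "H2", RIVALRY)}
        combos = list(itertools.product(labels, labels))
        for i, (la, lb) in enumerate(combos):
            k = f"c{i}"
            records += [_rec("H1", k, 1), _rec("H2", k, 1)]
            rels[("H1", k)] = _rel("H1", k, la)
            rels[("H2", k)] = _rel("H2", k, lb)
        net = build_network(records, ("H1", "H2"), rels)
        sub = extract_affinity_subnetwork(net, rels, "H1", "H2", CLASH)
        oracle = {
            f"c{i}"
            for i, (la, lb) in enumerate(combos)
            if la == RIVALRY and lb == RIVALRY
        }
        assert set(sub.member_clubs) == oracle

    def test_shared_enemy_count(self, coup_setup):
        net, rels = coup_setup
        shared = shared_enemy_clubs(rels, "H1", "H2", network=net)
        assert len(shared) == 16
        assert shared == shared_enemy_clubs(rels, "H1", "H2")


class TestLayout:
    @pytest.fixture()
    def laid_out(self):
        records = [
            _rec("H1", "H2", 5),
            _rec("H1", "near1", 4), _rec("H2", "near1", 1),
            _rec("H1", "equal", 2), _rec("H2", "equal", 2),
        ]
        rels = {
            ("H1", "H2"): _rel("H1", "H2", RIVALRY, statistic=2.0),
            ("H1", "near1"): _rel("H1", "near1", RIVALRY, statistic=3.0),
            ("H2", "near1"): _rel("H2", "near1", UNDEFINED, statistic=0.5),
            ("H1", "equal"): _rel("H1", "equal", RIVALRY, statistic=1.5),
            ("H2", "equal"): _rel("H2", "equal", RIVALRY, statistic=1.5),
        }
        net = build_network(records, ("H1", "H2"), rels)
        return net, rels

    @staticmethod
    def _dist(coords, a, b):
        return math.dist(coords[a], coords[b])

    def test_larger_affinity_statistic_sits_closer(self, laid_out):
        net, rels = laid_out
        coords = layout_circular(net, rels)
        assert self._dist(coords, "near1", "H1") < self._dist(coords, "near1", "H2")

    def test_equal_statistics_equidistant(self, laid_out):
        net, rels = laid_out
        coords = layout_circular(net, rels)
        assert math.isclose(
            self._dist(coords, "equal", "H1"),
            self._dist(coords, "equal", "H2"),
            rel_tol=1e-9,
        )

    def test_deterministic(self, laid_out):
        net, rels = laid_out
        assert layout_circular(net, rels, seed=3) == layout_circular(
            net, rels, seed=3
        )

    def test_empty_network_rejected(self):
        net = build_network([], ("H1",))
        with pytest.raises(ValueError):
            layout_circular(net)


class TestExports:
    def test_pajek_format_basics(self, tmp_path):
        records = [_rec("H1", "X", 2), _rec("H1", "Y", 3)]
        net = build_network(records, ("H1",))
        net_path, clu_path = export_network(net, "pajek_net_clu",
                                            tmp_path / "g.net")
        lines = open(net_path).read().splitlines()
        assert "*Vertices 3" in lines
        assert sum(1 for l in lines[lines.index("*Edges") + 1:]) == 2
        clu = [l for l in open(clu_path).read().splitlines()
               if not l.startswith(("%", "*"))]
        assert len(clu) == 3 and all(c.isdigit() for c in clu)

    def test_pajek_round_trip_byte_identical(self, tmp_path, simple_network):
        p1 = tmp_path / "a.net"
        export_network(simple_network, "pajek_net_clu", p1)
        back = import_pajek(p1, tmp_path / "a.clu")
        p2 = tmp_path / "b.net"
        export_network(back, "pajek_net_clu", p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert (tmp_path / "a.clu").read_bytes() == (tmp_path / "b.clu").read_bytes()

    def test_graphml_round_trip_attribute_equal(self, tmp_path, simple_network):
        path = tmp_path / "g.graphml"
        export_network(simple_network, "graphml", path)
        back = nx.read_graphml(path)
        g = simple_network.graph
        assert set(back.nodes) == set(g.nodes)
        for n in g.nodes:
            assert back.nodes[n]["total_incidents"] == g.nodes[n]["total_incidents"]
            assert back.nodes[n]["cluster"] == simple_network.partitions[n]
        for u, v in g.edges:
            assert back.edges[u, v]["incident_sum"] == g.edges[u, v]["incident_sum"]

    def test_edge_csv(self, tmp_path, simple_network):
        import pandas as pd

        path = tmp_path / "edges.csv"
        export_network(simple_network, "edge_csv", path)
        df = pd.read_csv(path)
        assert len(df) == simple_network.graph.number_of_edges()
        assert {"club_a", "club_b", "incident_sum"} <= set(df.columns)

    def test_unknown_format_rejected(self, simple_network, tmp_path):
        with pytest.raises(ValueError, match="unknown export format"):
            export_network(simple_network, "gexf", tmp_path / "x")
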