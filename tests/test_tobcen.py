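"""Time-ordered network layering, initial-node selection and stability."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.sparse.csgraph import shortest_path

from cernet.datatypes import Triplet
from cernet.discovery import BackgroundNetwork, build_gene_graph
from cernet.tobcen import (
    build_tobcen, map_triplets_to_levels, node_dysregulation,
    select_initial_nodes, stability_analysis, tabulate_level_changes,
)


def _scores_frame(rows):
    return pd.DataFrame(rows, columns=["lncRNA", "miRNA", "mRNA", "S"])


class TestNodeDysregulation:
    def test_mean_over_participating_triplets(self):
        f = _scores_frame([("l1", "m1", "y1", 2.0), ("l1", "m2", "y2", 4.0)])
        s = node_dysregulation(f)
        assert s["l1"] == 3.0 and s["y1"] == 2.0 and s["m2"] == 4.0

    def test_shuffle_invariance(self):
        rows = [("l1", "m1", "y1", 1.0), ("l2", "m1", "y2", 5.0), ("l1", "m3", "y3", 3.0)]
        a = node_dysregulation(_scores_frame(rows))
        b = node_dysregulation(_scores_frame(rows[::-1]))
        pd.testing.assert_series_equal(a, b)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            node_dysregulation(_scores_frame([]))


class TestInitialNodes:
    def test_intersection_of_bottom_deciles(self):
        a = pd.Series({"n1": 0.1, "n2": 0.5, "n3": 0.9, "n4": 0.95, "n5": 1.0})
        b = pd.Series({"n1": 0.2, "n2": 0.9, "n3": 0.1, "n4": 0.95, "n5": 1.0})
        # decile 0.4 -> bottom 2 of each: {n1, n2} & {n1, n3} = {n1}
        assert select_initial_nodes(a, b, decile=0.4, k=1) == ["n1"]

    def test_k_exceeding_pool_rejected(self):
        a = pd.Series({"n1": 0.1, "n2": 0.5, "n3": 0.9})
        with pytest.raises(ValueError, match="pool"):
            select_initial_nodes(a, None, decile=0.4, k=5)

    def test_single_condition_mode(self):
        a = pd.Series({"n1": 0.3, "n2": 0.1, "n3": 0.9, "n4": 1.0})
        assert select_initial_nodes(a, None, decile=0.5, k=2) == ["n2", "n1"]

    def test_disjoint_deciles_raise(self):
        a = pd.Series({"n1": 0.1, "n2": 0.9, "n3": 1.0})
        b = pd.Series({"n1": 0.9, "n2": 0.1, "n3": 1.0})
        with pytest.raises(ValueError, match="decile"):
            select_initial_nodes(a, b, decile=0.3, k=1)


def _path_network() -> BackgroundNetwork:
    # A - B - C - D path realised through two triplets sharing gene B/C
    t1 = Triplet("A", "B", "C")
    t2 = Triplet("C", "D", "E")
    g = build_gene_graph([t1, t2])
    return BackgroundNetwork([t1, t2], g)


class TestBuildTobcen:
    def test_path_graph_levels(self):
        g = nx.path_graph(["A", "B", "C", "D"])
        nx.set_node_attributes(g, "mRNA", "rna_class")
        net = BackgroundNetwork([], g)
        tob = build_tobcen(net, ["A"])
        assert tob.gene_level == {"A": 1, "B": 2, "C": 3, "D": 4}
        assert tob.n_levels == 4

    def test_triplet_gets_minimum_member_level(self):
        net = _path_network()
        tob = build_tobcen(net, ["A"])
        # t2 members C, D, E sit at levels 2, 3, 3 -> triplet level 2
        assert tob.gene_level["C"] == 2
        assert tob.triplet_level[("C", "D", "E")] == 2
        assert tob.triplet_level[("A", "B", "C")] == 1

    def test_levels_match_shortest_path_oracle_on_random_graphs(self):
        rng = np.random.default_rng(12)
        for rep in range(30):
            n = int(rng.integers(5, 51))
            g = nx.gnp_random_graph(n, 0.1, seed=int(rng.integers(2**31)))
            g = nx.relabel_nodes(g, {i: f"g{i}" for i in range(n)})
            nx.set_node_attributes(g, "mRNA", "rna_class")
            nodes = sorted(g.nodes)
            initial = list(rng.choice(nodes, size=min(2, n), replace=False))
            tob = build_tobcen(BackgroundNetwork([], g), initial)
            # oracle: dense all-pairs shortest paths via scipy
            adj = nx.to_numpy_array(g, nodelist=nodes)
            dist = shortest_path(adj, unweighted=True)
            idx = {v: i for i, v in enumerate(nodes)}
            for v in nodes:
                d = min(dist[idx[v], idx[s]] for s in initial)
                if np.isinf(d):
                    assert v in tob.unreachable
                else:
                    assert tob.gene_level[v] == int(d) + 1

    def test_unknown_initial_rejected(self):
        with pytest.raises(ValueError, match="ZZZ"):
            build_tobcen(_path_network(), ["ZZZ"])

    def test_unreachable_genes_reported_beyond_last_level(self):
        t1 = Triplet("A", "B", "C")
        t2 = Triplet("X", "Y", "Z")
        g = build_gene_graph([t1, t2])
        tob = build_tobcen(BackgroundNetwork([t1, t2], g), ["A"])
        assert set(tob.unreachable) == {"X", "Y", "Z"}
        assert tob.gene_level["X"] == 3  # one past the deepest reachable level

    def test_mapping_drops_foreign_triplets(self):
        net = _path_network()
        tob = build_tobcen(net, ["A"])
        mapped = map_triplets_to_levels(tob, [("A", "B", "C"), ("q", "r", "s")])
        assert mapped == {("A", "B", "C"): 1}


class TestStability:
    def test_identical_initial_nodes_give_no_change(self):
        net = _path_network()
        tob = build_tobcen(net, ["A", "B"])
        rep = stability_analysis(net, tob, n_rep=3, seed=0, level1_pool=["A", "B"])
        assert (rep.table["unchanged"] == 2).all()
        assert (rep.table["mean"] == 0).all() and (rep.table["sd"] == 0).all()

    def test_toy_network_hand_tabulation(self):
        # star of four triplets around miRNA H plus a pendant triplet
        trips = [Triplet(f"l{i}", "H", f"y{i}") for i in range(3)]
        trips.append(Triplet("l3", "m3", "y0"))
        g = build_gene_graph(trips)
        net = BackgroundNetwork(trips, g)
        original = build_tobcen(net, ["H"])
        # by hand: H at L1 -> all H-triplets L1; (l3, m3, y0): y0 at L2 -> L2
        assert original.triplet_level == {
            ("l0", "H", "y0"): 1, ("l1", "H", "y1"): 1,
            ("l2", "H", "y2"): 1, ("l3", "m3", "y0"): 2}
        alt = build_tobcen(net, ["l3", "y2"])
        # hand BFS: sources l3, y2 at L1; their neighbours y0, m3, l2, H at
        # L2; the remaining genes l0, l1, y1 at L3
        assert alt.gene_level == {"l3": 1, "y2": 1, "m3": 2, "y0": 2, "H": 2,
                                  "l2": 2, "l0": 3, "l1": 3, "y1": 3}
        h = tabulate_level_changes(original.triplet_level, alt.triplet_level)
        # triplet levels: (l0,H,y0): min(3,2,2)=2 (was 1, +1);
        # (l1,H,y1): min(3,2,3)=2 (+1); (l2,H,y2): min(3,2,1)=1 (0);
        # (l3,m3,y0): min(1,2,2)=1 (was 2, -1)
        assert h == {"unchanged": 1, "cross1": 3, "cross2": 0, "multi": 0,
                     "mean": pytest.approx((1 + 1 + 0 - 1) / 4),
                     "sd": pytest.approx(np.std([1, 1, 0, -1]))}

    def test_counts_partition_all_triplets(self, small_sim):
        from cernet.discovery import discover_triplets, largest_component
        ds, inter, _ = small_sim
        net = largest_component(discover_triplets(ds, inter))
        tob = build_tobcen(net, [sorted(net.genes())[0]])
        pool = sorted(net.genes())[:6]
        rep = stability_analysis(net, tob, n_rep=5, seed=3, level1_pool=pool)
        assert rep.totals_ok(len(net.triplets))

    def test_small_pool_rejected(self):
        net = _path_network()
        tob = build_tobcen(net, ["A"])
        with pytest.raises(ValueError, match="pool"):
            stability_analysis(net, tob, n_rep=2, seed=0, level1_pool=["A"])
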