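"""Network construction, centralities (vs brute-force oracle), key nodes."""

import numpy as np
import pandas as pd
import pytest

from diffcornet.network import (
    build_network,
    centrality_table,
    network_summary,
    rank_key_nodes,
)

# ---------------------------------------------------------------------------
# Independent oracle: exhaustive simple-path enumeration + hand-rolled
# shortest-path counting.  Deliberately avoids any graph library.
# ---------------------------------------------------------------------------


def _all_simple_paths(adj, s, t):
    paths = []

    def dfs(node, visited, path):
        if node == t:
            paths.append(list(path))
            return
        for nb in sorted(adj[node]):
            if nb not in visited:
                visited.add(nb)
                path.append(nb)
                dfs(nb, visited, path)
                path.pop()
                visited.remove(nb)

    dfs(s, {s}, [s])
    return paths


def brute_centralities(edges, closeness_convention="wf"):
    """Normalized betweenness and closeness by exhaustive path enumeration."""
    adj = {}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    nodes = sorted(adj)
    n = len(nodes)
    shortest, dist = {}, {}
    for s in nodes:
        for t in nodes:
            if s == t:
                continue
            paths = _all_simple_paths(adj, s, t)
            if paths:
                d = min(len(p) for p in paths) - 1
                shortest[(s, t)] = [p for p in paths if len(p) - 1 == d]
                dist[(s, t)] = d
            else:
                shortest[(s, t)] = []
                dist[(s, t)] = None
    bet = {}
    for v in nodes:
        total = 0.0
        for i, s in enumerate(nodes):
            for t in nodes[i + 1:]:
                if v in (s, t) or not shortest[(s, t)]:
                    continue
                through = sum(1 for p in shortest[(s, t)] if v in p[1:-1])
                total += through / len(shortest[(s, t)])
        bet[v] = total / ((n - 1) * (n - 2) / 2) if n > 2 else 0.0
    clo = {}
    for v in nodes:
        reach = [t for t in nodes if t != v and dist[(v, t)] is not None]
        sd = sum(dist[(v, t)] for t in reach)
        if sd == 0:
            clo[v] = 0.0
        elif closeness_convention == "wf":
            clo[v] = (len(reach) / (n - 1)) * (len(reach) / sd)
        else:
            clo[v] = 1.0 / sd
    return bet, clo


def edges_frame(pairs, rdiffs=None):
    k = len(pairs)
    rdiffs = rdiffs if rdiffs is not None else [1.0] * k
    return pd.DataFrame(
        {
            "metabolite_i": [a for a, _ in pairs],
            "metabolite_j": [b for _, b in pairs],
            "r_diff": rdiffs,
            "p_perm": [0.01] * k,
            "sign": ["positive" if r >= 0 else "negative" for r in rdiffs],
        }
    )


class TestBuildNetwork:
    def test_empty_edge_list_warns_and_flags(self):
        with pytest.warns(UserWarning, match="empty"):
            G = build_network(edges_frame([]))
        s = network_summary(G)
        assert s["n_nodes"] == 0 and s["mean_degree"] == 0.0 and s["empty"]

    def test_triangle_degrees_and_mean(self):
        G = build_network(edges_frame([("A", "B"), ("B", "C"), ("A", "C")]))
        assert dict(G.degree()) == {"A": 2, "B": 2, "C": 2}
        assert network_summary(G)["mean_degree"] == pytest.approx(2.0)

    def test_signed_edge_counts(self):
        G = build_network(
            edges_frame([("A", "B"), ("B", "C"), ("C", "D")], [2.0, -1.5, 0.5])
        )
        s = network_summary(G)
        assert (s["n_positive"], s["n_negative"]) == (2, 1)

    def test_mean_degree_of_cohort_sized_graph(self):
        """146 nodes carrying 632 edges average 8.66 connections."""
        rng = np.random.default_rng(0)
        nodes = [f"N{i}" for i in range(146)]
        pairs = set()
        while len(pairs) < 632:
            i, j = rng.integers(0, 146, 2)
            if i != j:
                pairs.add((nodes[min(i, j)], nodes[max(i, j)]))
        G = build_network(edges_frame(sorted(pairs)))
        assert round(network_summary(G)["mean_degree"], 2) == 8.66

    def test_duplicate_edge_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_network(edges_frame([("A", "B"), ("B", "A")]))

    def test_degree_sum_is_twice_edge_count(self):
        rng = np.random.default_rng(1)
        pairs = {(f"N{min(i, j)}", f"N{max(i, j)}")
                 for i, j in rng.integers(0, 30, (200, 2)) if i != j}
        G = build_network(edges_frame(sorted(pairs)))
        assert sum(d for _, d in G.degree()) == 2 * G.number_of_edges()


class TestCentralities:
    def test_path_graph_betweenness_and_closeness(self):
        G = build_network(edges_frame([("A", "B"), ("B", "C")]))
        t = centrality_table(G).set_index("metabolite")
        assert t.loc["B", "betweenness"] == pytest.approx(1.0)
        assert t.loc["A", "betweenness"] == 0.0
        assert t.loc["B", "closeness"] == pytest.approx(1.0)
        assert t.loc["A", "closeness"] == pytest.approx(2 / 3)

    def test_star_center_dominates(self):
        G = build_network(edges_frame([("Hub", f"L{i}") for i in range(5)]))
        t = centrality_table(G).set_index("metabolite")
        assert t.loc["Hub", "betweenness"] == pytest.approx(1.0)
        assert (t.drop("Hub")["betweenness"] == 0).all()

    def test_four_cycle_symmetric_and_matches_oracle(self):
        pairs = [("A", "B"), ("B", "C"), ("C", "D"), ("A", "D")]
        G = build_network(edges_frame(pairs))
        t = centrality_table(G).set_index("metabolite")
        bet, clo = brute_centralities(pairs)
        assert t["betweenness"].nunique() == 1
        for v in "ABCD":
            assert t.loc[v, "betweenness"] == pytest.approx(bet[v], abs=1e-12)
            assert t.loc[v, "closeness"] == pytest.approx(clo[v], abs=1e-12)

    def test_complete_graph_closeness_one(self):
        pairs = [("A", "B"), ("A", "C"), ("A", "D"), ("B", "C"), ("B", "D"), ("C", "D")]
        t = centrality_table(build_network(edges_frame(pairs)))
        assert np.allclose(t["closeness"], 1.0)

    def test_disconnected_triangles_component_scaled(self):
        pairs = [("A", "B"), ("B", "C"), ("A", "C"),
                 ("X", "Y"), ("Y", "Z"), ("X", "Z")]
        t = centrality_table(build_network(edges_frame(pairs)))
        # within-component closeness 1.0, scaled by (2 reachable)/(5 others)
        assert np.allclose(t["closeness"], 0.4)
        raw = centrality_table(build_network(edges_frame(pairs)),
                               closeness_convention="raw")
        assert np.allclose(raw["closeness"], 0.5)  # 1 / (1 + 1)

    @pytest.mark.parametrize("convention", ["wf", "raw"])
    def test_random_graphs_match_brute_force_oracle(self, convention):
        rng = np.random.default_rng(99)
        for _ in range(100):
            n = int(rng.integers(2, 9))
            p = rng.uniform(0.2, 0.9)
            pairs = [
                (f"N{i}", f"N{j}")
                for i in range(n)
                for j in range(i + 1, n)
                if rng.random() < p
            ]
            if not pairs:
                continue
            t = centrality_table(
                build_network(edges_frame(pairs)), closeness_convention=convention
            ).set_index("metabolite")
            bet, clo = brute_centralities(pairs, closeness_convention=convention)
            for v in t.index:
                assert t.loc[v, "betweenness"] == pytest.approx(bet[v], abs=1e-12)
                assert t.loc[v, "closeness"] == pytest.approx(clo[v], abs=1e-12)

    def test_invariant_to_node_relabeling(self):
        rng = np.random.default_rng(5)
        pairs = sorted({(f"N{min(i, j)}", f"N{max(i, j)}")
                        for i, j in rng.integers(0, 8, (15, 2)) if i != j})
        t1 = centrality_table(build_network(edges_frame(pairs)))
        relabel = {f"N{i}": f"Q{7 - i}" for i in range(8)}
        pairs2 = [tuple(sorted((relabel[a], relabel[b]))) for a, b in pairs]
        t2 = centrality_table(build_network(edges_frame(pairs2)))
        m1 = t1.set_index("metabolite")
        m2 = t2.set_index("metabolite")
        for v in m1.index:
            for col in ("degree", "betweenness", "closeness"):
                assert m1.loc[v, col] == pytest.approx(m2.loc[relabel[v], col], abs=1e-12)


class TestKeyNodes:
    def test_star_center_is_hub_and_bottleneck(self):
        G = build_network(edges_frame([("Hub", f"L{i}") for i in range(5)]))
        ranked = rank_key_nodes(centrality_table(G), top_k=1).set_index("metabolite")
        assert ranked.loc["Hub", ["is_hub", "is_bottleneck", "is_key"]].all()
        assert not ranked.drop("Hub")["is_key"].any()

    def test_distinct_hub_and_bottleneck(self):
        # Two 4-cliques joined through a bridge: the bridge has the highest
        # betweenness but degree 2; the attachment nodes have max degree 4.
        clique = lambda names: [
            (a, b) for i, a in enumerate(names) for b in names[i + 1:]
        ]
        pairs = clique(["a1", "a2", "a3", "a4"]) + clique(["c1", "c2", "c3", "c4"])
        pairs += [("a1", "bridge"), ("bridge", "c1")]
        G = build_network(edges_frame(pairs))
        ranked = rank_key_nodes(centrality_table(G), top_k=1).set_index("metabolite")
        assert ranked["degree"].idxmax() != "bridge"
        assert ranked.loc["bridge", "is_bottleneck"] and not ranked.loc["bridge", "is_hub"]
        top_deg = ranked["degree"].idxmax()
        assert ranked.loc[top_deg, "is_hub"]
        assert ranked["is_key"].sum() >= 2

    def test_top_k_at_least_n_flags_everything(self):
        G = build_network(edges_frame([("A", "B"), ("B", "C")]))
        ranked = rank_key_nodes(centrality_table(G), top_k=10)
        assert ranked["is_key"].all()

    def test_nonpositive_top_k_rejected(self):
        G = build_network(edges_frame([("A", "B")]))
        with pytest.raises(ValueError):
            rank_key_nodes(centrality_table(G), top_k=0)

    def test_report_sorted_by_degree_then_betweenness(self):
        pairs = [("A", "B"), ("A", "C"), ("A", "D"), ("B", "C"), ("D", "E")]
        ranked = rank_key_nodes(centrality_table(build_network(edges_frame(pairs))))
        degrees = ranked["degree"].to_list()
        assert degrees == sorted(degrees, reverse=True)
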