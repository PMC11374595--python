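"""Bipartite network bookkeeping, correlation and prioritization."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
import scipy.stats

from mirsource import regulatory_network as rn
from mirsource.literature_catalog import mined_sets
from mirsource.target_consensus import build_interactions


def interactions_df(edges, validated=()):
    validated = set(validated)
    return pd.DataFrame(
        {
            "mirna": [e[0] for e in edges],
            "target": [e[1] for e in edges],
            "n_sources": [2] * len(edges),
            "validated": [e in validated for e in edges],
            "mean_rank": [1.0] * len(edges),
        }
    )


def catalog_df(freqs, disease="IBD"):
    return pd.DataFrame(
        {
            "gene_symbol": list(freqs),
            "disease_label": [disease] * len(freqs),
            "frequency": list(freqs.values()),
            "biotype": ["miRNA"] * len(freqs),
        }
    )


class TestBuildNetwork:
    def test_degrees_of_star_graph(self):
        net = rn.build_network(
            interactions_df([("hsa-miR-1", t) for t in ("A", "B", "C")])
        )
        assert net.degree["hsa-miR-1"] == 3
        assert all(net.degree[t] == 1 for t in ("A", "B", "C"))

    def test_empty_interactions_give_empty_graph(self):
        net = rn.build_network(interactions_df([]))
        assert net.number_of_nodes() == 0

    def test_non_bipartite_input_rejected(self):
        with pytest.raises(ValueError, match="non-bipartite"):
            rn.build_network(interactions_df([("hsa-miR-1", "A"), ("A", "B")]))

    def test_self_edge_rejected(self):
        with pytest.raises(ValueError):
            rn.build_network(interactions_df([("A", "A")]))

    def test_bipartite_handshake(self, sim):
        mrnas, mirnas = mined_sets(sim.catalog, "IBD")
        inter = build_interactions(sim.predictions, sim.validated, mrnas, mirnas)
        net = rn.build_network(inter)
        biotypes = nx.get_node_attributes(net, "biotype")
        deg_mir = sum(d for n, d in net.degree() if biotypes[n] == "miRNA")
        deg_mrna = sum(d for n, d in net.degree() if biotypes[n] == "mRNA")
        assert deg_mir == deg_mrna == net.number_of_edges()


class TestNetworkStats:
    def test_fraction_validated(self):
        edges = [("hsa-miR-1", f"T{i}") for i in range(10)]
        net = rn.build_network(interactions_df(edges, validated=[edges[0]]))
        stats = rn.network_stats(net)
        assert stats.n_edges_predicted == 9
        assert stats.n_edges_validated == 1
        assert stats.fraction_validated == pytest.approx(0.1)

    def test_all_validated(self):
        edges = [("hsa-miR-1", "A"), ("hsa-miR-2", "B")]
        net = rn.build_network(interactions_df(edges, validated=edges))
        assert rn.network_stats(net).fraction_validated == 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_hand_enumeration_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        edges = list(
            {
                (f"hsa-miR-{rng.integers(5)}", f"T{rng.integers(15)}")
                for _ in range(30)
            }
        )
        validated = [e for e in edges if rng.random() < 0.3]
        net = rn.build_network(interactions_df(edges, validated))
        stats = rn.network_stats(net)
        # enumeration oracle straight from the edge list
        assert stats.n_edges_validated == len(validated)
        assert stats.n_edges_predicted == len(edges) - len(validated)
        assert stats.n_mirna == len({e[0] for e in edges})
        assert stats.n_mrna == len({e[1] for e in edges})


class TestFrequencyDegreeCorrelation:
    def test_perfect_monotone_gives_rho_one(self):
        edges = [(f"hsa-miR-{i}", f"T{j}") for i in range(3) for j in range((i + 1) * 2)]
        net = rn.build_network(interactions_df(edges))
        cat = catalog_df({f"hsa-miR-{i}": 10 * (i + 1) for i in range(3)})
        rho, p, n = rn.frequency_degree_correlation(net, cat)
        assert rho == pytest.approx(1.0)
        assert n == 3

    def test_log_transform_does_not_change_rho(self):
        rng = np.random.default_rng(4)
        edges = [(f"hsa-miR-{i}", f"T{j}") for i in range(8) for j in rng.choice(30, size=rng.integers(1, 10), replace=False)]
        net = rn.build_network(interactions_df(list(set(edges))))
        cat = catalog_df({f"hsa-miR-{i}": int(f) for i, f in enumerate(rng.integers(1, 50, 8))})
        r1, _, _ = rn.frequency_degree_correlation(net, cat, log_transform=False)
        r2, _, _ = rn.frequency_degree_correlation(net, cat, log_transform=True)
        assert r1 == pytest.approx(r2)

    def test_too_few_mirnas_refused(self):
        net = rn.build_network(interactions_df([("hsa-miR-1", "A"), ("hsa-miR-2", "B")]))
        cat = catalog_df({"hsa-miR-1": 5, "hsa-miR-2": 3})
        with pytest.raises(ValueError, match=">= 3"):
            rn.frequency_degree_correlation(net, cat)

    def test_exact_permutation_p_matches_enumeration_threshold(self):
        # at n=4 with a perfectly monotone pairing, only 2 of the 24
        # permutations achieve |rho| = 1, so the exact p is 2/24
        edges = [(f"hsa-miR-{i}", f"T{j}") for i in range(4) for j in range((i + 1) * 3)]
        net = rn.build_network(interactions_df(edges))
        cat = catalog_df({f"hsa-miR-{i}": 2 ** (i + 1) for i in range(4)})
        _, p, _ = rn.frequency_degree_correlation(net, cat, method="exact")
        assert p == pytest.approx(2 / 24)

    def test_null_mean_rho_near_zero(self):
        # permuting frequency independently of degree kills the correlation
        rng = np.random.default_rng(0)
        n = 200
        edges = [
            (f"hsa-miR-{i}", f"T{j}")
            for i in range(n)
            for j in rng.choice(400, size=rng.integers(1, 20), replace=False)
        ]
        net = rn.build_network(interactions_df(list(set(edges))))
        freqs = {f"hsa-miR-{i}": int(f) for i, f in enumerate(rng.integers(1, 100, n))}
        rhos = []
        for _ in range(200):
            perm = rng.permutation(list(freqs.values()))
            cat = catalog_df(dict(zip(freqs, (int(x) for x in perm))))
            rho, _, _ = rn.frequency_degree_correlation(net, cat)
            rhos.append(rho)
        assert abs(np.mean(rhos)) < 0.05


class TestRankMirnas:
    def brute_force(self, freq, deg):
        """Independent oracle: explicit rank computation and sort."""
        mirnas = sorted(deg)
        rf = scipy.stats.rankdata([-freq[m] for m in mirnas])
        rd = scipy.stats.rankdata([-deg[m] for m in mirnas])
        mean_rank = {m: (a + b) / 2 for m, a, b in zip(mirnas, rf, rd)}
        order = sorted(mirnas, key=lambda m: (mean_rank[m], -freq[m], m))
        return order

    def test_dominant_mirna_ranks_first(self):
        edges = [("hsa-miR-9", f"T{j}") for j in range(5)] + [("hsa-miR-1", "T0")]
        net = rn.build_network(interactions_df(edges))
        cat = catalog_df({"hsa-miR-9": 50, "hsa-miR-1": 2})
        top = rn.rank_mirnas(net, cat, k=2)
        assert top.iloc[0]["mirna"] == "hsa-miR-9"
        assert top.iloc[0]["final_rank"] == 1

    def test_swapped_ranks_tie_broken_by_frequency(self):
        # (rank_f, rank_d) = (1,2) and (2,1): equal mean rank, the more
        # frequently mentioned miRNA wins
        edges = [("hsa-miR-a", "T1")] + [("hsa-miR-b", f"T{j}") for j in range(1, 4)]
        net = rn.build_network(interactions_df(edges))
        cat = catalog_df({"hsa-miR-a": 9, "hsa-miR-b": 4})
        top = rn.rank_mirnas(net, cat, k=2)
        assert top.iloc[0]["mirna"] == "hsa-miR-a"
        assert top.iloc[0]["mean_rank"] == top.iloc[1]["mean_rank"]

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_sort_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        deg = {f"hsa-miR-{i}": 0 for i in range(n)}
        edges = []
        for i in range(n):
            targets = rng.choice(100, size=rng.integers(1, 15), replace=False)
            deg[f"hsa-miR-{i}"] = len(targets)
            edges += [(f"hsa-miR-{i}", f"T{j}") for j in targets]
        freq = {f"hsa-miR-{i}": int(rng.integers(1, 10)) for i in range(n)}
        net = rn.build_network(interactions_df(edges))
        ranked = rn.rank_mirnas(net, catalog_df(freq), k=n)
        assert list(ranked["mirna"]) == self.brute_force(freq, deg)

    def test_invariant_under_monotone_frequency_transform(self):
        rng = np.random.default_rng(8)
        edges = [
            (f"hsa-miR-{i}", f"T{j}")
            for i in range(10)
            for j in rng.choice(50, size=rng.integers(1, 10), replace=False)
        ]
        net = rn.build_network(interactions_df(list(set(edges))))
        freq = {f"hsa-miR-{i}": int(rng.integers(1, 30)) for i in range(10)}
        cat1 = catalog_df(freq)
        cat2 = catalog_df({m: f**3 + 1 for m, f in freq.items()})  # strictly monotone
        a = rn.rank_mirnas(net, cat1, k=10)
        b = rn.rank_mirnas(net, cat2, k=10)
        assert list(a["mirna"]) == list(b["mirna"])


class TestExport:
    def test_edge_list_round_trip_is_attribute_identical(self, tmp_path):
        edges = [("hsa-miR-1", "A"), ("hsa-miR-1", "B"), ("hsa-miR-2", "A")]
        net = rn.build_network(interactions_df(edges, validated=[edges[1]]))
        path = tmp_path / "net.tsv"
        rn.export_network(net, path, "edgelist")
        back = rn.import_edge_list(path)
        assert nx.utils.graphs_equal(net, back)

    def test_gexf_round_trip_preserves_attributes(self, tmp_path):
        edges = [("hsa-miR-1", "A"), ("hsa-miR-2", "B")]
        net = rn.build_network(interactions_df(edges, validated=[edges[0]]))
        path = tmp_path / "net.gexf"
        rn.export_network(net, path, "gexf")
        back = nx.read_gexf(path)
        assert set(back.nodes) == set(net.nodes)
        for n in net.nodes:
            assert back.nodes[n]["biotype"] == net.nodes[n]["biotype"]
        for u, v in net.edges:
            assert back.edges[u, v]["support"] == net.edges[u, v]["support"]

    def test_empty_graph_exports_valid_file(self, tmp_path):
        path = tmp_path / "empty.tsv"
        rn.export_network(nx.Graph(), path, "edgelist")
        assert rn.import_edge_list(path).number_of_nodes() == 0

    def test_edge_list_has_one_line_per_edge(self, tmp_path):
        edges = [("hsa-miR-1", f"T{i}") for i in range(10)]
        net = rn.build_network(interactions_df(edges))
        path = tmp_path / "net.tsv"
        rn.export_network(net, path, "edgelist")
        assert len(path.read_text().strip().splitlines()) == 11  # header + 10

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="unknown export format"):
            rn.export_network(nx.Graph(), tmp_path / "x", "graphml")
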