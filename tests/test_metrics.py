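import numpy as np
import pytest
from hypothesis import given, strategies as st

import covnet.metrics as gm
import oracles
from conftest import as_network, complete_graph, graph_from_edges, ring_lattice, star_graph


# -- worked examples --------------------------------------------------------


def test_path_graph_integration_measures():
    path = graph_from_edges(3, [(0, 1), (1, 2)])
    assert gm.char_path_length(path) == pytest.approx(4 / 3)
    assert gm.global_efficiency(path) == pytest.approx(5 / 6)
    assert gm.betweenness(path)[1] == pytest.approx(1.0)


def test_complete_graph_measures():
    k5 = complete_graph(5)
    assert gm.char_path_length(k5) == pytest.approx(1.0)
    assert gm.global_efficiency(k5) == pytest.approx(1.0)
    clus = gm.clustering_and_transitivity(k5)
    assert clus.mean_clustering == pytest.approx(1.0)
    assert clus.transitivity == pytest.approx(1.0)
    q, _ = gm.modularity(k5)
    assert q == pytest.approx(0.0, abs=1e-12)


def test_two_disconnected_dyads_efficiency():
    two_k2 = graph_from_edges(4, [(0, 1), (2, 3)])
    assert gm.global_efficiency(two_k2) == pytest.approx(1 / 3)
    with pytest.warns(UserWarning, match="disconnected"):
        assert gm.char_path_length(two_k2) == pytest.approx(1.0)


def test_star_graph_segregation_and_betweenness():
    star = star_graph(4)
    clus = gm.clustering_and_transitivity(star)
    assert clus.mean_clustering == 0.0 and clus.transitivity == 0.0
    assert gm.local_efficiency(star) == 0.0
    b = gm.betweenness(star)
    assert b[0] == pytest.approx(6.0)  # C(4,2) leaf pairs route via center
    assert np.all(b[1:] == 0)


def test_k4_local_efficiency_is_one():
    assert gm.local_efficiency(complete_graph(4)) == pytest.approx(1.0)


def test_ring_lattice_clustering_equals_transitivity():
    ring = ring_lattice(8, 2)
    clus = gm.clustering_and_transitivity(ring)
    assert clus.mean_clustering == pytest.approx(0.5)
    assert clus.transitivity == pytest.approx(0.5)
    # vertex-transitive: nodal clustering identical everywhere
    assert np.allclose(clus.nodal, 0.5)


def test_two_triangles_modularity_matches_exhaustive_optimum():
    two_tri = graph_from_edges(6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
    q, labels = gm.modularity(two_tri)
    assert q == pytest.approx(0.5)
    assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
    assert oracles.best_modularity(two_tri) == pytest.approx(0.5)


def test_edgeless_graph_modularity_raises():
    with pytest.raises(ValueError, match="edgeless"):
        gm.modularity(np.zeros((4, 4), dtype=bool))


# -- randomized oracle battery ----------------------------------------------


@pytest.mark.parametrize("batch", range(8))
def test_metrics_match_bruteforce_oracles_on_small_graphs(batch):
    """Randomized battery: exact agreement with enumeration oracles, n <= 10."""
    rng = np.random.default_rng(1000 + batch)
    for _ in range(25):
        n = int(rng.integers(4, 11))
        adj = oracles.random_graph(rng, n)
        if adj.any():
            assert gm.char_path_length(adj, warn_disconnected=False) == pytest.approx(
                oracles.char_path_length(adj), abs=1e-10
            )
        assert gm.global_efficiency(adj) == pytest.approx(
            oracles.global_efficiency(adj), abs=1e-10
        )
        clus = gm.clustering_and_transitivity(adj)
        assert np.allclose(clus.nodal, oracles.nodal_clustering(adj), atol=1e-10)
        assert clus.transitivity == pytest.approx(oracles.transitivity(adj), abs=1e-10)
        assert gm.local_efficiency(adj) == pytest.approx(
            oracles.local_efficiency(adj), abs=1e-10
        )
        assert np.allclose(gm.betweenness(adj), oracles.betweenness(adj), atol=1e-8)


def test_greedy_modularity_close_to_exhaustive_partition_optimum():
    """Greedy agglomeration Q vs exhaustive search over all partitions (n <= 8)."""
    rng = np.random.default_rng(2024)
    gaps = []
    for _ in range(25):
        n = int(rng.integers(4, 9))
        adj = oracles.random_graph(rng, n, p=0.45)
        if not adj.any():
            continue
        q_greedy, _ = gm.modularity(adj)
        q_best = oracles.best_modularity(adj)
        assert q_greedy <= q_best + 1e-10  # exhaustive is an upper bound
        gaps.append(q_best - q_greedy)
    assert max(gaps) <= 0.15
    assert np.mean(gaps) <= 0.03


# -- structural invariants --------------------------------------------------


@given(st.integers(min_value=0, max_value=10_000))
def test_adding_an_edge_improves_integration(seed):
    rng = np.random.default_rng(seed)
    adj = oracles.random_graph(rng, 8, p=0.4)
    empty = np.flatnonzero(~adj[np.triu_indices(8, 1)[0], np.triu_indices(8, 1)[1]])
    if empty.size == 0 or not adj.any():
        return
    rows, cols = np.triu_indices(8, 1)
    pick = int(rng.choice(empty))
    denser = adj.copy()
    denser[rows[pick], cols[pick]] = denser[cols[pick], rows[pick]] = True
    assert gm.global_efficiency(denser) >= gm.global_efficiency(adj) - 1e-12
    if oracles.largest_component(adj) == 8:  # Lp comparable only when connected
        assert gm.char_path_length(denser) <= gm.char_path_length(adj) + 1e-12


# -- random references and small-worldness ----------------------------------


def test_rewired_references_preserve_degree_sequence_and_seed():
    rng = np.random.default_rng(11)
    adj = oracles.random_graph(rng, 20, p=0.3)
    net = as_network(adj)
    refs1 = gm.random_reference(net, seed=5, n_networks=3, require_connected=False)
    refs2 = gm.random_reference(net, seed=5, n_networks=3, require_connected=False)
    for r1, r2 in zip(refs1, refs2):
        assert np.array_equal(r1.adjacency, r2.adjacency)  # determinism
    for r in refs1:
        assert np.array_equal(
            np.sort(r.adjacency.sum(0)), np.sort(adj.sum(0))
        )
    changed = any(not np.array_equal(r.adjacency, adj) for r in refs1)
    assert changed


def test_rewiring_destroys_lattice_clustering():
    ring = as_network(ring_lattice(30, 3))
    base = gm.clustering_and_transitivity(ring).mean_clustering
    rewired_cp = [
        gm.clustering_and_transitivity(r).mean_clustering
        for r in gm.random_reference(ring, seed=123, n_networks=20)
    ]
    assert np.mean(rewired_cp) < base


def test_too_small_graph_cannot_be_rewired():
    net = as_network(graph_from_edges(3, [(0, 1)]))
    with pytest.raises(ValueError, match="too small"):
        gm.random_reference(net, seed=0)


def test_small_world_self_normalization_is_unity():
    net = as_network(ring_lattice(16, 2))
    sw = gm.small_world(net, [net, net])
    assert sw.gamma == pytest.approx(1.0)
    assert sw.lam == pytest.approx(1.0)
    assert sw.sigma == pytest.approx(1.0)


def test_watts_strogatz_style_lattice_is_small_world():
    rng = np.random.default_rng(3)
    adj = ring_lattice(60, 3).copy()
    rows, cols = np.triu_indices(60, 1)
    # a few shortcuts: rewire ~5% of edges to random targets
    for _ in range(10):
        i, j = rng.integers(0, 60, 2)
        if i != j:
            adj[i, j] = adj[j, i] = True
    net = as_network(adj)
    refs = gm.random_reference(net, seed=9, n_networks=10)
    assert gm.small_world(net, refs).sigma > 1.0


def test_erdos_renyi_normalizes_to_unit_gamma_and_lambda():
    """ER graphs are their own degree-matched null: gamma ≈ lambda ≈ 1."""
    gammas, lams = [], []
    for seed in range(20):
        rng = np.random.default_rng(400 + seed)
        n = 200
        adj = oracles.random_graph(rng, n, p=0.05)
        net = as_network(adj)
        if not oracles.largest_component(adj) == n:
            continue
        refs = gm.random_reference(net, seed=seed, n_networks=2, swap_factor=10)
        sw = gm.small_world(net, refs)
        gammas.append(sw.gamma)
        lams.append(sw.lam)
    assert abs(np.mean(gammas) - 1.0) < 0.1
    assert abs(np.mean(lams) - 1.0) < 0.1


def test_global_metrics_bundle_is_consistent(default_networks):
    net = next(iter(default_networks.values()))
    refs = gm.random_reference(net, seed=2, n_networks=5)
    m = gm.global_metrics(net, refs)
    assert m.sigma == pytest.approx(m.gamma / m.lam)
    assert 0 <= m.global_efficiency <= 1
    assert 0 <= m.clustering_coefficient <= 1
    assert 0 <= m.transitivity <= 1
    assert m.char_path_length >= 1
    assert -0.5 <= m.modularity <= 1
    table = gm.nodal_metrics(net)
    assert table["degree"].sum() == 2 * net.n_edges
    assert (table.loc[table["degree"] <= 1, "betweenness"] == 0).all()
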