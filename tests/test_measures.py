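"""Degree, eigenvector centrality, density and activation timelines."""

import math

import numpy as np
import pytest

from morphnet.corpus import from_records
from morphnet.measures import (
    UndefinedMeasureError,
    activation_timeline,
    eigenvector_centrality,
    measure_table,
    network_density,
    node_degree,
)
from morphnet.networks import (
    BipartiteNetwork,
    build_network_series,
    build_session_network,
)

from conftest import make_table, random_bipartite_network


def star(n_leaves):
    roots = tuple(f"r-{i}-x" for i in range(n_leaves))
    edges = {(r, "P.c"): 1 for r in roots}
    return BipartiteNetwork("d", "CS", 1, 700, roots, ("P.c",), edges)


def test_worked_example_degree_is_four(worked_example_table):
    net = build_session_network(worked_example_table, "dyad2", "CS", 3)
    assert node_degree(net)["Qal.Present.Fm.Sg"] == 4


def test_single_root_degree_counts_its_patterns(fig_example_table):
    net = build_session_network(fig_example_table, "dyad1", "CS", 1)
    assert node_degree(net)["l-m-d"] == 2


def test_degree_undefined_on_empty_network(fig_example_table):
    empty = build_session_network(fig_example_table, "dyad1", "CDS", 1)
    with pytest.raises(UndefinedMeasureError):
        node_degree(empty)


def test_single_link_centralities_are_symmetric():
    res = eigenvector_centrality(star(1))
    assert res.converged
    assert res.centrality["r-0-x"] == pytest.approx(1 / math.sqrt(2), abs=1e-9)
    assert res.centrality["P.c"] == pytest.approx(1 / math.sqrt(2), abs=1e-9)


def test_star_closed_form_centrality():
    res = eigenvector_centrality(star(3))
    assert res.eigenvalue == pytest.approx(math.sqrt(3), abs=1e-9)
    assert res.centrality["P.c"] == pytest.approx(1 / math.sqrt(2), abs=1e-9)
    for leaf in ("r-0-x", "r-1-x", "r-2-x"):
        assert res.centrality[leaf] == pytest.approx(1 / math.sqrt(6), abs=1e-9)


def test_centrality_matches_dense_eigendecomposition():
    import networkx as nx

    rng = np.random.default_rng(5)
    for _ in range(10):
        net = random_bipartite_network(rng)
        res = eigenvector_centrality(net)
        A, nodes = net.full_adjacency()
        vals, vecs = np.linalg.eigh(A)
        x = np.array([res.centrality[n] for n in nodes])
        assert np.max(np.abs(A @ x - vals.max() * x)) < 1e-8
        assert np.max(np.abs(A @ x - res.eigenvalue * x)) < 1e-8
        if nx.is_connected(net.to_networkx()):
            lead = np.abs(vecs[:, np.argmax(vals)])
            lead /= np.linalg.norm(lead)
            assert np.max(np.abs(x - lead)) < 1e-8


def test_density_formula(fig_example_table):
    # star: n=4 nodes, m=3 links -> 3 / (4*3/2) = 0.5
    assert network_density(star(3)) == pytest.approx(0.5)
    # two-wordform network: n=3, m=2 -> 2/3
    fig_net = build_session_network(fig_example_table, "dyad1", "CS", 1)
    assert network_density(fig_net) == pytest.approx(2 / 3)
    # a fully linked network reaches density 1 (n=2 is the bipartite case)
    assert network_density(star(1)) == pytest.approx(1.0)


def test_bipartite_denominator_mode(fig_example_table):
    net = build_session_network(fig_example_table, "dyad1", "CS", 1)
    assert network_density(net, "bipartite") == pytest.approx(1.0)


def test_density_undefined_below_two_nodes(fig_example_table):
    empty = build_session_network(fig_example_table, "dyad1", "CDS", 1)
    assert math.isnan(network_density(empty))


def test_handshake_lemma_on_random_networks():
    rng = np.random.default_rng(9)
    for _ in range(100):
        net = random_bipartite_network(rng)
        assert sum(node_degree(net).values()) == 2 * net.m


def test_density_bounds_unipartite_mode():
    rng = np.random.default_rng(11)
    for _ in range(200):
        net = random_bipartite_network(rng)
        d = network_density(net)
        if net.n >= 3:
            assert 0 < d <= 1
        elif net.n == 2:
            assert d == 1.0


def test_activation_runs_and_gaps():
    rows = []
    for sess, age in [(6, 680), (8, 690)]:
        rows.append({"session_index": sess, "age_days": age, "root": "l-m-d",
                     "binyan": "Qal", "temporal": "Infinitive"})
    for sess, age in [(6, 680), (7, 685), (8, 690)]:
        rows.append({"session_index": sess, "age_days": age, "root": "g-d-l",
                     "binyan": "Qal", "temporal": "Infinitive"})
    table = make_table(rows)
    series = build_network_series(table, "dyad1")
    act = activation_timeline(series, "CS")
    assert act.stats.loc["l-m-d", "n_runs"] == 2
    assert act.stats.loc["l-m-d", "n_gaps"] == 1
    assert act.stats.loc["l-m-d", "mean_gap_length"] == 1.0
    assert act.stats.loc["g-d-l", "n_runs"] == 1
    assert act.stats.loc["g-d-l", "n_gaps"] == 0


def test_measure_table_row_counts():
    rows = []
    for sess, age in [(1, 664), (2, 668)]:
        for speaker in ("CS", "CDS"):
            for root in ("l-m-d", "g-d-l", "m-s-r"):
                rows.append({"session_index": sess, "age_days": age,
                             "speaker": speaker, "root": root,
                             "binyan": "Qal", "temporal": "Infinitive"})
    table = make_table(rows)
    series = build_network_series(table, "dyad1")
    measures = measure_table(series)
    node_rows = measures[measures.level == "node"]
    net_rows = measures[measures.level == "network"]
    # 3 roots + 1 pattern active per (session, speaker)
    assert len(node_rows) == 2 * 2 * 4
    assert len(net_rows) == 2 * 2
    # every node row has a matching network-level row
    keys = set(map(tuple, net_rows[["session_index", "speaker"]].values))
    assert set(map(tuple, node_rows[["session_index", "speaker"]].values)) <= keys


def test_measures_invariant_under_row_permutation(small_sim):
    _, table, _ = small_sim
    series = build_network_series(table, "dyad1")
    measures = measure_table(series)
    shuffled = from_records(
        table.df.sample(frac=1.0, random_state=3).to_dict("records")
    )
    measures2 = measure_table(build_network_series(shuffled, "dyad1"))
    left = measures.sort_values(["session_index", "speaker", "level", "node"]).reset_index(drop=True)
    right = measures2.sort_values(["session_index", "speaker", "level", "node"]).reset_index(drop=True)
    for col in ("degree", "centrality", "density"):
        np.testing.assert_allclose(left[col], right[col], atol=1e-12)


def test_centrality_residual_within_tolerance(small_sim):
    _, table, _ = small_sim
    series = build_network_series(table, "dyad1")
    for net in list(series.networks.values())[:6]:
        if net.is_empty or net.m < 1:
            continue
        res = eigenvector_centrality(net, tol=1e-10)
        assert res.residual < 1e-7
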