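import numpy as np
import pytest
from sklearn.metrics import rand_score

from fosmap.network import (
    bootstrap_null_edges,
    build_graph,
    build_network,
    cluster_communities,
    correlation_matrix,
    export_graphml,
    import_graphml,
)
from fosmap.synthetic import simulate_correlated_table, simulate_counts_table


def test_correlation_trivial_pairs():
    rows = []
    for s, (a, b) in enumerate(zip((1.0, 2.0, 3.0), (3.0, 2.0, 1.0))):
        for rid, v in ((1, a), (2, 2 * a), (3, b)):
            rows.append({"subject": f"s{s}", "condition": "c", "region_id": rid,
                         "acronym": f"R{rid}", "label_class": "cFos", "cells": 1,
                         "area_mm2": 1.0, "density": v})
    import pandas as pd

    r, regions = correlation_matrix(pd.DataFrame(rows), "c")
    i, j, k = regions.index(1), regions.index(2), regions.index(3)
    assert r[i, j] == pytest.approx(1.0)
    assert r[i, k] == pytest.approx(-1.0)
    assert np.allclose(np.diag(r), 1.0)


def test_correlation_matches_bruteforce_pearson():
    table = simulate_counts_table(n_regions=10, n_per_condition=8,
                                  conditions=("c",), seed=3)
    r, regions = correlation_matrix(table, "c")
    X = table.pivot_table(index="subject", columns="region_id",
                          values="density").to_numpy()
    p = len(regions)
    for i in range(p):
        for j in range(p):
            xi, xj = X[:, i], X[:, j]
            num = ((xi - xi.mean()) * (xj - xj.mean())).sum()
            den = np.sqrt(((xi - xi.mean()) ** 2).sum() * ((xj - xj.mean()) ** 2).sum())
            assert abs(r[i, j] - num / den) < 1e-12


def test_correlation_requires_three_subjects():
    table = simulate_counts_table(n_regions=3, n_per_condition=2,
                                  conditions=("c",), seed=0)
    with pytest.raises(ValueError):
        correlation_matrix(table, "c")


def test_zero_variance_region_set_missing(caplog):
    table = simulate_counts_table(n_regions=4, n_per_condition=5,
                                  conditions=("c",), seed=0)
    table.loc[table["region_id"] == 2, "density"] = 7.0
    with caplog.at_level("INFO"):
        r, regions = correlation_matrix(table, "c")
    j = regions.index(2)
    off_diag = [r[j, k] for k in range(len(regions)) if k != j]
    assert np.isnan(off_diag).all()
    assert r[j, j] == 1.0


def test_build_graph_thresholds():
    r = np.array([[1.0, 0.8, -0.2], [0.8, 1.0, 0.5], [-0.2, 0.5, 1.0]])
    assert build_graph(r, 0.75) == [(0, 1, 0.8)]
    assert len(build_graph(r, -1.0)) == 3  # complete graph
    assert build_graph(r, 1.0) == []
    with pytest.raises(ValueError):
        build_graph(r, 2.0)


def test_build_graph_matches_bruteforce_filter():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(8, 5))
    r = np.corrcoef(X, rowvar=False)
    edges = build_graph(r, 0.3)
    expected = [(i, j, r[i, j]) for i in range(5) for j in range(i + 1, 5)
                if r[i, j] >= 0.3]
    assert edges == expected


def test_cluster_two_cliques():
    edges = [(0, 1, 0.9), (1, 2, 0.9), (0, 2, 0.9),
             (3, 4, 0.9), (4, 5, 0.9), (3, 5, 0.9)]
    comm = cluster_communities(edges, n_nodes=6)
    assert comm[0] == comm[1] == comm[2]
    assert comm[3] == comm[4] == comm[5]
    assert comm[0] != comm[3]
    assert set(comm.values()) == {0, 1}


def test_cluster_empty_edges_singletons():
    comm = cluster_communities([], n_nodes=4)
    assert sorted(comm.values()) == [0, 1, 2, 3]


def test_cluster_recovers_planted_blocks():
    blocks = np.repeat([0, 1, 2], 10)
    scores = []
    for seed in range(10):
        rng = np.random.default_rng(seed)
        shared = rng.normal(size=(8, 3))
        X = np.sqrt(0.9) * shared[:, blocks] + np.sqrt(0.1) * rng.normal(size=(8, 30))
        r = np.corrcoef(X, rowvar=False)
        comm = cluster_communities(build_graph(r, 0.75), n_nodes=30)
        scores.append(rand_score(blocks, [comm[i] for i in range(30)]))
    assert np.mean(scores) >= 0.9


def test_null_edges_deterministic_given_seed():
    table = simulate_correlated_table(n_regions=8, seed=2)
    p1, r1, _ = bootstrap_null_edges(table, "ingroup", B=200, seed=5)
    p2, r2, _ = bootstrap_null_edges(table, "ingroup", B=200, seed=5)
    assert np.array_equal(p1, p2, equal_nan=True)
    assert np.array_equal(r1, r2)


def test_null_edges_validation():
    table = simulate_correlated_table(n_regions=5, conditions=("only",), seed=0)
    with pytest.raises(ValueError):
        bootstrap_null_edges(table, "only", B=200, seed=0)
    table2 = simulate_correlated_table(n_regions=5, seed=0)
    with pytest.raises(ValueError):
        bootstrap_null_edges(table2, "ingroup", B=50, seed=0)


def test_planted_unique_edge_is_flagged():
    table = simulate_correlated_table(n_regions=20, unique_edge=(2, 5),
                                      unique_r=0.9, seed=13)
    null_p, r_obs, regions = bootstrap_null_edges(table, "ingroup", B=500, seed=1)
    i, j = regions.index(2), regions.index(5)
    assert r_obs[i, j] > 0.7
    assert null_p[i, j] < 0.05


# ---------------------------------------------------------------------------
# GraphML

def test_graphml_roundtrip(tmp_path):
    table = simulate_correlated_table(n_regions=10, unique_edge=(1, 4),
                                      unique_r=0.9, seed=6)
    net = build_network(table, "ingroup", threshold=0.5, B=200, seed=3)
    path = tmp_path / "net.graphml"
    export_graphml(net, path)
    loaded = import_graphml(path)
    assert loaded.regions == net.regions
    assert loaded.communities == net.communities
    assert len(loaded.edges) == len(net.edges)
    for a, b in zip(loaded.edges, sorted(net.edges, key=lambda e: (e["i"], e["j"]))):
        assert a["i"] == b["i"] and a["j"] == b["j"]
        assert a["r"] == pytest.approx(b["r"], abs=1e-12)
        assert a["significant"] == b["significant"]


def test_graphml_empty_graph(tmp_path):
    table = simulate_correlated_table(n_regions=5, seed=1)
    net = build_network(table, "ingroup", threshold=0.9999, B=200, seed=0)
    path = tmp_path / "empty.graphml"
    export_graphml(net, path)
    loaded = import_graphml(path)
    assert loaded.edges == []
    assert len(loaded.regions) == 5


def test_import_handwritten_graphml(tmp_path):
    text = """<?xml version='1.0' encoding='utf-8'?>
<graphml xmlns="http://graphml.graphdrawing.org/xmlns">
  <key id="d0" for="node" attr.name="acronym" attr.type="string"/>
  <key id="d1" for="edge" attr.name="r" attr.type="double"/>
  <graph edgedefault="undirected">
    <node id="0"><data key="d0">ACC</data></node>
    <node id="1"><data key="d0">NAc</data></node>
    <node id="2"><data key="d0">INS</data></node>
    <edge source="0" target="1"><data key="d1">0.91</data></edge>
    <edge source="1" target="2"><data key="d1">0.82</data></edge>
  </graph>
</graphml>
"""
    path = tmp_path / "hand.graphml"
    path.write_text(text)
    net = import_graphml(path)
    assert net.acronyms == ["ACC", "NAc", "INS"]
    assert [(e["i"], e["j"], e["r"]) for e in net.edges] == [(0, 1, 0.91), (1, 2, 0.82)]


def test_import_malformed_graphml(tmp_path):
    path = tmp_path / "bad.graphml"
    path.write_text("this is not XML")
    with pytest.raises(ValueError):
        import_graphml(path)
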