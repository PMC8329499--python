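"""Filters, Pearson edges, network construction, MCODE, Table-1-style summary."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sedom.indices import index_table
from sedom.formula import parse_formula
from sedom.network import (
    _density,
    abundance_filter,
    build_network,
    correlated_molecule_summary,
    group_network,
    mcode,
    pearson_edges,
    prevalence_filter,
)


def test_prevalence_filter_strict_over_one_third():
    n = 36
    rows = {
        "in12": [1.0] * 12 + [0.0] * 24,  # 12 is not > 12 -> dropped
        "in13": [1.0] * 13 + [0.0] * 23,  # kept
        "everywhere": [1.0] * 36,
    }
    m = pd.DataFrame.from_dict(rows, orient="index", columns=[f"s{i}" for i in range(n)])
    kept, report = prevalence_filter(m)
    assert list(kept.index) == ["in13", "everywhere"]
    assert report["n_features_kept"] == 2


def test_abundance_filter_mean_threshold():
    m = pd.DataFrame(
        {"s1": [0.0006, 0.0004, 0.5], "s2": [0.0006, 0.0004, 0.5]},
        index=["kept", "dropped", "big"],
    )
    out = abundance_filter(m, min_pct=0.05)
    assert list(out.index) == ["kept", "big"]
    assert len(abundance_filter(m, min_pct=0.0)) == 3


def test_pearson_edges_examples(rng):
    n = 10
    x = rng.random(n)
    asv = pd.DataFrame(
        {f"s{i}": v for i, v in enumerate(np.vstack([2 * x + 3, -x, np.ones(n)]).T)},
    )
    asv.index = ["linear", "anti", "const"]
    dom = pd.DataFrame({f"s{i}": [v] for i, v in enumerate(x)}, index=["mol"])
    edges, log = pearson_edges(asv, dom, r_min=0.65, p_max=0.01)
    assert set(edges["asv"]) == {"linear"}
    assert edges["r"].iloc[0] == pytest.approx(1.0)
    assert any("const" in line for line in log)


def test_pearson_r065_at_n10_not_significant(rng):
    # r = 0.65 at n = 10 -> t ~ 2.42, two-sided p ~ 0.042 >= 0.01 -> rejected
    t = 0.65 * np.sqrt(8 / (1 - 0.65**2))
    p = 2 * stats.t.sf(t, df=8)
    assert p == pytest.approx(0.042, abs=0.002)
    base = rng.standard_normal(10)
    zb = (base - base.mean()) / base.std()
    nc = rng.standard_normal(10)
    nc -= nc.mean()
    nc -= (nc @ zb) / (zb @ zb) * zb  # orthogonal to zb, still zero-mean
    y = 0.65 * zb + np.sqrt(1 - 0.65**2) * nc / nc.std()
    r_real = np.corrcoef(base, y)[0, 1]
    assert r_real == pytest.approx(0.65, abs=1e-6)
    asv = pd.DataFrame([base - base.min() + 1], index=["a"], columns=[f"s{i}" for i in range(10)])
    dom = pd.DataFrame([y - y.min() + 1], index=["m"], columns=asv.columns)
    edges, _ = pearson_edges(asv, dom, r_min=0.65, p_max=0.01)
    assert len(edges) == 0


def test_build_network_summary_identity():
    edges = pd.DataFrame(
        {"asv": ["a1", "a1", "a2"], "molecule": ["m1", "m2", "m1"], "r": [0.9] * 3, "p": [1e-4] * 3}
    )
    g, summary = build_network(edges)
    assert summary.n_nodes == 4 and summary.n_edges == 3
    assert summary.average_neighbors == pytest.approx(2 * 3 / 4)
    dup = pd.concat([edges, edges.iloc[[0]]], ignore_index=True)
    g2, s2 = build_network(dup)
    assert s2.n_edges == 3  # duplicate edge collapsed
    g3, s3 = build_network(edges.iloc[:0])
    assert s3.n_nodes == 0 and s3.average_neighbors == 0.0


def test_group_network_conservation():
    edges = pd.DataFrame(
        {
            "asv": ["a1", "a2", "a3", "a3"],
            "molecule": ["m1", "m1", "m2", "m1"],
            "r": [0.9] * 4,
            "p": [1e-4] * 4,
        }
    )
    g, _ = build_network(edges)
    labels = {"a1": "G1", "a2": "G1", "a3": "G2", "m1": "lignins", "m2": "tannins"}
    h = group_network(g, labels)
    assert sum(d["weight"] for _, _, d in h.edges(data=True)) == g.number_of_edges()
    assert h.edges["G1", "lignins"]["weight"] == 2
    with pytest.raises(KeyError):
        group_network(g, {"a1": "G1"})


# -- MCODE -------------------------------------------------------------------


def test_mcode_k5_with_pendant_path():
    g = nx.complete_graph(5)
    g.add_edges_from([(4, 5), (5, 6)])
    mods = mcode(g)
    assert len(mods) == 1
    assert mods[0].nodes == frozenset(range(5))
    assert mods[0].score == pytest.approx(5.0)


def test_mcode_two_disjoint_k4_equal_scores():
    g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
    mods = mcode(g)
    assert len(mods) == 2
    assert mods[0].score == mods[1].score == pytest.approx(4.0)
    assert mods[0].nodes.isdisjoint(mods[1].nodes)


def test_mcode_edgeless_graph():
    assert mcode(nx.empty_graph(6)) == []


def _oracle_best_score(g):
    """Exhaustive search over connected induced subgraphs with min degree 2."""
    best = 0.0
    nodes = list(g.nodes)
    for r in range(3, len(nodes) + 1):
        for sub in itertools.combinations(nodes, r):
            h = g.subgraph(sub)
            if not nx.is_connected(h):
                continue
            if min(dict(h.degree()).values()) < 2:
                continue
            best = max(best, _density(h) * h.number_of_nodes())
    return best


def test_mcode_matches_oracle_on_planted_core_graphs(rng):
    """On graphs with one dense core plus sparse periphery, greedy MCODE
    recovers the exhaustively optimal density x size module."""
    for _ in range(40):
        k = int(rng.integers(4, 7))
        extra = int(rng.integers(1, 9 - k))
        g = nx.complete_graph(k)
        for j in range(extra):
            v = k + j
            g.add_node(v)
            for t in rng.choice(v, size=min(int(rng.integers(1, 3)), v), replace=False):
                g.add_edge(v, int(t))
        mods = mcode(g)
        top = mods[0].score if mods else 0.0
        assert top == pytest.approx(_oracle_best_score(g))


def test_mcode_never_exceeds_exhaustive_optimum(rng):
    """Greedy module score is bounded by the exhaustive densest-subgraph score
    on arbitrary random graphs (it need not attain it)."""
    for _ in range(40):
        n = int(rng.integers(4, 9))
        g = nx.gnp_random_graph(n, float(rng.uniform(0.2, 0.8)), seed=int(rng.integers(10**6)))
        mods = mcode(g)
        top = mods[0].score if mods else 0.0
        assert top <= _oracle_best_score(g) + 1e-9


def test_mcode_modules_are_vertex_disjoint(rng):
    g = nx.gnp_random_graph(40, 0.15, seed=5)
    mods = mcode(g)
    seen = set()
    for m in mods:
        assert not (m.nodes & seen)
        seen |= m.nodes
        assert m.score > 0


# -- Table-1-style summary -----------------------------------------------------


def _summary_fixture():
    tab = index_table([parse_formula(f) for f in ("C10H16O4", "C20H14O6")])
    edges = pd.DataFrame(
        {
            "asv": ["b1", "a1"],
            "molecule": [tab.index[0], tab.index[1]],
            "r": [0.9, 0.9],
            "p": [1e-4, 1e-4],
        }
    )
    domain = pd.Series({"b1": "Bacteria", "a1": "Archaea"})
    return tab, edges, domain


def test_summary_single_molecule_stats():
    tab, edges, domain = _summary_fixture()
    w = pd.Series(1.0, index=tab.index)
    out = correlated_molecule_summary(edges, tab, w, domain)
    assert out.loc[("Bacteria", "average"), "DBE"] == pytest.approx(tab["dbe"].iloc[0])
    assert out.loc[("Bacteria", "weighted_average"), "DBE"] == pytest.approx(tab["dbe"].iloc[0])
    assert out.loc[("Bacteria", "average_sd"), "DBE"] == 0.0
    assert out.loc[("Archaea", "n_molecules"), "DBE"] == 1


def test_summary_weighted_average_arithmetic():
    tab = index_table([parse_formula(f) for f in ("C10H12O3", "C20H12O5")])
    dbes = tab["dbe"]
    edges = pd.DataFrame(
        {"asv": ["b1", "b1"], "molecule": list(tab.index), "r": [0.9, 0.9], "p": [1e-4] * 2}
    )
    w = pd.Series([1.0, 3.0], index=tab.index)
    out = correlated_molecule_summary(edges, tab, w, pd.Series({"b1": "Bacteria"}))
    expected = (dbes.iloc[0] + 3 * dbes.iloc[1]) / 4
    assert out.loc[("Bacteria", "weighted_average"), "DBE"] == pytest.approx(expected)
    # equal weights reduce the weighted mean to the plain mean
    out2 = correlated_molecule_summary(edges, tab, pd.Series(1.0, index=tab.index), pd.Series({"b1": "Bacteria"}))
    assert out2.loc[("Bacteria", "weighted_average"), "DBE"] == pytest.approx(dbes.mean())
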