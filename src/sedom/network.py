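"""ASV-DOM bipartite association networks and MCODE module mining.

Features are pre-filtered by prevalence (detected in strictly more than a
fraction of samples, default one third) and, for molecules, by mean relative
abundance (default > 0.05%). Edges are significant positive Pearson
correlations between ASV and molecule profiles (defaults r >= 0.65 and
two-sided p < 0.01 from the t transform with n-2 df, no multiple-testing
correction). Dense modules are extracted with the MCODE algorithm (vertex
weighting by the density of the highest k-core of each closed neighborhood,
greedy seeded expansion, haircut post-processing, score = density x size).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "prevalence_filter",
    "abundance_filter",
    "pearson_edges",
    "NetworkSummary",
    "build_network",
    "group_network",
    "McodeModule",
    "mcode",
    "correlated_molecule_summary",
]


def prevalence_filter(
    matrix: pd.DataFrame, min_fraction: float = 1.0 / 3.0, strict: bool = True
) -> tuple[pd.DataFrame, dict]:
    """Keep features present (> 0) in more than ``min_fraction`` of samples.

    ``strict`` uses a strict inequality ("over one third"), so with 36
    samples a feature present in exactly 12 is dropped.
    """
    n = matrix.shape[1]
    present = (matrix > 0).sum(axis=1)
    cutoff = min_fraction * n
    keep = present > cutoff if strict else present >= cutoff
    report = {
        "n_samples": n,
        "n_features_in": int(matrix.shape[0]),
        "n_features_kept": int(keep.sum()),
        "cutoff_samples": float(cutoff),
        "strict": strict,
    }
    return matrix.loc[keep], report


def abundance_filter(matrix: pd.DataFrame, min_pct: float = 0.05) -> pd.DataFrame:
    """Keep molecules whose mean relative abundance exceeds ``min_pct`` percent.

    ``matrix`` must hold per-sample fractions; the mean is taken across
    samples and compared with min_pct / 100 (strict).
    """
    return matrix.loc[matrix.mean(axis=1) > min_pct / 100.0]


def pearson_edges(
    asv: pd.DataFrame,
    dom: pd.DataFrame,
    r_min: float = 0.65,
    p_max: float = 0.01,
) -> tuple[pd.DataFrame, list[str]]:
    """Significant positive Pearson correlations between ASVs and molecules.

    Both tables are feature x sample; only the shared samples are used (any
    dropped samples are noted in the returned log). Constant features are
    excluded with a log entry. Returns (edges, log) where edges has columns
    asv, molecule, r, p.
    """
    log: list[str] = []
    shared = asv.columns.intersection(dom.columns)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples")
    for side, table in (("asv", asv), ("dom", dom)):
        dropped = table.columns.difference(shared)
        if len(dropped):
            log.append(f"{side}: dropped samples without counterpart: {list(dropped)}")
    x = asv.loc[:, shared].to_numpy(dtype=float)
    y = dom.loc[:, shared].to_numpy(dtype=float)
    n = len(shared)

    def standardize(m, names, side):
        mu = m.mean(axis=1, keepdims=True)
        sd = m.std(axis=1, keepdims=True)
        const = (sd[:, 0] == 0) | ~np.isfinite(sd[:, 0])
        for name in np.asarray(names)[const]:
            log.append(f"{side}: excluded constant feature {name}")
        z = np.zeros_like(m)
        ok = ~const
        z[ok] = (m[ok] - mu[ok]) / sd[ok]
        return z, ok

    zx, okx = standardize(x, asv.index, "asv")
    zy, oky = standardize(y, dom.index, "dom")
    r = zx @ zy.T / n
    np.clip(r, -1.0, 1.0, out=r)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    mask = (r >= r_min) & (p < p_max) & okx[:, None] & oky[None, :]
    ii, jj = np.nonzero(mask)
    edges = pd.DataFrame(
        {
            "asv": asv.index.to_numpy()[ii],
            "molecule": dom.index.to_numpy()[jj],
            "r": r[ii, jj],
            "p": p[ii, jj],
        }
    )
    return edges, log


@dataclass(frozen=True)
class NetworkSummary:
    n_nodes: int
    n_edges: int
    average_neighbors: float  # 2E / N for a simple undirected graph
    degree: pd.Series


def build_network(edges: pd.DataFrame) -> tuple[nx.Graph, NetworkSummary]:
    """Simple undirected bipartite graph from an ASV-molecule edge table."""
    g = nx.Graph()
    for row in edges.itertuples(index=False):
        g.add_node(row.asv, kind="asv", bipartite=0)
        g.add_node(row.molecule, kind="molecule", bipartite=1)
        g.add_edge(row.asv, row.molecule, r=float(row.r), p=float(row.p))
    n, e = g.number_of_nodes(), g.number_of_edges()
    degree = pd.Series(dict(g.degree()), dtype=float).sort_index() if n else pd.Series(dtype=float)
    avg = 2.0 * e / n if n else 0.0
    return g, NetworkSummary(n_nodes=n, n_edges=e, average_neighbors=avg, degree=degree)


def group_network(g: nx.Graph, node_groups: dict) -> nx.Graph:
    """Collapse nodes by group label.

    Grouped edge weight = number of underlying significant pairs between the
    two groups; grouped node weight = summed degree of member nodes.
    """
    unlabeled = [v for v in g.nodes if v not in node_groups]
    if unlabeled:
        raise KeyError(f"nodes without a group label: {unlabeled[:5]}")
    h = nx.Graph()
    for v in g.nodes:
        grp = node_groups[v]
        if not h.has_node(grp):
            h.add_node(grp, weight=0, n_members=0)
        h.nodes[grp]["weight"] += g.degree(v)
        h.nodes[grp]["n_members"] += 1
    for u, v in g.edges:
        gu, gv = node_groups[u], node_groups[v]
        if h.has_edge(gu, gv):
            h.edges[gu, gv]["weight"] += 1
        else:
            h.add_edge(gu, gv, weight=1)
    return h


# ---------------------------------------------------------------------------
# MCODE


def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def _vertex_weights(g: nx.Graph) -> dict:
    """MCODE vertex weighting: k of the highest k-core of the closed
    neighborhood, times the density of that core."""
    weights = {}
    for v in g.nodes:
        nbhd = list(g.neighbors(v)) + [v]
        sub = g.subgraph(nbhd)
        if sub.number_of_edges() == 0:
            weights[v] = 0.0
            continue
        core_num = nx.core_number(sub)
        kmax = max(core_num.values())
        core_nodes = [u for u, c in core_num.items() if c >= kmax]
        weights[v] = kmax * _density(g.subgraph(core_nodes))
    return weights


@dataclass(frozen=True)
class McodeModule:
    nodes: frozenset
    seed: object
    score: float  # density x size
    density: float


def mcode(
    g: nx.Graph,
    degree_cutoff: int = 2,
    node_score_cutoff: float = 0.2,
    k_core: int = 2,
    haircut: bool = True,
    fluff: bool = False,
    max_depth: int = 100,
) -> list[McodeModule]:
    """MCODE dense-module detection with the published defaults.

    Vertices below ``degree_cutoff`` are never seeds. Complexes grow from the
    highest-weight unused vertex, admitting neighbors whose weight exceeds
    seed weight x (1 - node_score_cutoff), to ``max_depth`` hops. Modules
    must contain a ``k_core``-core; haircut trims them to their 2-core.
    Modules are vertex-disjoint and ranked by score = density x size.
    """
    if any(u == v for u, v in g.edges):
        g = g.copy()
        g.remove_edges_from(nx.selfloop_edges(g))
    weights = _vertex_weights(g)
    used: set = set()
    modules: list[McodeModule] = []
    order = sorted(g.nodes, key=lambda v: (-weights[v], str(v)))
    for seed in order:
        if seed in used or g.degree(seed) < degree_cutoff:
            continue
        threshold = weights[seed] * (1.0 - node_score_cutoff)
        members = {seed}
        frontier = [(seed, 0)]
        while frontier:
            v, depth = frontier.pop()
            if depth >= max_depth:
                continue
            for u in g.neighbors(v):
                if u in members or u in used:
                    continue
                if weights[u] > threshold:
                    members.add(u)
                    frontier.append((u, depth + 1))
        sub = g.subgraph(members)
        core = nx.k_core(sub, k_core)
        if core.number_of_nodes() == 0:
            used |= members
            continue
        final = nx.k_core(sub, 2) if haircut else sub
        if fluff:  # pragma: no cover - off by default, mirrors published flag
            extra = {
                u
                for v in list(final.nodes)
                for u in g.neighbors(v)
                if u not in used and _density(g.subgraph(list(g.neighbors(u)) + [u])) > 0.5
            }
            final = g.subgraph(set(final.nodes) | extra)
        if final.number_of_nodes() < 2:
            used |= members
            continue
        dens = _density(final)
        modules.append(
            McodeModule(
                nodes=frozenset(final.nodes),
                seed=seed,
                score=dens * final.number_of_nodes(),
                density=dens,
            )
        )
        used |= members | set(final.nodes)
    modules.sort(key=lambda m: (-m.score, -len(m.nodes), str(sorted(map(str, m.nodes)))))
    return modules


# ---------------------------------------------------------------------------
# correlated-molecule index summary (Table-1 style)

_SUMMARY_INDICES = {"dbe": "DBE", "mw": "MW", "ai_mod": "AI-mod", "hc": "H/C", "oc": "O/C"}


def _weighted_mean_sd(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    wsum = w.sum()
    m = float((w * x).sum() / wsum)
    var = float((w * (x - m) ** 2).sum() / wsum)
    return m, float(np.sqrt(var))


def correlated_molecule_summary(
    edges: pd.DataFrame,
    indices: pd.DataFrame,
    mean_fractions: pd.Series,
    asv_domain: dict | pd.Series,
) -> pd.DataFrame:
    """Average and abundance-weighted average indices of correlated molecules.

    A molecule is "bacteria-correlated" ("archaea-correlated") if it has at
    least one edge to an ASV of that domain; a molecule may count for both.
    For each domain the unweighted mean and SD over distinct molecules and
    the weighted mean and SD (weights = mean relative abundance) of DBE, MW,
    AI-mod, H/C and O/C are reported. Domains with no correlated molecule get
    NaN rows.
    """
    asv_domain = pd.Series(asv_domain)
    domains = sorted(set(asv_domain))
    rows = {}
    for domain in domains:
        asvs = set(asv_domain[asv_domain == domain].index)
        molecules = sorted(set(edges.loc[edges["asv"].isin(asvs), "molecule"]))
        for stat in ("average", "average_sd", "weighted_average", "weighted_average_sd"):
            rows[(domain, stat)] = {col: np.nan for col in _SUMMARY_INDICES.values()}
        rows[(domain, "n_molecules")] = {col: len(molecules) for col in _SUMMARY_INDICES.values()}
        if not molecules:
            continue
        sub = indices.loc[molecules]
        w = mean_fractions.reindex(molecules).to_numpy(dtype=float)
        if np.any(~np.isfinite(w)) or w.sum() <= 0:
            raise ValueError("mean_fractions must cover every correlated molecule")
        for key, col in _SUMMARY_INDICES.items():
            x = sub[key].to_numpy(dtype=float)
            rows[(domain, "average")][col] = float(x.mean())
            rows[(domain, "average_sd")][col] = float(x.std(ddof=0))
            wm, wsd = _weighted_mean_sd(x, w)
            rows[(domain, "weighted_average")][col] = wm
            rows[(domain, "weighted_average_sd")][col] = wsd
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index = pd.MultiIndex.from_tuples(out.index, names=["domain", "statistic"])
    return out
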