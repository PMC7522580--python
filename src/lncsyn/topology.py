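"""Topological characterization of the synergistic network.

Covers the degree-distribution power-law fit, clustering and path-length
metrics with a degree-preserving randomization null, node centralities,
per-node neighbor sign-consistency, and the shared-mRNA-count versus
co-expression-significance trend.

A strictly bipartite graph has no triangles, so its standard (triangle)
global clustering coefficient is identically zero; a 4-cycle based
coefficient is provided as the two-mode analogue and is the metric the
null comparison should use for cohesion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import SynergisticNetwork
from .stats import pearson_with_p


def _as_graph(network) -> nx.Graph:
    if isinstance(network, SynergisticNetwork):
        return network.graph
    if isinstance(network, nx.Graph):
        return network
    raise TypeError(f"expected a network, got {type(network)!r}")


# ---------------------------------------------------------------------------
# degree distribution


def fit_power_law(network) -> tuple[float, float]:
    """Fit P(k) ~ k**(-gamma) by least squares in log-log space.

    Accepts a network, a degree sequence, or a {degree: count} mapping.
    Returns (gamma, r_squared) of the line fitted to (log10 k,
    log10 P(k)) over observed positive degrees.  Fewer than 3 distinct
    positive degrees is an error (no meaningful line).
    """
    if isinstance(network, Mapping):
        counts = {int(k): float(v) for k, v in network.items() if k > 0 and v > 0}
    else:
        if isinstance(network, (SynergisticNetwork, nx.Graph)):
            degrees = [d for _, d in _as_graph(network).degree()]
        else:
            degrees = [int(d) for d in network]
        vals, cnts = np.unique([d for d in degrees if d > 0], return_counts=True)
        counts = dict(zip(vals.tolist(), cnts.tolist()))
    if len(counts) < 3:
        raise ValueError("need at least 3 distinct positive degrees for a power-law fit")
    k = np.array(sorted(counts))
    total = sum(counts.values())
    pk = np.array([counts[i] / total for i in k])
    x = np.log10(k)
    y = np.log10(pk)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r_squared = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(-slope), float(r_squared)


# ---------------------------------------------------------------------------
# clustering / path length


def _count_paths3_and_cycles4(g: nx.Graph) -> tuple[int, int]:
    """Counts of undirected 3-edge paths and (non-induced) 4-cycles."""
    nodes = list(g.nodes())
    idx = {n: i for i, n in enumerate(nodes)}
    deg = dict(g.degree())
    p3 = 0
    for u, v in g.edges():
        cn = len(set(g[u]) & set(g[v]))
        p3 += (deg[u] - 1) * (deg[v] - 1) - cn
    if len(nodes) == 0:
        return 0, 0
    A = nx.to_numpy_array(g, nodelist=nodes, dtype=np.int64)
    co = A @ A
    c4 = 0
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            c = co[i, j]
            if c >= 2:
                c4 += c * (c - 1) // 2
    return p3, c4 // 2


def clustering_and_path_metrics(network) -> tuple[float, float, float]:
    """(global_clustering, bipartite_cc4, mean_path_length).

    global_clustering is the usual 3 * triangles / connected triples;
    bipartite_cc4 is closed 3-edge paths / all 3-edge paths, where a path
    u-v-w-x is closed when the edge x-u exists (each 4-cycle closes four
    such paths); mean_path_length averages shortest-path lengths over all
    connected node pairs, pooled across components.
    """
    g = _as_graph(network)
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    global_clustering = nx.transitivity(g)
    if global_clustering == 0 and nx.is_bipartite(g) and g.number_of_edges() > 0:
        warnings.warn(
            "triangle clustering is identically 0 on a bipartite graph; "
            "use the 4-cycle coefficient for cohesion",
            stacklevel=2,
        )
    p3, c4 = _count_paths3_and_cycles4(g)
    bipartite_cc4 = (4.0 * c4 / p3) if p3 > 0 else 0.0

    total = 0
    count = 0
    for comp in nx.connected_components(g):
        if len(comp) < 2:
            continue
        sub = g.subgraph(comp)
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            for d in dists.values():
                if d > 0:
                    total += d
                    count += 1
    mean_path_length = total / count if count else float("nan")
    return float(global_clustering), float(bipartite_cc4), float(mean_path_length)


# ---------------------------------------------------------------------------
# degree-preserving null


@dataclass
class NullComparison:
    observed: float
    null_values: list[float]
    empirical_p: float
    n_replicates: int
    seed: int
    metric: str
    tail: str


_METRICS = {
    "mean_path_length": lambda g: clustering_and_path_metrics(g)[2],
    "global_clustering": lambda g: clustering_and_path_metrics(g)[0],
    "bipartite_cc4": lambda g: clustering_and_path_metrics(g)[1],
}


def _rewire_bipartite(edges: list[tuple], rng: np.random.Generator, n_swaps: int) -> list[tuple]:
    """Degree-preserving double-edge swaps on (lncRNA, miRNA, sign) triples.

    Swapping the miRNA endpoints of two edges keeps the bipartition and
    every node degree; signs travel with their lncRNA end.  Swaps that
    would duplicate an existing edge are rejected.
    """
    edges = list(edges)
    existing = {(l, m) for l, m, _ in edges}
    n_edges = len(edges)
    for _ in range(n_swaps):
        i, j = rng.integers(0, n_edges, size=2)
        if i == j:
            continue
        l1, m1, s1 = edges[i]
        l2, m2, s2 = edges[j]
        if m1 == m2 or (l1, m2) in existing or (l2, m1) in existing:
            continue
        existing.discard((l1, m1))
        existing.discard((l2, m2))
        edges[i] = (l1, m2, s1)
        edges[j] = (l2, m1, s2)
        existing.add((l1, m2))
        existing.add((l2, m1))
    return edges


def randomized_null(
    network,
    n_replicates: int = 1000,
    seed: int = 0,
    metric: str = "mean_path_length",
    swaps_per_edge: int = 10,
    tail: str = "greater",
) -> NullComparison:
    """Compare a topological metric against degree-preserving rewirings.

    Each replicate applies ``swaps_per_edge * |E|`` attempted double-edge
    swaps within the bipartite structure, then recomputes the metric.  The
    empirical p-value uses the add-one rule
    (1 + #{null at least as extreme}) / (n_replicates + 1).
    """
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    if tail not in ("greater", "less"):
        raise ValueError("tail must be 'greater' or 'less'")
    g = _as_graph(network)
    if g.number_of_edges() < 2:
        raise ValueError("network too small to rewire (< 2 edges)")
    classes = nx.get_node_attributes(g, "rna_class")
    edge_list = []
    for u, v, d in g.edges(data=True):
        lnc, mir = (u, v) if classes.get(u) == "lncRNA" else (v, u)
        edge_list.append((lnc, mir, d.get("sign", 1)))

    rng = np.random.default_rng(seed)
    n_swaps = swaps_per_edge * len(edge_list)
    null_values = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # the bipartite caveat is warned once, on the observed graph
        observed = _METRICS[metric](g)
        for _ in range(n_replicates):
            rewired = _rewire_bipartite(edge_list, rng, n_swaps)
            h = nx.Graph()
            for l, m, s in rewired:
                h.add_node(l, rna_class="lncRNA")
                h.add_node(m, rna_class="miRNA")
                h.add_edge(l, m, sign=s)
            null_values.append(_METRICS[metric](h))
    arr = np.asarray(null_values)
    if tail == "greater":
        extreme = int((arr >= observed).sum())
    else:
        extreme = int((arr <= observed).sum())
    empirical_p = (1 + extreme) / (n_replicates + 1)
    return NullComparison(
        observed=float(observed),
        null_values=[float(v) for v in null_values],
        empirical_p=float(empirical_p),
        n_replicates=n_replicates,
        seed=seed,
        metric=metric,
        tail=tail,
    )


# ---------------------------------------------------------------------------
# centralities


def compute_centralities(network) -> pd.DataFrame:
    """Degree, normalized betweenness and closeness for every node.

    Betweenness uses shortest-path counting with the standard pair
    normalization; closeness uses the Wasserman-Faust component scaling so
    disconnected graphs remain comparable.
    """
    g = _as_graph(network)
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    betweenness = nx.betweenness_centrality(g, normalized=True)
    closeness = nx.closeness_centrality(g, wf_improved=True)
    classes = nx.get_node_attributes(g, "rna_class")
    rows = [
        {
            "node_id": n,
            "rna_class": classes.get(n, ""),
            "degree": d,
            "betweenness": betweenness[n],
            "closeness": closeness[n],
        }
        for n, d in g.degree()
    ]
    return pd.DataFrame(rows).sort_values("node_id").reset_index(drop=True)


# ---------------------------------------------------------------------------
# neighbor sign consistency


def neighbor_consistency(
    network,
    consistency_threshold: float = 0.8,
    node_class: str = "lncRNA",
) -> tuple[pd.DataFrame, dict]:
    """Per-node split of positive/negative partners and a consistency flag.

    A node is consistent when at least ``consistency_threshold`` of its
    edges share one sign (boundary inclusive).  The summary reports the
    consistent fraction and, among consistent nodes, the positive/negative
    split.
    """
    g = _as_graph(network)
    rows = []
    for n, d in g.nodes(data=True):
        if d.get("rna_class") != node_class:
            continue
        signs = [g.edges[n, nbr].get("sign", 1) for nbr in g[n]]
        n_pos = sum(1 for s in signs if s > 0)
        n_neg = len(signs) - n_pos
        frac_pos = n_pos / len(signs) if signs else float("nan")
        consistent = bool(signs) and max(frac_pos, 1 - frac_pos) >= consistency_threshold
        if consistent:
            consistent_sign = 1 if frac_pos >= 1 - frac_pos else -1
        else:
            consistent_sign = 0
        rows.append(
            {
                "node_id": n,
                "n_pos": n_pos,
                "n_neg": n_neg,
                "frac_pos": frac_pos,
                "consistent": consistent,
                "consistent_sign": consistent_sign,
            }
        )
    profiles = pd.DataFrame(
        rows, columns=["node_id", "n_pos", "n_neg", "frac_pos", "consistent", "consistent_sign"]
    )
    if profiles.empty:
        return profiles, {"n_nodes": 0, "frac_consistent": float("nan")}
    n_cons = int(profiles["consistent"].sum())
    cons = profiles[profiles["consistent"]]
    summary = {
        "n_nodes": len(profiles),
        "n_consistent": n_cons,
        "frac_consistent": n_cons / len(profiles),
        "frac_consistent_positive": (cons["consistent_sign"] == 1).mean() if n_cons else float("nan"),
        "frac_consistent_negative": (cons["consistent_sign"] == -1).mean() if n_cons else float("nan"),
    }
    return profiles, summary


# ---------------------------------------------------------------------------
# shared-target count vs synergy significance


def shared_count_vs_significance(
    edges: pd.DataFrame | SynergisticNetwork,
    min_edges_per_bin: int = 5,
) -> tuple[pd.DataFrame, float, float]:
    """Trend between shared-mRNA count and co-expression significance.

    Edges are grouped by their shared-target count (counts with fewer than
    ``min_edges_per_bin`` edges are merged upward into the next count);
    per group the mean -log10 p of the synergy correlation is computed,
    and a Pearson trend between group centers and means is returned.
    With fewer than 3 groups, or zero variance across group means, the
    trend is undefined (NaN) and only the table is informative.
    """
    if isinstance(edges, SynergisticNetwork):
        edges = edges.edge_table().rename(columns={"n_shared_mrnas": "n_shared", "p": "p_syn"})
    df = edges.copy()
    if "n_shared" not in df.columns or "p_syn" not in df.columns:
        raise ValueError("edges must carry n_shared and p_syn columns")
    df = df.sort_values("n_shared")
    # merge sparse shared-count groups into the next larger count
    bins: list[list] = []
    current_rows: list = []
    current_counts: list = []
    for n_shared, grp in df.groupby("n_shared", sort=True):
        current_rows.append(grp)
        current_counts.append(n_shared)
        if sum(len(g) for g in current_rows) >= min_edges_per_bin:
            bins.append((current_counts, pd.concat(current_rows)))
            current_rows, current_counts = [], []
    if current_rows:
        if bins:
            prev_counts, prev_rows = bins[-1]
            bins[-1] = (prev_counts + current_counts, pd.concat([prev_rows] + current_rows))
        else:
            bins.append((current_counts, pd.concat(current_rows)))

    table = pd.DataFrame(
        {
            "bin_center": [float(np.mean(c)) for c, _ in bins],
            "shared_counts": [tuple(c) for c, _ in bins],
            "n_edges": [len(r) for _, r in bins],
            "mean_neglog10_p": [
                float(np.mean(-np.log10(np.maximum(r["p_syn"], 1e-300)))) for _, r in bins
            ],
        }
    )
    if len(table) < 3 or table["mean_neglog10_p"].nunique() == 1:
        return table, float("nan"), float("nan")
    trend_r, trend_p = pearson_with_p(table["bin_center"], table["mean_neglog10_p"])
    return table, trend_r, trend_p
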