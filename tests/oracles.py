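"""Independent reference implementations used only to check the package.

These deliberately avoid the code paths (and where possible the
libraries) used by the implementation: exact rational arithmetic for the
hypergeometric tail, direct shortest-path/path-count accumulation for
centralities, and a literal O-E sum for the log-rank statistic.
"""

from __future__ import annotations

from collections import deque
from fractions import Fraction
from math import comb

import numpy as np


def exact_hypergeom_upper(k: int, K: int, n: int, N: int) -> Fraction:
    """P(X >= k) by exhaustive enumeration with exact rationals."""
    total = comb(N, n)
    acc = 0
    for i in range(k, min(K, n) + 1):
        if n - i <= N - K:
            acc += comb(K, i) * comb(N - K, n - i)
    return Fraction(acc, total)


def _bfs_shortest_paths(adj: dict, source):
    """Distances and shortest-path counts from one source."""
    dist = {source: 0}
    sigma = {source: 1}
    queue = deque([source])
    while queue:
        v = queue.popleft()
        for w in adj[v]:
            if w not in dist:
                dist[w] = dist[v] + 1
                sigma[w] = 0
                queue.append(w)
            if dist[w] == dist[v] + 1:
                sigma[w] += sigma[v]
    return dist, sigma


def brute_centralities(graph) -> dict:
    """Degree, normalized betweenness and Wasserman-Faust closeness.

    Betweenness accumulates sigma_sv * sigma_vt / sigma_st over all
    unordered pairs {s, t} with v on a shortest s-t path, then divides by
    (n-1)(n-2)/2.  Closeness scales the within-component value by the
    reachable fraction.
    """
    nodes = list(graph.nodes())
    n = len(nodes)
    adj = {v: sorted(graph[v]) for v in nodes}
    dist_all = {}
    sigma_all = {}
    for s in nodes:
        dist_all[s], sigma_all[s] = _bfs_shortest_paths(adj, s)

    betweenness = {v: 0.0 for v in nodes}
    for i, s in enumerate(nodes):
        for t in nodes[i + 1 :]:
            if t not in dist_all[s]:
                continue
            d_st = dist_all[s][t]
            sig_st = sigma_all[s][t]
            for v in nodes:
                if v in (s, t) or v not in dist_all[s] or t not in dist_all[v]:
                    continue
                if dist_all[s][v] + dist_all[v][t] == d_st:
                    betweenness[v] += sigma_all[s][v] * sigma_all[v][t] / sig_st
    scale = (n - 1) * (n - 2) / 2
    if scale > 0:
        betweenness = {v: b / scale for v, b in betweenness.items()}

    closeness = {}
    for v in nodes:
        reach = len(dist_all[v]) - 1
        total = sum(dist_all[v].values())
        if reach == 0 or total == 0:
            closeness[v] = 0.0
        else:
            closeness[v] = (reach / (n - 1)) * (reach / total)

    return {
        v: {"degree": len(adj[v]), "betweenness": betweenness[v], "closeness": closeness[v]}
        for v in nodes
    }


def logrank_oe(time, event, group1_mask) -> tuple[float, float]:
    """Two-sample log-rank by a literal observed-minus-expected loop."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    g1 = np.asarray(group1_mask, bool)
    oe = 0.0
    var = 0.0
    for t in sorted(set(time[event == 1])):
        at_risk = time >= t
        n_total = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = int(((time == t) & (event == 1)).sum())
        d1 = int(((time == t) & (event == 1) & g1).sum())
        oe += d1 - d * n1 / n_total
        if n_total > 1:
            var += d * (n1 / n_total) * (1 - n1 / n_total) * (n_total - d) / (n_total - 1)
    return (0.0, 0.0) if var == 0 else (oe, var)


def breslow_partial_loglik(beta: float, time, event, x) -> float:
    """Literal Breslow partial log-likelihood for one covariate."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    x = np.asarray(x, float)
    ll = 0.0
    for t in sorted(set(time[event == 1])):
        at_risk = time >= t
        deaths = (time == t) & (event == 1)
        d = int(deaths.sum())
        ll += beta * x[deaths].sum() - d * np.log(np.exp(beta * x[at_risk]).sum())
    return float(ll)
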