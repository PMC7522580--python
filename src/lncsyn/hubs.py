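"""Disease-RNA enrichment, centrality comparison, hubs and hierarchy views.

Disease enrichment asks whether known disease RNAs are over-represented
among the network's members of a class relative to the candidate universe
(upper-tail hypergeometric).  Centrality comparisons use a one-sided
Wilcoxon rank-sum test (disease-annotated greater).  Hubs are the top
fraction of nodes by degree; the hub-induced subgraph and lncRNA-rooted
hierarchical views support mechanism inspection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import networkx as nx
import pandas as pd
from scipy import stats as sps

from .datatypes import AnnotationSet, SynergisticNetwork
from .stats import hypergeometric_upper


@dataclass
class EnrichmentResult:
    rna_class: str
    in_network_annotated: int
    network_class_size: int
    universe_annotated: int
    universe_size: int
    p_hyper: float


@dataclass
class HubSet:
    hub_ids: list[str]          # ordered by degree descending, ties by id
    top_frac: float
    n_hubs: int
    per_class: dict[str, int] = field(default_factory=dict)


def enrichment_test(
    network: SynergisticNetwork,
    annotated_ids: set[str],
    universe: set[str],
    rna_class: str,
) -> EnrichmentResult:
    """Hypergeometric enrichment of annotated RNAs among network members.

    ``universe`` is the candidate pool of the class considered for network
    membership (typically the RNAs of that class in the context-specific
    regulatory networks).
    """
    members = set(network.nodes_of_class(rna_class))
    if not members:
        raise ValueError(f"network has no nodes of class {rna_class!r}")
    universe = set(universe) | members  # members are by definition candidates
    annotated_in_universe = annotated_ids & universe
    k = len(members & annotated_in_universe)
    p = hypergeometric_upper(k, len(annotated_in_universe), len(members), len(universe))
    return EnrichmentResult(
        rna_class=rna_class,
        in_network_annotated=k,
        network_class_size=len(members),
        universe_annotated=len(annotated_in_universe),
        universe_size=len(universe),
        p_hyper=p,
    )


def compare_centrality(
    records: pd.DataFrame,
    annotated_ids: set[str],
    metric: str,
    alternative: str = "greater",
) -> tuple[float, float, dict]:
    """Wilcoxon rank-sum comparison of a centrality between groups.

    Splits the centrality table into annotated vs other nodes and runs a
    rank-sum test (one-sided "annotated greater" by default).  Exact
    enumeration is used for small tie-free samples, the tie-corrected
    normal approximation otherwise.  Returns (W, p, medians).
    """
    if metric not in ("degree", "betweenness", "closeness"):
        raise ValueError(f"unknown centrality metric {metric!r}")
    ann = records[records["node_id"].isin(annotated_ids)][metric].to_numpy(dtype=float)
    oth = records[~records["node_id"].isin(annotated_ids)][metric].to_numpy(dtype=float)
    if ann.size == 0 or oth.size == 0:
        raise ValueError("both groups must be non-empty")
    res = sps.mannwhitneyu(ann, oth, alternative=alternative, method="auto")
    medians = {"annotated": float(pd.Series(ann).median()), "other": float(pd.Series(oth).median())}
    return float(res.statistic), float(res.pvalue), medians


def select_hubs(network: SynergisticNetwork, top_frac: float = 0.1) -> HubSet:
    """Top-degree nodes: n_hubs = ceil(top_frac * |nodes|).

    Nodes are ranked by (degree descending, id ascending); boundary ties
    are resolved deterministically by id order.
    """
    g = network.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    ranked = sorted(g.degree(), key=lambda item: (-item[1], item[0]))
    n_hubs = math.ceil(top_frac * g.number_of_nodes())
    hub_ids = [n for n, _ in ranked[:n_hubs]]
    per_class: dict[str, int] = {}
    for n in hub_ids:
        c = g.nodes[n]["rna_class"]
        per_class[c] = per_class.get(c, 0) + 1
    return HubSet(hub_ids=hub_ids, top_frac=top_frac, n_hubs=n_hubs, per_class=per_class)


def _round_percent(x: float) -> int:
    return int(Decimal(100 * x).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def hub_composition(
    hubset: HubSet,
    network: SynergisticNetwork,
    annotation: AnnotationSet | None = None,
) -> pd.DataFrame:
    """Per-class hub ratios, optionally with disease-annotated fractions.

    Percentages are rounded half-up to integers.  ``hub_pct`` is the share
    of the class selected as hubs; ``annotated_hub_pct`` /
    ``annotated_nonhub_pct`` compare disease-label prevalence inside and
    outside the hub set.
    """
    hubs = set(hubset.hub_ids)
    rows = []
    for rna_class in ("lncRNA", "miRNA"):
        members = network.nodes_of_class(rna_class)
        if not members:
            continue
        class_hubs = [n for n in members if n in hubs]
        row = {
            "rna_class": rna_class,
            "n_class": len(members),
            "n_hubs": len(class_hubs),
            "hub_pct": _round_percent(len(class_hubs) / len(members)),
        }
        if annotation is not None:
            disease = annotation.disease_ids(rna_class)
            nonhubs = [n for n in members if n not in hubs]
            row["annotated_hub_pct"] = (
                _round_percent(sum(n in disease for n in class_hubs) / len(class_hubs))
                if class_hubs
                else 0
            )
            row["annotated_nonhub_pct"] = (
                _round_percent(sum(n in disease for n in nonhubs) / len(nonhubs))
                if nonhubs
                else 0
            )
        rows.append(row)
    return pd.DataFrame(rows)


def hub_subnetwork(
    network: SynergisticNetwork, hubset: HubSet
) -> tuple[SynergisticNetwork, list[str]]:
    """Induced subgraph on the hub nodes plus the isolated hubs.

    Returns the hub-hub edge network and the hubs with no hub partner
    (reported separately rather than silently dropped).
    """
    g = network.graph
    hubs = [n for n in hubset.hub_ids if n in g]
    sub = g.subgraph(hubs).copy()
    isolated = sorted(n for n in sub.nodes() if sub.degree(n) == 0)
    sub.remove_nodes_from(isolated)
    return SynergisticNetwork(sub), isolated


@dataclass
class HierarchicalView:
    root: str
    mirna_layer: pd.DataFrame     # partner miRNAs with sign and disease flag
    mrna_layer: list[str]         # shared regulated mRNAs
    term_layer: pd.DataFrame      # terms covering >= min_term_count layer-3 mRNAs
    min_term_count: int
    mir_shared: dict[str, tuple[str, ...]] = field(default_factory=dict)


def build_hierarchical_view(
    network: SynergisticNetwork,
    lnc_id: str,
    annotation: AnnotationSet,
    min_term_count: int = 5,
) -> HierarchicalView:
    """lncRNA-rooted lncRNA -> miRNA -> mRNA -> term hierarchy.

    Layer 2 holds the root's synergistic miRNA partners (with disease
    flags), layer 3 the mRNAs each edge's shared-target set contributes,
    and layer 4 the annotation terms covering at least ``min_term_count``
    of those mRNAs (a display filter, not an enrichment statistic).
    """
    g = network.graph
    if lnc_id not in g:
        raise KeyError(f"{lnc_id!r} is not in the network")
    if g.nodes[lnc_id].get("rna_class") != "lncRNA":
        raise ValueError(f"{lnc_id!r} is not a lncRNA")
    mir_rows = []
    mrnas: set[str] = set()
    mir_shared: dict[str, tuple[str, ...]] = {}
    for mir in sorted(g[lnc_id]):
        d = g.edges[lnc_id, mir]
        mir_rows.append(
            {
                "miRNA": mir,
                "sign": d.get("sign", 1),
                "disease": mir in annotation.disease_miRNAs,
            }
        )
        shared = tuple(sorted(d.get("shared_mrnas", ())))
        mir_shared[mir] = shared
        mrnas |= set(shared)
    mirna_layer = pd.DataFrame(mir_rows, columns=["miRNA", "sign", "disease"])
    term_counts: dict[str, int] = {}
    for m in mrnas:
        for t in annotation.mrna_terms.get(m, ()):
            term_counts[t] = term_counts.get(t, 0) + 1
    term_layer = pd.DataFrame(
        [(t, c) for t, c in sorted(term_counts.items()) if c >= min_term_count],
        columns=["term", "n_mrnas"],
    )
    return HierarchicalView(
        root=lnc_id,
        mirna_layer=mirna_layer,
        mrna_layer=sorted(mrnas),
        term_layer=term_layer,
        min_term_count=min_term_count,
        mir_shared=mir_shared,
    )


def hierarchical_view_graph(view: HierarchicalView, annotation: AnnotationSet) -> nx.Graph:
    """Materialize a hierarchical view as an attributed layered graph."""
    g = nx.Graph()
    g.add_node(view.root, layer=1, node_type="lncRNA")
    for row in view.mirna_layer.itertuples():
        g.add_node(row.miRNA, layer=2, node_type="miRNA", disease=bool(row.disease))
        g.add_edge(view.root, row.miRNA, sign=int(row.sign))
    for m in view.mrna_layer:
        g.add_node(m, layer=3, node_type="mRNA")
        for mir, shared in view.mir_shared.items():
            if m in shared:
                g.add_edge(mir, m)
    kept_terms = set(view.term_layer["term"])
    for m in view.mrna_layer:
        for t in annotation.mrna_terms.get(m, ()):
            if t in kept_terms:
                g.add_node(t, layer=4, node_type="term")
                g.add_edge(m, t)
    return g
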