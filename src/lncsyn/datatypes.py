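"""Core in-memory containers shared across the pipeline.

Expression profiles live in pandas DataFrames (rows = RNAs, columns =
samples); graphs live in :class:`networkx.Graph` wrapped by
:class:`SynergisticNetwork` so edge/node attribute conventions are kept in
one place.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

RNA_CLASSES = ("lncRNA", "miRNA", "mRNA")


@dataclass
class ExpressionMatrix:
    """Expression values for one RNA class.

    ``data`` is indexed by RNA identifier with one column per sample.  After
    :func:`lncsyn.io.preprocess_expression` the values are on log2 scale and
    contain no missing entries; straight off disk they may contain NaNs.
    """

    data: pd.DataFrame
    rna_class: str
    log_scale: bool = False

    def __post_init__(self) -> None:
        if self.rna_class not in RNA_CLASSES:
            raise ValueError(f"unknown rna_class {self.rna_class!r}")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate RNA ids: {dupes}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")

    @property
    def rna_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_rnas(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def restrict_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        samples = list(samples)
        missing = [s for s in samples if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples absent from {self.rna_class} matrix: {missing}")
        return ExpressionMatrix(self.data.loc[:, samples], self.rna_class, self.log_scale)


@dataclass
class ClinicalTable:
    """Per-sample survival and tissue annotations.

    ``data`` columns: ``sample_id``, ``time`` (days, >= 0), ``event``
    (1 = death, 0 = censored), ``tissue`` ("tumor" or "normal").
    """

    data: pd.DataFrame

    REQUIRED = ("sample_id", "time", "event", "tissue")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"clinical table missing columns: {missing}")
        df = self.data
        if df["sample_id"].duplicated().any():
            dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample ids in clinical table: {dupes}")
        if (df["time"] < 0).any():
            raise ValueError("negative survival times")
        if not df["event"].isin([0, 1]).all():
            raise ValueError("event indicator must be 0 or 1")
        if not df["tissue"].isin(["tumor", "normal"]).all():
            raise ValueError("tissue must be 'tumor' or 'normal'")

    def tumor(self) -> pd.DataFrame:
        return self.data[self.data["tissue"] == "tumor"].reset_index(drop=True)


@dataclass
class AnnotationSet:
    """Disease-labelled RNA identifiers plus mRNA term annotations."""

    disease_lncRNAs: set[str] = field(default_factory=set)
    disease_miRNAs: set[str] = field(default_factory=set)
    mrna_terms: dict[str, list[str]] = field(default_factory=dict)

    def disease_ids(self, rna_class: str) -> set[str]:
        if rna_class == "lncRNA":
            return self.disease_lncRNAs
        if rna_class == "miRNA":
            return self.disease_miRNAs
        raise ValueError(f"no disease labels for class {rna_class!r}")


@dataclass
class SynergisticNetwork:
    """Signed bipartite lncRNA-miRNA graph.

    Node attribute ``rna_class`` is "lncRNA" or "miRNA".  Edge attributes:
    ``sign`` (+1/-1), ``r`` (lncRNA-miRNA Pearson r), ``p`` (its two-sided
    p-value), ``shared_mrnas`` (tuple of co-regulated mRNA ids) and
    ``n_shared``.
    """

    graph: nx.Graph

    def __post_init__(self) -> None:
        for u, v in self.graph.edges():
            cu = self.graph.nodes[u].get("rna_class")
            cv = self.graph.nodes[v].get("rna_class")
            if {cu, cv} != {"lncRNA", "miRNA"}:
                raise ValueError(f"edge ({u}, {v}) violates lncRNA-miRNA bipartition")

    def nodes_of_class(self, rna_class: str) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d.get("rna_class") == rna_class
        )

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_table(self) -> pd.DataFrame:
        rows = []
        for u, v, d in self.graph.edges(data=True):
            lnc, mir = (u, v) if self.graph.nodes[u]["rna_class"] == "lncRNA" else (v, u)
            rows.append(
                {
                    "lncRNA": lnc,
                    "miRNA": mir,
                    "sign": d["sign"],
                    "r": d["r"],
                    "p": d["p"],
                    "n_shared_mrnas": d["n_shared"],
                    "shared_mrnas": ",".join(d["shared_mrnas"]),
                }
            )
        cols = ["lncRNA", "miRNA", "sign", "r", "p", "n_shared_mrnas", "shared_mrnas"]
        df = pd.DataFrame(rows, columns=cols)
        return df.sort_values(["lncRNA", "miRNA"]).reset_index(drop=True)

    def summary(self) -> dict:
        """Audit-trail counts: nodes per class and signed edge totals."""
        signs = [d["sign"] for _, _, d in self.graph.edges(data=True)]
        return {
            "n_lncRNAs": len(self.nodes_of_class("lncRNA")),
            "n_miRNAs": len(self.nodes_of_class("miRNA")),
            "n_edges": self.graph.number_of_edges(),
            "n_positive": sum(1 for s in signs if s > 0),
            "n_negative": sum(1 for s in signs if s < 0),
        }


def network_from_edges(edges: Iterable[Mapping]) -> SynergisticNetwork:
    """Assemble a SynergisticNetwork from edge records.

    Each record needs keys ``lncRNA``, ``miRNA``, ``sign``, ``r``, ``p`` and
    ``shared_mrnas`` (iterable of mRNA ids).  Declared nodes are exactly the
    incident RNAs, so no isolated nodes are created.
    """
    g = nx.Graph()
    for e in edges:
        lnc, mir = e["lncRNA"], e["miRNA"]
        if g.has_edge(lnc, mir):
            raise ValueError(f"duplicate edge ({lnc}, {mir})")
        shared = tuple(sorted(e["shared_mrnas"]))
        g.add_node(lnc, rna_class="lncRNA")
        g.add_node(mir, rna_class="miRNA")
        g.add_edge(
            lnc,
            mir,
            sign=int(e["sign"]),
            r=float(e["r"]),
            p=float(e["p"]),
            shared_mrnas=shared,
            n_shared=len(shared),
        )
    return SynergisticNetwork(g)
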