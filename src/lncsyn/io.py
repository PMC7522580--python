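"""Reading, validation, preprocessing and serialization of pipeline data.

All on-disk formats are plain text: tab-separated tables for expression,
prior pairs, clinical data and networks; one-id-per-line files for disease
labels; GraphML for attributed graphs.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import (
    AnnotationSet,
    ClinicalTable,
    ExpressionMatrix,
    SynergisticNetwork,
    network_from_edges,
)

MISSING_TOKENS = {"", "na", "nan", "null"}

PRIOR_COLUMNS = ["regulator_id", "regulator_class", "mrna_id", "n_programs", "n_clip", "validated"]


# ---------------------------------------------------------------------------
# expression


def read_expression_table(path, rna_class: str) -> ExpressionMatrix:
    """Read a tab-separated RNA x sample expression table.

    First column holds RNA ids, the header row sample ids.  Empty cells and
    the tokens NA/NaN/null (any case) are treated as missing.  Duplicate RNA
    or sample ids and non-numeric cells raise with the offending id named.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, index_col=0, keep_default_na=False)
    if df.index.name is None and df.shape[1] == 0:
        raise ValueError(f"{path}: malformed header (no sample columns)")
    if df.columns.has_duplicates:
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate sample ids {dupes}")
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate RNA ids {dupes}")

    cleaned = df.apply(lambda col: col.str.strip())
    is_missing = cleaned.apply(lambda col: col.str.lower().isin(MISSING_TOKENS))
    numeric = cleaned.mask(is_missing).apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~is_missing
    if bad.any().any():
        r, c = np.argwhere(bad.values)[0]
        raise ValueError(
            f"{path}: non-numeric value {cleaned.iat[r, c]!r} "
            f"at RNA {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    return ExpressionMatrix(numeric.astype(float), rna_class, log_scale=False)


def write_expression_table(matrix: ExpressionMatrix, path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="rna_id", na_rep="NA")


def preprocess_expression(
    raw: ExpressionMatrix,
    max_missing_frac: float = 0.3,
    knn_k: int = 10,
    pseudocount: float = 1.0,
) -> ExpressionMatrix:
    """Filter, impute and log-transform a raw expression matrix.

    RNAs missing in more than ``max_missing_frac`` of samples are removed.
    Each remaining gap is filled with the unweighted mean of the ``knn_k``
    nearest RNAs (Euclidean distance over mutually observed samples) that
    have an observed value in that sample.  Finally every entry is mapped to
    log2(x + pseudocount).
    """
    values = raw.data.to_numpy(dtype=float).copy()
    missing_frac = np.isnan(values).mean(axis=1)
    keep = missing_frac <= max_missing_frac
    if not keep.any():
        raise ValueError("all RNAs exceed the missingness threshold")
    values = values[keep]
    ids = [r for r, k in zip(raw.rna_ids, keep) if k]

    if np.isnan(values).any():
        values = _knn_impute_rows(values, knn_k, ids)

    if np.any(values + pseudocount <= 0):
        raise ValueError("log2 transform undefined: values <= -pseudocount present")
    logged = np.log2(values + pseudocount)
    out = pd.DataFrame(logged, index=ids, columns=raw.sample_ids)
    return ExpressionMatrix(out, raw.rna_class, log_scale=True)


def _knn_impute_rows(values: np.ndarray, knn_k: int, ids: Sequence[str]) -> np.ndarray:
    """Row-wise KNN imputation on a matrix containing NaNs."""
    filled = values.copy()
    obs = ~np.isnan(values)
    for i in np.flatnonzero(np.isnan(values).any(axis=1)):
        diff = values - values[i]
        mutual = obs & obs[i]
        diff[~mutual] = 0.0
        d2 = np.einsum("ij,ij->i", diff, diff)
        usable_base = mutual.any(axis=1)
        usable_base[i] = False
        for j in np.flatnonzero(~obs[i]):
            donors = np.flatnonzero(usable_base & obs[:, j])
            if donors.size == 0:
                raise ValueError(f"no donor rows to impute RNA {ids[i]!r}")
            if donors.size < knn_k:
                warnings.warn(
                    f"only {donors.size} donor RNAs (< k={knn_k}) for {ids[i]!r}",
                    stacklevel=3,
                )
            nearest = donors[np.argsort(d2[donors], kind="mergesort")[:knn_k]]
            filled[i, j] = values[nearest, j].mean()
    return filled


def match_samples(*matrices: ExpressionMatrix) -> list[ExpressionMatrix]:
    """Restrict matrices to their common samples, in a shared column order.

    The order follows the first matrix's columns.  An empty intersection is
    an error.
    """
    if len(matrices) < 2:
        raise ValueError("need at least two matrices to match")
    common = set(matrices[0].sample_ids)
    for m in matrices[1:]:
        common &= set(m.sample_ids)
    if not common:
        raise ValueError("no samples shared by all matrices")
    ordered = [s for s in matrices[0].sample_ids if s in common]
    return [m.restrict_samples(ordered) for m in matrices]


# ---------------------------------------------------------------------------
# prior pairs


def read_prior_pairs(path) -> pd.DataFrame:
    """Read a regulator->mRNA prior pair table (see PRIOR_COLUMNS)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PRIOR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: prior pair table missing columns {missing}")
    df["validated"] = df["validated"].astype(bool)
    if (df["n_programs"] < 0).any() or (df["n_clip"] < 0).any():
        raise ValueError(f"{path}: negative evidence counts")
    return df[PRIOR_COLUMNS].copy()


def write_prior_pairs(pairs: pd.DataFrame, path) -> None:
    pairs.to_csv(path, sep="\t", index=False)


def filter_prior_pairs(
    pairs: pd.DataFrame,
    min_programs: int = 3,
    min_clip: int = 3,
    keep_validated: bool = True,
) -> pd.DataFrame:
    """Evidence-filter and deduplicate prior regulator->mRNA pairs.

    A pair is retained if it has prediction support from at least
    ``min_programs`` programs AND at least ``min_clip`` CLIP-seq datasets,
    or (when ``keep_validated``) if it is flagged as experimentally
    validated.  Duplicated (regulator, mRNA) entries are merged first,
    keeping the maximal evidence counts and OR-ing the validated flag.
    """
    if pairs.empty:
        warnings.warn("empty prior pair set", stacklevel=2)
        return pairs.copy()
    merged = (
        pairs.groupby(["regulator_id", "regulator_class", "mrna_id"], as_index=False)
        .agg(n_programs=("n_programs", "max"), n_clip=("n_clip", "max"), validated=("validated", "any"))
    )
    keep = (merged["n_programs"] >= min_programs) & (merged["n_clip"] >= min_clip)
    if keep_validated:
        keep |= merged["validated"]
    out = merged[keep].reset_index(drop=True)[
        ["regulator_id", "regulator_class", "mrna_id", "n_programs", "n_clip", "validated"]
    ]
    if out.empty:
        warnings.warn("no prior pairs survive the evidence filter", stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# clinical / annotation


def read_clinical_table(path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t")
    return ClinicalTable(df)


def write_clinical_table(table: ClinicalTable, path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


def read_id_list(path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_id_list(ids: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for i in sorted(set(ids)):
            fh.write(f"{i}\n")


def read_term_mapping(path) -> dict[str, list[str]]:
    """Read a two-column (mrna_id, term) tab-separated mapping."""
    df = pd.read_csv(path, sep="\t")
    if not {"mrna_id", "term"}.issubset(df.columns):
        raise ValueError(f"{path}: term mapping needs columns mrna_id, term")
    out: dict[str, list[str]] = {}
    for mrna, term in zip(df["mrna_id"], df["term"]):
        out.setdefault(str(mrna), []).append(str(term))
    return out


def write_term_mapping(mapping: dict[str, list[str]], path) -> None:
    rows = [(m, t) for m in sorted(mapping) for t in mapping[m]]
    pd.DataFrame(rows, columns=["mrna_id", "term"]).to_csv(path, sep="\t", index=False)


def read_annotation_set(lnc_path, mir_path, terms_path=None) -> AnnotationSet:
    return AnnotationSet(
        disease_lncRNAs=read_id_list(lnc_path),
        disease_miRNAs=read_id_list(mir_path),
        mrna_terms=read_term_mapping(terms_path) if terms_path else {},
    )


# ---------------------------------------------------------------------------
# networks


def write_network(network: SynergisticNetwork, path, format: str = "edgelist_tsv") -> None:
    """Serialize a synergistic network as a TSV edge list or GraphML."""
    path = Path(path)
    if format == "edgelist_tsv":
        network.edge_table().to_csv(path, sep="\t", index=False)
    elif format == "graphml":
        g = nx.Graph()
        for n, d in network.graph.nodes(data=True):
            g.add_node(n, rna_class=d["rna_class"])
        for u, v, d in network.graph.edges(data=True):
            g.add_edge(
                u,
                v,
                sign=int(d["sign"]),
                r=float(d["r"]),
                p=float(d["p"]),
                shared_mrnas=",".join(d["shared_mrnas"]),
                n_shared=int(d["n_shared"]),
            )
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path, format: str = "edgelist_tsv") -> SynergisticNetwork:
    path = Path(path)
    if format == "edgelist_tsv":
        df = pd.read_csv(path, sep="\t", dtype={"shared_mrnas": str})
        edges = [
            {
                "lncRNA": row.lncRNA,
                "miRNA": row.miRNA,
                "sign": row.sign,
                "r": row.r,
                "p": row.p,
                "shared_mrnas": row.shared_mrnas.split(",") if isinstance(row.shared_mrnas, str) and row.shared_mrnas else (),
            }
            for row in df.itertuples()
        ]
        return network_from_edges(edges)
    if format == "graphml":
        g = nx.read_graphml(path)
        edges = [
            {
                "lncRNA": u if g.nodes[u]["rna_class"] == "lncRNA" else v,
                "miRNA": v if g.nodes[u]["rna_class"] == "lncRNA" else u,
                "sign": d["sign"],
                "r": d["r"],
                "p": d["p"],
                "shared_mrnas": d["shared_mrnas"].split(",") if d.get("shared_mrnas") else (),
            }
            for u, v, d in g.edges(data=True)
        ]
        net = network_from_edges(edges)
        # preserve declared-but-isolated nodes if any were stored
        for n, d in g.nodes(data=True):
            if n not in net.graph:
                net.graph.add_node(n, rna_class=d["rna_class"])
        return net
    raise ValueError(f"unknown network format {format!r}")
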