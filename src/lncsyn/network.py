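"""Four-step construction of the signed lncRNA-miRNA synergistic network.

1. Evidence-filtered prior regulator->mRNA pairs (see :mod:`lncsyn.io`).
2. Expression filtering: each prior pair is tested by Pearson correlation
   on sample-matched profiles; lncRNA-mRNA pairs are kept when the
   correlation is significant after FDR adjustment (either sign), while
   miRNA-mRNA pairs must additionally be strongly negative (r < -0.4).
3. Co-regulation: every lncRNA-miRNA pair sharing at least one regulated
   mRNA is tested for a surprisingly large shared-target overlap with an
   upper-tail hypergeometric test, FDR-adjusted within the family.
4. Synergy: each co-regulated pair's own expression correlation gives the
   interaction direction (sign of r) and its raw p-value the final filter.

FDR adjustment is Benjamini-Hochberg, applied separately within each
testing family (lncRNA-mRNA, miRNA-mRNA, co-regulation).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, SynergisticNetwork, network_from_edges
from .stats import benjamini_hochberg, hypergeometric_upper, pearson_matrix_with_p

REGULATORY_COLUMNS = ["regulator_id", "regulator_class", "mrna_id", "r", "p", "p_adj"]

COREG_COLUMNS = ["lnc_id", "mir_id", "k", "K", "n", "N", "p_hyper", "p_adj", "shared_mrnas"]


def build_regulatory_network(
    priors: pd.DataFrame,
    expr_reg: ExpressionMatrix,
    expr_mrna: ExpressionMatrix,
    mode: str,
    alpha: float = 0.05,
    r_max: float | None = None,
) -> pd.DataFrame:
    """Expression-filter prior pairs into a context-specific regulatory network.

    ``mode`` selects the regulator class and its default threshold set:
    "lncRNA" keeps pairs with adjusted p < alpha at either correlation
    sign; "miRNA" additionally requires r < r_max (default -0.4),
    reflecting the repressive miRNA-target relationship.  BH adjustment is
    computed over exactly the pairs tested in this call.
    """
    if mode not in ("lncRNA", "miRNA"):
        raise ValueError(f"mode must be 'lncRNA' or 'miRNA', got {mode!r}")
    if mode == "miRNA" and r_max is None:
        r_max = -0.4
    if list(expr_reg.sample_ids) != list(expr_mrna.sample_ids):
        raise ValueError("expression matrices are not sample-matched")

    pairs = priors[priors["regulator_class"] == mode]
    pairs = pairs[
        pairs["regulator_id"].isin(expr_reg.data.index)
        & pairs["mrna_id"].isin(expr_mrna.data.index)
    ].drop_duplicates(subset=["regulator_id", "mrna_id"])
    if pairs.empty:
        warnings.warn(f"no testable {mode}-mRNA prior pairs", stacklevel=2)
        return pd.DataFrame(columns=REGULATORY_COLUMNS)

    X = expr_reg.data.loc[pairs["regulator_id"]].to_numpy()
    Y = expr_mrna.data.loc[pairs["mrna_id"]].to_numpy()
    r, p = pearson_matrix_with_p(X, Y)
    p_adj = benjamini_hochberg(p)

    out = pd.DataFrame(
        {
            "regulator_id": pairs["regulator_id"].to_numpy(),
            "regulator_class": mode,
            "mrna_id": pairs["mrna_id"].to_numpy(),
            "r": r,
            "p": p,
            "p_adj": p_adj,
        }
    )
    keep = (out["p_adj"] < alpha) & np.isfinite(out["r"])
    if r_max is not None:
        keep &= out["r"] < r_max
    return out[keep].reset_index(drop=True)


def find_coregulated_pairs(
    lnc_net: pd.DataFrame,
    mir_net: pd.DataFrame,
    alpha_coreg: float = 0.01,
    universe_size: int | None = None,
) -> pd.DataFrame:
    """Shared-target test for every candidate lncRNA-miRNA pair.

    For a lncRNA regulating K mRNAs and a miRNA regulating n mRNAs out of
    a universe of N, the overlap k is referred to the upper tail of
    Hypergeometric(N, K, n).  Pairs with no shared target are not tested
    (they cannot be co-regulated, and including them would only inflate
    the adjustment family).  By default N is the number of distinct mRNAs
    in the union of the two regulatory networks.
    """
    if lnc_net.empty or mir_net.empty:
        return pd.DataFrame(columns=COREG_COLUMNS)
    lnc_targets = {r: set(g["mrna_id"]) for r, g in lnc_net.groupby("regulator_id")}
    mir_targets = {r: set(g["mrna_id"]) for r, g in mir_net.groupby("regulator_id")}
    if universe_size is None:
        universe_size = len(set(lnc_net["mrna_id"]) | set(mir_net["mrna_id"]))
    N = int(universe_size)

    rows = []
    for lnc in sorted(lnc_targets):
        K = len(lnc_targets[lnc])
        for mir in sorted(mir_targets):
            shared = lnc_targets[lnc] & mir_targets[mir]
            if not shared:
                continue
            n = len(mir_targets[mir])
            k = len(shared)
            rows.append(
                {
                    "lnc_id": lnc,
                    "mir_id": mir,
                    "k": k,
                    "K": K,
                    "n": n,
                    "N": N,
                    "p_hyper": hypergeometric_upper(k, K, n, N),
                    "shared_mrnas": tuple(sorted(shared)),
                }
            )
    if not rows:
        return pd.DataFrame(columns=COREG_COLUMNS)
    df = pd.DataFrame(rows)
    df["p_adj"] = benjamini_hochberg(df["p_hyper"].to_numpy())
    df = df[df["p_adj"] < alpha_coreg].reset_index(drop=True)
    return df[COREG_COLUMNS]


def assign_synergy(
    co_pairs: pd.DataFrame,
    expr_lnc: ExpressionMatrix,
    expr_mir: ExpressionMatrix,
    synergy_alpha: float = 0.05,
    adjust: bool = False,
) -> SynergisticNetwork:
    """Correlate each co-regulated pair and assemble the signed network.

    A pair becomes an edge when its lncRNA-miRNA expression correlation is
    significant (raw p < synergy_alpha by default; set ``adjust`` for an
    FDR-adjusted cut instead).  The edge sign is the sign of r.
    """
    if co_pairs.empty:
        return network_from_edges([])
    if list(expr_lnc.sample_ids) != list(expr_mir.sample_ids):
        raise ValueError("expression matrices are not sample-matched")

    present = co_pairs["lnc_id"].isin(expr_lnc.data.index) & co_pairs["mir_id"].isin(
        expr_mir.data.index
    )
    skipped = co_pairs[~present]
    if not skipped.empty:
        warnings.warn(
            f"skipping {len(skipped)} co-regulated pairs with RNAs absent from expression",
            stacklevel=2,
        )
    co = co_pairs[present].reset_index(drop=True)
    if co.empty:
        return network_from_edges([])

    X = expr_lnc.data.loc[co["lnc_id"]].to_numpy()
    Y = expr_mir.data.loc[co["mir_id"]].to_numpy()
    r, p = pearson_matrix_with_p(X, Y)
    crit = benjamini_hochberg(p) if adjust else p
    edges = []
    for i in range(len(co)):
        if crit[i] < synergy_alpha and np.isfinite(r[i]) and r[i] != 0.0:
            edges.append(
                {
                    "lncRNA": co.at[i, "lnc_id"],
                    "miRNA": co.at[i, "mir_id"],
                    "sign": 1 if r[i] > 0 else -1,
                    "r": r[i],
                    "p": p[i],
                    "shared_mrnas": co.at[i, "shared_mrnas"],
                }
            )
    return network_from_edges(edges)


def build_synergistic_network(
    priors: pd.DataFrame,
    expr_lnc: ExpressionMatrix,
    expr_mir: ExpressionMatrix,
    expr_mrna: ExpressionMatrix,
    lnc_alpha: float = 0.05,
    mir_alpha: float = 0.05,
    mir_r_max: float = -0.4,
    coreg_alpha: float = 0.01,
    synergy_alpha: float = 0.05,
    universe_size: int | None = None,
) -> tuple[SynergisticNetwork, dict]:
    """Run steps 2-4 end to end; returns the network and intermediates.

    The second element maps stage names to the intermediate tables
    (``lnc_regulatory``, ``mir_regulatory``, ``coregulated``), mirroring
    the audit-trail counts a practitioner reports after every filter.
    """
    lnc_net = build_regulatory_network(priors, expr_lnc, expr_mrna, "lncRNA", alpha=lnc_alpha)
    mir_net = build_regulatory_network(
        priors, expr_mir, expr_mrna, "miRNA", alpha=mir_alpha, r_max=mir_r_max
    )
    co = find_coregulated_pairs(lnc_net, mir_net, alpha_coreg=coreg_alpha, universe_size=universe_size)
    net = assign_synergy(co, expr_lnc, expr_mir, synergy_alpha=synergy_alpha)
    return net, {"lnc_regulatory": lnc_net, "mir_regulatory": mir_net, "coregulated": co}
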