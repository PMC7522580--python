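import sys
import warnings
from pathlib import Path

import networkx as nx
import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper module

from lncsyn import io as lio
from lncsyn import network as lnet
from lncsyn.datatypes import SynergisticNetwork, network_from_edges
from lncsyn.simulate import generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """Synthetic dataset at the generator's default study conditions."""
    return generate_dataset(seed=1)


@pytest.fixture(scope="session")
def pipeline_products(default_dataset):
    """Preprocessed matrices, filtered priors and the inferred network."""
    ds = default_dataset
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mats = [
            lio.preprocess_expression(m) for m in (ds.expr_lnc, ds.expr_mir, ds.expr_mrna)
        ]
        expr_lnc, expr_mir, expr_mrna = lio.match_samples(*mats)
        priors = lio.filter_prior_pairs(ds.priors)
    net, intermediates = lnet.build_synergistic_network(priors, expr_lnc, expr_mir, expr_mrna)
    return {
        "dataset": ds,
        "expr_lnc": expr_lnc,
        "expr_mir": expr_mir,
        "expr_mrna": expr_mrna,
        "priors": priors,
        "network": net,
        "intermediates": intermediates,
    }


def random_bipartite_network(
    n_lnc: int, n_mir: int, n_edges: int, seed: int
) -> SynergisticNetwork:
    """A random signed bipartite network for topology/hub tests."""
    rng = np.random.default_rng(seed)
    possible = [(f"L{i}", f"M{j}") for i in range(n_lnc) for j in range(n_mir)]
    chosen = rng.choice(len(possible), size=min(n_edges, len(possible)), replace=False)
    edges = []
    for idx in chosen:
        lnc, mir = possible[idx]
        r = float(rng.uniform(-0.9, 0.9)) or 0.1
        edges.append(
            {
                "lncRNA": lnc,
                "miRNA": mir,
                "sign": 1 if r > 0 else -1,
                "r": r,
                "p": float(rng.uniform(1e-6, 0.04)),
                "shared_mrnas": tuple(f"G{k}" for k in rng.choice(50, size=rng.integers(1, 6), replace=False)),
            }
        )
    return network_from_edges(edges)
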