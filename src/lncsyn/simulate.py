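"""Synthetic sample-matched expression, priors, clinical and label data.

The generator plants co-regulation modules with a known sign so that every
stage of the pipeline — expression preprocessing, correlation filtering,
shared-target testing, signed synergy assignment, hub analysis and the
survival model — can be exercised and scored against ground truth.

Each module m consists of one lncRNA, one miRNA and ``module_size`` mRNAs
tied to a per-sample latent factor z_m ~ N(0, 1):

    lncRNA_m = mu + signal_sd * z_m + noise
    miRNA_m  = mu + s_m * signal_sd * z_m + noise     (s_m = +/-1)
    mRNA     = mu - (miRNA_m - mu_mir) + noise        (anticorrelated)

so the miRNA and its targets are strongly negatively correlated, the
lncRNA correlates with the same targets, and corr(lncRNA_m, miRNA_m) has
sign s_m.  All other RNAs are independent noise.  Expression is emitted on
linear scale (2**g - 1) with injected missingness so preprocessing is
exercised end to end.

Survival times for tumor samples are exponential with a log-linear hazard
in the expression of two designated risk lncRNAs (the module-0 and
module-1 lncRNAs), mirroring a linear risk-score model; censoring replaces
a configurable fraction of events with uniformly drawn earlier times.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import AnnotationSet, ClinicalTable, ExpressionMatrix
from . import io as lio


@dataclass
class SimulationConfig:
    n_samples: int = 120          # tumor samples (survival cohort)
    n_normal: int = 30            # additional normal-tissue samples
    n_lnc: int = 60
    n_mir: int = 120
    n_mrna: int = 800
    n_modules: int = 20           # planted synergistic lncRNA-miRNA pairs
    module_size: int = 15         # shared mRNAs per module
    frac_positive_sign: float = 0.5
    signal_sd: float = 1.0
    noise_sd: float = 0.5
    background_pair_density: float = 0.01   # fraction of mRNAs each regulator targets at random
    missing_frac: float = 0.05
    baseline_rate: float = 1.0 / 1000.0     # events per day at the mean covariate
    beta: tuple[float, float] = (0.5, 1.1)  # log-hazard per unit expression of the risk lncRNAs
    censor_frac: float = 0.3
    false_label_frac: float = 0.1
    tumor_effect: float = 1.0     # tumor-vs-normal shift of the second risk lncRNA
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_samples", "n_lnc", "n_mir", "n_mrna", "n_modules", "module_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_normal < 0:
            raise ValueError("n_normal must be non-negative")
        if not 0 <= self.frac_positive_sign <= 1:
            raise ValueError("frac_positive_sign must be in [0, 1]")
        if not 0 <= self.censor_frac < 1:
            raise ValueError("censor_frac must be in [0, 1)")
        if not 0 <= self.missing_frac < 1:
            raise ValueError("missing_frac must be in [0, 1)")
        if self.n_modules > min(self.n_lnc, self.n_mir):
            raise ValueError("n_modules exceeds the lncRNA or miRNA pool")
        if self.n_modules * self.module_size > self.n_mrna:
            raise ValueError("module mRNA demand exceeds the mRNA pool")
        if self.n_modules < 2:
            raise ValueError("need at least 2 modules to designate two risk lncRNAs")


@dataclass
class GroundTruth:
    pairs: list[tuple[str, str, int]]           # (lncRNA, miRNA, sign)
    module_mrnas: dict[int, tuple[str, ...]]
    risk_lnc_ids: tuple[str, str]
    betas: tuple[float, float]
    disease_lncRNAs: set[str]
    disease_miRNAs: set[str]


@dataclass
class SimulatedDataset:
    expr_lnc: ExpressionMatrix     # linear scale, with missing values
    expr_mir: ExpressionMatrix
    expr_mrna: ExpressionMatrix
    priors: pd.DataFrame
    clinical: ClinicalTable
    annotation: AnnotationSet
    truth: GroundTruth
    config: SimulationConfig
    log_expression: dict = field(repr=False, default_factory=dict)  # noise-free-of-missingness log2 matrices


def generate_dataset(config: SimulationConfig | None = None, **overrides) -> SimulatedDataset:
    """Generate a complete synthetic dataset. Deterministic given the seed."""
    if config is None:
        config = SimulationConfig(**overrides)
    elif overrides:
        config = SimulationConfig(**{**asdict(config), **overrides})
    config.validate()
    rng = np.random.default_rng(config.seed)

    cols = [f"T{i + 1:04d}" for i in range(config.n_samples)] + [
        f"N{i + 1:04d}" for i in range(config.n_normal)
    ]
    n_cols = len(cols)
    lnc_ids = [f"LNC{i + 1:04d}" for i in range(config.n_lnc)]
    mir_ids = [f"MIR{i + 1:04d}" for i in range(config.n_mir)]
    mrna_ids = [f"MRNA{i + 1:04d}" for i in range(config.n_mrna)]

    total_sd = np.hypot(config.signal_sd, config.noise_sd)
    mu_lnc = rng.uniform(3, 8, config.n_lnc)
    mu_mir = rng.uniform(3, 8, config.n_mir)
    mu_mrna = rng.uniform(3, 8, config.n_mrna)
    g_lnc = mu_lnc[:, None] + rng.normal(0, total_sd, (config.n_lnc, n_cols))
    g_mir = mu_mir[:, None] + rng.normal(0, total_sd, (config.n_mir, n_cols))
    g_mrna = mu_mrna[:, None] + rng.normal(0, total_sd, (config.n_mrna, n_cols))

    n_pos = int(round(config.frac_positive_sign * config.n_modules))
    signs = np.array([1] * n_pos + [-1] * (config.n_modules - n_pos))
    signs = signs[rng.permutation(config.n_modules)]

    truth_pairs: list[tuple[str, str, int]] = []
    module_mrnas: dict[int, tuple[str, ...]] = {}
    prior_rows: list[tuple] = []
    for m in range(config.n_modules):
        z = rng.normal(0, 1, n_cols)
        s = int(signs[m])
        g_lnc[m] = mu_lnc[m] + config.signal_sd * z + rng.normal(0, config.noise_sd, n_cols)
        mir_centered = s * config.signal_sd * z + rng.normal(0, config.noise_sd, n_cols)
        g_mir[m] = mu_mir[m] + mir_centered
        lo = m * config.module_size
        targets = mrna_ids[lo : lo + config.module_size]
        for t, j in zip(targets, range(lo, lo + config.module_size)):
            g_mrna[j] = mu_mrna[j] - mir_centered + rng.normal(0, config.noise_sd, n_cols)
        truth_pairs.append((lnc_ids[m], mir_ids[m], s))
        module_mrnas[m] = tuple(targets)
        for t in targets:
            prior_rows.append((lnc_ids[m], "lncRNA", t, rng.integers(3, 8), rng.integers(3, 7), bool(rng.random() < 0.2)))
            prior_rows.append((mir_ids[m], "miRNA", t, rng.integers(3, 8), rng.integers(3, 7), bool(rng.random() < 0.2)))

    # disease-state shift: second risk lncRNA up-regulated in tumor samples
    risk_idx = (0, 1)
    g_lnc[risk_idx[1], : config.n_samples] += config.tumor_effect

    # random background prior pairs for every regulator (mostly pruned by
    # either the evidence filter or the expression-correlation filter)
    n_bg = max(1, int(round(config.background_pair_density * config.n_mrna)))
    for ids, klass in ((lnc_ids, "lncRNA"), (mir_ids, "miRNA")):
        for reg in ids:
            for t in rng.choice(mrna_ids, size=n_bg, replace=False):
                prior_rows.append(
                    (reg, klass, t, int(rng.integers(0, 8)), int(rng.integers(0, 7)), bool(rng.random() < 0.1))
                )
    priors = pd.DataFrame(prior_rows, columns=lio.PRIOR_COLUMNS)
    priors = priors.drop_duplicates(subset=["regulator_id", "mrna_id"], keep="first").reset_index(drop=True)

    # survival for tumor samples: exponential, log-linear hazard in the two
    # designated risk lncRNAs' (log-scale) expression
    x1 = g_lnc[risk_idx[0], : config.n_samples]
    x2 = g_lnc[risk_idx[1], : config.n_samples]
    b1, b2 = config.beta
    rate = config.baseline_rate * np.exp(b1 * (x1 - x1.mean()) + b2 * (x2 - x2.mean()))
    times = rng.exponential(1.0 / rate)
    event = (rng.random(config.n_samples) >= config.censor_frac).astype(int)
    censored = event == 0
    times[censored] = rng.uniform(0, times[censored])
    clin_rows = [
        {"sample_id": cols[i], "time": float(times[i]), "event": int(event[i]), "tissue": "tumor"}
        for i in range(config.n_samples)
    ] + [
        {"sample_id": c, "time": 0.0, "event": 0, "tissue": "normal"}
        for c in cols[config.n_samples :]
    ]
    clinical = ClinicalTable(pd.DataFrame(clin_rows))

    # disease labels: planted nodes plus a fraction of mislabelled background
    planted_lnc = {p[0] for p in truth_pairs}
    planted_mir = {p[1] for p in truth_pairs}
    n_false_lnc = int(round(config.false_label_frac * len(planted_lnc)))
    n_false_mir = int(round(config.false_label_frac * len(planted_mir)))
    bg_lnc = [i for i in lnc_ids if i not in planted_lnc]
    bg_mir = [i for i in mir_ids if i not in planted_mir]
    disease_lnc = planted_lnc | set(rng.choice(bg_lnc, size=min(n_false_lnc, len(bg_lnc)), replace=False))
    disease_mir = planted_mir | set(rng.choice(bg_mir, size=min(n_false_mir, len(bg_mir)), replace=False))

    # term annotations: one process per module plus a broad background term
    mrna_terms: dict[str, list[str]] = {}
    for m, targets in module_mrnas.items():
        for t in targets:
            mrna_terms.setdefault(t, []).append(f"process_{m:02d}")
    for t in rng.choice(mrna_ids, size=config.n_mrna // 3, replace=False):
        mrna_terms.setdefault(t, []).append("metabolic_process")
    annotation = AnnotationSet(set(disease_lnc), set(disease_mir), mrna_terms)

    def to_linear(g: np.ndarray, ids: list[str], klass: str) -> ExpressionMatrix:
        raw = np.power(2.0, g) - 1.0
        if config.missing_frac > 0:
            mask = rng.random(raw.shape) < config.missing_frac
            raw = raw.copy()
            raw[mask] = np.nan
        return ExpressionMatrix(pd.DataFrame(raw, index=ids, columns=cols), klass, log_scale=False)

    expr_lnc = to_linear(g_lnc, lnc_ids, "lncRNA")
    expr_mir = to_linear(g_mir, mir_ids, "miRNA")
    expr_mrna = to_linear(g_mrna, mrna_ids, "mRNA")

    truth = GroundTruth(
        pairs=truth_pairs,
        module_mrnas=module_mrnas,
        risk_lnc_ids=(lnc_ids[risk_idx[0]], lnc_ids[risk_idx[1]]),
        betas=(b1, b2),
        disease_lncRNAs=planted_lnc,
        disease_miRNAs=planted_mir,
    )
    log_expr = {
        "lncRNA": pd.DataFrame(g_lnc, index=lnc_ids, columns=cols),
        "miRNA": pd.DataFrame(g_mir, index=mir_ids, columns=cols),
        "mRNA": pd.DataFrame(g_mrna, index=mrna_ids, columns=cols),
    }
    return SimulatedDataset(
        expr_lnc, expr_mir, expr_mrna, priors, clinical, annotation, truth, config, log_expr
    )


def write_dataset(ds: SimulatedDataset, out_dir) -> dict[str, Path]:
    """Write every fixture file in the pipeline's input formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expr_lnc": out / "expression_lncRNA.tsv",
        "expr_mir": out / "expression_miRNA.tsv",
        "expr_mrna": out / "expression_mRNA.tsv",
        "priors": out / "prior_pairs.tsv",
        "clinical": out / "clinical.tsv",
        "disease_lnc": out / "disease_lncRNAs.txt",
        "disease_mir": out / "disease_miRNAs.txt",
        "terms": out / "mrna_terms.tsv",
    }
    lio.write_expression_table(ds.expr_lnc, paths["expr_lnc"])
    lio.write_expression_table(ds.expr_mir, paths["expr_mir"])
    lio.write_expression_table(ds.expr_mrna, paths["expr_mrna"])
    lio.write_prior_pairs(ds.priors, paths["priors"])
    lio.write_clinical_table(ds.clinical, paths["clinical"])
    lio.write_id_list(ds.annotation.disease_lncRNAs, paths["disease_lnc"])
    lio.write_id_list(ds.annotation.disease_miRNAs, paths["disease_mir"])
    lio.write_term_mapping(ds.annotation.mrna_terms, paths["terms"])
    return paths
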