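"""End-to-end orchestration: simulate/load -> preprocess -> network ->
topology -> disease hubs -> prognosis, with a reproducibility manifest.

Every stage's outputs are written under the run directory and checksummed
into the manifest; all randomness derives from the seeds recorded in the
configuration, so re-running a manifest's config reproduces its outputs.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as lio
from . import hubs as lhubs
from . import network as lnet
from . import survival as lsurv
from . import topology as ltopo
from .datatypes import SynergisticNetwork
from .simulate import SimulationConfig, generate_dataset, write_dataset

__version__ = "0.1.0"


@dataclass
class RunConfig:
    """All thresholds and inputs for a full run.

    Defaults follow the method's reference settings: 30% missingness cap,
    adjusted p < 0.05 for lncRNA-mRNA correlation, r < -0.4 and adjusted
    p < 0.05 for miRNA-mRNA, adjusted p < 0.01 for co-regulation, raw
    p < 0.05 for synergy, top 10% hubs, 80% neighbor consistency, 70%
    training fraction.
    """

    out_dir: str = "lncsyn_run"
    seed: int = 0
    simulation: dict | None = field(default_factory=dict)  # SimulationConfig overrides; None -> load inputs
    inputs: dict = field(default_factory=dict)              # file paths when not simulating
    max_missing_frac: float = 0.3
    knn_k: int = 10
    pseudocount: float = 1.0
    min_programs: int = 3
    min_clip: int = 3
    lnc_alpha: float = 0.05
    mir_alpha: float = 0.05
    mir_r_max: float = -0.4
    coreg_alpha: float = 0.01
    synergy_alpha: float = 0.05
    consistency_threshold: float = 0.8
    top_frac: float = 0.1
    null_replicates: int = 200
    train_frac: float = 0.7
    min_term_count: int = 5
    risk_lnc_ids: list | None = None   # None -> screen hub lncRNAs by Cox p

    def validate(self) -> None:
        for name in ("lnc_alpha", "mir_alpha", "coreg_alpha", "synergy_alpha"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0 <= self.max_missing_frac <= 1:
            raise ValueError("max_missing_frac outside [0, 1]")
        if not 0 < self.train_frac < 1:
            raise ValueError("train_frac outside (0, 1)")
        if not 0 < self.top_frac <= 1:
            raise ValueError("top_frac outside (0, 1]")
        if not 0 <= self.consistency_threshold <= 1:
            raise ValueError("consistency_threshold outside [0, 1]")
        if self.simulation is None and not self.inputs:
            raise ValueError("config must specify either simulation overrides or input paths")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class PipelineRun:
    """Stage runner that accumulates outputs, notices and the manifest."""

    def __init__(self, config: RunConfig):
        config.validate()
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {
            "package_version": __version__,
            "config": _jsonable(asdict(config)),
            "stages": {},
            "notices": [],
        }
        self.results: dict = {}

    def _record(self, stage: str, outputs: dict[str, Path], t0: float, counts: dict | None = None):
        self.manifest["stages"][stage] = {
            "outputs": {k: {"path": str(p), "sha256": _sha256(Path(p))} for k, p in outputs.items()},
            "counts": counts or {},
            "seconds": round(_time.monotonic() - t0, 3),
        }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def run_all(config: RunConfig) -> dict:
    """Execute every stage in dependency order; returns the manifest.

    When the synergistic network is empty, the downstream stages are
    skipped with an explicit notice instead of failing.
    """
    run = PipelineRun(config)
    ds = _stage_data(run)
    expr_lnc, expr_mir, expr_mrna, priors, clinical, annotation = ds
    net, intermediates = _stage_network(run, priors, expr_lnc, expr_mir, expr_mrna)
    if net.n_edges == 0:
        run.manifest["notices"].append(
            "synergistic network is empty; topology, disease and prognosis stages skipped"
        )
    else:
        _stage_topology(run, net)
        hubset = _stage_disease(run, net, intermediates, annotation)
        _stage_prognosis(run, net, hubset, expr_lnc, clinical)
    manifest_path = run.out / "manifest.json"
    manifest_path.write_text(json.dumps(_jsonable(run.manifest), indent=2, sort_keys=True))
    run.results["manifest_path"] = manifest_path
    run.results["manifest"] = run.manifest
    return run.results


def _stage_data(run: PipelineRun):
    cfg = run.config
    t0 = _time.monotonic()
    data_dir = run.out / "data"
    if cfg.simulation is not None:
        sim_cfg = SimulationConfig(**{"seed": cfg.seed, **cfg.simulation})
        ds = generate_dataset(sim_cfg)
        paths = write_dataset(ds, data_dir)
        raw_lnc, raw_mir, raw_mrna = ds.expr_lnc, ds.expr_mir, ds.expr_mrna
        priors_raw = ds.priors
        clinical = ds.clinical
        annotation = ds.annotation
        run.results["ground_truth"] = ds.truth
    else:
        paths = {k: Path(v) for k, v in cfg.inputs.items()}
        raw_lnc = lio.read_expression_table(paths["expr_lnc"], "lncRNA")
        raw_mir = lio.read_expression_table(paths["expr_mir"], "miRNA")
        raw_mrna = lio.read_expression_table(paths["expr_mrna"], "mRNA")
        priors_raw = lio.read_prior_pairs(paths["priors"])
        clinical = lio.read_clinical_table(paths["clinical"])
        annotation = lio.read_annotation_set(
            paths["disease_lnc"], paths["disease_mir"], paths.get("terms")
        )

    expr = [
        lio.preprocess_expression(m, cfg.max_missing_frac, cfg.knn_k, cfg.pseudocount)
        for m in (raw_lnc, raw_mir, raw_mrna)
    ]
    expr_lnc, expr_mir, expr_mrna = lio.match_samples(*expr)
    priors = lio.filter_prior_pairs(priors_raw, cfg.min_programs, cfg.min_clip)
    counts = {
        "n_lncRNAs": expr_lnc.n_rnas,
        "n_miRNAs": expr_mir.n_rnas,
        "n_mRNAs": expr_mrna.n_rnas,
        "n_samples": expr_lnc.n_samples,
        "n_prior_pairs_raw": len(priors_raw),
        "n_prior_pairs_filtered": len(priors),
    }
    run._record("data", paths, t0, counts)
    run.results.update(
        expr_lnc=expr_lnc, expr_mir=expr_mir, expr_mrna=expr_mrna,
        priors=priors, clinical=clinical, annotation=annotation,
    )
    return expr_lnc, expr_mir, expr_mrna, priors, clinical, annotation


def _stage_network(run: PipelineRun, priors, expr_lnc, expr_mir, expr_mrna):
    cfg = run.config
    t0 = _time.monotonic()
    net, inter = lnet.build_synergistic_network(
        priors, expr_lnc, expr_mir, expr_mrna,
        lnc_alpha=cfg.lnc_alpha, mir_alpha=cfg.mir_alpha, mir_r_max=cfg.mir_r_max,
        coreg_alpha=cfg.coreg_alpha, synergy_alpha=cfg.synergy_alpha,
    )
    out = run.out / "network"
    out.mkdir(exist_ok=True)
    paths = {
        "edges": out / "synergistic_edges.tsv",
        "graphml": out / "synergistic_network.graphml",
        "lnc_regulatory": out / "lncRNA_mRNA_regulatory.tsv",
        "mir_regulatory": out / "miRNA_mRNA_regulatory.tsv",
        "coregulated": out / "coregulated_pairs.tsv",
        "summary": out / "network_summary.json",
    }
    lio.write_network(net, paths["edges"], "edgelist_tsv")
    lio.write_network(net, paths["graphml"], "graphml")
    inter["lnc_regulatory"].to_csv(paths["lnc_regulatory"], sep="\t", index=False)
    inter["mir_regulatory"].to_csv(paths["mir_regulatory"], sep="\t", index=False)
    co = inter["coregulated"].copy()
    if not co.empty:
        co["shared_mrnas"] = co["shared_mrnas"].map(",".join)
    co.to_csv(paths["coregulated"], sep="\t", index=False)
    summary = dict(
        net.summary(),
        n_lnc_regulatory=len(inter["lnc_regulatory"]),
        n_mir_regulatory=len(inter["mir_regulatory"]),
        n_coregulated=len(inter["coregulated"]),
    )
    Path(paths["summary"]).write_text(json.dumps(_jsonable(summary), indent=2))
    run._record("network", paths, t0, summary)
    run.results.update(network=net, intermediates=inter, network_summary=summary)
    return net, inter


def _stage_topology(run: PipelineRun, net: SynergisticNetwork):
    cfg = run.config
    t0 = _time.monotonic()
    out = run.out / "topology"
    out.mkdir(exist_ok=True)
    centralities = ltopo.compute_centralities(net)
    profiles_lnc, summary_lnc = ltopo.neighbor_consistency(net, cfg.consistency_threshold, "lncRNA")
    profiles_mir, summary_mir = ltopo.neighbor_consistency(net, cfg.consistency_threshold, "miRNA")
    gcc, cc4, mpl = clustering = ltopo.clustering_and_path_metrics(net)
    report = {
        "global_clustering": gcc,
        "bipartite_cc4": cc4,
        "mean_path_length": mpl,
        "consistency_lncRNA": summary_lnc,
        "consistency_miRNA": summary_mir,
    }
    try:
        gamma, r2 = ltopo.fit_power_law(net)
        report["power_law"] = {"gamma": gamma, "r_squared": r2}
    except ValueError as exc:
        run.manifest["notices"].append(f"power-law fit unavailable: {exc}")
    try:
        null = ltopo.randomized_null(
            net, n_replicates=cfg.null_replicates, seed=cfg.seed, metric="mean_path_length"
        )
        report["null_mean_path_length"] = {
            "observed": null.observed,
            "null_mean": float(np.mean(null.null_values)),
            "empirical_p": null.empirical_p,
            "n_replicates": null.n_replicates,
        }
    except ValueError as exc:
        run.manifest["notices"].append(f"randomization null unavailable: {exc}")
    table, trend_r, trend_p = ltopo.shared_count_vs_significance(net)
    report["shared_count_trend"] = {"r": trend_r, "p": trend_p, "n_bins": len(table)}

    paths = {
        "centralities": out / "centralities.tsv",
        "consistency_lnc": out / "neighbor_consistency_lncRNA.tsv",
        "consistency_mir": out / "neighbor_consistency_miRNA.tsv",
        "shared_count_bins": out / "shared_count_bins.tsv",
        "report": out / "topology_report.json",
    }
    centralities.to_csv(paths["centralities"], sep="\t", index=False)
    profiles_lnc.to_csv(paths["consistency_lnc"], sep="\t", index=False)
    profiles_mir.to_csv(paths["consistency_mir"], sep="\t", index=False)
    table.to_csv(paths["shared_count_bins"], sep="\t", index=False)
    Path(paths["report"]).write_text(json.dumps(_jsonable(report), indent=2, default=str))
    run._record("topology", paths, t0, {"n_nodes": len(centralities)})
    run.results.update(centralities=centralities, topology_report=report)


def _stage_disease(run: PipelineRun, net, intermediates, annotation):
    cfg = run.config
    t0 = _time.monotonic()
    out = run.out / "disease"
    out.mkdir(exist_ok=True)
    lnc_universe = set(intermediates["lnc_regulatory"]["regulator_id"])
    mir_universe = set(intermediates["mir_regulatory"]["regulator_id"])
    report: dict = {"enrichment": {}, "centrality_comparison": {}}
    for rna_class, universe in (("lncRNA", lnc_universe), ("miRNA", mir_universe)):
        try:
            enr = lhubs.enrichment_test(
                net, annotation.disease_ids(rna_class), universe, rna_class
            )
            report["enrichment"][rna_class] = asdict(enr)
        except ValueError as exc:
            run.manifest["notices"].append(f"enrichment skipped for {rna_class}: {exc}")
    centralities = run.results["centralities"]
    for rna_class in ("lncRNA", "miRNA"):
        recs = centralities[centralities["rna_class"] == rna_class]
        disease = annotation.disease_ids(rna_class)
        for metric in ("degree", "betweenness", "closeness"):
            try:
                w, p, med = lhubs.compare_centrality(recs, disease, metric)
                report["centrality_comparison"][f"{rna_class}_{metric}"] = {
                    "W": w, "p": p, **med
                }
            except ValueError as exc:
                run.manifest["notices"].append(
                    f"centrality comparison skipped ({rna_class}, {metric}): {exc}"
                )
    hubset = lhubs.select_hubs(net, cfg.top_frac)
    composition = lhubs.hub_composition(hubset, net, annotation)
    subnet, isolated = lhubs.hub_subnetwork(net, hubset)
    report["hubs"] = {
        "n_hubs": hubset.n_hubs,
        "per_class": hubset.per_class,
        "isolated_hubs": isolated,
    }
    paths = {
        "hub_ids": out / "hub_ids.txt",
        "composition": out / "hub_composition.tsv",
        "subnetwork": out / "hub_subnetwork.graphml",
        "report": out / "disease_report.json",
    }
    lio.write_id_list(hubset.hub_ids, paths["hub_ids"])
    composition.to_csv(paths["composition"], sep="\t", index=False)
    lio.write_network(subnet, paths["subnetwork"], "graphml")
    Path(paths["report"]).write_text(json.dumps(_jsonable(report), indent=2))
    run._record("disease", paths, t0, {"n_hubs": hubset.n_hubs})
    run.results.update(hubset=hubset, hub_composition=composition, disease_report=report)

    # hierarchical views for the top hub lncRNAs
    views_dir = run.out / "hierarchy"
    views_dir.mkdir(exist_ok=True)
    hub_lncs = [h for h in hubset.hub_ids if net.graph.nodes[h]["rna_class"] == "lncRNA"][:2]
    view_paths = {}
    for lnc in hub_lncs:
        view = lhubs.build_hierarchical_view(net, lnc, annotation, cfg.min_term_count)
        g = lhubs.hierarchical_view_graph(view, annotation)
        import networkx as nx

        p = views_dir / f"hierarchy_{lnc}.graphml"
        nx.write_graphml(g, p)
        view_paths[lnc] = p
    if view_paths:
        run._record("hierarchy", view_paths, t0)
    return hubset


def _stage_prognosis(run: PipelineRun, net, hubset, expr_lnc, clinical):
    cfg = run.config
    t0 = _time.monotonic()
    out = run.out / "prognosis"
    out.mkdir(exist_ok=True)
    tumor = clinical.tumor()
    usable = [s for s in tumor["sample_id"] if s in expr_lnc.data.columns]
    clin = lsurv.ClinicalTable(tumor[tumor["sample_id"].isin(usable)].reset_index(drop=True))
    train_ids, test_ids = lsurv.split_train_test(clin, cfg.train_frac, cfg.seed)

    hub_lncs = [h for h in hubset.hub_ids if net.graph.nodes[h]["rna_class"] == "lncRNA"]
    screen_rows = []
    clin_idx = clin.data.set_index("sample_id").loc[train_ids]
    for lnc in hub_lncs:
        if lnc not in expr_lnc.data.index:
            continue
        try:
            res = lsurv.cox_univariate(
                clin_idx["time"], clin_idx["event"],
                expr_lnc.data.loc[lnc, train_ids], covariate_id=lnc,
            )
        except ValueError as exc:
            run.manifest["notices"].append(f"Cox screen skipped for {lnc}: {exc}")
            continue
        if res.converged:
            screen_rows.append(asdict(res))
    screen = pd.DataFrame(screen_rows)
    paths = {"cox_screen": out / "cox_screen.tsv"}
    screen.to_csv(paths["cox_screen"], sep="\t", index=False)

    if cfg.risk_lnc_ids:
        risk_lncs = list(cfg.risk_lnc_ids)
    else:
        sig = screen[screen["p"] < 0.05].sort_values("p") if not screen.empty else screen
        risk_lncs = list(sig["covariate_id"].head(2)) if not screen.empty else []
    report: dict = {"train_ids": train_ids, "test_ids": test_ids, "risk_lncRNAs": risk_lncs}
    if len(risk_lncs) < 2:
        run.manifest["notices"].append(
            "fewer than two prognostic hub lncRNAs; risk model skipped"
        )
    else:
        model, fits = lsurv.build_risk_model(expr_lnc, clin, risk_lncs, train_ids)
        report["coefficients"] = {lnc: coef for lnc, coef in model.terms}
        report["cutoff"] = model.cutoff
        for name, ids in (("train", train_ids), ("test", test_ids)):
            try:
                comp = lsurv.score_and_stratify(model, expr_lnc, clin, ids)
                report[f"logrank_{name}"] = {
                    "chi2": comp.logrank_chi2,
                    "p": comp.logrank_p,
                    "group_sizes": comp.group_sizes,
                }
                for grp, curve in comp.km_curves.items():
                    p = out / f"km_{name}_{grp}.tsv"
                    curve.to_csv(p, sep="\t", index=False)
                    paths[f"km_{name}_{grp}"] = p
            except ValueError as exc:
                run.manifest["notices"].append(f"stratification failed on {name} set: {exc}")
        run.results["risk_model"] = model
    paths["report"] = out / "prognosis_report.json"
    Path(paths["report"]).write_text(json.dumps(_jsonable(report), indent=2))
    run._record("prognosis", paths, t0, {"n_screened": len(screen)})
    run.results["prognosis_report"] = report
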