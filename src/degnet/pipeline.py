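"""End-to-end orchestration: io → DE → consensus → networks → CCPs → ORA → survival.

A run is driven by a :class:`PipelineConfig` (constructible from YAML). Every
stage writes its tables under the output directory and contributes record
counts and parameters to a JSON run report, so each decision in a run is
auditable. Any stage error aborts the run, naming the stage.

Numbers in TSV outputs are serialized at 10 significant digits, which makes
re-runs on identical inputs byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import consensus, coexpression, enrichment, survival
from .datasets import ExpressionDataset, read_expression_matrix, write_expression_matrix, write_class_labels
from .diffexp import DEGTable, differential_expression
from .simulate import SimulationConfig, simulate_collection, simulate_survival

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and the cause."""


@dataclass
class DatasetSpec:
    dataset_id: str
    disease_group: str
    matrix_path: str
    labels_path: str


@dataclass
class PipelineConfig:
    datasets: list[DatasetSpec]
    output_dir: str
    seed: int = 0
    fdr_max: float = 0.05
    min_abs_log2fc: float = 1.0
    thresholds: consensus.ConsensusThresholds = field(
        default_factory=consensus.ConsensusThresholds)
    network_mode: str = "first_local_max"
    network_samples: str = "all"
    tf_list_path: str | None = None
    gene_sets_path: str | None = None
    survival_path: str | None = None
    survival_mode: str = "median"
    max_network_genes: int = 500

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        base = Path(path).parent

        def resolve(p):
            return str((base / p).resolve()) if p else None

        datasets = [DatasetSpec(d["dataset_id"], d["disease_group"],
                                resolve(d["matrix"]), resolve(d["labels"]))
                    for d in raw["datasets"]]
        th = consensus.ConsensusThresholds(**raw.get("thresholds", {}))
        return cls(
            datasets=datasets,
            output_dir=resolve(raw.get("output_dir", "degnet_out")),
            seed=int(raw.get("seed", 0)),
            fdr_max=float(raw.get("fdr_max", 0.05)),
            min_abs_log2fc=float(raw.get("min_abs_log2fc", 1.0)),
            thresholds=th,
            network_mode=raw.get("network_mode", "first_local_max"),
            network_samples=raw.get("network_samples", "all"),
            tf_list_path=resolve(raw.get("tf_list")),
            gene_sets_path=resolve(raw.get("gene_sets")),
            survival_path=resolve(raw.get("survival")),
            survival_mode=raw.get("survival_mode", "median"),
            max_network_genes=int(raw.get("max_network_genes", 500)),
        )


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 — re-raise with stage name
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


@_stage("io")
def _load_datasets(cfg: PipelineConfig) -> list[ExpressionDataset]:
    return [read_expression_matrix(d.matrix_path, d.dataset_id,
                                   d.disease_group, d.labels_path)
            for d in cfg.datasets]


@_stage("differential_expression")
def _run_de(cfg: PipelineConfig, datasets, out: Path) -> list[DEGTable]:
    tables = []
    de_dir = out / "de"
    de_dir.mkdir(parents=True, exist_ok=True)
    for ds in datasets:
        t = differential_expression(ds, fdr_max=cfg.fdr_max,
                                    min_abs_log2fc=cfg.min_abs_log2fc)
        t.write(de_dir / f"{ds.dataset_id}.deg.tsv")
        tables.append(t)
    return tables


@_stage("consensus")
def _run_consensus(cfg: PipelineConfig, tables, tf_list, out: Path):
    tally = consensus.tally_votes(tables)
    calls = consensus.classify_winners(tally, cfg.thresholds)
    if tf_list:
        calls = consensus.annotate_tf(calls, tf_list)
    else:
        calls["is_tf"] = False
    tally.to_csv(out / "vote_tally.tsv", sep="\t")
    consensus.write_winner_table(calls, out / "winners.tsv")
    return tally, calls


@_stage("networks")
def _run_networks(cfg: PipelineConfig, datasets, calls, tf_list, out: Path):
    winner_genes = list(calls.index[calls["status"] != "none"])
    node_genes = sorted(set(winner_genes) | set(tf_list or ()))
    if not node_genes:
        logger.warning("no winner genes and no TF list — network stage skipped")
        return {}
    if len(node_genes) > cfg.max_network_genes:
        logger.warning("network gene list truncated from %d to %d",
                       len(node_genes), cfg.max_network_genes)
        node_genes = node_genes[:cfg.max_network_genes]
    nets = {}
    net_dir = out / "networks"
    net_dir.mkdir(parents=True, exist_ok=True)
    for ds in datasets:
        present = [g for g in node_genes if g in ds.values.index]
        if len(present) < 2:
            logger.warning("%s: fewer than 2 network genes present — skipped",
                           ds.dataset_id)
            continue
        net = coexpression.coexpression_network(
            ds, present, mode=cfg.network_mode, samples=cfg.network_samples)
        coexpression.write_edge_list(net, net_dir / f"{ds.dataset_id}.edges.tsv")
        coexpression.write_graphml(net, net_dir / f"{ds.dataset_id}.graphml")
        if net.curves is not None:
            coexpression.write_curves(net.curves,
                                      net_dir / f"{ds.dataset_id}.curves.tsv")
        nets[ds.dataset_id] = (ds.disease_group, net)
    return nets


@_stage("ccp")
def _run_ccps(nets, out: Path) -> pd.DataFrame:
    rows = []
    ids = sorted(nets)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            ga, na = nets[a]
            gb, nb = nets[b]
            if ga == gb:
                continue  # CCPs are sought across disease groups
            for rank, comp in enumerate(coexpression.find_ccps(na, nb), start=1):
                rows.append((a, b, rank, len(comp), ",".join(comp)))
    df = pd.DataFrame(rows, columns=["network_a", "network_b", "ccp_rank",
                                     "n_nodes", "members"])
    df.to_csv(out / "ccps.tsv", sep="\t", index=False)
    return df


@_stage("ora")
def _run_ora(cfg: PipelineConfig, calls, out: Path):
    collection = enrichment.read_gmt(cfg.gene_sets_path)
    query = set(calls.index[calls["status"] != "none"]) & collection.universe
    if not query:
        logger.warning("no winner genes inside the gene-set universe — "
                       "enrichment skipped")
        return None
    results = enrichment.ora(query, collection, fdr_max=cfg.fdr_max)
    results.to_csv(out / "ora.tsv", sep="\t", index=False,
                   float_format="%.10g")
    return results


@_stage("survival")
def _run_survival(cfg: PipelineConfig, calls, out: Path):
    surv = pd.read_csv(cfg.survival_path, sep="\t")
    gene_cols = [c for c in surv.columns
                 if c not in ("subject_id", "time", "event")]
    winner_tfs = set(calls.index[(calls["status"] != "none") & calls["is_tf"]])
    genes = [g for g in gene_cols if g in winner_tfs] or gene_cols
    results = survival.screen_genes(surv, genes, mode=cfg.survival_mode)
    results.to_csv(out / "survival_screen.tsv", sep="\t",
                   float_format="%.10g")
    return results


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages in order; returns (and writes) the run report."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"parameters": {
        "seed": cfg.seed, "fdr_max": cfg.fdr_max,
        "min_abs_log2fc": cfg.min_abs_log2fc,
        "thresholds": vars(cfg.thresholds).copy(),
        "network_mode": cfg.network_mode,
        "network_samples": cfg.network_samples,
        "survival_mode": cfg.survival_mode,
    }, "stages": {}}

    datasets = _load_datasets(cfg)
    report["stages"]["io"] = {
        "n_datasets": len(datasets),
        "groups": {g: sum(d.disease_group == g for d in datasets)
                   for g in sorted({d.disease_group for d in datasets})},
    }

    tables = _run_de(cfg, datasets, out)
    report["stages"]["differential_expression"] = {
        t.dataset_id: {"up": t.n_up, "down": t.n_down} for t in tables}

    tf_list: set[str] = set()
    if cfg.tf_list_path:
        tf_list = consensus.read_tf_list(cfg.tf_list_path)
    else:
        logger.warning("no TF list supplied — networks use winners only")

    tally, calls = _run_consensus(cfg, tables, tf_list, out)
    report["stages"]["consensus"] = {
        "n_genes": len(calls),
        "common_winners": int((calls["status"] == "common_winner").sum()),
        "unique_lc_winners": int((calls["status"] == "unique_lc_winner").sum()),
        "winner_tfs": int((calls["is_tf"] & (calls["status"] != "none")).sum()),
        "group_patterns": consensus.categorize_table(
            calls[calls["status"] != "none"]),
    }

    nets = _run_networks(cfg, datasets, calls, tf_list, out)
    report["stages"]["networks"] = {
        ds_id: {"tau_star": net.tau_star, "n_edges": net.graph.number_of_edges()}
        for ds_id, (_, net) in nets.items()}

    ccps = _run_ccps(nets, out)
    report["stages"]["ccp"] = {"n_ccps": len(ccps),
                               "largest": int(ccps["n_nodes"].max()) if len(ccps) else 0}

    if cfg.gene_sets_path:
        ora_res = _run_ora(cfg, calls, out)
        report["stages"]["ora"] = {
            "n_sets_tested": 0 if ora_res is None else len(ora_res),
            "n_significant": 0 if ora_res is None
            else int(ora_res["significant"].sum())}

    if cfg.survival_path:
        surv_res = _run_survival(cfg, calls, out)
        report["stages"]["survival"] = {
            "n_genes_screened": len(surv_res),
            "n_significant": int((surv_res["p_value"] <= 0.05).sum())}

    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


# -- synthetic input bundles ---------------------------------------------------

def write_simulated_inputs(cfg: SimulationConfig, out_dir: str | Path,
                           gene_sets: dict[str, list[str]] | None = None
                           ) -> PipelineConfig:
    """Materialize a simulated collection as a ready-to-run input bundle.

    Writes expression TSVs, label files, the TF list and truth table, a
    survival table for the genes with nonzero betas, optionally a GMT file,
    and a pipeline YAML pointing at all of them. Returns the parsed
    :class:`PipelineConfig`.
    """
    out = Path(out_dir)
    (out / "data").mkdir(parents=True, exist_ok=True)
    datasets, truth = simulate_collection(cfg)
    specs = []
    for ds in datasets:
        mpath = out / "data" / f"{ds.dataset_id}.tsv"
        lpath = out / "data" / f"{ds.dataset_id}.labels.tsv"
        write_expression_matrix(ds, mpath)
        write_class_labels(ds, lpath)
        specs.append({"dataset_id": ds.dataset_id,
                      "disease_group": ds.disease_group,
                      "matrix": str(mpath.relative_to(out)),
                      "labels": str(lpath.relative_to(out))})
    truth.to_csv(out / "truth.tsv", sep="\t")
    tf_path = out / "tf_list.txt"
    tf_path.write_text("\n".join(sorted(truth.index[truth["is_tf"]])) + "\n")

    raw: dict = {"datasets": specs, "output_dir": "results",
                 "seed": cfg.seed, "tf_list": "tf_list.txt"}
    if cfg.survival_betas:
        lc = next(ds for ds in datasets if ds.disease_group == "LC")
        surv = simulate_survival(
            lc.values.loc[list(cfg.survival_betas)], cfg.survival_betas,
            base_rate=cfg.base_rate, censoring_rate=cfg.censoring_rate,
            seed=np.random.SeedSequence([cfg.seed, 7]))
        surv.to_csv(out / "survival.tsv", sep="\t", index=False,
                    float_format="%.10g")
        raw["survival"] = "survival.tsv"
    if gene_sets:
        universe = set(truth.index)
        coll = enrichment.GeneSetCollection(
            {k: frozenset(v) for k, v in gene_sets.items()}, frozenset(universe))
        enrichment.write_gmt(coll, out / "gene_sets.gmt")
        raw["gene_sets"] = "gene_sets.gmt"
    yaml_path = out / "pipeline.yaml"
    with open(yaml_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
    return PipelineConfig.from_yaml(yaml_path)
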