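"""End-to-end orchestration: load inputs, run every analysis stage in
dependency order, write TSV outputs plus a machine-readable run report.

Stage order follows the analysis narrative: event tables -> PSI matrix ->
single-sample differential calls -> splicing burden -> clustering and
cell-type variance partition -> functional prioritization -> survival
models.  A run is reproducible: the report carries a hash of every
semantically relevant configuration field, and rerunning with identical
config and inputs rewrites identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import burden as burden_mod
from . import clustering as cluster_mod
from . import differential as diff_mod
from . import outcomes as outcomes_mod
from . import prioritize as prio_mod
from .annotation import read_features, read_gtf
from .events import EVENT_TYPES
from .rmats_io import PsiMatrix, assemble_psi_matrix, read_sample_events

log = logging.getLogger("spliceburden")


@dataclass
class AnalysisParams:
    """Every tunable threshold of the pipeline, at its published default."""

    min_reads: int = 10
    z_thresh: float = 2.0
    dpsi_thresh: float = 0.2
    min_cohort_n: int = 10
    min_recurrence: int = 2
    top_k: int = 5000
    min_coverage_frac: float = 0.75
    n_clusters: int = 10
    tpm_threshold: float = 10.0
    recurrence_threshold: int = 10
    stats_mode: str = "full"       # or "leave-one-out"
    distance: str = "euclidean"    # or "correlation"
    linkage: str = "ward"          # or "average"
    hypermutant_tmb: float = 10.0

    def validate(self) -> None:
        for name in ("min_reads", "z_thresh", "dpsi_thresh", "min_cohort_n",
                     "min_recurrence", "top_k", "n_clusters", "tpm_threshold",
                     "recurrence_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")


@dataclass
class PipelineConfig:
    rmats_dir: str
    manifest: str
    tpm: str
    out_dir: str
    gtf: Optional[str] = None
    features: Optional[str] = None
    kinase_list: Optional[str] = None
    splicing_kinase_list: Optional[str] = None
    sf_list: Optional[str] = None
    marker_sets: Optional[str] = None
    params: AnalysisParams = field(default_factory=AnalysisParams)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        params = AnalysisParams(**raw.pop("params", {}))
        return cls(params=params, **raw)

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir")  # where outputs land is not semantic
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def validate_paths(self) -> None:
        required = {"rmats_dir": self.rmats_dir, "manifest": self.manifest,
                    "tpm": self.tpm}
        optional = {"gtf": self.gtf, "features": self.features,
                    "kinase_list": self.kinase_list,
                    "splicing_kinase_list": self.splicing_kinase_list,
                    "sf_list": self.sf_list, "marker_sets": self.marker_sets}
        for name, p in required.items():
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"config.{name}: missing path {p!r}")
        for name, p in optional.items():
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config.{name}: missing path {p!r}")


def load_rmats_dir(rmats_dir: Union[str, Path], min_reads: int = 10) -> PsiMatrix:
    """Assemble the cohort PSI matrix from rmats/<sample>/<TYPE>.MATS.JC.txt."""
    root = Path(rmats_dir)
    tables = {}
    for sdir in sorted(p for p in root.iterdir() if p.is_dir()):
        per_type = []
        for etype in EVENT_TYPES:
            f = sdir / f"{etype}.MATS.JC.txt"
            if f.exists():
                per_type.append(read_sample_events(f, etype))
        if per_type:
            tables[sdir.name] = per_type
    if not tables:
        raise FileNotFoundError(f"no sample tables under {root}")
    return assemble_psi_matrix(tables, min_reads=min_reads)


def _read_gene_list(path: Optional[str]) -> Optional[List[str]]:
    if path is None:
        return None
    return pd.read_csv(path, sep="\t")["gene"].astype(str).tolist()


def run_analysis(psi: PsiMatrix, manifest: pd.DataFrame, tpm: pd.DataFrame,
                 params: AnalysisParams,
                 models=None, features: Optional[pd.DataFrame] = None,
                 kinase_genes: Optional[Sequence[str]] = None,
                 splicing_kinase_genes: Optional[Sequence[str]] = None,
                 sf_genes: Optional[Sequence[str]] = None,
                 marker_sets: Optional[Mapping[str, Sequence[str]]] = None,
                 ) -> Dict[str, object]:
    """Run every analysis stage on in-memory inputs; returns a dict of
    stage outputs keyed by output name."""
    params.validate()
    out: Dict[str, object] = {}
    t0 = time.time()

    def mark(stage, n):
        log.info("stage %-22s rows=%-8d t=%.1fs", stage, n, time.time() - t0)

    manifest = manifest.set_index("sample_id") \
        if "sample_id" in manifest.columns else manifest

    # differential splicing
    stats = diff_mod.cohort_event_stats(psi, mode=params.stats_mode,
                                        min_cohort_n=params.min_cohort_n)
    calls = diff_mod.call_differential(psi, stats, z_thresh=params.z_thresh,
                                       dpsi_thresh=params.dpsi_thresh)
    out["calls"] = calls
    mark("differential", len(calls))
    recurrent = diff_mod.recurrence(calls, min_recurrence=params.min_recurrence)
    out["recurrent"] = recurrent
    mark("recurrence", len(recurrent))
    out["histology_specific"] = diff_mod.histology_specific(
        recurrent, calls, manifest.reset_index())
    # splicing burden
    sbi = burden_mod.compute_sbi(calls, psi, stats)
    sbi = burden_mod.assign_sbi_groups(sbi)
    out["sbi"] = sbi
    mark("sbi", len(sbi))
    if "tmb" in manifest.columns:
        tmb = manifest["tmb"]
        cors = [burden_mod.grouped_correlation(sbi["sbi"], tmb, label="all")]
        cors.append(burden_mod.grouped_correlation(
            sbi["sbi"], tmb, label="non-hypermutant",
            exclude_filter=burden_mod.hypermutant_filter(
                tmb, params.hypermutant_tmb)))
        out["tmb_correlation"] = pd.concat(cors, ignore_index=True)
    if sf_genes:
        present = [g for g in sf_genes if g in tpm.index]
        out["sf_association"] = burden_mod.sf_expression_association(
            tpm, sbi, present)
        out["sf_sbi_correlation"] = pd.concat([
            burden_mod.grouped_correlation(
                sbi["sbi"], np.log2(tpm.loc[g] + 1.0), label=g)
            .assign(gene=g) for g in present[:40]], ignore_index=True)
    # clustering
    top = cluster_mod.top_variable_events(
        psi, k=params.top_k, min_coverage_frac=params.min_coverage_frac)
    sub = psi.subset_events(top)
    clust = cluster_mod.cluster_samples(sub, k=params.n_clusters,
                                        linkage=params.linkage,
                                        distance=params.distance)
    out["clusters"] = clust.assignments.to_frame()
    mark("clustering", len(clust.assignments))
    enrich = [cluster_mod.cluster_enrichment(
        clust.assignments, manifest["histology"]).assign(label_type="histology")]
    if "molecular_subtype" in manifest.columns:
        enrich.append(cluster_mod.cluster_enrichment(
            clust.assignments, manifest["molecular_subtype"])
            .assign(label_type="molecular_subtype"))
    out["enrichment"] = pd.concat(enrich, ignore_index=True)
    if marker_sets:
        scores = cluster_mod.celltype_scores(tpm, marker_sets)
        out["celltype_scores"] = scores
        ve = cluster_mod.psi_variance_explained(sub, scores)
        out["variance_explained"] = ve
        mark("variance_explained", len(ve))
    # prioritization
    if models is not None and features is not None and kinase_genes:
        impacts = prio_mod.affected_features(recurrent, psi.events, models,
                                             features)
        out["impacts"] = impacts
        cfg = prio_mod.CascadeConfig(
            kinase_genes=kinase_genes,
            splicing_kinase_genes=splicing_kinase_genes
            or prio_mod.SPLICING_KINASES,
            tpm_threshold=params.tpm_threshold,
            recurrence_threshold=params.recurrence_threshold)
        cascade = prio_mod.run_cascade(recurrent, psi.events, impacts, tpm,
                                       cfg, models=models)
        out["cascade_stages"] = cascade.stages
        out["candidates"] = cascade.candidates
        out["cascade_drop_log"] = cascade.drop_log
        mark("prioritize", len(cascade.candidates))
    # outcomes
    records = manifest.copy()
    records["cluster"] = clust.assignments.reindex(records.index).astype(str)
    records["sbi"] = sbi["sbi"].reindex(records.index)
    if {"os_days", "os_status"} <= set(records.columns):
        rec = records.rename(columns={"os_days": "time", "os_status": "status"})
        rec = rec.dropna(subset=["cluster"])
        try:
            fit = outcomes_mod.fit_cox(
                rec, ["cluster", "resection", "age_at_diagnosis"])
            out["cox_cluster"] = fit.table.assign(model="cluster+resection+age",
                                                  converged=fit.converged)
            fit2 = outcomes_mod.fit_cox(
                rec, ["cluster", "resection", "age_at_diagnosis", "sbi"],
                interactions=[("sbi", "cluster")])
            out["cox_sbi_interaction"] = fit2.table.assign(
                model="cluster+resection+age+sbi+sbi:cluster",
                converged=fit2.converged)
            mark("outcomes", len(fit.table))
        except ValueError as err:
            log.warning("survival stage skipped: %s", err)
            out["cox_error"] = str(err)
    return out


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full pipeline from a config; returns the run directory."""
    config.params.validate()
    config.validate_paths()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    report = {"config_hash": config.config_hash(), "stages": {},
              "params": asdict(config.params), "seed": config.seed}
    stage = "load"
    try:
        psi = load_rmats_dir(config.rmats_dir, min_reads=config.params.min_reads)
        manifest = pd.read_csv(config.manifest, sep="\t")
        tpm = pd.read_csv(config.tpm, sep="\t", index_col=0)
        models = read_gtf(config.gtf) if config.gtf else None
        features = read_features(config.features) if config.features else None
        kinases = _read_gene_list(config.kinase_list)
        spl_kinases = _read_gene_list(config.splicing_kinase_list)
        sf_genes = _read_gene_list(config.sf_list)
        marker_sets = None
        if config.marker_sets:
            mdf = pd.read_csv(config.marker_sets, sep="\t")
            marker_sets = {t: list(g["gene"]) for t, g in mdf.groupby("cell_type")}
        report["stages"]["load"] = {"n_events": len(psi.event_keys),
                                    "n_samples": len(psi.samples)}
        stage = "analysis"
        results = run_analysis(psi, manifest, tpm, config.params,
                               models=models, features=features,
                               kinase_genes=kinases,
                               splicing_kinase_genes=spl_kinases,
                               sf_genes=sf_genes, marker_sets=marker_sets)
        stage = "write"
        psi.write(out_dir / "psi.tsv", out_dir / "coverage.tsv",
                  out_dir / "events.tsv")
        for name, obj in results.items():
            if isinstance(obj, pd.DataFrame):
                keep_index = not (isinstance(obj.index, pd.RangeIndex)
                                  and obj.index.name is None)
                obj.round(6).to_csv(out_dir / f"{name}.tsv", sep="\t",
                                    index=keep_index)
                report["stages"][name] = {"rows": len(obj)}
            else:
                report["stages"][name] = {"value": str(obj)}
    except Exception as err:
        report["error"] = {"stage": stage, "message": str(err)}
        (out_dir / "report.json").write_text(json.dumps(report, indent=2,
                                                        sort_keys=True))
        log.removeHandler(handler)
        raise
    (out_dir / "report.json").write_text(json.dumps(report, indent=2,
                                                    sort_keys=True))
    log.removeHandler(handler)
    return out_dir
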