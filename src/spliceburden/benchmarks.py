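"""Parameter-recovery benchmarks on synthetic cohorts with known truth.

Each function generates its own inputs at the study conditions it states,
runs the corresponding analysis stage, and scores the result against the
planted ground truth.  They are used both by the test suite and by the
repository's acceptance script; all randomness flows through the ``seed``
argument.
"""

from __future__ import annotations

import hashlib
import time
from fractions import Fraction
from math import comb
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import adjusted_rand_score

from .annotation import AnnotationError, TranscriptModel, genomic_to_protein
from .burden import compute_sbi
from .clustering import (cluster_samples, psi_variance_explained,
                         top_variable_events)
from .differential import call_differential, cohort_event_stats, recurrence
from .outcomes import fit_cox
from .prioritize import CascadeConfig, affected_features, run_cascade
from .rmats_io import compute_psi
from .simulate import SimConfig, simulate_cohort, simulate_survival


def psi_oracle_error(seed: int, n: int = 1000) -> float:
    """Max |compute_psi - exact rational arithmetic| over random counts."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n):
        ijc = int(rng.integers(0, 1000))
        sjc = int(rng.integers(0, 1000))
        if ijc + sjc == 0:
            ijc = 1
        li, ls = int(rng.integers(1, 500)), int(rng.integers(1, 500))
        exact = Fraction(ijc, li) / (Fraction(ijc, li) + Fraction(sjc, ls))
        worst = max(worst, abs(compute_psi(ijc, sjc, li, ls) - float(exact)))
    return worst


def differential_recovery(seed: int, n_samples: int = 200,
                          n_events: int = 20000) -> Dict[str, float]:
    """Sensitivity / false-call rate / SBI rank recovery on one cohort.

    Conditions: 2% planted outlier cells, dPSI effect 0.4, Beta
    concentration 200, no cluster structure, default call thresholds.
    """
    cfg = SimConfig(n_samples=n_samples, n_events={"SE": n_events},
                    planted_fraction=0.02, effect_size=0.4,
                    concentration=200.0, frac_cluster_informative=0.0,
                    include_annotation=False, seed=seed)
    cohort = simulate_cohort(cfg)
    stats = cohort_event_stats(cohort.psi)
    calls = call_differential(cohort.psi, stats)
    truth = set(map(tuple,
                    cohort.truth.differential[["sample_id", "event_key"]]
                    .to_numpy()))
    called = set(map(tuple, calls[["sample_id", "event_key"]].to_numpy()))
    n_cells = int(cohort.psi.psi.notna().to_numpy().sum())
    sens = len(truth & called) / len(truth)
    fcr = len(called - truth) / (n_cells - len(truth))
    sbi = compute_sbi(calls, cohort.psi, stats)
    rho = sps.spearmanr(
        sbi["sbi"],
        cohort.truth.sample_planted_fraction.loc[sbi.index]).statistic
    return {"sensitivity": sens, "false_call_rate": fcr,
            "sbi_spearman": float(rho), "n_cells": n_cells}


def clustering_recovery(seed: int, n_samples: int = 200,
                        n_events: int = 6000) -> float:
    """ARI of hierarchical clustering vs planted 10-cluster structure.

    Conditions: between-cluster separation 0.3 PSI, within-cluster noise
    sd ~0.05 (Beta concentration 99), top-5000 variable-event selection.
    """
    cfg = SimConfig(n_samples=n_samples, n_events={"SE": n_events},
                    n_clusters=10, cluster_dpsi=0.3, concentration=99.0,
                    frac_cluster_informative=0.3,
                    include_annotation=False, seed=seed)
    cohort = simulate_cohort(cfg)
    sub = cohort.psi.subset_events(top_variable_events(cohort.psi, k=5000))
    res = cluster_samples(sub, k=10)
    truth = cohort.truth.clusters.loc[res.assignments.index]
    return float(adjusted_rand_score(truth, res.assignments))


def fisher_enumeration_error(max_n: int = 30) -> Tuple[float, int]:
    """Max |scipy Fisher p - exact hypergeometric enumeration| over every
    2x2 table with total count <= max_n; also returns the table count."""
    worst, count = 0.0, 0
    for n in range(1, max_n + 1):
        for a in range(n + 1):
            for b in range(n + 1 - a):
                for c in range(n + 1 - a - b):
                    d = n - a - b - c
                    r1, c1 = a + b, a + c
                    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
                    weights = {k: comb(r1, k) * comb(n - r1, c1 - k)
                               for k in range(lo, hi + 1)}
                    w_obs = weights[a]
                    exact = sum(w for w in weights.values()
                                if w <= w_obs) / comb(n, c1)
                    _, p = sps.fisher_exact([[a, b], [c, d]])
                    worst = max(worst, abs(p - exact))
                    count += 1
    return worst, count


def random_transcript_model(rng: np.random.Generator):
    """A random toy transcript (either strand, 1-8 exons, UTRs allowed)."""
    while True:
        n_exons = int(rng.integers(1, 9))
        pos = int(rng.integers(0, 1000))
        exons = []
        for _ in range(n_exons):
            length = int(rng.integers(3, 60))
            exons.append((pos, pos + length))
            pos += length + int(rng.integers(10, 80))
        strand = "+" if rng.random() < 0.5 else "-"
        span_lo, span_hi = exons[0][0], exons[-1][1]
        lo = int(rng.integers(span_lo, max(span_lo + 1, span_hi - 3)))
        cds_bases = [b for s, e in exons for b in range(s, e) if b >= lo]
        cds_bases = cds_bases[: 3 * (len(cds_bases) // 3)]
        if len(cds_bases) < 3:
            continue
        try:
            return TranscriptModel(
                transcript_id="T", gene_symbol="G", chrom="chr1",
                strand=strand, exons=exons,
                cds_span=(cds_bases[0], cds_bases[-1] + 1))
        except AnnotationError:
            continue


def mapping_oracle_mismatches(seed: int, n_models: int = 200,
                              queries_per_model: int = 5) -> int:
    """Disagreements between genomic_to_protein and per-base enumeration."""
    rng = np.random.default_rng(seed)
    mismatches = 0
    for _ in range(n_models):
        m = random_transcript_model(rng)
        coding = [b for s, e in m.cds_segments for b in range(s, e)]
        if m.strand == "-":
            coding = coding[::-1]
        index_of = {b: i for i, b in enumerate(coding)}
        span_lo, span_hi = m.exons[0][0], m.exons[-1][1]
        for _ in range(queries_per_model):
            qs = int(rng.integers(span_lo - 20, span_hi + 10))
            qe = qs + int(rng.integers(1, 80))
            hits = [index_of[b] for b in range(qs, qe) if b in index_of]
            expected = ((min(hits) // 3 + 1, max(hits) // 3 + 1)
                        if hits else None)
            if genomic_to_protein((qs, qe), m) != expected:
                mismatches += 1
    return mismatches


def cascade_recovery(seed: int, n_samples: int = 200,
                     n_events: int = 4000) -> Dict[str, object]:
    """Exact-match of the prioritization cascade against planted truth."""
    cfg = SimConfig(n_samples=n_samples,
                    n_events={"SE": n_events, "A5SS": 80, "A3SS": 80,
                              "RI": 80, "MXE": 40}, seed=seed)
    c = simulate_cohort(cfg)
    stats = cohort_event_stats(c.psi)
    calls = call_differential(c.psi, stats)
    rec = recurrence(calls)
    imp = affected_features(rec, c.psi.events, c.models, c.features)
    table = run_cascade(
        rec, c.psi.events, imp, c.tpm,
        CascadeConfig(kinase_genes=c.kinase_genes,
                      splicing_kinase_genes=c.splicing_kinase_genes),
        models=c.models)
    counts = table.stages["n_surviving"].to_numpy()
    return {
        "exact_match": sorted(table.candidates["event_key"])
        == sorted(c.truth.candidate_event_keys),
        "monotone": bool((np.diff(counts) <= 0).all()),
        "n_candidates": len(table.candidates),
        "stage_counts": counts.tolist(),
    }


def cox_recovery(seed: int, n_seeds: int = 50, n: int = 1000,
                 true_hr: float = 2.0,
                 censoring_rate: float = 0.3) -> Dict[str, float]:
    """CI coverage of the Cox estimator for a planted binary hazard ratio
    and for an independent null covariate."""
    rng = np.random.default_rng(seed)
    cover_true = cover_null = 0
    for _ in range(n_seeds):
        rec = simulate_survival(n, np.log(true_hr), rng,
                                censoring_rate=censoring_rate)
        rec["noise"] = rng.normal(0, 1, n)
        fit = fit_cox(rec, ["x", "noise"])
        t = fit.table.set_index("term")
        if t.loc["x", "CI_low"] <= true_hr <= t.loc["x", "CI_high"]:
            cover_true += 1
        if t.loc["noise", "CI_low"] <= 1.0 <= t.loc["noise", "CI_high"]:
            cover_null += 1
    return {"coverage_true_hr": cover_true / n_seeds,
            "coverage_null": cover_null / n_seeds, "n_seeds": n_seeds}


def variance_partition_null(seed: int, n: int = 200, p: int = 6,
                            n_events: int = 400) -> Dict[str, float]:
    """Null calibration of the PSI variance partition plus the
    perfect-linear positive control.

    Under independence the per-event R^2 of an OLS fit on p regressors
    has expectation p/(n-1); the benchmark reports the empirical mean and
    its standard error over ``n_events`` independent events.
    """
    from .rmats_io import PsiMatrix

    rng = np.random.default_rng(seed)
    samples = [f"S{i:04d}" for i in range(n)]
    scores = pd.DataFrame(rng.normal(0, 1, (n, p)),
                          index=pd.Index(samples, name="sample_id"),
                          columns=[f"celltype_{t}" for t in range(p)])
    vals = rng.uniform(0, 1, (n_events, n))
    idx = pd.Index([f"E{i:05d}" for i in range(n_events)], name="event_key")
    psi = PsiMatrix(events=pd.DataFrame(index=idx),
                    psi=pd.DataFrame(vals, index=idx, columns=samples),
                    covered=pd.DataFrame(True, index=idx, columns=samples))
    out = psi_variance_explained(psi, scores)
    mean_r2 = float(out["r_squared"].mean())
    se = float(out["r_squared"].std(ddof=1) / np.sqrt(len(out)))
    # positive control: PSI an exact linear function of one score
    y = 0.4 + 0.05 * scores.iloc[:, 0].to_numpy()
    psi1 = PsiMatrix(
        events=pd.DataFrame(index=idx[:1]),
        psi=pd.DataFrame(y[None, :], index=idx[:1], columns=samples),
        covered=pd.DataFrame(True, index=idx[:1], columns=samples))
    perfect = float(psi_variance_explained(psi1, scores).iloc[0]["r_squared"])
    return {"mean_r2": mean_r2, "expected_r2": p / (n - 1), "se": se,
            "perfect_r2": perfect, "n_events": n_events}


def _tree_digest(root: Path) -> str:
    h = hashlib.sha256()
    for p in sorted(root.rglob("*.tsv")) + [root / "report.json"]:
        if p.is_file():
            h.update(p.name.encode())
            h.update(p.read_bytes())
    return h.hexdigest()


def pipeline_reproducibility(workdir: Path, seed: int) -> Dict[str, object]:
    """Write the default synthetic cohort, run the full pipeline twice on
    it, and compare every output byte for byte."""
    from .pipeline import PipelineConfig, run_pipeline
    from .simulate import write_cohort

    workdir = Path(workdir)
    cohort = simulate_cohort(SimConfig(seed=seed))
    fix = write_cohort(cohort, workdir / "cohort", overwrite=True)

    def cfg(out):
        return PipelineConfig(
            rmats_dir=str(fix / "rmats"), manifest=str(fix / "manifest.tsv"),
            tpm=str(fix / "tpm.tsv"), gtf=str(fix / "annotation.gtf"),
            features=str(fix / "features.tsv"),
            kinase_list=str(fix / "kinase_genes.tsv"),
            splicing_kinase_list=str(fix / "splicing_kinase_genes.tsv"),
            sf_list=str(fix / "sf_genes.tsv"),
            marker_sets=str(fix / "marker_sets.tsv"),
            out_dir=str(workdir / out), seed=seed)

    t0 = time.time()
    out1 = run_pipeline(cfg("run1"))
    runtime = time.time() - t0
    out2 = run_pipeline(cfg("run2"))
    identical = _tree_digest(out1) == _tree_digest(out2)
    cand = pd.read_csv(out1 / "candidates.tsv", sep="\t")
    return {"runtime_seconds": runtime,
            "byte_identical": identical,
            "candidates_match_truth":
                sorted(cand["event_key"]) ==
                sorted(cohort.truth.candidate_event_keys),
            "n_samples": cohort.config.n_samples,
            "n_events": len(cohort.events)}
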