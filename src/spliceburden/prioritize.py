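"""Functional prioritization of recurrent splice events.

Recurrent differential events are projected onto protein space and pushed
through an ordered filter cascade: (1) recurrent differential events in,
(2) at least one protein-feature impact, (3) gene is a kinase, (4) gene is
a splicing-regulatory kinase, (5) cohort expression above a TPM floor,
(6) called in more than a minimum number of tumors, and (7) removal of
retained introns and RI-like A5SS/A3SS events, whose short-read support
is unreliable.  Survivor counts after every stage are recorded so the
cascade is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation import TranscriptModel, genomic_to_protein

#: Kinases with established roles in splicing regulation; the default
#: stage-4 allow-list.
SPLICING_KINASES = ("CLK1", "CLK2", "CLK3", "CLK4", "FASTK", "MARK2",
                    "PKN2", "PRKDC", "SMG1", "SRPK1", "SRPK3")

#: Event classes eligible for exon->protein mapping.  MXE is excluded:
#: with two variable exons a single gain/loss projection is ill-defined.
MAPPABLE_TYPES = ("SE", "A5SS", "A3SS", "RI")


@dataclass
class CascadeConfig:
    kinase_genes: Sequence[str] = ()
    splicing_kinase_genes: Sequence[str] = SPLICING_KINASES
    tpm_threshold: float = 10.0
    recurrence_threshold: int = 10
    drop_ri: bool = True
    drop_ri_like: bool = True
    tpm_statistic: str = "median"  # or "per_sample": median over calling samples


def affected_features(recurrent: pd.DataFrame, events_meta: pd.DataFrame,
                      models: Sequence[TranscriptModel],
                      features: pd.DataFrame) -> pd.DataFrame:
    """Protein-feature impacts for recurrent events.

    For every transcript model of the event's gene the variable region is
    projected to amino acids; a feature is impacted when its aa interval
    intersects the projection, except disulfide bonds, which are impacted
    only when a bonded endpoint residue itself falls inside the
    projection.  The predicted label follows the event's cohort direction
    class: inclusion -> gain, skipping -> loss, mixed -> mixed.

    Returns a tidy frame (event_key, transcript_id, feature_id,
    feature_type, aa interval of the overlap, predicted).
    """
    by_gene: Dict[str, List[TranscriptModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_symbol, []).append(m)
    feat_by_gene = dict(tuple(features.groupby("gene"))) if len(features) else {}
    label_map = {"inclusion": "gain", "skipping": "loss", "mixed": "mixed"}
    rows = []
    for key in recurrent.index:
        meta = events_meta.loc[key]
        if meta["event_type"] not in MAPPABLE_TYPES:
            continue
        gene = meta["gene_symbol"]
        if gene not in by_gene or gene not in feat_by_gene:
            continue
        region = (int(meta["variable_start"]), int(meta["variable_end"]))
        if meta["event_type"] == "RI":
            # a retained intron has no CDS overlap itself; the impacted
            # residues are the codons flanking the interrupted junction
            region = (region[0] - 1, region[1] + 1)
        direction = recurrent.loc[key, "direction_class"]
        for model in by_gene[gene]:
            if model.chrom != meta["chrom"]:
                continue
            aa = genomic_to_protein(region, model)
            if aa is None:
                continue
            lo, hi = aa
            gfeat = feat_by_gene[gene]
            if "transcript" in gfeat.columns:
                tfeat = gfeat[(gfeat["transcript"].isna())
                              | (gfeat["transcript"] == model.transcript_id)]
            else:
                tfeat = gfeat
            for f in tfeat.itertuples():
                if f.feature_type == "disulfide_bond":
                    impacted = (lo <= f.aa_start <= hi) or (lo <= f.aa_end <= hi)
                else:
                    impacted = not (f.aa_end < lo or f.aa_start > hi)
                if impacted:
                    rows.append({
                        "event_key": key, "gene": gene,
                        "transcript_id": model.transcript_id,
                        "feature_id": f.feature_id,
                        "feature_type": f.feature_type,
                        "overlap_aa_start": max(lo, f.aa_start),
                        "overlap_aa_end": min(hi, f.aa_end),
                        "projection_aa_start": lo, "projection_aa_end": hi,
                        "predicted": label_map[direction],
                    })
    cols = ["event_key", "gene", "transcript_id", "feature_id", "feature_type",
            "overlap_aa_start", "overlap_aa_end", "projection_aa_start",
            "projection_aa_end", "predicted"]
    return pd.DataFrame(rows, columns=cols)


def _is_ri_like(meta_row: pd.Series,
                models: Sequence[TranscriptModel]) -> bool:
    """True when the variable region spans an entire annotated intron —
    the signature of a retained intron mis-annotated as A5SS/A3SS."""
    vs, ve = int(meta_row["variable_start"]), int(meta_row["variable_end"])
    for m in models:
        if m.chrom != meta_row["chrom"]:
            continue
        for is_, ie in m.introns:
            if vs <= is_ and ie <= ve:
                return True
    return False


@dataclass
class CandidateTable:
    stages: pd.DataFrame      # stage, description, n_surviving
    candidates: pd.DataFrame  # final surviving events
    drop_log: pd.DataFrame    # event_key, stage dropped at


def run_cascade(recurrent: pd.DataFrame, events_meta: pd.DataFrame,
                impacts: pd.DataFrame, tpm: pd.DataFrame,
                config: CascadeConfig,
                models: Optional[Sequence[TranscriptModel]] = None) -> CandidateTable:
    """Apply the ordered prioritization cascade to recurrent events."""
    if not len(config.kinase_genes):
        raise ValueError("cascade requires a non-empty kinase gene list")
    kinases = set(config.kinase_genes)
    spl_kinases = set(config.splicing_kinase_genes)
    by_gene: Dict[str, List[TranscriptModel]] = {}
    for m in (models or []):
        by_gene.setdefault(m.gene_symbol, []).append(m)

    surviving = list(recurrent.sort_index().index)
    genes = events_meta["gene_symbol"]
    impacted_keys = set(impacts["event_key"]) if len(impacts) else set()
    stages = [("recurrent_differential", "recurrent differential events",
               len(surviving))]
    dropped = []

    def apply(name, desc, keep_fn):
        nonlocal surviving
        kept = []
        for k in surviving:
            if keep_fn(k):
                kept.append(k)
            else:
                dropped.append({"event_key": k, "stage": name})
        surviving = kept
        stages.append((name, desc, len(surviving)))

    apply("feature_impact", "predicted gain/loss of a protein feature",
          lambda k: k in impacted_keys)
    apply("kinase", "gene encodes a kinase", lambda k: genes.loc[k] in kinases)
    apply("splicing_kinase", "kinase with a splicing-regulatory role",
          lambda k: genes.loc[k] in spl_kinases)

    def expressed(k):
        g = genes.loc[k]
        if g not in tpm.index:
            return False
        if config.tpm_statistic == "median":
            return float(tpm.loc[g].median()) > config.tpm_threshold
        raise ValueError(f"unknown tpm_statistic {config.tpm_statistic!r}")

    apply("expression", f"cohort median TPM > {config.tpm_threshold}", expressed)
    apply("recurrence", f"called in > {config.recurrence_threshold} tumors",
          lambda k: int(recurrent.loc[k, "n_samples_called"])
          > config.recurrence_threshold)

    def not_ri(k):
        etype = events_meta.loc[k, "event_type"]
        if config.drop_ri and etype == "RI":
            return False
        if (config.drop_ri_like and etype in ("A5SS", "A3SS")
                and genes.loc[k] in by_gene
                and _is_ri_like(events_meta.loc[k], by_gene[genes.loc[k]])):
            return False
        return True

    apply("ri_exclusion", "drop RI and RI-like A5SS/A3SS events", not_ri)

    cand_rows = []
    for k in surviving:
        ev_imp = impacts[impacts["event_key"] == k]
        g = genes.loc[k]
        cand_rows.append({
            "event_key": k, "gene": g,
            "event_type": events_meta.loc[k, "event_type"],
            "direction_class": recurrent.loc[k, "direction_class"],
            "n_samples_called": int(recurrent.loc[k, "n_samples_called"]),
            "mean_abs_dpsi": float(recurrent.loc[k, "mean_abs_dpsi"]),
            "n_impacted_features": int(ev_imp["feature_id"].nunique()),
            "impacted_features": ";".join(sorted(ev_imp["feature_id"].unique())),
            "median_tpm": float(tpm.loc[g].median()) if g in tpm.index else np.nan,
        })
    stage_df = pd.DataFrame(stages, columns=["stage", "description", "n_surviving"])
    cand_df = pd.DataFrame(cand_rows, columns=[
        "event_key", "gene", "event_type", "direction_class",
        "n_samples_called", "mean_abs_dpsi", "n_impacted_features",
        "impacted_features", "median_tpm"])
    drop_df = pd.DataFrame(dropped, columns=["event_key", "stage"])
    return CandidateTable(stages=stage_df, candidates=cand_df, drop_log=drop_df)
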