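"""Synthetic splicing cohort with planted ground truth.

Generates everything the pipeline consumes — per-sample rMATS-style event
tables, a clinical manifest, a gene TPM matrix, a toy genome annotation
with protein features, marker and kinase gene lists — from a single
seeded configuration, together with a :class:`TruthBundle` recording what
was planted so every downstream stage can be scored.

The generative model, per event j and sample i:

* a base inclusion mean ``m0_j ~ U(0.10, 0.90)``; a configurable fraction
  of events is *cluster-informative*, with per-cluster means
  ``m0_j +/- cluster_dpsi/2`` so samples carry a cluster signature;
* outlier (differential) cells are planted by shifting the target mean by
  ``+/- effect_size`` (clipped to [0.01, 0.99]); planting avoids
  cluster-informative events so the two kinds of structure never
  confound.  Each sample draws its own planting rate, uniform on
  ``(0, 2 * planted_fraction)``, giving the cohort a true burden ranking;
* the realised PSI is ``Beta(m c, (1-m) c)`` with concentration ``c``;
* junction counts invert rMATS length normalisation: with total reads
  ``n ~ LogNormal`` the inclusion count is ``Binomial(n, p)`` where
  ``p = psi L_i / (psi L_i + (1 - psi) L_s)``, so the length-normalised
  PSI recovers the target in expectation.

Expression couples designated splicing-factor genes to the planted
burden, marker genes to Dirichlet cell-type fractions, and survival times
are exponential with log-hazard linear in cluster membership and in the
planted candidate event's PSI.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .annotation import TranscriptModel
from .events import COORD_COLUMNS, make_event_key
from .rmats_io import DEFAULT_MIN_READS, PsiMatrix, compute_psi

DEFAULT_HISTOLOGIES = {
    "LGG": 0.22, "MB": 0.18, "HGG": 0.14, "EPN": 0.10, "DMG": 0.08,
    "ATRT": 0.06, "CRANIO": 0.06, "MENING": 0.06, "GCT": 0.05, "SCHWAN": 0.05,
}

DEFAULT_N_EVENTS = {"SE": 20000, "A5SS": 300, "A3SS": 300, "RI": 300, "MXE": 100}

#: (inc_form_len, skip_form_len) per event class, typical 100-bp-read values.
FORM_LENGTHS = {"SE": (198, 99), "MXE": (198, 99), "A5SS": (99, 99),
                "A3SS": (99, 99), "RI": (198, 99)}


class SimulationError(ValueError):
    """Infeasible simulation configuration."""


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort."""

    n_samples: int = 200
    histologies: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HISTOLOGIES))
    n_clusters: int = 10
    n_events: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_N_EVENTS))
    concentration: float = 200.0          # Beta concentration c (PSI noise)
    planted_fraction: float = 0.02        # mean per-sample outlier rate
    effect_size: float = 0.4              # |dPSI| of planted outliers
    frac_cluster_informative: float = 0.30
    cluster_dpsi: float = 0.30            # between-cluster PSI separation
    mean_total_reads: float = 100.0       # lognormal mean of IJC+SJC per cell
    read_ln_sigma: float = 0.6
    min_reads: int = DEFAULT_MIN_READS
    # expression
    n_sf_genes: int = 40
    sf_coupling_slope: float = 30.0       # log2-TPM units per unit burden
    n_celltypes: int = 6
    markers_per_type: int = 8
    marker_coupling: float = 8.0
    n_background_genes: int = 150
    # survival
    baseline_hazard: float = 1.0 / 1500.0  # events/day
    psi_log_hr: float = -1.5               # candidate-PSI effect on log hazard
    cluster_log_hr_sd: float = 0.5
    censoring_rate: float = 0.3
    include_annotation: bool = True
    seed: int = 0

    def validate(self) -> None:
        props = np.array(list(self.histologies.values()), dtype=float)
        if abs(props.sum() - 1.0) > 1e-6:
            raise SimulationError("histology proportions must sum to 1")
        if not (0 < self.concentration):
            raise SimulationError("concentration must be positive")
        if not (0 <= self.planted_fraction < 0.5):
            raise SimulationError("planted_fraction must be in [0, 0.5)")
        # the worst-case base mean must admit a +/- effect_size shift that
        # stays inside (0.01, 0.99)
        m_worst = 0.5
        if not (m_worst + self.effect_size <= 0.99
                or m_worst - self.effect_size >= 0.01):
            raise SimulationError(
                f"effect_size {self.effect_size} pushes PSI outside (0, 1)")
        if self.effect_size <= 0.2:
            raise SimulationError(
                "effect_size must exceed the 0.2 dPSI call threshold")
        if self.n_clusters < 1 or self.n_samples < self.n_clusters:
            raise SimulationError("need n_samples >= n_clusters >= 1")


@dataclass
class TruthBundle:
    """Planted ground truth, kept apart from the emitted fixtures."""

    differential: pd.DataFrame          # sample_id, event_key, direction, true_dpsi
    sample_planted_fraction: pd.Series  # per-sample true outlier fraction
    clusters: pd.Series                 # sample_id -> true cluster (1..k)
    cell_fractions: pd.DataFrame        # samples x cell types
    candidate_event_keys: List[str]     # events the cascade must recover
    special_events: pd.DataFrame        # role, event_key, gene, n_planted
    survival_coefs: Dict[str, float]


@dataclass
class SyntheticCohort:
    config: SimConfig
    events: pd.DataFrame            # rMATS-dialect metadata per event
    psi: PsiMatrix
    manifest: pd.DataFrame
    tpm: pd.DataFrame               # genes x samples
    marker_sets: Dict[str, List[str]]
    sf_genes: List[str]
    kinase_genes: List[str]
    splicing_kinase_genes: List[str]
    models: List[TranscriptModel]
    features: pd.DataFrame
    truth: TruthBundle


# ---------------------------------------------------------------------------
# toy annotation

#: (role, gene, in kinase list, in splicing-kinase list, median TPM,
#:  n planted samples, event type)
_SPECIAL_PLAN = [
    ("candidate", "CLK1", True, True, 60.0, 14, "SE"),
    ("decoy_ri", "SRPK1", True, True, 45.0, 14, "RI"),
    ("decoy_ri_like", "CLK3", True, True, 40.0, 14, "A5SS"),
    ("decoy_low_tpm", "FASTK", True, True, 4.0, 14, "SE"),
    ("decoy_low_recurrence", "MARK2", True, True, 50.0, 4, "SE"),
    ("decoy_kinase_only", "BRAF", True, False, 55.0, 14, "SE"),
    ("decoy_non_kinase", "NCAM1", False, False, 70.0, 14, "SE"),
    ("decoy_no_feature", "CLK4", True, True, 50.0, 14, "SE"),
]

_EXTRA_KINASES = ("BRAF", "EGFR", "CDK4", "CDK6", "ALK", "AURKA")


def _make_gene_model(rng: np.random.Generator, gene: str, chrom: str,
                     start: int, strand: str, n_exons: int,
                     tx_suffix: str = "T1") -> TranscriptModel:
    """One toy transcript: contiguous CDS over all exons, frame-closed."""
    exon_lens = rng.integers(60, 201, size=n_exons)
    intron_lens = rng.integers(80, 501, size=n_exons - 1)
    total = int(exon_lens.sum())
    exon_lens[-1] += (-total) % 3  # close the reading frame
    exons = []
    pos = start
    for i in range(n_exons):
        exons.append((pos, pos + int(exon_lens[i])))
        pos = exons[-1][1] + (int(intron_lens[i]) if i < n_exons - 1 else 0)
    return TranscriptModel(
        transcript_id=f"{gene}-{tx_suffix}", gene_symbol=gene, chrom=chrom,
        strand=strand, exons=exons, cds_span=(exons[0][0], exons[-1][1]))


def simulate_annotation(config: SimConfig, rng: np.random.Generator
                        ) -> Tuple[List[TranscriptModel], pd.DataFrame]:
    """Toy genome annotation: ~50 genes with exon/CDS geometry and protein
    features of the four UniProt-style categories at known positions."""
    models: List[TranscriptModel] = []
    feat_rows = []
    special_genes = [p[1] for p in _SPECIAL_PLAN]
    generic = [f"TG{i:02d}" for i in range(42)]
    cursor = 1000
    for gi, gene in enumerate(special_genes + generic):
        strand = "+" if gi % 2 == 0 else "-"
        n_exons = int(rng.integers(5, 11)) if gene in special_genes \
            else int(rng.integers(3, 11))
        m = _make_gene_model(rng, gene, "chrA", cursor, strand, n_exons)
        models.append(m)
        cursor = m.exons[-1][1] + int(rng.integers(2000, 5001))
        plen = m.protein_length
        # place one domain over the middle of the protein plus smaller
        # features; the special genes get their domain positioned against
        # the variable exon below, generic genes get random placements
        if gene not in special_genes:
            if plen >= 30:
                a = int(rng.integers(1, plen // 3))
                b = min(plen, a + int(rng.integers(20, max(21, plen // 2))))
                feat_rows.append((gene, None, "domain", a, b))
            feat_rows.append((gene, None, "localization_signal", 1,
                              min(plen, int(rng.integers(8, 25)))))
            if plen >= 20:
                r1, r2 = sorted(rng.integers(1, plen + 1, size=2))
                if r1 < r2:
                    feat_rows.append((gene, None, "disulfide_bond", int(r1), int(r2)))
                site = int(rng.integers(1, plen + 1))
                feat_rows.append((gene, None, "modified_residue", site, site))
    by_gene = {m.gene_symbol: m for m in models}
    # a second transcript for the candidate gene: identical minus one
    # 3'-terminal exon, exercising the per-model union in mapping
    cand = by_gene["CLK1"]
    if len(cand.exons) >= 4:
        ex2 = [list(e) for e in cand.exons[:-1]]
        total2 = sum(e - s for s, e in ex2)
        ex2[-1][1] -= total2 % 3  # keep the shorter CDS frame-closed
        models.append(TranscriptModel(
            transcript_id="CLK1-T2", gene_symbol="CLK1", chrom=cand.chrom,
            strand=cand.strand,
            exons=[(s, e) for s, e in ex2],
            cds_span=(ex2[0][0], ex2[-1][1])))

    from .annotation import genomic_to_protein

    for role, gene, *_rest in _SPECIAL_PLAN:
        m = by_gene[gene]
        plen = m.protein_length
        var_exon = m.exons[2]  # internal exon used by the special event
        aa = genomic_to_protein(var_exon, m)
        lo, hi = aa
        if role == "decoy_no_feature":
            # features deliberately placed clear of the variable exon
            if hi + 10 < plen:
                feat_rows.append((gene, None, "domain", hi + 5,
                                  min(plen, hi + 30)))
            feat_rows.append((gene, None, "modified_residue", plen, plen))
        else:
            # a kinase-type domain fully containing the exon projection
            a = max(1, lo - 5)
            b = min(plen, hi + 5)
            feat_rows.append((gene, None, "domain", a, b))
            feat_rows.append((gene, None, "modified_residue",
                              min(plen, hi), min(plen, hi)))
            feat_rows.append((gene, None, "localization_signal", 1,
                              min(plen, 15)))
    features = pd.DataFrame(feat_rows, columns=["gene", "transcript",
                                                "feature_type", "aa_start",
                                                "aa_end"])
    features["feature_id"] = [
        f"{r.gene}:{r.feature_type}:{r.aa_start}-{r.aa_end}"
        for r in features.itertuples()]
    return models, features


# ---------------------------------------------------------------------------
# event universe

def _background_events(config: SimConfig, gene_pool: Sequence[str]) -> pd.DataFrame:
    """Coordinate table for the unplanted event universe (rMATS dialect)."""
    rows = []
    type_offset = {"SE": 0, "A5SS": 40_000_000, "A3SS": 80_000_000,
                   "RI": 120_000_000, "MXE": 160_000_000}
    for etype, n in config.n_events.items():
        base0 = type_offset[etype]
        for i in range(n):
            b = base0 + 10_000 * i + 1000
            chrom = f"chr{1 + i % 22}"
            strand = "+" if i % 2 == 0 else "-"
            if etype == "SE":
                coords = (b + 200, b + 300, b, b + 100, b + 400, b + 500)
            elif etype == "MXE":
                coords = (b + 200, b + 300, b + 400, b + 500, b, b + 100,
                          b + 600, b + 700)
            elif etype == "A5SS":
                coords = (b, b + 250, b, b + 150, b + 400, b + 500)
            elif etype == "A3SS":
                coords = (b + 100, b + 350, b + 200, b + 350, b - 200, b - 100)
            else:  # RI
                coords = (b, b + 400, b, b + 100, b + 300, b + 400)
            gene = gene_pool[i % len(gene_pool)]
            rows.append((etype, gene, chrom, strand) + coords)
    max_coords = max(len(c) for c in COORD_COLUMNS.values())
    recs = []
    for row in rows:
        etype = row[0]
        coords = row[4:]
        rec = {"event_type": etype, "geneSymbol": row[1], "GeneID": row[1],
               "chr": row[2], "strand": row[3]}
        for col, val in zip(COORD_COLUMNS[etype], coords):
            rec[col] = val
        recs.append(rec)
    return pd.DataFrame(recs)


def _special_event_rows(models_by_gene: Mapping[str, TranscriptModel]
                        ) -> pd.DataFrame:
    """Events tied to the toy annotation (candidate + cascade decoys)."""
    recs = []
    for role, gene, *_ in _SPECIAL_PLAN:
        m = models_by_gene[gene]
        ex = m.exons
        etype = {"decoy_ri": "RI", "decoy_ri_like": "A5SS"}.get(role, "SE")
        rec = {"event_type": etype, "geneSymbol": gene, "GeneID": gene,
               "chr": m.chrom, "strand": m.strand, "_role": role}
        if etype == "SE":
            rec.update({"exonStart_0base": ex[2][0], "exonEnd": ex[2][1],
                        "upstreamES": ex[1][0], "upstreamEE": ex[1][1],
                        "downstreamES": ex[3][0], "downstreamEE": ex[3][1]})
        elif etype == "RI":
            rec.update({"riExonStart_0base": ex[2][0], "riExonEnd": ex[3][1],
                        "upstreamES": ex[2][0], "upstreamEE": ex[2][1],
                        "downstreamES": ex[3][0], "downstreamEE": ex[3][1]})
        else:  # A5SS whose long form swallows intron 2 entirely (RI-like)
            rec.update({"longExonStart_0base": ex[2][0], "longExonEnd": ex[3][1],
                        "shortES": ex[2][0], "shortEE": ex[2][1],
                        "flankingES": ex[4][0], "flankingEE": ex[4][1]})
        recs.append(rec)
    return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# cohort generation

def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate one cohort (in memory) from the seeded configuration."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_s = config.n_samples
    samples = [f"S{i + 1:04d}" for i in range(n_s)]

    # --- annotation and gene lists -------------------------------------
    if config.include_annotation:
        models, features = simulate_annotation(config, rng)
    else:
        models, features = [], pd.DataFrame(
            columns=["gene", "transcript", "feature_type", "aa_start",
                     "aa_end", "feature_id"])
    models_by_gene: Dict[str, TranscriptModel] = {}
    for m in models:
        models_by_gene.setdefault(m.gene_symbol, m)
    splicing_kinases = [p[1] for p in _SPECIAL_PLAN if p[3]]
    kinase_genes = sorted({p[1] for p in _SPECIAL_PLAN if p[2]}
                          | set(_EXTRA_KINASES) | set(splicing_kinases))
    sf_genes = [f"SF{i:03d}" for i in range(config.n_sf_genes)]
    background_genes = [f"G{i:04d}" for i in range(config.n_background_genes)]
    marker_sets = {
        f"celltype_{t + 1}": [f"MK{t}_{j}" for j in range(config.markers_per_type)]
        for t in range(config.n_celltypes)}

    # --- event universe -------------------------------------------------
    ev = _background_events(config, background_genes)
    if config.include_annotation:
        special = _special_event_rows(models_by_gene)
        roles = list(special.pop("_role"))
        ev = pd.concat([ev, special], ignore_index=True)
    else:
        roles = []
    keys = np.empty(len(ev), dtype=object)
    et_arr = ev["event_type"].to_numpy()
    for t in pd.unique(ev["event_type"]):
        mask = et_arr == t
        sub = ev.loc[mask]
        coord_str = sub[list(COORD_COLUMNS[t])].astype(np.int64).astype(str) \
            .agg(":".join, axis=1)
        keys[mask] = (t + "|" + sub["chr"].astype(str) + "|" + sub["strand"]
                      + "|" + coord_str).to_numpy()
    ev.index = pd.Index(keys, name="event_key")
    if ev.index.duplicated().any():
        raise SimulationError("event universe produced duplicate keys")
    role_of = dict(zip(ev.index[-len(roles):], roles)) if roles else {}
    n_ev = len(ev)
    order = np.argsort(ev.index)
    ev = ev.iloc[order]

    # --- cluster structure ----------------------------------------------
    hist_names = list(config.histologies)
    props = np.array([config.histologies[h] for h in hist_names])
    hist_idx = rng.choice(len(hist_names), size=n_s, p=props)
    k = config.n_clusters
    primary_cluster = np.arange(len(hist_names)) % k
    clusters = primary_cluster[hist_idx] + 1
    flip = rng.random(n_s) < 0.10
    clusters[flip] = rng.integers(1, k + 1, size=flip.sum())

    is_special = np.array([key in role_of for key in ev.index])
    m0 = rng.uniform(0.10, 0.90, size=n_ev)
    informative = (rng.random(n_ev) < config.frac_cluster_informative) & ~is_special
    # special events: high constitutive inclusion so planted skipping is
    # unambiguous
    m0[is_special] = 0.85
    # per-cluster means for informative events
    signs = rng.choice([-1.0, 1.0], size=(n_ev, k))
    m0_inf = np.clip(m0, 0.25, 0.75)
    cluster_means = np.where(informative[:, None],
                             m0_inf[:, None] + signs * config.cluster_dpsi / 2.0,
                             m0[:, None])
    target = cluster_means[:, clusters - 1]  # n_ev x n_s

    # --- planted outliers -----------------------------------------------
    rate = rng.uniform(0.0, 2.0 * config.planted_fraction, size=n_s)
    eligible = ~informative & ~is_special
    planted = (rng.random((n_ev, n_s)) < rate[None, :]) & eligible[:, None]
    up_room = m0 + config.effect_size <= 0.99
    down_room = m0 - config.effect_size >= 0.01
    up = np.where(up_room & down_room,
                  rng.random(n_ev) < 0.5, up_room)
    shift = np.where(up, config.effect_size, -config.effect_size)
    # special events: fixed planted sample sets, always skipping
    special_truth = []
    for key, role in role_of.items():
        plan = next(p for p in _SPECIAL_PLAN if p[0] == role)
        n_plant = plan[5]
        j = ev.index.get_loc(key)
        cols = rng.choice(n_s, size=n_plant, replace=False)
        planted[j, :] = False
        planted[j, cols] = True
        shift[j] = -config.effect_size
        special_truth.append({"role": role, "gene": plan[1], "event_key": key,
                              "n_planted": n_plant})
    target = np.where(planted, np.clip(target + shift[:, None], 0.01, 0.99),
                      target)
    target = np.clip(target, 0.01, 0.99)

    # --- PSI and junction counts ----------------------------------------
    c = config.concentration
    psi_true = rng.beta(target * c, (1.0 - target) * c)
    mu_ln = np.log(config.mean_total_reads) - config.read_ln_sigma ** 2 / 2.0
    total = np.maximum(
        1, np.round(rng.lognormal(mu_ln, config.read_ln_sigma,
                                  size=(n_ev, n_s)))).astype(np.int64)
    li = np.array([FORM_LENGTHS[t][0] for t in ev["event_type"]], dtype=float)
    ls = np.array([FORM_LENGTHS[t][1] for t in ev["event_type"]], dtype=float)
    p_inc = psi_true * li[:, None] / (
        psi_true * li[:, None] + (1.0 - psi_true) * ls[:, None])
    ijc = rng.binomial(total, p_inc)
    sjc = total - ijc

    psi_obs = compute_psi(ijc, sjc, li[:, None], ls[:, None])
    covered = (ijc + sjc) >= config.min_reads
    psi_masked = np.where(covered, psi_obs, np.nan)
    idx = ev.index
    events_meta = _events_meta(ev)
    psi = PsiMatrix(
        events=events_meta,
        psi=pd.DataFrame(psi_masked, index=idx, columns=samples),
        covered=pd.DataFrame(covered, index=idx, columns=samples),
        ijc=pd.DataFrame(ijc.astype(float), index=idx, columns=samples),
        sjc=pd.DataFrame(sjc.astype(float), index=idx, columns=samples),
        min_reads=config.min_reads,
    )

    # --- truth: differential cells ---------------------------------------
    rows_p, cols_p = np.nonzero(planted)
    truth_diff = pd.DataFrame({
        "sample_id": np.asarray(samples)[cols_p],
        "event_key": np.asarray(idx)[rows_p],
        "direction": np.where(shift[rows_p] > 0, "inclusion", "skipping"),
        "true_dpsi": shift[rows_p],
    })
    planted_frac = pd.Series(planted.sum(axis=0) / n_ev,
                             index=pd.Index(samples, name="sample_id"),
                             name="planted_fraction")

    # --- expression -------------------------------------------------------
    frac = rng.dirichlet(np.full(config.n_celltypes, 2.0), size=n_s)
    cell_fracs = pd.DataFrame(frac, index=pd.Index(samples, name="sample_id"),
                              columns=list(marker_sets))
    tpm = _expression_matrix(config, rng, samples, sf_genes, marker_sets,
                             cell_fracs, background_genes, planted_frac)

    # --- survival ----------------------------------------------------------
    cand_keys = [t["event_key"] for t in special_truth
                 if t["role"] == "candidate"]
    if cand_keys:
        cand_psi = target[idx.get_loc(cand_keys[0]), :]
    else:
        cand_psi = np.full(n_s, 0.8)
    cluster_log_hr = np.concatenate(
        [[0.0], rng.normal(0.0, config.cluster_log_hr_sd, size=k - 1)])
    manifest = _manifest(config, rng, samples, hist_names, hist_idx, clusters,
                         cluster_log_hr, cand_psi, planted_frac)

    truth = TruthBundle(
        differential=truth_diff,
        sample_planted_fraction=planted_frac,
        clusters=pd.Series(clusters, index=pd.Index(samples, name="sample_id"),
                           name="cluster"),
        cell_fractions=cell_fracs,
        candidate_event_keys=cand_keys,
        special_events=pd.DataFrame(special_truth,
                                    columns=["role", "gene", "event_key",
                                             "n_planted"]),
        survival_coefs={"psi_log_hr": config.psi_log_hr,
                        "baseline_hazard": config.baseline_hazard,
                        **{f"cluster_{i + 1}_log_hr": float(v)
                           for i, v in enumerate(cluster_log_hr)}},
    )
    return SyntheticCohort(
        config=config, events=ev, psi=psi, manifest=manifest, tpm=tpm,
        marker_sets=marker_sets, sf_genes=sf_genes,
        kinase_genes=kinase_genes, splicing_kinase_genes=splicing_kinases,
        models=models, features=features, truth=truth)


def _events_meta(ev: pd.DataFrame) -> pd.DataFrame:
    """Vectorised variable-region annotation (mirrors SpliceEvent rules)."""
    out = ev.rename(columns={"geneSymbol": "gene_symbol", "chr": "chrom",
                             "GeneID": "gene_id"}).copy()
    vs = np.zeros(len(ev), dtype=np.int64)
    ve = np.zeros(len(ev), dtype=np.int64)
    et = ev["event_type"].to_numpy()
    for t in set(et):
        mask = et == t
        sub = ev.loc[mask]
        if t in ("SE", "MXE"):
            cols = COORD_COLUMNS[t][:2]
            vs[mask] = sub[cols[0]]
            ve[mask] = sub[cols[1]]
        elif t == "RI":
            vs[mask] = sub["upstreamEE"]
            ve[mask] = sub["downstreamES"]
        else:
            long_s = sub["longExonStart_0base"].to_numpy()
            long_e = sub["longExonEnd"].to_numpy()
            short_s = sub["shortES"].to_numpy()
            short_e = sub["shortEE"].to_numpy()
            same_start = long_s == short_s
            vs[mask] = np.where(same_start, short_e, long_s)
            ve[mask] = np.where(same_start, long_e, short_s)
    out["variable_start"] = vs
    out["variable_end"] = ve
    return out


def _expression_matrix(config, rng, samples, sf_genes, marker_sets,
                       cell_fracs, background_genes, planted_frac):
    n_s = len(samples)
    rows = {}
    burden = planted_frac.to_numpy()
    burden_c = burden - burden.mean()
    for g in sf_genes:
        base = rng.uniform(3.0, 6.0)
        slope = config.sf_coupling_slope * rng.uniform(0.5, 1.0)
        log2 = base + slope * burden_c + rng.normal(0, 0.3, n_s)
        rows[g] = np.maximum(0.0, 2.0 ** log2 - 1.0)
    for t, (ctype, markers) in enumerate(marker_sets.items()):
        f = cell_fracs[ctype].to_numpy()
        for g in markers:
            base = rng.uniform(2.0, 5.0)
            log2 = base + config.marker_coupling * f + rng.normal(0, 0.3, n_s)
            rows[g] = np.maximum(0.0, 2.0 ** log2 - 1.0)
    for g in background_genes:
        base = rng.uniform(0.5, 7.0)
        rows[g] = np.maximum(0.0, 2.0 ** (base + rng.normal(0, 0.4, n_s)) - 1.0)
    for role, gene, _k, _sk, med_tpm, _n, _t in _SPECIAL_PLAN:
        log2 = np.log2(med_tpm + 1.0) + rng.normal(0, 0.2, n_s)
        rows[gene] = np.maximum(0.0, 2.0 ** log2 - 1.0)
    for gene in _EXTRA_KINASES:
        rows[gene] = np.maximum(
            0.0, 2.0 ** (rng.uniform(3.0, 6.0) + rng.normal(0, 0.3, n_s)) - 1.0)
    tpm = pd.DataFrame(rows, index=pd.Index(samples, name="sample_id")).T
    tpm.index.name = "gene"
    return tpm.round(4)


def _manifest(config, rng, samples, hist_names, hist_idx, clusters,
              cluster_log_hr, cand_psi, planted_frac):
    n_s = len(samples)
    age = np.round(rng.uniform(0.5, 18.0, n_s), 1)
    resection = rng.choice(["gross/near total", "partial", "biopsy"],
                           size=n_s, p=[0.5, 0.3, 0.2])
    # TMB: lognormal, mostly independent of burden, a hypermutant tail
    log_tmb = rng.normal(np.log(2.0), 0.8, n_s) + 3.0 * (
        planted_frac.to_numpy() - planted_frac.mean())
    tmb = np.exp(log_tmb)
    hyper = rng.random(n_s) < 0.03
    tmb[hyper] *= 20.0
    rows = {"sample_id": samples,
            "histology": [hist_names[i] for i in hist_idx],
            "molecular_subtype": [f"{hist_names[i]}_sub{1 + c % 2}"
                                  for i, c in zip(hist_idx, clusters)],
            "age_at_diagnosis": age, "resection": resection,
            "tmb": np.round(tmb, 3)}
    for endpoint, scale in (("os", 1.0), ("efs", 1.6)):
        h = config.baseline_hazard * scale * np.exp(
            cluster_log_hr[clusters - 1] + config.psi_log_hr * cand_psi)
        t_event = rng.exponential(1.0 / h)
        cr = config.censoring_rate
        h_c = config.baseline_hazard * scale * (cr / max(1e-9, 1.0 - cr))
        t_cens = rng.exponential(1.0 / h_c, size=n_s)
        t_cens = np.minimum(t_cens, 4000.0)
        time = np.minimum(t_event, t_cens)
        status = (t_event <= t_cens).astype(int)
        rows[f"{endpoint}_days"] = np.round(np.maximum(time, 1.0), 1)
        rows[f"{endpoint}_status"] = status
    return pd.DataFrame(rows)


def simulate_survival(n: int, log_hr: float, rng: np.random.Generator,
                      censoring_rate: float = 0.3,
                      baseline_hazard: float = 1.0 / 1000.0,
                      covariate: str = "binary") -> pd.DataFrame:
    """Stand-alone survival generator for estimator checks.

    One covariate x (binary balanced or U(0,1)) with true log hazard ratio
    ``log_hr``; exponential event times, independent exponential censoring
    tuned to the requested rate.
    """
    if covariate == "binary":
        x = rng.permutation(np.repeat([0.0, 1.0], [n - n // 2, n // 2]))
    else:
        x = rng.uniform(0, 1, n)
    h = baseline_hazard * np.exp(log_hr * x)
    t_event = rng.exponential(1.0 / h)
    h_c = baseline_hazard * censoring_rate / max(1e-9, 1.0 - censoring_rate)
    t_cens = rng.exponential(1.0 / h_c, size=n)
    time = np.minimum(t_event, t_cens)
    status = (t_event <= t_cens).astype(int)
    return pd.DataFrame({"time": np.maximum(time, 1e-3), "status": status,
                         "x": x})


# ---------------------------------------------------------------------------
# serialisation

def write_cohort(cohort: SyntheticCohort, outdir: Union[str, Path],
                 overwrite: bool = False) -> Path:
    """Write the cohort as pipeline-consumable fixtures plus truth TSVs.

    Layout: rmats/<sample>/<TYPE>.MATS.JC.txt, manifest.tsv, tpm.tsv,
    annotation.gtf, features.tsv, kinase_genes.tsv,
    splicing_kinase_genes.tsv, sf_genes.tsv, marker_sets.tsv, truth/*.tsv.
    """
    from .annotation import write_gtf
    from .rmats_io import write_sample_events

    out = Path(outdir)
    if out.exists() and overwrite:
        shutil.rmtree(out)
    out.mkdir(parents=True, exist_ok=False)
    (out / "rmats").mkdir()
    ev = cohort.events
    ijc, sjc = cohort.psi.ijc, cohort.psi.sjc
    li = pd.Series([FORM_LENGTHS[t][0] for t in ev["event_type"]], index=ev.index)
    ls = pd.Series([FORM_LENGTHS[t][1] for t in ev["event_type"]], index=ev.index)
    for sample in cohort.psi.samples:
        sdir = out / "rmats" / sample
        sdir.mkdir()
        for etype in sorted(ev["event_type"].unique()):
            mask = ev["event_type"] == etype
            sub = ev.loc[mask].copy()
            if not len(sub):
                continue
            tab = pd.DataFrame({
                "event_type": etype,
                "ID": np.arange(len(sub)),
                "GeneID": sub["GeneID"], "geneSymbol": sub["geneSymbol"],
                "chr": sub["chr"], "strand": sub["strand"],
            }, index=sub.index)
            for col in COORD_COLUMNS[etype]:
                tab[col] = sub[col].astype(np.int64)
            tab["IJC_SAMPLE_1"] = ijc.loc[sub.index, sample].astype(np.int64)
            tab["SJC_SAMPLE_1"] = sjc.loc[sub.index, sample].astype(np.int64)
            tab["IncFormLen"] = li.loc[sub.index].astype(np.int64)
            tab["SkipFormLen"] = ls.loc[sub.index].astype(np.int64)
            tab["IncLevel1"] = compute_psi(
                tab["IJC_SAMPLE_1"], tab["SJC_SAMPLE_1"],
                tab["IncFormLen"], tab["SkipFormLen"])
            write_sample_events(tab, sdir / f"{etype}.MATS.JC.txt")
    cohort.manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    cohort.tpm.to_csv(out / "tpm.tsv", sep="\t")
    if cohort.models:
        write_gtf(cohort.models, out / "annotation.gtf")
        cohort.features.to_csv(out / "features.tsv", sep="\t", index=False)
    pd.DataFrame({"gene": cohort.kinase_genes}).to_csv(
        out / "kinase_genes.tsv", sep="\t", index=False)
    pd.DataFrame({"gene": cohort.splicing_kinase_genes}).to_csv(
        out / "splicing_kinase_genes.tsv", sep="\t", index=False)
    pd.DataFrame({"gene": cohort.sf_genes}).to_csv(
        out / "sf_genes.tsv", sep="\t", index=False)
    pd.DataFrame([(t, g) for t, gs in cohort.marker_sets.items() for g in gs],
                 columns=["cell_type", "gene"]).to_csv(
        out / "marker_sets.tsv", sep="\t", index=False)
    tdir = out / "truth"
    tdir.mkdir()
    tr = cohort.truth
    tr.differential.to_csv(tdir / "differential.tsv", sep="\t", index=False)
    tr.sample_planted_fraction.to_frame().to_csv(
        tdir / "planted_fraction.tsv", sep="\t")
    tr.clusters.to_frame().to_csv(tdir / "clusters.tsv", sep="\t")
    tr.cell_fractions.to_csv(tdir / "cell_fractions.tsv", sep="\t")
    tr.special_events.to_csv(tdir / "special_events.tsv", sep="\t", index=False)
    pd.DataFrame({"event_key": tr.candidate_event_keys}).to_csv(
        tdir / "candidates.tsv", sep="\t", index=False)
    pd.Series(tr.survival_coefs, name="value").rename_axis("coef").to_csv(
        tdir / "survival_coefs.tsv", sep="\t")
    return out
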