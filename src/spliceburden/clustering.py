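"""Splicing-based cohort structure: variable-event selection, hierarchical
clustering, label enrichment, and cell-type variance partitioning.

Samples are clustered on the PSI of the most variable events (default top
5000 among events covered in >= 75% of samples), agglomeratively with Ward
linkage on Euclidean distance, and the tree cut at a fixed k (default 10).
Cluster-label association uses one-vs-rest 2x2 Fisher exact tests with
Haldane-Anscombe-corrected odds ratios.  To ask how much of an event's
PSI variability merely tracks cellular composition, marker-based cell-type
scores are regressed against each event's PSI and the R^2 binned at
30% / 50%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .rmats_io import PsiMatrix

DEFAULT_TOP_K = 5000
DEFAULT_N_CLUSTERS = 10
DEFAULT_MIN_COVERAGE_FRAC = 0.75


def top_variable_events(psi: PsiMatrix, k: int = DEFAULT_TOP_K,
                        min_coverage_frac: float = DEFAULT_MIN_COVERAGE_FRAC) -> List[str]:
    """Keys of the k most variable events among well-covered ones.

    Events covered in >= min_coverage_frac of samples are ranked by PSI
    sample variance (over covered cells); ties break lexicographically by
    event_key so the selection is deterministic.
    """
    vals = psi.psi.to_numpy()
    n_cov = np.isfinite(vals).sum(axis=1)
    eligible = n_cov >= min_coverage_frac * vals.shape[1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        var = np.nanvar(vals, axis=1, ddof=1)
    var = np.where(n_cov > 1, var, 0.0)
    keys = np.asarray(psi.psi.index)
    elig_keys, elig_var = keys[eligible], var[eligible]
    if len(elig_keys) < k:
        warnings.warn(
            f"only {len(elig_keys)} eligible events for top_variable_events(k={k})")
    order = np.lexsort((elig_keys, -elig_var))
    return list(elig_keys[order[:k]])


@dataclass
class ClusterResult:
    """Sample-to-cluster assignment with the parameters that produced it."""

    assignments: pd.Series  # sample_id -> cluster id in 1..k
    k: int
    linkage: str = "ward"
    distance: str = "euclidean"
    linkage_matrix: Optional[np.ndarray] = field(default=None, repr=False)


def cluster_samples(psi: PsiMatrix, k: int = DEFAULT_N_CLUSTERS,
                    linkage: str = "ward",
                    distance: str = "euclidean") -> ClusterResult:
    """Agglomerative clustering of samples on (imputed) PSI.

    Missing cells are imputed with the event median before computing
    distances.  ``distance='correlation'`` uses 1 - Pearson.  Cluster ids
    are relabelled 1..k in order of first appearance over the sorted
    sample list, which makes the partition invariant to input sample
    order up to nothing at all — the labels themselves are canonical.
    """
    mat = psi.psi
    n = mat.shape[1]
    if k < 2 or k > n:
        raise ValueError(f"k={k} out of range for {n} samples")
    # canonical sample order for deterministic linkage
    cols = sorted(mat.columns)
    x = mat[cols].to_numpy().T  # samples x events
    med = np.nanmedian(mat.to_numpy(), axis=1)
    fill = np.broadcast_to(med, x.shape)
    x = np.where(np.isfinite(x), x, fill)
    if linkage == "ward" and distance != "euclidean":
        raise ValueError("ward linkage requires euclidean distance")
    d = pdist(x, metric=distance)
    z = hierarchy.linkage(d, method=linkage)
    raw = hierarchy.fcluster(z, t=k, criterion="maxclust")
    # canonical labels: 1..k by first appearance
    relabel: Dict[int, int] = {}
    labels = np.empty_like(raw)
    for i, c in enumerate(raw):
        relabel.setdefault(c, len(relabel) + 1)
        labels[i] = relabel[c]
    assign = pd.Series(labels, index=pd.Index(cols, name="sample_id"),
                       name="cluster")
    return ClusterResult(assignments=assign, k=k, linkage=linkage,
                         distance=distance, linkage_matrix=z)


def cluster_enrichment(clusters: pd.Series, labels: pd.Series) -> pd.DataFrame:
    """One-vs-rest Fisher exact enrichment of labels in clusters.

    For each (cluster, label) pair a 2x2 table a,b,c,d is built
    (a = in-cluster with label, b = in-cluster without, c = out-of-cluster
    with, d = out-of-cluster without).  OR = (a d)/(b c) with 0.5 added to
    every cell when any is zero (Haldane-Anscombe); the uncorrected OR is
    kept with an infinity flag.  p from the two-sided Fisher exact test,
    BH-adjusted across all rows.
    """
    common = clusters.index.intersection(labels.index)
    missing = clusters.index.difference(labels.index)
    if len(missing):
        raise ValueError(f"samples without labels: {list(missing)[:5]}")
    cl, lab = clusters.loc[common], labels.loc[common]
    rows = []
    for c in sorted(cl.unique()):
        in_c = cl == c
        for l in sorted(lab.unique()):
            has = lab == l
            a = int((in_c & has).sum())
            b = int((in_c & ~has).sum())
            cc = int((~in_c & has).sum())
            d = int((~in_c & ~has).sum())
            _, p = sps.fisher_exact([[a, b], [cc, d]], alternative="two-sided")
            raw_or = np.inf if b * cc == 0 and a * d > 0 else (
                np.nan if b * cc == 0 else a * d / (b * cc))
            if min(a, b, cc, d) == 0:
                or_ = (a + .5) * (d + .5) / ((b + .5) * (cc + .5))
                corrected = True
            else:
                or_, corrected = a * d / (b * cc), False
            rows.append({"cluster": c, "label": l, "a": a, "b": b, "c": cc,
                         "d": d, "odds_ratio": or_, "raw_or_infinite":
                         bool(np.isinf(raw_or)), "haldane_corrected": corrected,
                         "p": p})
    out = pd.DataFrame(rows)
    out["adj_p"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def celltype_scores(tpm: pd.DataFrame,
                    marker_sets: Mapping[str, Sequence[str]]) -> pd.DataFrame:
    """Marker-based cell-type scores from bulk expression.

    Per cell type: z-score log2(TPM+1) of each marker gene across samples
    and average over the type's markers.  Markers absent from the matrix
    are dropped with a warning; a type with no usable (present,
    non-constant) marker is an error.  Returns samples x types.
    """
    log = np.log2(tpm + 1.0)
    out = {}
    for ctype, markers in marker_sets.items():
        present = [g for g in markers if g in log.index]
        dropped = set(markers) - set(present)
        if dropped:
            warnings.warn(f"{ctype}: markers missing from expression: {sorted(dropped)}")
        sub = log.loc[present]
        sd = sub.std(axis=1, ddof=1)
        usable = sub.index[sd > 0]
        if len(usable) == 0:
            raise ValueError(f"cell type {ctype!r} has no usable marker genes")
        z = sub.loc[usable].sub(sub.loc[usable].mean(axis=1), axis=0) \
            .div(sd.loc[usable], axis=0)
        out[ctype] = z.mean(axis=0)
    scores = pd.DataFrame(out)
    scores.index.name = "sample_id"
    return scores


def psi_variance_explained(psi: PsiMatrix, scores: pd.DataFrame,
                           bins: Sequence[float] = (0.30, 0.50)) -> pd.DataFrame:
    """Per-event R^2 of PSI on the cell-type scores.

    Ordinary least squares of each event's PSI (covered samples only) on
    all score columns plus an intercept; R^2 = 1 - RSS/TSS.  Events with
    fewer than n_types + 2 covered samples or zero PSI variance are
    skipped.  Bins: '<30%', '30-50%' (closed) and '>50%'.
    """
    lo, hi = bins
    common = [s for s in psi.psi.columns if s in scores.index]
    mat = psi.psi[common].to_numpy()
    x_full = np.column_stack([np.ones(len(common)),
                              scores.loc[common].to_numpy()])
    p = x_full.shape[1]
    rows = []
    for i, key in enumerate(psi.psi.index):
        y = mat[i]
        mask = np.isfinite(y)
        if mask.sum() < p + 1:
            continue
        yy = y[mask]
        tss = float(np.sum((yy - yy.mean()) ** 2))
        if tss < 1e-10:  # constant PSI (within float round-off)
            continue
        beta, *_ = np.linalg.lstsq(x_full[mask], yy, rcond=None)
        rss = float(np.sum((yy - x_full[mask] @ beta) ** 2))
        r2 = max(0.0, min(1.0, 1.0 - rss / tss))
        b = "<30%" if r2 < lo else ("30-50%" if r2 <= hi else ">50%")
        rows.append({"event_key": key, "r_squared": r2, "bin": b,
                     "n": int(mask.sum())})
    return pd.DataFrame(rows).set_index("event_key") if rows else \
        pd.DataFrame(columns=["r_squared", "bin", "n"])


def silhouette_k_scan(psi: PsiMatrix, k_values: Sequence[int],
                      linkage: str = "ward") -> pd.DataFrame:
    """Mean silhouette width per candidate k (diagnostic only, never
    auto-applied)."""
    from sklearn.metrics import silhouette_score

    rows = []
    for k in k_values:
        res = cluster_samples(psi, k=k, linkage=linkage)
        mat = psi.psi[res.assignments.index].to_numpy().T
        med = np.nanmedian(mat, axis=0)
        mat = np.where(np.isfinite(mat), mat, np.broadcast_to(med, mat.shape))
        rows.append({"k": k, "silhouette":
                     float(silhouette_score(mat, res.assignments.to_numpy()))})
    return pd.DataFrame(rows)
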