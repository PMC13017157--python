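"""Single-sample differential splicing against cohort statistics.

Each tumor is compared to the whole cohort rather than to a matched
normal: for every event j we take the cohort mean mu_j and standard
deviation sigma_j of PSI over covered samples, and a sample i is called
differential for event j when both the z-score |psi_ij - mu_j| / sigma_j
and the PSI shift |psi_ij - mu_j| clear their thresholds (defaults
|z| > 2 and |dPSI| > 0.2, strict).  Calls carry a direction: inclusion
(dPSI > 0) or skipping (dPSI < 0).  Recurrent events are those called in
at least ``min_recurrence`` samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .rmats_io import PsiMatrix

DEFAULT_Z_THRESH = 2.0
DEFAULT_DPSI_THRESH = 0.2
DEFAULT_MIN_COHORT_N = 10
DEFAULT_MIN_RECURRENCE = 2


@dataclass
class CohortEventStats:
    """Per-event cohort mean/sd of PSI over covered samples.

    In ``full`` mode mu/sigma include every covered sample (the queried
    sample among them); ``leave-one-out`` mode stores sufficient
    statistics so each sample is scored against the cohort without
    itself.  Events with fewer than ``min_cohort_n`` covered samples or
    zero variance are non-evaluable.
    """

    mean: pd.Series
    sd: pd.Series
    n: pd.Series
    evaluable: pd.Series
    mode: str = "full"
    min_cohort_n: int = DEFAULT_MIN_COHORT_N
    # sufficient statistics for leave-one-out scoring
    _sum: Optional[pd.Series] = None
    _sumsq: Optional[pd.Series] = None


def cohort_event_stats(psi: PsiMatrix, mode: str = "full",
                       min_cohort_n: int = DEFAULT_MIN_COHORT_N) -> CohortEventStats:
    """Cohort per-event PSI statistics (sample sd, n-1 denominator)."""
    if mode not in ("full", "leave-one-out"):
        raise ValueError(f"unknown stats mode {mode!r}")
    vals = psi.psi.to_numpy()
    n = np.sum(np.isfinite(vals), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(np.where(np.isfinite(vals), vals, np.nan), axis=1)
        sd = np.nanstd(vals, axis=1, ddof=1)
    mean = np.where(n > 0, mean, np.nan)
    sd = np.where(n > 1, sd, np.nan)
    evaluable = (n >= min_cohort_n) & (sd > 0)
    if not evaluable.any():
        warnings.warn("no evaluable events in cohort statistics")
    idx = psi.psi.index
    stats = CohortEventStats(
        mean=pd.Series(mean, index=idx), sd=pd.Series(sd, index=idx),
        n=pd.Series(n, index=idx), evaluable=pd.Series(evaluable, index=idx),
        mode=mode, min_cohort_n=min_cohort_n,
    )
    if mode == "leave-one-out":
        finite = np.where(np.isfinite(vals), vals, 0.0)
        stats._sum = pd.Series(finite.sum(axis=1), index=idx)
        stats._sumsq = pd.Series((finite ** 2).sum(axis=1), index=idx)
    return stats


def _loo_mean_sd(stats: CohortEventStats, vals: np.ndarray):
    """Leave-one-out mu and sigma per cell from sufficient statistics."""
    n = stats.n.to_numpy()[:, None]
    s = stats._sum.to_numpy()[:, None]
    ss = stats._sumsq.to_numpy()[:, None]
    present = np.isfinite(vals)
    x = np.where(present, vals, 0.0)
    n_i = np.where(present, n - 1, n)
    s_i = np.where(present, s - x, s)
    ss_i = np.where(present, ss - x ** 2, ss)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu = s_i / n_i
        var = (ss_i - n_i * mu ** 2) / (n_i - 1)
    var = np.clip(var, 0.0, None)
    sd = np.sqrt(var)
    mu = np.where(n_i >= 1, mu, np.nan)
    sd = np.where(n_i >= 2, sd, np.nan)
    return mu, sd, n_i


def call_differential(psi: PsiMatrix, stats: CohortEventStats,
                      z_thresh: float = DEFAULT_Z_THRESH,
                      dpsi_thresh: float = DEFAULT_DPSI_THRESH) -> pd.DataFrame:
    """Emit per-(sample, event) differential calls.

    Returns a tidy DataFrame with columns sample_id, event_key, psi,
    delta_psi, z, direction; one row per call.  A call requires the cell
    to be covered, the event evaluable, and both |z| > z_thresh and
    |delta_psi| > dpsi_thresh (strict inequalities).
    """
    if z_thresh <= 0 or dpsi_thresh <= 0:
        raise ValueError("thresholds must be positive")
    if not stats.mean.index.equals(psi.psi.index):
        raise ValueError("stats were not computed from this matrix")
    vals = psi.psi.to_numpy()
    if stats.mode == "leave-one-out":
        mu, sd, n_eff = _loo_mean_sd(stats, vals)
        evaluable = (n_eff >= stats.min_cohort_n) & (sd > 0)
    else:
        mu = stats.mean.to_numpy()[:, None]
        sd = stats.sd.to_numpy()[:, None]
        evaluable = stats.evaluable.to_numpy()[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        dpsi = vals - mu
        z = dpsi / sd
    hit = (np.isfinite(vals) & evaluable
           & (np.abs(z) > z_thresh) & (np.abs(dpsi) > dpsi_thresh))
    rows, cols = np.nonzero(hit)
    order = np.lexsort((rows, cols))  # sort by sample then event: stable output
    rows, cols = rows[order], cols[order]
    samples = np.asarray(psi.psi.columns)
    keys = np.asarray(psi.psi.index)
    d = dpsi[rows, cols]
    calls = pd.DataFrame({
        "sample_id": samples[cols],
        "event_key": keys[rows],
        "psi": vals[rows, cols],
        "delta_psi": d,
        "z": z[rows, cols],
        "direction": np.where(d > 0, "inclusion", "skipping"),
    })
    return calls


def recurrence(calls: pd.DataFrame,
               min_recurrence: int = DEFAULT_MIN_RECURRENCE) -> pd.DataFrame:
    """Summarise events called in >= min_recurrence samples.

    direction_class is 'inclusion' if every call is inclusion, 'skipping'
    if every call is skipping, else 'mixed'.
    """
    if len(calls) == 0:
        return pd.DataFrame(columns=["event_key", "n_samples_called", "n_inclusion",
                                     "n_skipping", "direction_class", "mean_abs_dpsi"]
                            ).set_index("event_key")
    tmp = calls.assign(
        _inc=(calls["direction"] == "inclusion").astype(int),
        _abs_dpsi=calls["delta_psi"].abs(),
    )
    out = tmp.groupby("event_key").agg(
        n_samples_called=("sample_id", "size"),
        n_inclusion=("_inc", "sum"),
        mean_abs_dpsi=("_abs_dpsi", "mean"),
    )
    out["n_skipping"] = out["n_samples_called"] - out["n_inclusion"]
    out = out[out["n_samples_called"] >= min_recurrence]
    out["direction_class"] = np.select(
        [out["n_skipping"] == 0, out["n_inclusion"] == 0],
        ["inclusion", "skipping"], default="mixed")
    out = out[["n_samples_called", "n_inclusion", "n_skipping",
               "direction_class", "mean_abs_dpsi"]]
    out.index.name = "event_key"
    return out.sort_index()


def histology_specific(recurrent: pd.DataFrame, calls: pd.DataFrame,
                       manifest: pd.DataFrame) -> pd.DataFrame:
    """Histology-specific recurrent events, normalised per patient.

    An event is specific to a histology when every sample it was called in
    belongs to that histology; otherwise it is shared.  Returns one row per
    histology with the count of specific events and that count divided by
    the number of cohort patients of the histology, plus a 'shared' row.
    """
    if "histology" not in manifest.columns:
        raise ValueError("manifest needs a 'histology' column")
    hist = manifest.set_index("sample_id")["histology"] \
        if "sample_id" in manifest.columns else manifest["histology"]
    missing = sorted(set(calls["sample_id"]) - set(hist.index))
    if missing:
        raise ValueError(f"samples missing from manifest: {missing}")
    rec_calls = calls[calls["event_key"].isin(recurrent.index)]
    ev_hist = rec_calls.assign(histology=hist.loc[rec_calls["sample_id"]].to_numpy())
    nuniq = ev_hist.groupby("event_key")["histology"].nunique()
    specific_events = nuniq[nuniq == 1].index
    spec_hist = ev_hist[ev_hist["event_key"].isin(specific_events)] \
        .groupby("event_key")["histology"].first()
    counts = spec_hist.value_counts()
    n_patients = hist.value_counts()
    rows = []
    for h in sorted(n_patients.index):
        c = int(counts.get(h, 0))
        rows.append({"histology": h, "n_specific_events": c,
                     "n_patients": int(n_patients[h]),
                     "events_per_patient": c / n_patients[h]})
    rows.append({"histology": "shared", "n_specific_events":
                 int((nuniq > 1).sum()), "n_patients": len(hist),
                 "events_per_patient": float((nuniq > 1).sum()) / len(hist)})
    return pd.DataFrame(rows)
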