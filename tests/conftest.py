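"""Shared fixtures: handcrafted rMATS-style tables and small synthetic
cohorts (generated at test time, nothing stored on disk)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from spliceburden.events import COORD_COLUMNS, make_event_key
from spliceburden.rmats_io import PsiMatrix
from spliceburden.simulate import SimConfig, simulate_cohort


def se_table(rows):
    """Build a per-sample SE event table in the shape read_sample_events
    returns.

    ``rows`` is a list of dicts with keys: gene, chrom, strand, coords
    (6-tuple), ijc, sjc, and optional lens (2-tuple, default (198, 99)).
    """
    recs, keys = [], []
    for i, r in enumerate(rows):
        li, ls = r.get("lens", (198, 99))
        rec = {"event_type": "SE", "ID": i, "GeneID": r.get("gene", f"G{i}"),
               "geneSymbol": r.get("gene", f"G{i}"), "chr": r["chrom"],
               "strand": r["strand"]}
        for col, v in zip(COORD_COLUMNS["SE"], r["coords"]):
            rec[col] = v
        rec.update(IJC_SAMPLE_1=r["ijc"], SJC_SAMPLE_1=r["sjc"],
                   IncFormLen=li, SkipFormLen=ls)
        total = r["ijc"] / li + r["sjc"] / ls
        rec["IncLevel1"] = (r["ijc"] / li) / total if total else np.nan
        recs.append(rec)
        keys.append(make_event_key("SE", r["chrom"], r["strand"],
                                   tuple(r["coords"])))
    df = pd.DataFrame(recs)
    df.index = pd.Index(keys, name="event_key")
    return df


def psi_from_array(values, samples=None, events=None, covered=None):
    """Wrap a dense (events x samples) array as a PsiMatrix; NaN = missing."""
    values = np.asarray(values, dtype=float)
    n_ev, n_s = values.shape
    samples = samples or [f"S{j:03d}" for j in range(n_s)]
    events = events or [f"E{i:05d}" for i in range(n_ev)]
    idx = pd.Index(events, name="event_key")
    psi = pd.DataFrame(values, index=idx, columns=samples)
    cov = pd.DataFrame(np.isfinite(values) if covered is None else covered,
                       index=idx, columns=samples)
    meta = pd.DataFrame(index=idx)
    return PsiMatrix(events=meta, psi=psi, covered=cov)


@pytest.fixture(scope="session")
def cohort150():
    """Mid-size cohort with annotation: large enough that 14 planted
    samples stay a small fraction and the cascade truth is recoverable."""
    cfg = SimConfig(n_samples=150,
                    n_events={"SE": 4000, "A5SS": 80, "A3SS": 80,
                              "RI": 80, "MXE": 40},
                    seed=31)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def flat_cohort():
    """Small cohort without cluster structure, for differential/SBI checks."""
    cfg = SimConfig(n_samples=100, n_events={"SE": 3000},
                    frac_cluster_informative=0.0, seed=17)
    return simulate_cohort(cfg)
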