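"""Splicing Burden Index (SBI) and its cohort associations.

The SBI of a tumor is the proportion of its evaluable splice events that
are called differential against the cohort: numerator = differential
calls in that sample, denominator = events both covered in the sample and
cohort-evaluable.  Samples are grouped by cohort quartiles of SBI — high
(>= Q3) and low (<= Q1), the rest mid — and the module provides the
correlation and differential-expression analyses built on those groups:
TMB~SBI correlation with optional hypermutant exclusion, cluster- or
histology-stratified correlations, and the splicing-factor gene
high-vs-low expression comparison with Benjamini-Hochberg correction.
"""

from __future__ import annotations

import warnings
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .differential import CohortEventStats
from .rmats_io import PsiMatrix

DEFAULT_HYPERMUTANT_TMB = 10.0  # mutations/Mb


def compute_sbi(calls: pd.DataFrame, psi: PsiMatrix,
                stats: CohortEventStats,
                global_denominator: bool = False) -> pd.DataFrame:
    """Per-sample splicing burden.

    Returns a DataFrame indexed by sample_id with n_differential,
    n_evaluable and sbi.  With ``global_denominator`` the denominator is
    the cohort-wide evaluable event count for every sample instead of the
    per-sample covered subset.
    """
    evaluable = stats.evaluable.to_numpy()
    covered = psi.psi.notna().to_numpy()  # psi present => covered
    denom = (covered & evaluable[:, None]).sum(axis=0)
    if global_denominator:
        denom = np.full_like(denom, int(evaluable.sum()))
    samples = pd.Index(psi.psi.columns, name="sample_id")
    zero = samples[denom == 0]
    if len(zero):
        raise ValueError(f"samples with zero evaluable events: {list(zero)}")
    n_calls = calls.groupby("sample_id").size().reindex(samples, fill_value=0)
    out = pd.DataFrame({
        "n_differential": n_calls.astype(int),
        "n_evaluable": denom,
    }, index=samples)
    out["sbi"] = out["n_differential"] / out["n_evaluable"]
    return out


def assign_sbi_groups(sbi: pd.DataFrame) -> pd.DataFrame:
    """Label samples high (sbi >= Q3) / low (sbi <= Q1) / mid.

    Quartiles are order statistics: Q3 is the observation at the ceiling
    of the 0.75 linear rank and Q1 at the floor of the 0.25 rank, so with
    n divisible by 4 exactly n/4 samples land in each extreme group.
    Boundary ties are included in the extreme groups.  A degenerate
    cohort where Q1 == Q3
    (every sample would be both high and low) is resolved to all-mid with
    a warning.
    """
    if len(sbi) < 4:
        raise ValueError("need >= 4 samples for quartile groups")
    v = sbi["sbi"].to_numpy()
    q1 = np.quantile(v, 0.25, method="lower")
    q3 = np.quantile(v, 0.75, method="higher")
    out = sbi.copy()
    if q1 == q3:
        warnings.warn("degenerate SBI distribution (Q1 == Q3); all samples mid")
        out["group"] = "mid"
    else:
        out["group"] = np.select([v >= q3, v <= q1], ["high", "low"], "mid")
    out.attrs["q1"], out.attrs["q3"] = float(q1), float(q3)
    return out


def grouped_correlation(x: pd.Series, y: pd.Series,
                        grouping: Optional[pd.Series] = None,
                        method: str = "pearson",
                        exclude_filter: Optional[Callable[[pd.DataFrame], pd.Series]] = None,
                        label: str = "all") -> pd.DataFrame:
    """Correlate two per-sample variables, overall or within groups.

    ``x`` and ``y`` are aligned on their index (sample ids).
    ``exclude_filter`` receives the aligned frame and returns a boolean
    keep-mask (e.g. to drop hypermutant tumors before a TMB correlation).
    BH adjustment is applied across the rows of one invocation; groups
    with < 3 pairs or zero variance are flagged not-computable.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    df = pd.DataFrame({"x": x, "y": y}).dropna()
    if grouping is not None:
        df["group"] = grouping.reindex(df.index)
        df = df.dropna(subset=["group"])
    if exclude_filter is not None:
        df = df[exclude_filter(df)]
    rows = []
    groups = df.groupby("group") if grouping is not None else [(label, df)]
    corr = sps.pearsonr if method == "pearson" else sps.spearmanr
    for g, sub in groups:
        row = {"group": g, "n": len(sub), "method": method,
               "r": np.nan, "p": np.nan, "computable": False}
        if len(sub) >= 3 and sub["x"].nunique() > 1 and sub["y"].nunique() > 1:
            res = corr(sub["x"], sub["y"])
            row.update(r=float(res.statistic), p=float(res.pvalue), computable=True)
        rows.append(row)
    out = pd.DataFrame(rows)
    out["adj_p"] = np.nan
    ok = out["computable"].to_numpy()
    if ok.any():
        out.loc[ok, "adj_p"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    return out


def hypermutant_filter(tmb: pd.Series,
                       cutoff: float = DEFAULT_HYPERMUTANT_TMB) -> Callable:
    """Keep-mask factory dropping samples with TMB above ``cutoff``."""
    def _keep(df: pd.DataFrame) -> pd.Series:
        return tmb.reindex(df.index) <= cutoff
    return _keep


def sf_expression_association(tpm: pd.DataFrame, sbi_groups: pd.DataFrame,
                              sf_genes: Sequence[str],
                              alpha: float = 0.05) -> pd.DataFrame:
    """High-vs-low SBI differential expression over a splicing-factor list.

    ``tpm`` is genes x samples.  Per gene: two-sided Wilcoxon rank-sum on
    log2(TPM+1) between high- and low-SBI samples; effect is the
    difference of group means on that scale (log2 fold change); BH across
    the listed genes; ``significant`` flags adj_p < alpha.
    """
    sf_genes = list(sf_genes)
    if not sf_genes:
        return pd.DataFrame(columns=["gene", "effect", "statistic", "p",
                                     "adj_p", "significant"])
    missing = [g for g in sf_genes if g not in tpm.index]
    if missing:
        raise ValueError(f"genes absent from TPM matrix: {missing[:5]}")
    hi = sbi_groups.index[sbi_groups["group"] == "high"]
    lo = sbi_groups.index[sbi_groups["group"] == "low"]
    hi = [s for s in hi if s in tpm.columns]
    lo = [s for s in lo if s in tpm.columns]
    if len(hi) < 3 or len(lo) < 3:
        raise ValueError("each SBI group needs >= 3 samples with expression")
    log = np.log2(tpm.loc[sf_genes] + 1.0)
    rows = []
    for gene in sf_genes:
        a, b = log.loc[gene, hi].to_numpy(), log.loc[gene, lo].to_numpy()
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            stat, p = np.nan, 1.0
        else:
            stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        rows.append({"gene": gene, "effect": float(a.mean() - b.mean()),
                     "statistic": float(stat) if np.isfinite(stat) else np.nan,
                     "p": float(p)})
    out = pd.DataFrame(rows)
    out["adj_p"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant"] = out["adj_p"] < alpha
    return out
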