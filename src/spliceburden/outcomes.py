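"""Outcome modelling: proportional-hazards fits, Kaplan-Meier strata, and
ordered age-group trend tests.

Cox models are fit by partial likelihood with Efron tie handling
(Breslow by flag).  Categorical covariates are expanded against declared
reference levels — cluster 1 and gross/near-total resection by default —
and interactions (e.g. SBI x cluster) are formed as products with the
non-reference dummies.  Histology groups below a minimum size can be
collapsed into a single level before fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

DEFAULT_REFERENCES = {"cluster": "1", "resection": "gross/near total"}


@dataclass
class CoxFit:
    """Hazard ratios with 95% CIs per model term."""

    table: pd.DataFrame  # term, HR, CI_low, CI_high, p, coef, se
    n: int
    n_events: int
    converged: bool
    tie_method: str
    diagnostics: str = ""

    def hr(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "HR"])


def _design_matrix(records: pd.DataFrame, terms: Sequence[str],
                   interactions: Sequence[Tuple[str, str]] = (),
                   references: Optional[Mapping[str, str]] = None,
                   collapse_below: Optional[int] = None,
                   collapse_cols: Sequence[str] = ("histology_group",)) -> pd.DataFrame:
    refs = dict(DEFAULT_REFERENCES)
    if references:
        refs.update(references)
    df = records.copy()
    for col in collapse_cols:
        if collapse_below and col in df.columns and col in terms:
            counts = df[col].value_counts()
            small = counts.index[counts < collapse_below]
            if len(small):
                df[col] = df[col].where(~df[col].isin(small), "Collapsed")
    X = pd.DataFrame(index=df.index)
    dummy_groups: Dict[str, List[str]] = {}
    for term in terms:
        if term not in df.columns:
            raise ValueError(f"unknown covariate {term!r}")
        col = df[term]
        if pd.api.types.is_numeric_dtype(col) and col.nunique() > 2 or \
                pd.api.types.is_float_dtype(col):
            X[term] = col.astype(float)
        elif pd.api.types.is_numeric_dtype(col) and set(col.unique()) <= {0, 1}:
            X[term] = col.astype(float)
        else:
            levels = sorted(col.astype(str).unique())
            if len(levels) < 2:
                raise ValueError(f"factor {term!r} has a single level")
            ref = str(refs.get(term, levels[0]))
            if ref not in levels:
                ref = levels[0]
            cols = []
            for lv in levels:
                if lv == ref:
                    continue
                name = f"{term}[{lv}]"
                X[name] = (col.astype(str) == lv).astype(float)
                cols.append(name)
            dummy_groups[term] = cols
    for a, b in interactions:
        a_cols = dummy_groups.get(a, [a] if a in X.columns else None)
        b_cols = dummy_groups.get(b, [b] if b in X.columns else None)
        if a_cols is None or b_cols is None:
            raise ValueError(f"interaction {a}:{b} references unknown terms")
        for ca in a_cols:
            for cb in b_cols:
                X[f"{ca}:{cb}"] = X[ca] * X[cb]
    return X


def fit_cox(records: pd.DataFrame, terms: Sequence[str],
            interactions: Sequence[Tuple[str, str]] = (),
            time_col: str = "time", status_col: str = "status",
            references: Optional[Mapping[str, str]] = None,
            collapse_below: Optional[int] = None,
            tie_method: str = "efron") -> CoxFit:
    """Fit a proportional-hazards model.

    ``terms`` name covariate columns of ``records``; strings/categories are
    dummy-expanded against their reference level, numeric columns enter
    per unit.  ``interactions`` is a list of term pairs.  Histology groups
    with fewer than ``collapse_below`` samples are merged into a
    'Collapsed' level.  Non-convergence is reported on the fit, not
    silently dropped; complete separation raises naming the term.
    """
    if tie_method not in ("efron", "breslow"):
        raise ValueError(f"unknown tie method {tie_method!r}")
    data = records.dropna(subset=[time_col, status_col])
    if (data[time_col] <= 0).any():
        raise ValueError("survival times must be positive")
    if int(data[status_col].sum()) < 1:
        raise ValueError("need at least one event")
    X = _design_matrix(data, terms, interactions, references, collapse_below)
    fit_df = X.copy()
    fit_df[time_col] = data[time_col].astype(float)
    fit_df[status_col] = data[status_col].astype(int)
    fit_df = fit_df.dropna()
    cph = CoxPHFitter()
    converged, diag = True, ""
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            cph.fit(fit_df, duration_col=time_col, event_col=status_col)
        except ConvergenceError as err:
            msg = str(err)
            if "complete separation" in msg.lower() or "perfect" in msg.lower():
                raise ValueError(f"complete separation in Cox model: {msg}") from err
            converged, diag = False, msg
            # ridge fallback stabilises near-collinear designs; the fit is
            # flagged non-converged either way
            cph = CoxPHFitter(penalizer=0.1)
            cph.fit(fit_df, duration_col=time_col, event_col=status_col,
                    fit_options={"step_size": 0.1})
        for w in caught:
            if "convergence" in str(w.message).lower() or \
                    "collinear" in str(w.message).lower():
                converged = False
                diag = (diag + " " + str(w.message)).strip()
    summary = cph.summary
    table = pd.DataFrame({
        "term": summary.index,
        "coef": summary["coef"].to_numpy(),
        "se": summary["se(coef)"].to_numpy(),
        "HR": summary["exp(coef)"].to_numpy(),
        "CI_low": summary["exp(coef) lower 95%"].to_numpy(),
        "CI_high": summary["exp(coef) upper 95%"].to_numpy(),
        "p": summary["p"].to_numpy(),
    }).reset_index(drop=True)
    return CoxFit(table=table, n=len(fit_df),
                  n_events=int(fit_df[status_col].sum()),
                  converged=converged, tie_method=tie_method,
                  diagnostics=diag)


@dataclass
class KmResult:
    curves: pd.DataFrame  # stratum, time, survival
    logrank_p: float
    threshold: float
    counts: Dict[str, int]


def km_strata(records: pd.DataFrame, score: pd.Series,
              split: Union[str, float] = "median",
              time_col: str = "time", status_col: str = "status") -> KmResult:
    """Kaplan-Meier curves for high vs low halves of a continuous score.

    ``split='median'`` dichotomises at the median (high: score > median);
    a float splits at that value.  Two-sided log-rank test between the
    strata.
    """
    s = score.reindex(records.index).dropna()
    rec = records.loc[s.index]
    thr = float(np.median(s)) if split == "median" else float(split)
    high = s > thr
    if high.all() or (~high).all():
        raise ValueError("all samples fall on one side of the split")
    curves = []
    counts = {}
    for name, mask in (("low", ~high), ("high", high)):
        km = KaplanMeierFitter()
        km.fit(rec.loc[mask, time_col], rec.loc[mask, status_col], label=name)
        sf = km.survival_function_
        curves.append(pd.DataFrame({"stratum": name, "time": sf.index,
                                    "survival": sf[name].to_numpy()}))
        counts[name] = int(mask.sum())
    res = logrank_test(rec.loc[high, time_col], rec.loc[~high, time_col],
                       rec.loc[high, status_col], rec.loc[~high, status_col])
    return KmResult(curves=pd.concat(curves, ignore_index=True),
                    logrank_p=float(res.p_value), threshold=thr, counts=counts)


@dataclass
class AgeTrendResult:
    pairwise: pd.DataFrame  # group_a, group_b, statistic, p, adj_p
    trend_rho: float
    trend_p: float


def age_trend(values: pd.Series, group: pd.Series,
              ordered_groups: Sequence[str]) -> AgeTrendResult:
    """Monotone trend of a quantity across ordered age groups.

    Adjacent group pairs are compared with two-sided Wilcoxon rank-sum
    tests (BH-adjusted); the trend statistic is the Spearman correlation
    between the values and the group rank.  A negative rho with small
    pairwise p-values is the oncofetal signature: high early, declining
    with age.
    """
    groups = list(ordered_groups)
    seen = set(group.dropna().unique())
    if not set(groups) >= seen:
        raise ValueError(f"unordered group labels: {sorted(seen - set(groups))}")
    df = pd.DataFrame({"value": values, "group": group}).dropna()
    by = {g: df.loc[df["group"] == g, "value"].to_numpy() for g in groups}
    for g in groups:
        if len(by[g]) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 values")
    rows = []
    for ga, gb in zip(groups, groups[1:]):
        stat, p = sps.mannwhitneyu(by[ga], by[gb], alternative="two-sided")
        rows.append({"group_a": ga, "group_b": gb, "statistic": float(stat),
                     "p": float(p)})
    pairwise = pd.DataFrame(rows)
    pairwise["adj_p"] = multipletests(pairwise["p"], method="fdr_bh")[1]
    rank = df["group"].map({g: i for i, g in enumerate(groups)})
    rho, p = sps.spearmanr(df["value"], rank)
    return AgeTrendResult(pairwise=pairwise, trend_rho=float(rho),
                          trend_p=float(p))
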