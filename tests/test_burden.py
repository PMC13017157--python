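"""Splicing Burden Index, quartile groups, correlations and the
splicing-factor expression comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from spliceburden.burden import (assign_sbi_groups, compute_sbi,
                                 grouped_correlation, hypermutant_filter,
                                 sf_expression_association)
from spliceburden.differential import call_differential, cohort_event_stats

from conftest import psi_from_array


def _sbi_frame(values):
    return pd.DataFrame({
        "n_differential": 0, "n_evaluable": 1,
        "sbi": values}, index=[f"S{i}" for i in range(len(values))])


class TestComputeSbi:
    def test_division_and_null_burden(self, flat_cohort):
        psi = flat_cohort.psi
        st = cohort_event_stats(psi)
        calls = call_differential(psi, st)
        sbi = compute_sbi(calls, psi, st)
        assert ((sbi["sbi"] >= 0) & (sbi["sbi"] <= 1)).all()
        assert (sbi["n_differential"] <= sbi["n_evaluable"]).all()
        one = sbi.iloc[0]
        assert one["sbi"] == pytest.approx(one["n_differential"]
                                           / one["n_evaluable"])
        # no-call matrix: sbi exactly 0 everywhere
        empty = calls.iloc[0:0]
        assert (compute_sbi(empty, psi, st)["sbi"] == 0).all()

    def test_saturation(self):
        # a 12-event two-sample matrix where every cell is called
        vals = np.column_stack([np.full(12, 0.05), np.full(12, 0.95)])
        vals += np.linspace(0, 0.01, 12)[:, None]
        psi = psi_from_array(vals)
        st = cohort_event_stats(psi, min_cohort_n=2)
        from spliceburden.differential import CohortEventStats
        stats = CohortEventStats(
            mean=pd.Series(0.5, index=psi.psi.index),
            sd=pd.Series(0.05, index=psi.psi.index),
            n=pd.Series(2, index=psi.psi.index),
            evaluable=pd.Series(True, index=psi.psi.index))
        calls = call_differential(psi, stats)
        sbi = compute_sbi(calls, psi, stats)
        assert (sbi["sbi"] == 1.0).all()

    def test_zero_denominator_names_sample(self):
        vals = np.array([[0.5, np.nan]])
        psi = psi_from_array(vals)
        st = cohort_event_stats(psi, min_cohort_n=1)
        # second sample covers nothing evaluable
        st.evaluable.iloc[0] = True
        calls = pd.DataFrame(columns=["sample_id", "event_key"])
        with pytest.raises(ValueError, match="S001"):
            compute_sbi(calls, psi, st)

    def test_adding_sample_leaves_others_unchanged(self, flat_cohort):
        psi = flat_cohort.psi
        st = cohort_event_stats(psi)
        calls = call_differential(psi, st)
        sbi_all = compute_sbi(calls, psi, st)
        sub = psi.psi.columns[:-1]
        from spliceburden.rmats_io import PsiMatrix
        psi_sub = PsiMatrix(events=psi.events, psi=psi.psi[sub],
                            covered=psi.covered[sub], min_reads=psi.min_reads)
        sbi_sub = compute_sbi(calls[calls["sample_id"].isin(sub)], psi_sub, st)
        pd.testing.assert_series_equal(sbi_all.loc[sub, "sbi"],
                                       sbi_sub["sbi"], check_names=False)


class TestQuartileGroups:
    def test_evenly_spaced_eight(self):
        out = assign_sbi_groups(_sbi_frame(
            [0.01, 0.02, 0.03, 0.04, 0.05, 0.06, 0.07, 0.08]))
        assert list(out[out.group == "high"].sbi) == [0.07, 0.08]
        assert list(out[out.group == "low"].sbi) == [0.01, 0.02]

    def test_four_distinct_values(self):
        out = assign_sbi_groups(_sbi_frame([0.01, 0.02, 0.03, 0.04]))
        assert (out.group == "high").sum() == 1
        assert (out.group == "low").sum() == 1

    def test_degenerate_distribution_all_mid(self):
        with pytest.warns(UserWarning, match="degenerate"):
            out = assign_sbi_groups(_sbi_frame([0.02] * 6))
        assert (out.group == "mid").all()

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match=">= 4"):
            assign_sbi_groups(_sbi_frame([0.1, 0.2, 0.3]))

    def test_boundary_ties_included(self):
        out = assign_sbi_groups(_sbi_frame(
            [0.01, 0.01, 0.02, 0.03, 0.05, 0.05, 0.05, 0.06]))
        # Q3 = 0.05: every tied sample is high
        assert (out[out.sbi == 0.05].group == "high").all()


def test_bh_matches_step_up_oracle():
    """statsmodels BH equals a brute-force step-up implementation."""
    def oracle(p):
        p = np.asarray(p, dtype=float)
        n = len(p)
        order = np.argsort(p)
        adj = np.empty(n)
        prev = 1.0
        for rank in range(n, 0, -1):
            i = order[rank - 1]
            prev = min(prev, p[i] * n / rank)
            adj[i] = prev
        return adj

    rng = np.random.default_rng(5)
    for _ in range(100):
        p = rng.uniform(0, 1, size=rng.integers(1, 40))
        np.testing.assert_allclose(multipletests(p, method="fdr_bh")[1],
                                   oracle(p), atol=1e-12)


class TestGroupedCorrelation:
    def test_perfect_linear(self):
        x = pd.Series(np.arange(10.0), index=[f"S{i}" for i in range(10)])
        out = grouped_correlation(x, 2 * x + 1)
        assert out.iloc[0]["r"] == pytest.approx(1.0)

    def test_textbook_five_points(self):
        pts = [(1, 2), (2, 1), (3, 4), (4, 3), (5, 5)]
        x = pd.Series([p[0] for p in pts], dtype=float)
        y = pd.Series([p[1] for p in pts], dtype=float)
        xm, ym = x - x.mean(), y - y.mean()
        expected = (xm * ym).sum() / np.sqrt((xm ** 2).sum() * (ym ** 2).sum())
        out = grouped_correlation(x, y)
        assert out.iloc[0]["r"] == pytest.approx(expected, abs=1e-12)

    def test_independent_null(self):
        rng = np.random.default_rng(9)
        hits = 0
        for _ in range(20):
            x = pd.Series(rng.normal(0, 1, 1000))
            y = pd.Series(rng.permutation(x.to_numpy()), index=x.index)
            row = grouped_correlation(x, y).iloc[0]
            hits += abs(row["r"]) < 0.1 and row["p"] > 0.01
        assert hits >= 19

    def test_grouping_and_exclusion(self):
        idx = [f"S{i}" for i in range(40)]
        rng = np.random.default_rng(3)
        x = pd.Series(rng.normal(0, 1, 40), index=idx)
        y = x + rng.normal(0, 0.1, 40)
        g = pd.Series(["a"] * 20 + ["b"] * 20, index=idx)
        out = grouped_correlation(x, y, grouping=g)
        assert set(out["group"]) == {"a", "b"}
        assert (out["r"] > 0.9).all()
        tmb = pd.Series(np.where(np.arange(40) < 5, 50.0, 1.0), index=idx)
        out2 = grouped_correlation(x, y,
                                   exclude_filter=hypermutant_filter(tmb))
        assert out2.iloc[0]["n"] == 35

    def test_zero_variance_flagged(self):
        x = pd.Series([1.0, 1.0, 1.0, 1.0])
        y = pd.Series([1.0, 2.0, 3.0, 4.0])
        out = grouped_correlation(x, y)
        assert not out.iloc[0]["computable"]


class TestSfAssociation:
    def _groups(self, n_per=200):
        idx = [f"S{i}" for i in range(2 * n_per)]
        return pd.DataFrame(
            {"sbi": 0.0, "group": ["high"] * n_per + ["low"] * n_per},
            index=pd.Index(idx, name="sample_id"))

    def test_null_gene_not_significant(self):
        rng = np.random.default_rng(21)
        groups = self._groups()
        tpm = pd.DataFrame({s: [float(rng.lognormal(3, 0.5))]
                            for s in groups.index}, index=["SF1"])
        out = sf_expression_association(tpm, groups, ["SF1"])
        assert not out.iloc[0]["significant"]

    def test_fourfold_shift_detected(self):
        rng = np.random.default_rng(22)
        groups = self._groups()
        hi = groups.index[groups.group == "high"]
        expr = pd.Series(rng.lognormal(np.log(20), 0.05, len(groups)),
                         index=groups.index)
        expr.loc[hi] *= 4.0
        tpm = pd.DataFrame([expr.to_numpy()], index=["SF1"],
                           columns=groups.index)
        out = sf_expression_association(tpm, groups, ["SF1"])
        assert out.iloc[0]["significant"]
        assert out.iloc[0]["effect"] == pytest.approx(2.0, abs=0.2)

    def test_empty_gene_list(self):
        out = sf_expression_association(pd.DataFrame(), self._groups(5), [])
        assert len(out) == 0

    def test_bh_monotone_in_rank(self, flat_cohort):
        c = flat_cohort
        st = cohort_event_stats(c.psi)
        calls = call_differential(c.psi, st)
        sbi = assign_sbi_groups(compute_sbi(calls, c.psi, st))
        out = sf_expression_association(c.tpm, sbi, c.sf_genes)
        out = out.sort_values("p")
        assert (out["adj_p"] >= out["p"] - 1e-15).all()
        assert out["adj_p"].is_monotonic_increasing

    def test_planted_burden_coupling_recovered(self, flat_cohort):
        """SF genes coupled to the planted burden come out significant."""
        c = flat_cohort
        st = cohort_event_stats(c.psi)
        calls = call_differential(c.psi, st)
        sbi = assign_sbi_groups(compute_sbi(calls, c.psi, st))
        out = sf_expression_association(c.tpm, sbi, c.sf_genes)
        assert out["significant"].mean() > 0.8


def test_sbi_ranking_recovers_planted_burden(flat_cohort):
    from scipy.stats import spearmanr

    c = flat_cohort
    st = cohort_event_stats(c.psi)
    calls = call_differential(c.psi, st)
    sbi = compute_sbi(calls, c.psi, st)
    rho = spearmanr(sbi["sbi"],
                    c.truth.sample_planted_fraction.loc[sbi.index]).statistic
    assert rho >= 0.9
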