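"""Variable-event selection, hierarchical clustering, Fisher enrichment,
marker scores and PSI variance partitioning."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn.metrics import adjusted_rand_score

from spliceburden.clustering import (celltype_scores, cluster_enrichment,
                                     cluster_samples, psi_variance_explained,
                                     top_variable_events)
from spliceburden.rmats_io import PsiMatrix

from conftest import psi_from_array


class TestTopVariableEvents:
    def test_constant_event_ranks_last(self):
        vals = np.vstack([np.full(8, 0.5),
                          np.linspace(0.1, 0.9, 8)])
        psi = psi_from_array(vals, events=["const", "varying"])
        assert top_variable_events(psi, k=1) == ["varying"]

    def test_clamp_when_k_exceeds_eligible(self):
        psi = psi_from_array(np.random.default_rng(0).uniform(0, 1, (5, 8)))
        with pytest.warns(UserWarning, match="eligible"):
            out = top_variable_events(psi, k=50)
        assert len(out) == 5

    def test_tie_break_by_event_key(self):
        col = np.array([0.2, 0.4, 0.6, 0.8])
        psi = psi_from_array(np.vstack([col, col, col]),
                             events=["b_ev", "a_ev", "c_ev"])
        assert top_variable_events(psi, k=2) == ["a_ev", "b_ev"]

    def test_coverage_filter(self):
        vals = np.vstack([np.linspace(0, 1, 8), np.linspace(0, 1, 8)])
        vals[1, :4] = np.nan  # 50% coverage: ineligible at 0.75
        psi = psi_from_array(vals, events=["full", "half"])
        with pytest.warns(UserWarning):
            assert top_variable_events(psi, k=2) == ["full"]


def _two_block_psi(rng, n_per=20, n_events=60, sep=0.5, sd=0.05):
    means = np.where(rng.random(n_events) < 0.5, 0.25, 0.25 + sep)
    a = np.clip(means[:, None] + rng.normal(0, sd, (n_events, n_per)), 0, 1)
    b = np.clip((0.75 - means)[:, None] + rng.normal(0, sd, (n_events, n_per)),
                0, 1)
    return psi_from_array(np.hstack([a, b])), \
        np.array([0] * n_per + [1] * n_per)


class TestClusterSamples:
    def test_two_planted_blocks_recovered(self):
        rng = np.random.default_rng(4)
        psi, truth = _two_block_psi(rng)
        res = cluster_samples(psi, k=2)
        labels = res.assignments.loc[psi.psi.columns]
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(5)
        psi, _ = _two_block_psi(rng)
        res1 = cluster_samples(psi, k=2)
        perm = list(reversed(psi.psi.columns))
        psi2 = PsiMatrix(events=psi.events, psi=psi.psi[perm],
                         covered=psi.covered[perm])
        res2 = cluster_samples(psi2, k=2)
        a = res1.assignments.sort_index()
        b = res2.assignments.sort_index()
        assert adjusted_rand_score(a, b) == 1.0

    def test_duplicate_sample_joins_same_cluster(self):
        rng = np.random.default_rng(6)
        psi, _ = _two_block_psi(rng)
        dup = psi.psi.copy()
        dup["dup_of_first"] = dup[dup.columns[0]]
        cov = psi.covered.copy()
        cov["dup_of_first"] = cov[cov.columns[0]]
        psi2 = PsiMatrix(events=psi.events, psi=dup, covered=cov)
        res = cluster_samples(psi2, k=2)
        assert res.assignments["dup_of_first"] == \
            res.assignments[dup.columns[0]]

    def test_bad_k_rejected(self):
        psi, _ = _two_block_psi(np.random.default_rng(7), n_per=3)
        with pytest.raises(ValueError, match="out of range"):
            cluster_samples(psi, k=1)
        with pytest.raises(ValueError, match="out of range"):
            cluster_samples(psi, k=7)


def fisher_two_sided_oracle(a, b, c, d):
    """Exhaustive hypergeometric enumeration in exact integer arithmetic."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    weights = {k: comb(r1, k) * comb(n - r1, c1 - k) for k in range(lo, hi + 1)}
    denom = comb(n, c1)
    w_obs = weights[a]
    return sum(w for w in weights.values() if w <= w_obs) / denom


class TestEnrichment:
    def test_fisher_matches_enumeration_small_tables(self):
        rng = np.random.default_rng(8)
        for _ in range(300):
            n = int(rng.integers(2, 21))
            a = int(rng.integers(0, n + 1))
            b = int(rng.integers(0, n + 1 - a))
            c = int(rng.integers(0, n + 1 - a - b))
            d = n - a - b - c
            _, p = sps.fisher_exact([[a, b], [c, d]])
            assert p == pytest.approx(fisher_two_sided_oracle(a, b, c, d),
                                      rel=1e-9, abs=1e-12)

    def test_or_and_p_on_known_table(self):
        # a=8 b=2 c=4 d=86: OR = 8*86/(2*4) = 86
        samples = [f"S{i}" for i in range(100)]
        cl = pd.Series(["c1"] * 10 + ["c2"] * 90, index=samples)
        lab = pd.Series(["epn"] * 8 + ["other"] * 2 + ["epn"] * 4
                        + ["other"] * 86, index=samples)
        out = cluster_enrichment(cl, lab)
        row = out[(out.cluster == "c1") & (out.label == "epn")].iloc[0]
        assert row["odds_ratio"] == pytest.approx(86.0)
        assert not row["haldane_corrected"]
        assert row["p"] == pytest.approx(fisher_two_sided_oracle(8, 2, 4, 86),
                                         rel=1e-9)

    def test_perfect_overlap_uses_haldane(self):
        samples = [f"S{i}" for i in range(30)]
        cl = pd.Series(["c1"] * 10 + ["c2"] * 20, index=samples)
        lab = pd.Series(["x"] * 10 + ["y"] * 20, index=samples)
        out = cluster_enrichment(cl, lab)
        row = out[(out.cluster == "c1") & (out.label == "x")].iloc[0]
        assert row["raw_or_infinite"]
        assert row["haldane_corrected"]
        expected = (10.5 * 20.5) / (0.5 * 0.5)
        assert row["odds_ratio"] == pytest.approx(expected)

    def test_independent_label_near_null(self):
        samples = [f"S{i}" for i in range(80)]
        cl = pd.Series((["c1"] * 20 + ["c2"] * 20) * 2, index=samples)
        lab = pd.Series(["x", "y"] * 40, index=samples)
        out = cluster_enrichment(cl, lab)
        assert (out["p"] > 0.5).all()

    def test_missing_labels_rejected(self):
        cl = pd.Series([1, 2], index=["a", "b"])
        lab = pd.Series(["x"], index=["a"])
        with pytest.raises(ValueError, match="without labels"):
            cluster_enrichment(cl, lab)


class TestCelltypeScores:
    def _tpm(self, rows):
        return pd.DataFrame.from_dict(rows, orient="index",
                                      columns=[f"S{i}" for i in range(6)])

    def test_single_marker_reduces_to_zscore(self):
        tpm = self._tpm({"m1": [1.0, 2, 4, 8, 16, 32]})
        scores = celltype_scores(tpm, {"typeA": ["m1"]})
        log = np.log2(tpm.loc["m1"] + 1)
        expected = (log - log.mean()) / log.std(ddof=1)
        np.testing.assert_allclose(scores["typeA"], expected)

    def test_constant_marker_error(self):
        tpm = self._tpm({"m1": [5.0] * 6})
        with pytest.raises(ValueError, match="no usable"):
            celltype_scores(tpm, {"typeA": ["m1"]})

    def test_missing_marker_warns_and_drops(self):
        tpm = self._tpm({"m1": [1.0, 2, 4, 8, 16, 32]})
        with pytest.warns(UserWarning, match="missing"):
            scores = celltype_scores(tpm, {"typeA": ["m1", "absent"]})
        assert scores.shape == (6, 1)

    def test_scores_track_planted_fractions(self, cohort150):
        c = cohort150
        scores = celltype_scores(c.tpm, c.marker_sets)
        for ctype in c.marker_sets:
            r = np.corrcoef(scores[ctype],
                            c.truth.cell_fractions[ctype])[0, 1]
            assert r >= 0.9, ctype


class TestVarianceExplained:
    def test_perfect_linear_r2_one(self):
        rng = np.random.default_rng(10)
        scores = pd.DataFrame(rng.normal(0, 1, (30, 2)),
                              index=[f"S{i:03d}" for i in range(30)],
                              columns=["t1", "t2"])
        y = 0.3 + 0.1 * scores["t1"].to_numpy()
        psi = psi_from_array(y[None, :], samples=list(scores.index))
        out = psi_variance_explained(psi, scores)
        assert out.iloc[0]["r_squared"] == pytest.approx(1.0, abs=1e-10)

    def test_constant_psi_skipped(self):
        scores = pd.DataFrame(np.random.default_rng(0).normal(0, 1, (20, 2)),
                              index=[f"S{i:03d}" for i in range(20)])
        psi = psi_from_array(np.full((1, 20), 0.4),
                             samples=list(scores.index))
        assert len(psi_variance_explained(psi, scores)) == 0

    def test_r2_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            n, p = int(rng.integers(10, 40)), int(rng.integers(1, 5))
            X = rng.normal(0, 1, (n, p))
            y = rng.uniform(0, 1, n)
            scores = pd.DataFrame(X, index=[f"S{i:03d}" for i in range(n)])
            psi = psi_from_array(y[None, :], samples=list(scores.index))
            out = psi_variance_explained(psi, scores)
            Xd = np.column_stack([np.ones(n), X])
            beta = np.linalg.solve(Xd.T @ Xd, Xd.T @ y)
            resid = y - Xd @ beta
            r2 = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
            assert out.iloc[0]["r_squared"] == pytest.approx(r2, abs=1e-8)

    def test_null_mean_matches_analytic_expectation(self):
        rng = np.random.default_rng(13)
        n, p, n_events = 200, 6, 300
        scores = pd.DataFrame(rng.normal(0, 1, (n, p)),
                              index=[f"S{i:03d}" for i in range(n)])
        psi = psi_from_array(rng.uniform(0, 1, (n_events, n)),
                             samples=list(scores.index))
        out = psi_variance_explained(psi, scores)
        expected = p / (n - 1)
        se = out["r_squared"].std(ddof=1) / np.sqrt(len(out))
        assert abs(out["r_squared"].mean() - expected) < 2 * se
        assert (out["bin"] == "<30%").all()

    def test_bin_edges_left_closed(self):
        assert_bin = lambda r2, b: b == (
            "<30%" if r2 < 0.30 else ("30-50%" if r2 <= 0.50 else ">50%"))
        rng = np.random.default_rng(14)
        scores = pd.DataFrame(rng.normal(0, 1, (50, 1)),
                              index=[f"S{i:03d}" for i in range(50)])
        for frac in (0.1, 0.3, 0.45, 0.5, 0.7):
            sig = scores.iloc[:, 0].to_numpy()
            noise = rng.normal(0, 1, 50)
            y = np.sqrt(frac) * (sig - sig.mean()) / sig.std()
            y = y + np.sqrt(1 - frac) * (noise - noise.mean()) / noise.std()
            psi = psi_from_array(((y - y.min()) / (np.ptp(y) + 1e-9))[None, :],
                                 samples=list(scores.index))
            out = psi_variance_explained(psi, scores)
            assert assert_bin(out.iloc[0]["r_squared"], out.iloc[0]["bin"])
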