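"""Genomic-to-protein projection, feature-impact rules, and the
prioritization cascade."""

import numpy as np
import pandas as pd
import pytest

from spliceburden.annotation import (AnnotationError, TranscriptModel,
                                     genomic_to_protein, read_gtf, write_gtf)
from spliceburden.differential import call_differential, cohort_event_stats, \
    recurrence
from spliceburden.prioritize import (CascadeConfig, affected_features,
                                     run_cascade)


def toy_model(strand="+", exons=((100, 106), (206, 212)),
              cds_span=None, tid="T1", gene="G"):
    exons = [tuple(e) for e in exons]
    cds_span = cds_span or (exons[0][0], exons[-1][1])
    return TranscriptModel(transcript_id=tid, gene_symbol=gene, chrom="chr1",
                           strand=strand, exons=exons, cds_span=cds_span)


class TestModelInvariants:
    def test_overlapping_exons_rejected(self):
        with pytest.raises(AnnotationError, match="overlap"):
            toy_model(exons=((100, 110), (105, 120)))

    def test_frame_violation_rejected(self):
        with pytest.raises(AnnotationError, match="multiple of 3"):
            toy_model(exons=((100, 104), (206, 212)))

    def test_cds_outside_exons_rejected(self):
        with pytest.raises(AnnotationError, match="exon union"):
            toy_model(cds_span=(90, 212))


class TestGenomicToProtein:
    def test_first_codon(self):
        m = toy_model()
        assert genomic_to_protein((100, 103), m) == (1, 1)

    def test_junction_straddling_plus_strand(self):
        # exon1 carries CDS bases 1..6, exon2 bases 7..12; genomic span of
        # CDS bases 4..9 is [103,106) u [206,209)
        m = toy_model()
        assert genomic_to_protein((103, 209), m) == (2, 3)

    def test_junction_straddling_minus_strand(self):
        # mirror geometry: on '-' the CDS reads right-to-left
        m = toy_model(strand="-")
        # CDS bases 4..9 now live at [206,209) (bases 4..6) u [103,106)
        assert genomic_to_protein((103, 209), m) == (2, 3)

    def test_no_cds_intersection(self):
        m = toy_model()
        assert genomic_to_protein((150, 200), m) is None  # intronic

    def test_utr_clipped(self):
        # 5' UTR at [100,104): CDS = [104,110) u [200,209), 15 bases
        m = toy_model(exons=((100, 110), (200, 212)), cds_span=(104, 209))
        assert genomic_to_protein((100, 105), m) == (1, 1)

    def test_matches_per_base_enumeration_oracle(self):
        """200 random toy transcripts, both strands, queries straddling
        junctions and UTRs."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            n_exons = int(rng.integers(1, 9))
            pos = int(rng.integers(0, 1000))
            exons = []
            for _ in range(n_exons):
                length = int(rng.integers(3, 60))
                exons.append((pos, pos + length))
                pos += length + int(rng.integers(10, 80))
            strand = "+" if rng.random() < 0.5 else "-"
            span_lo, span_hi = exons[0][0], exons[-1][1]
            # random CDS start inside the span, then trim the tail so the
            # CDS length is a multiple of 3
            lo = int(rng.integers(span_lo, max(span_lo + 1, span_hi - 3)))
            cds_bases = [b for s, e in exons for b in range(s, e) if b >= lo]
            cds_bases = cds_bases[: 3 * (len(cds_bases) // 3)]
            if not cds_bases:
                continue
            cds_span = (cds_bases[0], cds_bases[-1] + 1)
            try:
                m = toy_model(strand=strand, exons=exons, cds_span=cds_span)
            except AnnotationError:
                continue  # degenerate trim; skip
            coding = [b for s, e in m.cds_segments for b in range(s, e)]
            if strand == "-":
                coding = coding[::-1]
            index_of = {b: i for i, b in enumerate(coding)}
            for _ in range(5):
                qs = int(rng.integers(span_lo - 20, span_hi + 10))
                qe = qs + int(rng.integers(1, 80))
                hits = [index_of[b] for b in range(qs, qe) if b in index_of]
                expected = (min(hits) // 3 + 1, max(hits) // 3 + 1) \
                    if hits else None
                assert genomic_to_protein((qs, qe), m) == expected


class TestFeatureImpacts:
    def _inputs(self, feature_rows, direction="skipping"):
        m = toy_model(exons=((0, 90), (190, 280), (380, 470)),
                      gene="KIN1")
        key = "SE|chr1|+|190:280:0:90:380:470"
        events_meta = pd.DataFrame({
            "event_type": ["SE"], "gene_symbol": ["KIN1"], "chrom": ["chr1"],
            "strand": ["+"], "variable_start": [190], "variable_end": [280],
        }, index=pd.Index([key], name="event_key"))
        recurrent = pd.DataFrame({
            "n_samples_called": [12], "n_inclusion": [0], "n_skipping": [12],
            "direction_class": [direction], "mean_abs_dpsi": [0.35],
        }, index=events_meta.index)
        features = pd.DataFrame(feature_rows,
                                columns=["gene", "transcript", "feature_type",
                                         "aa_start", "aa_end"])
        features["feature_id"] = [f"f{i}" for i in range(len(features))]
        return recurrent, events_meta, [m], features

    def test_domain_overlap_gives_loss_for_skipping(self):
        # exon 2 spans CDS bases 91..180 -> aa 31..60
        rec, meta, models, feats = self._inputs(
            [("KIN1", None, "domain", 10, 50)])
        imp = affected_features(rec, meta, models, feats)
        assert len(imp) == 1
        assert imp.iloc[0]["predicted"] == "loss"
        assert imp.iloc[0]["overlap_aa_start"] == 31
        assert imp.iloc[0]["overlap_aa_end"] == 50

    def test_disjoint_feature_no_impact(self):
        rec, meta, models, feats = self._inputs(
            [("KIN1", None, "domain", 80, 90)])
        assert len(affected_features(rec, meta, models, feats)) == 0

    def test_disulfide_bond_endpoint_rule(self):
        # projection aa 31..60; bond 12-80: neither endpoint inside -> no
        # impact even though the span 12..80 crosses the projection
        rec, meta, models, feats = self._inputs(
            [("KIN1", None, "disulfide_bond", 12, 80)], direction="inclusion")
        assert len(affected_features(rec, meta, models, feats)) == 0
        rec, meta, models, feats = self._inputs(
            [("KIN1", None, "disulfide_bond", 40, 80)], direction="inclusion")
        imp = affected_features(rec, meta, models, feats)
        assert len(imp) == 1 and imp.iloc[0]["predicted"] == "gain"


@pytest.fixture(scope="module")
def cascade_result(cohort150):
    c = cohort150
    st = cohort_event_stats(c.psi)
    calls = call_differential(c.psi, st)
    rec = recurrence(calls)
    imp = affected_features(rec, c.psi.events, c.models, c.features)
    cfg = CascadeConfig(kinase_genes=c.kinase_genes,
                        splicing_kinase_genes=c.splicing_kinase_genes)
    table = run_cascade(rec, c.psi.events, imp, c.tpm, cfg, models=c.models)
    return c, rec, imp, table


class TestCascade:
    def test_candidates_equal_planted_truth(self, cascade_result):
        c, _, _, table = cascade_result
        assert sorted(table.candidates["event_key"]) == \
            sorted(c.truth.candidate_event_keys)

    def test_survivor_counts_monotone(self, cascade_result):
        _, _, _, table = cascade_result
        counts = table.stages["n_surviving"].to_numpy()
        assert (np.diff(counts) <= 0).all()

    def test_decoys_drop_at_designed_stages(self, cascade_result):
        c, _, _, table = cascade_result
        expected_stage = {
            "decoy_no_feature": "feature_impact",
            "decoy_non_kinase": "kinase",
            "decoy_kinase_only": "splicing_kinase",
            "decoy_low_tpm": "expression",
            "decoy_low_recurrence": "recurrence",
            "decoy_ri": "ri_exclusion",
            "decoy_ri_like": "ri_exclusion",
        }
        drop = table.drop_log.set_index("event_key")["stage"]
        for row in c.truth.special_events.itertuples():
            if row.role == "candidate":
                continue
            assert drop.loc[row.event_key] == expected_stage[row.role], row.role

    def test_event_order_invariance(self, cascade_result):
        c, rec, imp, table = cascade_result
        cfg = CascadeConfig(kinase_genes=c.kinase_genes,
                            splicing_kinase_genes=c.splicing_kinase_genes)
        shuffled = rec.sample(frac=1.0, random_state=1)
        table2 = run_cascade(shuffled, c.psi.events, imp, c.tpm, cfg,
                             models=c.models)
        assert list(table2.candidates["event_key"]) == \
            list(table.candidates["event_key"])
        pd.testing.assert_frame_equal(table.stages, table2.stages)

    def test_empty_kinase_list_rejected(self, cascade_result):
        c, rec, imp, _ = cascade_result
        with pytest.raises(ValueError, match="kinase"):
            run_cascade(rec, c.psi.events, imp, c.tpm,
                        CascadeConfig(kinase_genes=[]))


def test_gtf_roundtrip(tmp_path, cohort150):
    models = cohort150.models
    path = tmp_path / "toy.gtf"
    write_gtf(models, path)
    back = read_gtf(path)
    assert len(back) == len(models)
    orig = {m.transcript_id: m for m in models}
    for m in back:
        o = orig[m.transcript_id]
        assert m.exons == o.exons
        assert m.cds_segments == o.cds_segments
        assert m.strand == o.strand
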