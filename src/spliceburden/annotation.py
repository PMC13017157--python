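"""Transcript models, protein features, and genomic-to-protein projection.

The projection is the geometric core of functional prioritization: a
genomic interval (e.g. a skipped exon) is intersected with a transcript's
coding sequence, the intersection is read off in spliced-CDS coordinates
(strand-aware, minus-strand transcripts read right-to-left), and the
covered coding offsets are floored to codons to give a 1-based inclusive
amino-acid interval.  All genomic intervals are half-open [start, end)
with 0-based starts, matching the splice-event convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import pandas as pd

FEATURE_TYPES = ("domain", "disulfide_bond", "localization_signal",
                 "modified_residue")


class AnnotationError(ValueError):
    """Malformed transcript model or feature table."""


@dataclass
class TranscriptModel:
    """Exon/CDS geometry of one transcript.

    ``exons`` are non-overlapping half-open genomic intervals sorted by
    genomic position; ``cds_span`` is the genomic extent of translation.
    The spliced CDS length must be a multiple of 3.
    """

    transcript_id: str
    gene_symbol: str
    chrom: str
    strand: str
    exons: List[Tuple[int, int]]
    cds_span: Tuple[int, int]
    _cds_segments: List[Tuple[int, int]] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.transcript_id}: bad strand")
        ex = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if e1 > s2:
                raise AnnotationError(f"{self.transcript_id}: overlapping exons")
        for s, e in ex:
            if s >= e:
                raise AnnotationError(f"{self.transcript_id}: empty exon")
        self.exons = ex
        cs, ce = self.cds_span
        if cs >= ce:
            raise AnnotationError(f"{self.transcript_id}: empty CDS span")
        segs = []
        for s, e in ex:
            os_, oe = max(s, cs), min(e, ce)
            if os_ < oe:
                segs.append((os_, oe))
        if not segs or segs[0][0] != cs or segs[-1][1] != ce:
            raise AnnotationError(
                f"{self.transcript_id}: cds_span not within exon union")
        self._cds_segments = segs
        if self.cds_length % 3 != 0:
            raise AnnotationError(
                f"{self.transcript_id}: CDS length {self.cds_length} not a multiple of 3")

    @property
    def cds_segments(self) -> List[Tuple[int, int]]:
        """Genomic CDS pieces (exon ∩ CDS span), in genomic order."""
        return list(self._cds_segments)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self._cds_segments)

    @property
    def protein_length(self) -> int:
        return self.cds_length // 3

    @property
    def introns(self) -> List[Tuple[int, int]]:
        return [(e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])]

    def coding_offset(self, pos: int) -> Optional[int]:
        """0-based spliced-CDS offset of genomic base ``pos`` (or None)."""
        segs = self._cds_segments
        before = 0
        order = segs if self.strand == "+" else list(reversed(segs))
        for s, e in order:
            if s <= pos < e:
                return before + (pos - s if self.strand == "+" else e - 1 - pos)
            before += e - s
        return None


def genomic_to_protein(interval: Tuple[int, int],
                       model: TranscriptModel) -> Optional[Tuple[int, int]]:
    """Project a genomic interval onto the transcript's protein.

    Returns the 1-based inclusive amino-acid interval covered by the
    intersection of ``interval`` with the CDS, or None when the
    intersection is empty.  aa = floor(coding_offset / 3) + 1, so partial
    codons count as touched.
    """
    qs, qe = interval
    if qs >= qe:
        raise AnnotationError(f"empty query interval [{qs}, {qe})")
    offsets: List[int] = []
    before = 0
    segs = model._cds_segments
    order = segs if model.strand == "+" else list(reversed(segs))
    for s, e in order:
        os_, oe = max(s, qs), min(e, qe)
        if os_ < oe:
            if model.strand == "+":
                offsets.append(before + (os_ - s))
                offsets.append(before + (oe - 1 - s))
            else:
                offsets.append(before + (e - oe))
                offsets.append(before + (e - 1 - os_))
        before += e - s
    if not offsets:
        return None
    return (min(offsets) // 3 + 1, max(offsets) // 3 + 1)


def read_gtf(path: Union[str, Path]) -> List[TranscriptModel]:
    """Load transcript models from a GTF with explicit transcript/exon/CDS
    records."""
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True,
                            disable_infer_genes=True,
                            disable_infer_transcripts=True)
    models = []
    for tx in db.features_of_type("transcript"):
        exons = [(f.start - 1, f.end) for f in
                 db.children(tx, featuretype="exon")]
        cds = [(f.start - 1, f.end) for f in db.children(tx, featuretype="CDS")]
        if not exons or not cds:
            continue
        cds_span = (min(s for s, _ in cds), max(e for _, e in cds))
        gene = tx.attributes.get("gene_name", tx.attributes.get("gene_id", ["?"]))[0]
        models.append(TranscriptModel(
            transcript_id=tx.id, gene_symbol=gene, chrom=tx.seqid,
            strand=tx.strand, exons=sorted(exons), cds_span=cds_span))
    return models


def write_gtf(models: Sequence[TranscriptModel], path: Union[str, Path],
              source: str = "spliceburden") -> None:
    """Serialise transcript models as GTF (gene/transcript/exon/CDS rows)."""
    lines = []
    by_gene: Dict[str, List[TranscriptModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_symbol, []).append(m)
    for gene in by_gene:
        txs = by_gene[gene]
        g_start = min(m.exons[0][0] for m in txs)
        g_end = max(m.exons[-1][1] for m in txs)
        chrom, strand = txs[0].chrom, txs[0].strand
        attrs = f'gene_id "{gene}"; gene_name "{gene}";'
        lines.append(f"{chrom}\t{source}\tgene\t{g_start + 1}\t{g_end}\t.\t{strand}\t.\t{attrs}")
        for m in txs:
            tattrs = f'gene_id "{gene}"; transcript_id "{m.transcript_id}"; gene_name "{gene}";'
            lines.append(f"{chrom}\t{source}\ttranscript\t{m.exons[0][0] + 1}\t"
                         f"{m.exons[-1][1]}\t.\t{strand}\t.\t{tattrs}")
            for s, e in m.exons:
                lines.append(f"{chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t{tattrs}")
            for s, e in m.cds_segments:
                lines.append(f"{chrom}\t{source}\tCDS\t{s + 1}\t{e}\t.\t{strand}\t0\t{tattrs}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_features(path: Union[str, Path]) -> pd.DataFrame:
    """Protein-feature table: gene, transcript (optional), feature_type,
    aa_start, aa_end (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "feature_type", "aa_start", "aa_end"}
    missing = required - set(df.columns)
    if missing:
        raise AnnotationError(f"feature table missing columns: {sorted(missing)}")
    bad = ~df["feature_type"].isin(FEATURE_TYPES)
    if bad.any():
        raise AnnotationError(
            f"unknown feature types: {sorted(df.loc[bad, 'feature_type'].unique())}")
    if ((df["aa_start"] < 1) | (df["aa_start"] > df["aa_end"])).any():
        raise AnnotationError("feature aa interval violates 1 <= start <= end")
    if "feature_id" not in df.columns:
        df = df.copy()
        df["feature_id"] = [f"{r.gene}:{r.feature_type}:{r.aa_start}-{r.aa_end}"
                            for r in df.itertuples()]
    return df
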