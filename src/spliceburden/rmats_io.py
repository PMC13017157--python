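"""Reading, writing and assembling rMATS-style per-sample event tables.

One sample's splicing output is a set of ``<TYPE>.MATS.JC.txt`` TSVs, one
per event class (SE, A5SS, A3SS, RI, MXE), each row carrying the event
coordinates plus inclusion/skipping junction counts (IJC/SJC) and the
effective form lengths used for length normalisation.  This module turns
a cohort of such tables into a :class:`PsiMatrix`: events x samples PSI
with a coverage mask implementing the minimum junction-read filter.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .events import (
    COORD_COLUMNS,
    COUNT_COLUMNS,
    EVENT_TYPES,
    EventError,
    make_event_key,
)

#: Default minimum total junction reads (IJC + SJC) for a PSI value to count
#: as observed in a sample.
DEFAULT_MIN_READS = 10

_META_COLUMNS = ("ID", "GeneID", "geneSymbol", "chr", "strand")


class RmatsParseError(ValueError):
    """Raised when an rMATS-style table violates the dialect."""


def compute_psi(ijc, sjc, inc_form_len, skip_form_len):
    """Length-normalised percent-spliced-in.

    PSI = (IJC / L_inc) / (IJC / L_inc + SJC / L_skip), the rMATS
    definition: junction counts are scaled by the number of read positions
    supporting each form before taking the inclusion fraction.

    Accepts scalars or aligned numpy arrays.  Cells with IJC = SJC = 0 have
    undefined PSI and come back as NaN; scalar input with zero total raises
    instead, since a caller passing a single cell can check first.
    """
    ijc = np.asarray(ijc, dtype=float)
    sjc = np.asarray(sjc, dtype=float)
    li = np.asarray(inc_form_len, dtype=float)
    ls = np.asarray(skip_form_len, dtype=float)
    if np.any(li < 1) or np.any(ls < 1):
        raise EventError("form lengths must be >= 1")
    inc = ijc / li
    skip = sjc / ls
    total = inc + skip
    scalar = total.ndim == 0
    if scalar:
        if total == 0:
            raise EventError("PSI undefined: ijc = sjc = 0")
        return float(inc / total)
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(total > 0, inc / np.where(total > 0, total, 1.0), np.nan)
    return psi


def read_sample_events(path: Union[str, Path], event_type: str) -> pd.DataFrame:
    """Read one sample's event table for one event class.

    Returns a DataFrame indexed by ``event_key`` with the dialect's meta,
    coordinate and count columns.  Missing required columns and malformed
    coordinates raise :class:`RmatsParseError` naming the column or line.
    """
    if event_type not in EVENT_TYPES:
        raise RmatsParseError(f"unknown event type {event_type!r}")
    df = pd.read_csv(path, sep="\t", dtype={"chr": str})
    required = list(_META_COLUMNS) + list(COORD_COLUMNS[event_type]) + list(COUNT_COLUMNS)
    for col in required:
        if col not in df.columns:
            raise RmatsParseError(f"{path}: missing required column {col!r}")
    coord_cols = list(COORD_COLUMNS[event_type])
    for col in coord_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
        # fallthrough below raises with the first bad line
        if bad.any():
            raise RmatsParseError(f"{path}: malformed coordinate in {col!r} at line {line}")
        df[col] = vals.astype(np.int64)
    starts = df[coord_cols[::2]].to_numpy()
    ends = df[coord_cols[1::2]].to_numpy()
    bad_rows = (starts >= ends).any(axis=1) | (starts < 0).any(axis=1)
    if bad_rows.any():
        line = int(np.flatnonzero(bad_rows)[0]) + 2
        raise RmatsParseError(
            f"{path}: interval end <= start at line {line}")
    bad_strand = ~df["strand"].isin(["+", "-"])
    if bad_strand.any():
        line = int(np.flatnonzero(bad_strand.to_numpy())[0]) + 2
        raise RmatsParseError(f"{path}: bad strand at line {line}")
    keys = [
        make_event_key(event_type, c, s, tuple(row))
        for c, s, row in zip(df["chr"], df["strand"], df[coord_cols].to_numpy())
    ]
    out = df[required].copy()
    if "IncLevel1" in df.columns:
        out["IncLevel1"] = pd.to_numeric(df["IncLevel1"], errors="coerce")
    out.insert(0, "event_type", event_type)
    out.index = pd.Index(keys, name="event_key")
    return out


def write_sample_events(table: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a per-sample event table back to the rMATS dialect.

    Output is byte-stable: fixed column order, tab separation, and
    ``IncLevel1`` rendered with 6 decimals (``NA`` when missing).
    """
    if len(table) == 0 and "event_type" not in table.columns:
        raise RmatsParseError("cannot infer event type from empty untyped table")
    event_type = table["event_type"].iloc[0] if len(table) else None
    cols = list(_META_COLUMNS)
    if event_type is not None:
        cols += list(COORD_COLUMNS[event_type])
    else:  # header-only degenerate file: keep whatever coord columns exist
        cols += [c for c in table.columns if c not in cols and c not in
                 ("event_type", "IncLevel1") and c not in COUNT_COLUMNS]
    cols += list(COUNT_COLUMNS)
    out = table.reindex(columns=cols + ["IncLevel1"]).copy()
    if "IncLevel1" in table.columns:
        lvl = pd.to_numeric(table["IncLevel1"], errors="coerce")
    else:
        lvl = pd.Series(np.nan, index=table.index)
    out["IncLevel1"] = ["NA" if not np.isfinite(v) else f"{v:.6f}" for v in lvl]
    buf = io.StringIO()
    out.to_csv(buf, sep="\t", index=False, lineterminator="\n")
    Path(path).write_text(buf.getvalue())


@dataclass
class PsiMatrix:
    """Events x samples PSI with coverage mask and count provenance.

    ``psi`` holds NaN where a cell is unobserved (IJC + SJC = 0) or fails
    the coverage filter; ``covered`` is True exactly where
    IJC + SJC >= ``min_reads``.  ``events`` carries one metadata row per
    event (type, gene, chrom, strand, variable region).
    """

    events: pd.DataFrame
    psi: pd.DataFrame
    covered: pd.DataFrame
    ijc: Optional[pd.DataFrame] = None
    sjc: Optional[pd.DataFrame] = None
    min_reads: int = DEFAULT_MIN_READS

    @property
    def samples(self) -> List[str]:
        return list(self.psi.columns)

    @property
    def event_keys(self) -> List[str]:
        return list(self.psi.index)

    def __post_init__(self) -> None:
        if self.psi.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        if not self.psi.index.equals(self.covered.index):
            raise ValueError("psi/covered event index mismatch")
        present = self.psi.notna()
        if (present & ~self.covered).to_numpy().any():
            raise ValueError("psi present in uncovered cell")
        vals = self.psi.to_numpy()
        if np.nanmin(vals, initial=0.0) < 0 or np.nanmax(vals, initial=1.0) > 1:
            raise ValueError("psi outside [0, 1]")

    def subset_events(self, keys: Sequence[str]) -> "PsiMatrix":
        keys = list(keys)
        return PsiMatrix(
            events=self.events.loc[keys],
            psi=self.psi.loc[keys],
            covered=self.covered.loc[keys],
            ijc=None if self.ijc is None else self.ijc.loc[keys],
            sjc=None if self.sjc is None else self.sjc.loc[keys],
            min_reads=self.min_reads,
        )

    def write(self, psi_path: Union[str, Path], coverage_path: Union[str, Path],
              events_path: Optional[Union[str, Path]] = None) -> None:
        """Export PSI matrix TSV with a sidecar coverage TSV (0/1)."""
        psi = self.psi.round(6)
        psi.to_csv(psi_path, sep="\t", float_format="%.6f", na_rep="NA")
        self.covered.astype(int).to_csv(coverage_path, sep="\t")
        if events_path is not None:
            self.events.to_csv(events_path, sep="\t")

    @classmethod
    def read(cls, psi_path: Union[str, Path], coverage_path: Union[str, Path],
             events_path: Optional[Union[str, Path]] = None,
             min_reads: int = DEFAULT_MIN_READS) -> "PsiMatrix":
        psi = pd.read_csv(psi_path, sep="\t", index_col=0, na_values="NA")
        covered = pd.read_csv(coverage_path, sep="\t", index_col=0).astype(bool)
        if events_path is not None:
            events = pd.read_csv(events_path, sep="\t", index_col=0)
        else:
            events = pd.DataFrame(index=psi.index)
        return cls(events=events, psi=psi, covered=covered, min_reads=min_reads)


def assemble_psi_matrix(
    per_sample_tables: Mapping[str, Union[pd.DataFrame, Iterable[pd.DataFrame]]],
    min_reads: int = DEFAULT_MIN_READS,
    keep_counts: bool = True,
) -> PsiMatrix:
    """Assemble the cohort PSI matrix from per-sample event tables.

    ``per_sample_tables`` maps sample id to a table (or list of tables, one
    per event class) as returned by :func:`read_sample_events`.  Events are
    unioned across samples; a cell is covered iff IJC + SJC >= ``min_reads``,
    and PSI at uncovered or unobserved cells is missing.  Duplicate
    (sample, event) rows are an error.
    """
    if not per_sample_tables:
        raise ValueError("need at least one sample table")
    sample_frames: Dict[str, pd.DataFrame] = {}
    meta_frames = []
    for sample, tables in per_sample_tables.items():
        if isinstance(tables, pd.DataFrame):
            tables = [tables]
        tables = list(tables)
        tab = tables[0] if len(tables) == 1 else pd.concat(tables)
        if tab.index.duplicated().any():
            dup = tab.index[tab.index.duplicated()][0]
            raise ValueError(f"duplicate event {dup!r} in sample {sample!r}")
        sample_frames[sample] = tab
        meta_frames.append(tab[["event_type", "GeneID", "geneSymbol", "chr", "strand"]
                               + [c for c in tab.columns if c in
                                  {x for cols in COORD_COLUMNS.values() for x in cols}]])
    # Event universe: union, ordered by event_key for determinism.
    meta = pd.concat(meta_frames)
    meta = meta[~meta.index.duplicated(keep="first")].sort_index()
    universe = meta.index

    n_ev, n_s = len(universe), len(sample_frames)
    samples = sorted(sample_frames)
    ijc = np.full((n_ev, n_s), -1.0)
    sjc = np.full((n_ev, n_s), -1.0)
    psi = np.full((n_ev, n_s), np.nan)
    pos = pd.Series(np.arange(n_ev), index=universe)
    for j, sample in enumerate(samples):
        tab = sample_frames[sample]
        rows = pos[tab.index].to_numpy()
        i_ = tab["IJC_SAMPLE_1"].to_numpy(dtype=float)
        s_ = tab["SJC_SAMPLE_1"].to_numpy(dtype=float)
        ijc[rows, j] = i_
        sjc[rows, j] = s_
        psi[rows, j] = compute_psi(i_, s_, tab["IncFormLen"].to_numpy(),
                                   tab["SkipFormLen"].to_numpy())
    observed = ijc >= 0
    total = np.where(observed, ijc + sjc, -1.0)
    covered = total >= min_reads
    psi = np.where(covered, psi, np.nan)

    events_meta = _normalize_meta(meta)
    idx = pd.Index(universe, name="event_key")
    return PsiMatrix(
        events=events_meta,
        psi=pd.DataFrame(psi, index=idx, columns=samples),
        covered=pd.DataFrame(covered, index=idx, columns=samples),
        ijc=pd.DataFrame(np.where(observed, ijc, np.nan), index=idx, columns=samples) if keep_counts else None,
        sjc=pd.DataFrame(np.where(observed, sjc, np.nan), index=idx, columns=samples) if keep_counts else None,
        min_reads=min_reads,
    )


def _normalize_meta(meta: pd.DataFrame) -> pd.DataFrame:
    """Per-event metadata with a uniform variable-region annotation."""
    from .events import SpliceEvent

    var_start = np.empty(len(meta), dtype=np.int64)
    var_end = np.empty(len(meta), dtype=np.int64)
    for i, (_, row) in enumerate(meta.iterrows()):
        etype = row["event_type"]
        coords = tuple(int(row[c]) for c in COORD_COLUMNS[etype])
        ev = SpliceEvent(etype, str(row["geneSymbol"]), str(row["chr"]),
                         str(row["strand"]), coords, gene_id=str(row["GeneID"]))
        var_start[i], var_end[i] = ev.variable_region
    out = meta.copy()
    out = out.rename(columns={"geneSymbol": "gene_symbol", "chr": "chrom",
                              "GeneID": "gene_id"})
    out["variable_start"] = var_start
    out["variable_end"] = var_end
    out.index.name = "event_key"
    return out
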