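"""Splice-event identity and junction-count primitives.

Coordinates follow the rMATS dialect throughout the package: starts are
0-based (``exonStart_0base``), ends are exclusive, so every interval is
half-open ``[start, end)``.  Event identity is a deterministic string key
built from the event type, chromosome, strand and the full coordinate
tuple, so two files describing the same event always agree on the key.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

EVENT_TYPES = ("SE", "A5SS", "A3SS", "RI", "MXE")

#: Coordinate columns of the rMATS *.MATS.JC.txt dialect, per event type,
#: in file order.
COORD_COLUMNS = {
    "SE": (
        "exonStart_0base", "exonEnd",
        "upstreamES", "upstreamEE",
        "downstreamES", "downstreamEE",
    ),
    "MXE": (
        "1stExonStart_0base", "1stExonEnd",
        "2ndExonStart_0base", "2ndExonEnd",
        "upstreamES", "upstreamEE",
        "downstreamES", "downstreamEE",
    ),
    "A5SS": (
        "longExonStart_0base", "longExonEnd",
        "shortES", "shortEE",
        "flankingES", "flankingEE",
    ),
    "A3SS": (
        "longExonStart_0base", "longExonEnd",
        "shortES", "shortEE",
        "flankingES", "flankingEE",
    ),
    "RI": (
        "riExonStart_0base", "riExonEnd",
        "upstreamES", "upstreamEE",
        "downstreamES", "downstreamEE",
    ),
}

COUNT_COLUMNS = ("IJC_SAMPLE_1", "SJC_SAMPLE_1", "IncFormLen", "SkipFormLen")


class EventError(ValueError):
    """Malformed splice-event record."""


@dataclass(frozen=True)
class JunctionCounts:
    """Inclusion/skipping junction read counts with effective form lengths."""

    ijc: int
    sjc: int
    inc_form_len: int
    skip_form_len: int

    def __post_init__(self) -> None:
        if self.ijc < 0 or self.sjc < 0:
            raise EventError("junction counts must be non-negative")
        if self.inc_form_len < 1 or self.skip_form_len < 1:
            raise EventError("form lengths must be >= 1")


@dataclass(frozen=True)
class SpliceEvent:
    """One alternative-splicing event in rMATS coordinates.

    ``variable_region`` is the segment whose inclusion PSI measures: the
    cassette exon for SE, the alternative extension for A5SS/A3SS, the
    retained intron for RI, and the first mutually-exclusive exon for MXE.
    ``flanking_regions`` are the constitutive neighbours.
    """

    event_type: str
    gene_symbol: str
    chrom: str
    strand: str
    coords: Tuple[int, ...]
    gene_id: str = ""
    event_key: str = field(init=False)

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise EventError(f"unknown event type {self.event_type!r}")
        if self.strand not in ("+", "-"):
            raise EventError(f"strand must be '+' or '-', got {self.strand!r}")
        ncoord = len(COORD_COLUMNS[self.event_type])
        if len(self.coords) != ncoord:
            raise EventError(
                f"{self.event_type} needs {ncoord} coordinates, got {len(self.coords)}"
            )
        for start, end in zip(self.coords[::2], self.coords[1::2]):
            if not (0 <= start < end):
                raise EventError(
                    f"interval [{start}, {end}) violates start < end"
                )
        object.__setattr__(self, "event_key", make_event_key(
            self.event_type, self.chrom, self.strand, self.coords))

    @property
    def variable_region(self) -> Tuple[int, int]:
        c = self.coords
        if self.event_type in ("SE", "MXE"):
            return (c[0], c[1])
        if self.event_type == "RI":
            # retained intron = gap between the two flanking exons
            return (c[3], c[4])
        # A5SS / A3SS: extension of the long exon relative to the short one.
        long_s, long_e, short_s, short_e = c[0], c[1], c[2], c[3]
        if long_s == short_s:
            return (short_e, long_e)
        return (long_s, short_s)

    @property
    def flanking_regions(self) -> Tuple[Tuple[int, int], ...]:
        c = self.coords
        if self.event_type in ("SE", "RI"):
            return ((c[2], c[3]), (c[4], c[5]))
        if self.event_type == "MXE":
            return ((c[4], c[5]), (c[6], c[7]))
        return ((c[4], c[5]),)


def make_event_key(event_type: str, chrom: str, strand: str,
                   coords: Tuple[int, ...]) -> str:
    """Deterministic, injective key over (type, chrom, strand, coordinates)."""
    coord_str = ":".join(str(c) for c in coords)
    return f"{event_type}|{chrom}|{strand}|{coord_str}"
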