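"""Shared record types and the pair-alignment table.

Collections of read-pair alignments are carried as a pandas DataFrame with
the columns in :data:`PAIR_COLUMNS` (one row per pair, 0-based half-open
coordinates for each mate).  The :class:`PairAlignment` dataclass is the
single-record view used at I/O boundaries and in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

PAIR_COLUMNS = [
    "chrom",
    "up_start",
    "up_end",
    "down_start",
    "down_end",
    "proper_orientation",
    "mapq_up",
    "mapq_down",
    "pair_id",
]


@dataclass(frozen=True)
class PairAlignment:
    """Mapped positions of both mates of one read pair.

    The upstream read is the mate with the smaller coordinate; coordinates
    are 0-based half-open.  Overlapping mates are allowed (``up_end`` may
    exceed ``down_start``) but ``up_start <= down_start`` always holds.
    """

    chrom: str
    up_start: int
    up_end: int
    down_start: int
    down_end: int
    proper_orientation: bool = True
    mapq_up: int = 60
    mapq_down: int = 60
    pair_id: str = ""

    def __post_init__(self) -> None:
        if not (self.up_start < self.up_end and self.down_start < self.down_end):
            raise ValueError("read intervals must be non-empty")
        if self.up_start > self.down_start:
            raise ValueError("upstream read must not start after downstream read")
        if self.mapq_up < 0 or self.mapq_down < 0:
            raise ValueError("mapping qualities must be >= 0")

    @property
    def inner_distance(self) -> int:
        """Inner gap between the two mates (may be negative if they overlap)."""
        return self.down_start - self.up_end


def pairs_to_frame(pairs: Iterable[PairAlignment]) -> pd.DataFrame:
    """Build the canonical pair-alignment table from individual records."""
    rows = [
        (
            p.chrom,
            p.up_start,
            p.up_end,
            p.down_start,
            p.down_end,
            p.proper_orientation,
            p.mapq_up,
            p.mapq_down,
            p.pair_id,
        )
        for p in pairs
    ]
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def frame_to_pairs(frame: pd.DataFrame) -> list[PairAlignment]:
    """Materialize :class:`PairAlignment` records from the table."""
    return [
        PairAlignment(
            chrom=row.chrom,
            up_start=int(row.up_start),
            up_end=int(row.up_end),
            down_start=int(row.down_start),
            down_end=int(row.down_end),
            proper_orientation=bool(row.proper_orientation),
            mapq_up=int(row.mapq_up),
            mapq_down=int(row.mapq_down),
            pair_id=str(row.pair_id),
        )
        for row in frame.itertuples(index=False)
    ]


@dataclass(frozen=True)
class SVRecord:
    """A structural variant in reference coordinates (0-based half-open).

    Deletions have ``start < end``; insertions are anchored at a single
    reference point (``start == end``) and carry the inserted length in
    ``ins_length``.
    """

    chrom: str
    start: int
    end: int
    sv_type: str  # "DEL" or "INS"
    ins_length: int = 0

    def __post_init__(self) -> None:
        if self.sv_type not in ("DEL", "INS"):
            raise ValueError(f"sv_type must be DEL or INS, got {self.sv_type!r}")
        if self.sv_type == "DEL" and not self.start < self.end:
            raise ValueError("DEL requires start < end")
        if self.sv_type == "INS":
            if self.start != self.end:
                raise ValueError("INS anchor requires start == end")
            if self.ins_length < 1:
                raise ValueError("INS requires ins_length >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start if self.sv_type == "DEL" else self.ins_length


@dataclass(frozen=True)
class DeletionCall:
    """A genomic interval predicted as deleted (0-based half-open)."""

    chrom: str
    start: int
    end: int
    support: int = 0
    source: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"deletion call requires start < end, got [{self.start}, {self.end})"
            )
        if self.support < 0:
            raise ValueError("support must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start
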