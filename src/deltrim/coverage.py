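"""Per-base coverage tracks built from pair alignments.

Coverage counts individual reads (each mate separately): ``counts[i]`` is
the number of read alignments covering base ``offset + i``.  Both
concordant and discordant reads contribute by default, since any uniquely
mapped read is evidence that its bases exist in the sample; a
``concordant_only`` switch restricts the track to properly oriented pairs
within the expected insert range when that stricter reading is wanted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DeletionCall

__all__ = ["CoverageTrack", "filter_unique_pairs", "build_coverage", "slice_coverage"]


@dataclass(frozen=True)
class CoverageTrack:
    """Non-negative per-base read counts over ``[offset, offset + len)``."""

    chrom: str
    offset: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if counts.size and counts.min() < 0:
            raise ValueError("coverage counts must be >= 0")
        object.__setattr__(self, "counts", counts)

    @property
    def end(self) -> int:
        return self.offset + len(self.counts)


def filter_unique_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    """Keep only pairs where both mates mapped uniquely (MAPQ > 0)."""
    keep = (pairs["mapq_up"] > 0) & (pairs["mapq_down"] > 0)
    return pairs.loc[keep].reset_index(drop=True)


def build_coverage(
    pairs: pd.DataFrame,
    chrom: str,
    start: int,
    end: int,
    concordant_only: bool = False,
) -> CoverageTrack:
    """Per-base read coverage of ``chrom:[start, end)`` from a pair table.

    Each mate of each pair is counted as an independent read interval;
    intervals are clipped to the region.  Implemented with a difference
    array, so it runs in O(reads + region length).
    """
    if end <= start:
        raise ValueError(f"malformed region [{start}, {end})")
    sel = pairs.loc[pairs["chrom"] == chrom]
    if concordant_only:
        sel = sel.loc[sel["proper_orientation"].astype(bool)]
    starts = np.concatenate([sel["up_start"].to_numpy(), sel["down_start"].to_numpy()])
    ends = np.concatenate([sel["up_end"].to_numpy(), sel["down_end"].to_numpy()])
    starts = np.clip(starts, start, end)
    ends = np.clip(ends, start, end)
    diff = np.zeros(end - start + 1, dtype=np.int64)
    np.add.at(diff, starts - start, 1)
    np.add.at(diff, ends - start, -1)
    counts = np.cumsum(diff[:-1])
    return CoverageTrack(chrom=chrom, offset=start, counts=counts)


def slice_coverage(track: CoverageTrack, call: DeletionCall) -> np.ndarray:
    """Per-base counts across a deletion call, ordered from its upstream
    end (the call must lie within the track span)."""
    if call.chrom != track.chrom:
        raise ValueError(f"call on {call.chrom} but track on {track.chrom}")
    if call.start < track.offset or call.end > track.end:
        raise ValueError(
            f"call [{call.start}, {call.end}) outside track "
            f"[{track.offset}, {track.end})"
        )
    return track.counts[call.start - track.offset : call.end - track.offset]
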