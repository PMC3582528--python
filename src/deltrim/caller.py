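"""Minimal threshold-based read-pair deletion caller.

A pair whose mates map in proper orientation but farther apart than
expected spans a deletion.  The caller estimates the insert-size
distribution from the data, flags pairs with inner distance beyond
``mu + m * sigma`` (``m = 3`` by convention) as deletion-discordant,
clusters mutually overlapping discordant pairs by single linkage, and
emits, for every cluster with at least ``min_support`` pairs, the
intersection of the supporting inner intervals
``[max(up_end), min(down_start))``.  The emitted interval therefore lies
inside every supporting pair, so for a real deletion both call ends sit in
the flanks, at or outside the true breakpoints.

This is deliberately the simplest faithful realization of threshold-based
read-pair calling; it exists so the trimming stage can be exercised
end-to-end without an external caller.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DeletionCall

__all__ = [
    "InsertStats",
    "estimate_insert_stats",
    "classify_pair",
    "classify_pairs",
    "call_deletions",
]

CONCORDANT = "concordant"
DISCORDANT_DELETION = "discordant_deletion"
OTHER = "other"


@dataclass(frozen=True)
class InsertStats:
    """Insert-size model: mean / SD of inner distances and the number of
    standard deviations beyond which a distance is called discordant."""

    mu: float
    sigma: float
    m: float = 3.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.m <= 0:
            raise ValueError("m must be > 0")

    @property
    def deletion_threshold(self) -> float:
        return self.mu + self.m * self.sigma


def _inner_distances(pairs: pd.DataFrame) -> np.ndarray:
    return (pairs["down_start"] - pairs["up_end"]).to_numpy(dtype=float)


def estimate_insert_stats(pairs: pd.DataFrame, m: float = 3.0) -> InsertStats:
    """Estimate mu and sigma of the inner distance from properly oriented
    pairs, with one pass of outlier exclusion.

    Pairs spanning real deletions have grossly inflated distances; dropping
    distances above ``mu0 + 5 sigma0`` (initial estimates) before
    re-estimating keeps them from biasing the insert model.
    """
    proper = pairs.loc[pairs["proper_orientation"].astype(bool)]
    if len(proper) < 2:
        raise ValueError("need at least two properly oriented pairs")
    dist = _inner_distances(proper)
    mu0 = float(dist.mean())
    sd0 = float(dist.std(ddof=1))
    kept = dist[dist <= mu0 + 5.0 * sd0]
    if kept.size < 2:
        kept = dist
    return InsertStats(
        mu=float(kept.mean()), sigma=float(kept.std(ddof=1)), m=float(m)
    )


def classify_pairs(pairs: pd.DataFrame, stats: InsertStats) -> np.ndarray:
    """Vectorized classification of every pair in the table.

    Deletion-discordant pairs are properly oriented with inner distance
    above ``mu + m sigma``; pairs with aberrant orientation are ``other``;
    everything else is concordant.
    """
    proper = pairs["proper_orientation"].to_numpy(dtype=bool)
    dist = _inner_distances(pairs)
    out = np.full(len(pairs), CONCORDANT, dtype=object)
    out[~proper] = OTHER
    out[proper & (dist > stats.deletion_threshold)] = DISCORDANT_DELETION
    return out


def classify_pair(pair, stats: InsertStats) -> str:
    """Classify a single :class:`~deltrim.core.PairAlignment`."""
    if not pair.proper_orientation:
        return OTHER
    if pair.inner_distance > stats.deletion_threshold:
        return DISCORDANT_DELETION
    return CONCORDANT


def call_deletions(
    discordant: pd.DataFrame, min_support: int = 2, source: str = "rp_caller"
) -> list[DeletionCall]:
    """Cluster deletion-discordant pairs and emit deletion calls.

    Pairs whose inner intervals ``[up_end, down_start)`` overlap are joined
    transitively (single linkage, per contig).  Each cluster of at least
    ``min_support`` pairs yields the call ``[max(up_end), min(down_start))``
    with the cluster size as support; degenerate clusters whose
    intersection is empty are dropped.
    """
    calls: list[DeletionCall] = []
    for chrom, group in discordant.groupby("chrom", sort=True):
        g = group.sort_values("up_end", kind="stable")
        inner_start = g["up_end"].to_numpy()
        inner_end = g["down_start"].to_numpy()
        i = 0
        n = len(g)
        while i < n:
            j = i + 1
            max_end = inner_end[i]
            while j < n and inner_start[j] < max_end:
                max_end = max(max_end, inner_end[j])
                j += 1
            size = j - i
            if size >= min_support:
                start = int(inner_start[i:j].max())
                end = int(inner_end[i:j].min())
                if start < end:
                    calls.append(
                        DeletionCall(
                            chrom=str(chrom),
                            start=start,
                            end=end,
                            support=size,
                            source=source,
                        )
                    )
            i = j
    calls.sort(key=lambda c: (c.chrom, c.start, c.end))
    return calls
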