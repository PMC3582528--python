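"""Coverage-guided trimming of homozygous-deletion call ends.

A homozygous deletion produces no reads, so bases near a call's ends that
are covered by read alignments are probably flanking sequence that the
caller overshot.  The trimmer walks inward from each end of a call and
removes:

1. an initial *high-coverage run* — a maximal stretch whose per-base
   coverage exceeds the threshold ``k`` — unconditionally; then
2. further blocks consisting of a low-coverage stretch followed by another
   high-coverage run, but only while the *joint coverage* (the running mean
   coverage of everything walked so far) stays above ``k * f``.  An
   extension whose joint coverage fails the test is not trimmed, and a
   trailing low-coverage stretch alone never is — trimming must always end
   on a high-coverage run.

The two ends are trimmed independently and symmetrically (the downstream
end is the upstream trim of the reversed coverage vector); when the trims
meet or cross, the whole call is removed.  Calls whose interior has no
coverage above ``k`` are left untouched, so the procedure is harmless for
calls that are already correct.  ``k`` separates real coverage from noise
(raise it on deep or dirty data); ``f`` in (0, 1] controls how aggressively
fragmented high-coverage evidence is absorbed (smaller is more aggressive).

``joint_reset`` selects a variant in which the running sum restarts after
every committed block instead of accumulating from the call's first base;
the cumulative form is the default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .core import DeletionCall
from .coverage import CoverageTrack, slice_coverage

__all__ = [
    "TrimParams",
    "TrimResult",
    "trim_upstream_length",
    "trim_downstream_length",
    "trim_call",
    "trim_calls",
]


@dataclass(frozen=True)
class TrimParams:
    """Trimming thresholds.

    ``k``: coverage above this is "high" (strict comparison); ``f``:
    fraction of ``k`` the joint coverage must exceed to keep absorbing
    fragmented high-coverage regions; ``pad``: bases to widen the call by on
    both sides before trimming (for window-based callers whose breakpoints
    may already sit inside the deletion).
    """

    k: int = 2
    f: float = 0.5
    pad: int = 0
    joint_reset: bool = False

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be a positive integer, got {self.k}")
        if not 0.0 < self.f <= 1.0:
            raise ValueError(f"f must be in (0, 1], got {self.f}")
        if self.pad < 0:
            raise ValueError(f"pad must be >= 0, got {self.pad}")


@dataclass(frozen=True)
class TrimResult:
    """Outcome of trimming one call.

    ``trimmed`` is ``None`` when the trims met or crossed and the call was
    removed entirely.  ``padded`` is the interval the trimmer actually
    worked on (equal to ``original`` when ``pad == 0``); the invariant
    ``trim_up + trim_down == len(padded) - len(trimmed)`` holds whenever
    the call survives.
    """

    original: DeletionCall
    padded: DeletionCall
    trimmed: Optional[DeletionCall]
    trim_up: int
    trim_down: int

    @property
    def removed(self) -> bool:
        return self.trimmed is None


def _validate_vector(cov: Sequence[int]) -> np.ndarray:
    c = np.asarray(cov)
    if c.ndim != 1 or c.size == 0:
        raise ValueError("coverage vector must be non-empty and one-dimensional")
    if c.min() < 0:
        raise ValueError("coverage must be >= 0")
    return c


def trim_upstream_length(cov: Sequence[int], params: TrimParams) -> int:
    """Number of bases to trim from the upstream end of a call.

    ``cov`` is the call's per-base coverage ordered from the upstream end.
    Returns the length of the longest prefix that ends on a high-coverage
    run and whose every committed extension kept the joint coverage above
    ``k * f``.
    """
    c = _validate_vector(cov)
    k, kf = params.k, params.k * params.f
    L = c.size
    x = 0  # bases examined so far
    s = 0  # coverage sum over the examined prefix (or since last commit)
    while x < L and c[x] > k:
        s += int(c[x])
        x += 1
    y = x  # the initial high-coverage run is trimmed unconditionally
    denom_base = 0  # start of the current joint-coverage window
    if params.joint_reset:
        s = 0
        denom_base = x
    while True:
        while x < L and c[x] <= k:
            s += int(c[x])
            x += 1
        run_start = x
        while x < L and c[x] > k:
            s += int(c[x])
            x += 1
        if x == run_start:  # no high-coverage run reached: nothing to commit
            break
        if s / (x - denom_base) > kf:
            y = x
            if params.joint_reset:
                s = 0
                denom_base = x
        else:
            break
    return y


def trim_downstream_length(cov: Sequence[int], params: TrimParams) -> int:
    """Bases to trim from the downstream end: the upstream trim of the
    reversed coverage vector."""
    return trim_upstream_length(np.asarray(cov)[::-1], params)


def trim_call(
    call: DeletionCall, track: CoverageTrack, params: TrimParams
) -> TrimResult:
    """Trim one deletion call against a coverage track.

    The call is first widened by ``params.pad`` on both sides, then the two
    ends are trimmed independently on the padded coverage vector.  Returns
    a removed result when the two trims meet or cross.
    """
    padded = DeletionCall(
        chrom=call.chrom,
        start=call.start - params.pad,
        end=call.end + params.pad,
        support=call.support,
        source=call.source,
    )
    cov = slice_coverage(track, padded)
    up = trim_upstream_length(cov, params)
    down = trim_downstream_length(cov, params)
    if up + down >= padded.length:
        return TrimResult(call, padded, None, up, down)
    trimmed = DeletionCall(
        chrom=call.chrom,
        start=padded.start + up,
        end=padded.end - down,
        support=call.support,
        source=call.source,
    )
    return TrimResult(call, padded, trimmed, up, down)


def trim_calls(
    calls: Sequence[DeletionCall],
    tracks: Union[CoverageTrack, dict[str, CoverageTrack]],
    params: TrimParams,
) -> list[TrimResult]:
    """Trim a batch of calls, preserving input order.

    ``tracks`` is a single coverage track or a mapping from contig name to
    track covering every (padded) call on that contig.
    """
    if isinstance(tracks, CoverageTrack):
        tracks = {tracks.chrom: tracks}
    results = []
    for call in calls:
        if call.chrom not in tracks:
            raise ValueError(f"no coverage track for contig {call.chrom!r}")
        results.append(trim_call(call, tracks[call.chrom], params))
    return results
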