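"""Accuracy metrics for deletion calls against a bp-resolved truth set.

A call is *correct* when it overlaps exactly one true deletion and that
deletion overlaps exactly one call (one-to-one by at least one shared
base).  For correct calls the breakpoint accuracy is summarized by the

* upstream difference  = truth.start - call.start, and
* downstream difference = call.end - truth.end;

positive values mean the called end lies outside the true deletion,
negative ones that it intruded inside, and zero is exact.  Because both
intervals use the same half-open convention, the differences are invariant
to the coordinate convention itself.

``recall`` is the fraction of true deletions hit by a correct call and
``precision`` the fraction of calls that are correct; quartiles of the two
differences summarize resolution, and ``n_covering`` counts correct calls
that contain their whole true deletion (both differences >= 0) — the calls
a coverage-based trimmer can actually improve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import DeletionCall, SVRecord

__all__ = [
    "EvalRecord",
    "EvalSummary",
    "match_calls",
    "breakpoint_differences",
    "summarize",
    "compare_before_after",
    "difference_histogram",
]

CORRECT = "correct"
UNMATCHED = "unmatched_call"
AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class EvalRecord:
    """One call matched against the truth set."""

    call: DeletionCall
    truth: Optional[SVRecord]
    upstream_diff: Optional[int]
    downstream_diff: Optional[int]
    status: str


@dataclass(frozen=True)
class EvalSummary:
    n_truth: int
    n_calls: int
    n_correct: int
    recall: float
    precision: float
    upstream_quartiles: tuple[float, float, float]
    downstream_quartiles: tuple[float, float, float]
    n_covering: int


def _overlap_counts(
    starts_a: np.ndarray, ends_a: np.ndarray, starts_b: np.ndarray, ends_b: np.ndarray
) -> np.ndarray:
    """For each interval in A, the number of intervals in B sharing >= 1 base."""
    if starts_b.size == 0 or starts_a.size == 0:
        return np.zeros(starts_a.size, dtype=np.int64)
    # counts via boundary sweep: intervals of B overlapping [s, e) are those
    # with start < e minus those with end <= s (B sorted by each key).
    b_starts = np.sort(starts_b)
    b_ends = np.sort(ends_b)
    return np.searchsorted(b_starts, ends_a, side="left") - np.searchsorted(
        b_ends, starts_a, side="right"
    )


def _first_overlap(
    start: int, end: int, starts: np.ndarray, ends: np.ndarray
) -> Optional[int]:
    hits = np.flatnonzero((starts < end) & (ends > start))
    return int(hits[0]) if hits.size else None


def match_calls(
    calls: Sequence[DeletionCall], truths: Sequence[SVRecord]
) -> list[EvalRecord]:
    """Match every call against the truth deletions (per contig).

    Only DEL truth records are considered.  Calls overlapping no truth are
    ``unmatched_call``; calls in any overlap pattern other than one-to-one
    are ``ambiguous``; one-to-one matches are ``correct`` and carry the two
    breakpoint differences.
    """
    truths = [t for t in truths if t.sv_type == "DEL"]
    records: list[EvalRecord] = []
    by_chrom: dict[str, tuple[list[DeletionCall], list[SVRecord]]] = {}
    for c in calls:
        by_chrom.setdefault(c.chrom, ([], []))[0].append(c)
    for t in truths:
        by_chrom.setdefault(t.chrom, ([], []))[1].append(t)
    for chrom in sorted(by_chrom):
        cs, ts = by_chrom[chrom]
        c_starts = np.array([c.start for c in cs], dtype=np.int64)
        c_ends = np.array([c.end for c in cs], dtype=np.int64)
        t_starts = np.array([t.start for t in ts], dtype=np.int64)
        t_ends = np.array([t.end for t in ts], dtype=np.int64)
        n_truth_overlaps = _overlap_counts(c_starts, c_ends, t_starts, t_ends)
        n_call_overlaps = _overlap_counts(t_starts, t_ends, c_starts, c_ends)
        for i, call in enumerate(cs):
            if n_truth_overlaps[i] == 0:
                records.append(EvalRecord(call, None, None, None, UNMATCHED))
                continue
            j = _first_overlap(call.start, call.end, t_starts, t_ends)
            if n_truth_overlaps[i] == 1 and n_call_overlaps[j] == 1:
                truth = ts[j]
                up = truth.start - call.start
                down = call.end - truth.end
                records.append(EvalRecord(call, truth, up, down, CORRECT))
            else:
                records.append(EvalRecord(call, ts[j], None, None, AMBIGUOUS))
    return records


def breakpoint_differences(record: EvalRecord) -> tuple[int, int]:
    """(upstream, downstream) breakpoint differences of a correct match."""
    if record.status != CORRECT:
        raise ValueError("differences are defined only for correct calls")
    return record.upstream_diff, record.downstream_diff


def _quartiles(values: list[int]) -> tuple[float, float, float]:
    if not values:
        return (float("nan"),) * 3
    q = np.quantile(np.asarray(values, dtype=float), [0.25, 0.5, 0.75])
    return tuple(float(v) for v in q)


def summarize(
    records: Sequence[EvalRecord], truths: Sequence[SVRecord]
) -> EvalSummary:
    """Counts, recall/precision and difference quartiles for one call set."""
    truths = [t for t in truths if t.sv_type == "DEL"]
    correct = [r for r in records if r.status == CORRECT]
    n_truth = len(truths)
    n_calls = len(records)
    n_correct = len(correct)
    ups = [r.upstream_diff for r in correct]
    downs = [r.downstream_diff for r in correct]
    return EvalSummary(
        n_truth=n_truth,
        n_calls=n_calls,
        n_correct=n_correct,
        recall=n_correct / n_truth if n_truth else 0.0,
        precision=n_correct / n_calls if n_calls else 0.0,
        upstream_quartiles=_quartiles(ups),
        downstream_quartiles=_quartiles(downs),
        n_covering=sum(
            1 for r in correct if r.upstream_diff >= 0 and r.downstream_diff >= 0
        ),
    )


@dataclass(frozen=True)
class PairedComparison:
    """Per-truth paired differences before and after trimming."""

    n_paired: int
    n_lost: int  # truths correct before but not after (removed or degraded)
    median_before: float
    median_after: float
    fraction_improved: float
    fraction_overtrimmed: float  # difference driven negative from non-negative
    before: tuple[int, ...] = ()
    after: tuple[int, ...] = ()


def compare_before_after(
    raw_records: Sequence[EvalRecord],
    trimmed_records: Sequence[EvalRecord],
    which: str = "upstream",
) -> PairedComparison:
    """Pair correct calls before/after trimming by their matched truth.

    ``which`` selects the upstream or downstream difference.  Truths whose
    call was removed by trimming (or stopped being a one-to-one match)
    count as lost.
    """
    idx = 0 if which == "upstream" else 1

    def keyed(records):
        return {
            (r.truth.chrom, r.truth.start, r.truth.end): breakpoint_differences(r)[idx]
            for r in records
            if r.status == CORRECT
        }

    before = keyed(raw_records)
    after = keyed(trimmed_records)
    shared = sorted(set(before) & set(after))
    b = [before[key] for key in shared]
    a = [after[key] for key in shared]
    n = len(shared)
    improved = sum(1 for x, y in zip(b, a) if abs(y) < abs(x))
    overtrimmed = sum(1 for x, y in zip(b, a) if x >= 0 > y)
    return PairedComparison(
        n_paired=n,
        n_lost=len(set(before) - set(after)),
        median_before=float(np.median(b)) if n else float("nan"),
        median_after=float(np.median(a)) if n else float("nan"),
        fraction_improved=improved / n if n else 0.0,
        fraction_overtrimmed=overtrimmed / n if n else 0.0,
        before=tuple(b),
        after=tuple(a),
    )


def difference_histogram(
    records: Sequence[EvalRecord], which: str = "upstream", bin_width: int = 2
):
    """Histogram of breakpoint differences of correct calls.

    Returns a DataFrame with ``bin_start`` (inclusive) and ``count``
    columns; the default 2 bp bins match the resolution at which the
    difference distributions are usually inspected.
    """
    import pandas as pd

    idx = 0 if which == "upstream" else 1
    vals = np.array(
        [breakpoint_differences(r)[idx] for r in records if r.status == CORRECT]
    )
    if vals.size == 0:
        return pd.DataFrame({"bin_start": [], "count": []})
    lo = int(np.floor(vals.min() / bin_width) * bin_width)
    hi = int(np.floor(vals.max() / bin_width) * bin_width) + bin_width
    edges = np.arange(lo, hi + 1, bin_width)
    counts, _ = np.histogram(vals, bins=edges)
    return pd.DataFrame({"bin_start": edges[:-1], "count": counts})
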