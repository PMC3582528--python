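"""Synthetic genomes, homozygous deletions/insertions, and paired reads.

The generator emulates a whole-genome resequencing experiment on a sample
that differs from the reference by homozygous deletions and insertions:

1. a uniform-random reference sequence is drawn;
2. a set of non-overlapping deletions (lengths log-uniform between 100 bp
   and 10 kb by default) is removed from it, and an equal number of random
   fragments — whose lengths are a permutation of the deletion lengths, so
   the two SV classes are symmetric — is inserted elsewhere;
3. single-nucleotide substitutions are sprinkled at a per-base rate of
   1e-4;
4. paired reads (100 bp mates, inner distance Normal(200, 50) truncated at
   zero) are drawn uniformly from the modified genome at a chosen depth of
   coverage (2-20 is the realistic range for the downstream analysis);
5. reads are projected back to reference coordinates by an idealized
   unique mapper: a read maps iff its sample interval corresponds to one
   contiguous stretch of the reference, so reads inside novel insertions or
   crossing an SV junction are unmapped and the whole pair is discarded
   (the same effect as removing pairs with a zero mapping-quality mate).

Genome sequences are held as ``numpy`` arrays of 2-bit base codes
(0..3 = ACGT); :func:`codes_to_str` / :func:`str_to_codes` convert at the
FASTA boundary.  All steps are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import PAIR_COLUMNS, SVRecord

__all__ = [
    "SimConfig",
    "CoordinateMap",
    "PlacementError",
    "simulate_reference",
    "draw_sv_set",
    "apply_svs",
    "add_substitutions",
    "generate_pairs",
    "project_to_reference",
    "codes_to_str",
    "str_to_codes",
    "revcomp_codes",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE_OF = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_OF[_b] = _i
    _CODE_OF[ord(chr(_b).lower())] = _i


class PlacementError(ValueError):
    """Raised when the requested SVs cannot be placed without overlap."""


def codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def str_to_codes(seq: str) -> np.ndarray:
    codes = _CODE_OF[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes == 255).any():
        raise ValueError("sequence contains characters outside ACGT")
    return codes


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement in code space (complement is 3 - code)."""
    return (3 - codes)[::-1]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated resequencing experiment.

    Defaults describe the standard scenario used throughout: a 10 Mb
    single-contig genome carrying 50 homozygous deletions with log-uniform
    lengths between 100 and 10,000 bases, sequenced with 100 bp mates at
    inner distance 200 +/- 50 bp and substitution rate 1e-4 per base.
    """

    genome_length: int = 10_000_000
    n_deletions: int = 50
    deletion_length_range: tuple[int, int] = (100, 10_000)
    deletion_length_sampler: Optional[Callable[[np.random.Generator, int], np.ndarray]] = None
    coverage: float = 5.0
    read_length: int = 100
    distance_mean: float = 200.0
    distance_sd: float = 50.0
    substitution_rate: float = 1e-4
    seed: int = 0
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        if self.genome_length < 1:
            raise ValueError("genome_length must be >= 1")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if self.distance_sd < 0:
            raise ValueError("distance_sd must be >= 0")
        if not 0.0 <= self.substitution_rate <= 1.0:
            raise ValueError("substitution_rate must be in [0, 1]")

    @property
    def min_sv_gap(self) -> int:
        """Minimum separation between SVs so that deletion calls are
        unambiguously one-to-one: twice (pair distance + read length)."""
        return int(2 * (self.distance_mean + self.read_length))

    def sample_deletion_lengths(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.deletion_length_sampler is not None:
            lengths = np.asarray(self.deletion_length_sampler(rng, n), dtype=np.int64)
        else:
            lo, hi = self.deletion_length_range
            lengths = np.rint(
                np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
            ).astype(np.int64)
        if n and lengths.min() < 1:
            raise ValueError("deletion lengths must be >= 1")
        return lengths


@dataclass(frozen=True)
class CoordinateMap:
    """Piecewise map from sample coordinates back to reference coordinates.

    Segments partition the sample genome; each is either a contiguous copy
    of a reference stretch (``ref_starts >= 0``) or novel inserted sequence
    (``ref_starts == -1``).
    """

    sample_starts: np.ndarray  # sorted segment starts in sample coords
    lengths: np.ndarray
    ref_starts: np.ndarray  # -1 marks novel (inserted) sequence

    @property
    def sample_length(self) -> int:
        return int(self.sample_starts[-1] + self.lengths[-1]) if len(self.lengths) else 0

    def map_intervals(self, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Reference start for each [start, end) sample interval, or -1.

        An interval maps iff it lies inside a single non-novel segment, so
        intervals in novel sequence or crossing any SV junction return -1.
        """
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        idx = np.searchsorted(self.sample_starts, starts, side="right") - 1
        idx = np.clip(idx, 0, len(self.lengths) - 1)
        seg_start = self.sample_starts[idx]
        seg_end = seg_start + self.lengths[idx]
        ref = self.ref_starts[idx]
        ok = (starts >= seg_start) & (ends <= seg_end) & (ref >= 0) & (starts < ends)
        out = np.where(ok, ref + (starts - seg_start), -1)
        return out

    def map_interval(self, start: int, end: int) -> Optional[int]:
        """Scalar convenience wrapper around :meth:`map_intervals`."""
        res = int(self.map_intervals(np.array([start]), np.array([end]))[0])
        return None if res < 0 else res


def _as_rng(seed: Union[int, np.random.Generator]) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_reference(length: int, seed: Union[int, np.random.Generator]) -> np.ndarray:
    """Uniform random A/C/G/T sequence of the given length (as base codes)."""
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    rng = _as_rng(seed)
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def draw_sv_set(
    config: SimConfig,
    genome_length: Optional[int] = None,
    seed: Union[int, np.random.Generator, None] = None,
) -> list[SVRecord]:
    """Draw non-overlapping deletion and insertion records.

    Produces ``n_deletions`` DEL intervals plus an equal number of INS
    anchors whose inserted lengths are a permutation of the deletion
    lengths.  Consecutive SVs (and the genome ends) are separated by at
    least ``config.min_sv_gap`` bases; the remaining slack is spread at
    random, so placement never needs rejection sampling.
    """
    G = config.genome_length if genome_length is None else genome_length
    rng = _as_rng(config.seed if seed is None else seed)
    n = config.n_deletions
    if n == 0:
        return []
    del_lengths = config.sample_deletion_lengths(rng, n)
    ins_lengths = rng.permutation(del_lengths)
    # interleave DELs and INSs in random genomic order
    order = rng.permutation(np.r_[np.zeros(n, bool), np.ones(n, bool)])
    footprints = np.zeros(2 * n, dtype=np.int64)
    footprints[~order] = del_lengths  # DELs occupy reference bases
    gap = config.min_sv_gap
    need = int(footprints.sum()) + (2 * n + 1) * gap
    slack = G - need
    if slack < 0:
        raise PlacementError(
            f"cannot place {n} deletions + {n} insertions with min gap {gap} "
            f"in a genome of {G} bases (need {need})"
        )
    extras = rng.multinomial(slack, np.full(2 * n + 1, 1.0 / (2 * n + 1)))
    records: list[SVRecord] = []
    pos = 0
    i_del = i_ins = 0
    for i in range(2 * n):
        pos += gap + int(extras[i])
        if order[i]:  # INS anchor
            records.append(
                SVRecord(config.chrom, pos, pos, "INS", int(ins_lengths[i_ins]))
            )
            i_ins += 1
        else:
            length = int(del_lengths[i_del])
            records.append(SVRecord(config.chrom, pos, pos + length, "DEL"))
            pos += length
            i_del += 1
    return records


def _check_svs(svs: Sequence[SVRecord], genome_length: int) -> None:
    prev_end = 0
    for sv in svs:
        if sv.start < prev_end:
            raise ValueError("SV records must be sorted and non-overlapping")
        if sv.end > genome_length:
            raise ValueError("SV record extends past the reference end")
        prev_end = sv.end


def apply_svs(
    reference: np.ndarray,
    svs: Sequence[SVRecord],
    seed: Union[int, np.random.Generator] = 0,
) -> tuple[np.ndarray, CoordinateMap]:
    """Apply deletions and insertions to a reference sequence.

    Returns the modified sample sequence and the coordinate map that sends
    each sample base back to its reference origin (insertions are marked
    novel).  The sample length equals ``len(reference) - sum(DEL lengths)
    + sum(INS lengths)`` by construction.
    """
    _check_svs(svs, len(reference))
    rng = _as_rng(seed)
    pieces: list[np.ndarray] = []
    seg_lengths: list[int] = []
    seg_refs: list[int] = []
    cursor = 0  # current reference position

    def emit_ref(upto: int) -> None:
        nonlocal cursor
        if upto > cursor:
            pieces.append(reference[cursor:upto])
            seg_lengths.append(upto - cursor)
            seg_refs.append(cursor)
        cursor = upto

    for sv in svs:
        emit_ref(sv.start)
        if sv.sv_type == "DEL":
            cursor = sv.end
        else:
            frag = rng.integers(0, 4, size=sv.ins_length, dtype=np.uint8)
            pieces.append(frag)
            seg_lengths.append(sv.ins_length)
            seg_refs.append(-1)
    emit_ref(len(reference))

    lengths = np.asarray(seg_lengths, dtype=np.int64)
    if lengths.size == 0:  # reference fully deleted
        sample = np.empty(0, dtype=np.uint8)
        starts = np.empty(0, dtype=np.int64)
        refs = np.empty(0, dtype=np.int64)
    else:
        sample = np.concatenate(pieces)
        starts = np.concatenate([[0], np.cumsum(lengths)[:-1]])
        refs = np.asarray(seg_refs, dtype=np.int64)
    return sample, CoordinateMap(starts, lengths, refs)


def add_substitutions(
    sequence: np.ndarray,
    rate: float,
    seed: Union[int, np.random.Generator],
) -> np.ndarray:
    """Replace each base independently by a *different* base with the given
    probability; the input array is not modified."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate must be in [0, 1], got {rate}")
    rng = _as_rng(seed)
    out = sequence.copy()
    hit = np.flatnonzero(rng.random(len(sequence)) < rate)
    if hit.size:
        shift = rng.integers(1, 4, size=hit.size, dtype=np.uint8)
        out[hit] = (out[hit] + shift) % 4
    return out


def generate_pairs(
    sample: np.ndarray,
    config: SimConfig,
    seed: Union[int, np.random.Generator],
) -> pd.DataFrame:
    """Draw paired-read placements from the sample genome.

    The number of pairs is ``round(coverage * length / (2 * read_length))``;
    each pair has a uniform upstream start and an inner distance drawn from
    ``Normal(distance_mean, distance_sd)``, rounded and truncated at zero.
    Returns a DataFrame in *sample* coordinates with columns ``up_start``,
    ``up_end``, ``down_start``, ``down_end`` and ``pair_id``.
    """
    L = len(sample)
    r = config.read_length
    if L <= 2 * r + config.distance_mean:
        raise ValueError("sample sequence too short for the configured pairs")
    n = int(round(config.coverage * L / (2.0 * r)))
    rng = _as_rng(seed)
    if n == 0:
        return pd.DataFrame(
            columns=["up_start", "up_end", "down_start", "down_end", "pair_id"]
        )
    gaps = np.rint(rng.normal(config.distance_mean, config.distance_sd, size=n))
    gaps = np.maximum(gaps, 0).astype(np.int64)
    spans = 2 * r + gaps
    spans = np.minimum(spans, L)  # guard against extreme tail draws
    gaps = spans - 2 * r
    up_start = np.floor(rng.random(n) * (L - spans + 1)).astype(np.int64)
    up_end = up_start + r
    down_start = up_end + gaps
    return pd.DataFrame(
        {
            "up_start": up_start,
            "up_end": up_end,
            "down_start": down_start,
            "down_end": down_start + r,
            "pair_id": [f"pair{i}" for i in range(n)],
        }
    )


def project_to_reference(
    pairs: pd.DataFrame,
    cmap: CoordinateMap,
    chrom: str = "chr1",
) -> pd.DataFrame:
    """Project sample-coordinate pair placements onto the reference.

    Each read maps iff its sample interval is one contiguous reference
    stretch; pairs with an unmapped read (novel sequence or an SV junction)
    are dropped, mirroring the removal of pairs with a zero-MAPQ mate.
    Retained reads get MAPQ 60.  A pair whose mates flank a deletion keeps
    both reads and its reference inner distance grows by the deleted
    length; mates that flank an insertion move closer together and, for
    insertions longer than the pair span, may even swap reference order, in
    which case the pair is flagged as improperly oriented.
    """
    if len(pairs) == 0:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    a_ref = cmap.map_intervals(pairs["up_start"].to_numpy(), pairs["up_end"].to_numpy())
    b_ref = cmap.map_intervals(
        pairs["down_start"].to_numpy(), pairs["down_end"].to_numpy()
    )
    keep = (a_ref >= 0) & (b_ref >= 0)
    a_ref = a_ref[keep]
    b_ref = b_ref[keep]
    r_up = (pairs["up_end"] - pairs["up_start"]).to_numpy()[keep]
    r_down = (pairs["down_end"] - pairs["down_start"]).to_numpy()[keep]
    # the mate at the smaller reference coordinate is the upstream read
    swapped = b_ref < a_ref
    up_start = np.where(swapped, b_ref, a_ref)
    up_len = np.where(swapped, r_down, r_up)
    down_start = np.where(swapped, a_ref, b_ref)
    down_len = np.where(swapped, r_up, r_down)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "up_start": up_start,
            "up_end": up_start + up_len,
            "down_start": down_start,
            "down_end": down_start + down_len,
            "proper_orientation": ~swapped,
            "mapq_up": 60,
            "mapq_down": 60,
            "pair_id": pairs["pair_id"].to_numpy()[keep],
        }
    )
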