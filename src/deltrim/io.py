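"""Readers and writers for the interchange formats.

BED (0-based half-open) carries deletion calls and truth sets, bedGraph
carries coverage tracks, and read-pair alignments travel either as SAM
(via pysam) or as the internal tab-delimited pair table with the columns
of :data:`deltrim.core.PAIR_COLUMNS`.  Everything written here can be read
back losslessly by the corresponding reader.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
import pysam

from .core import PAIR_COLUMNS, DeletionCall, SVRecord
from .coverage import CoverageTrack
from .simulate import codes_to_str, revcomp_codes

__all__ = [
    "FormatError",
    "read_bed",
    "write_bed",
    "read_truth_bed",
    "write_truth_bed",
    "read_alignments",
    "write_pairs_tsv",
    "write_sam",
    "read_bedgraph",
    "write_bedgraph",
    "write_fasta",
    "read_fasta",
    "write_fastq",
]

logger = logging.getLogger("deltrim")


class FormatError(ValueError):
    """Malformed input file (message includes the offending line)."""


def _bed_rows(path: Union[str, Path]):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise FormatError(
                    f"{path}:{lineno}: start must be < end, got {start} >= {end}"
                )
            yield lineno, fields, start, end


def read_bed(path: Union[str, Path]) -> list[DeletionCall]:
    """Read deletion calls from BED3+ (name -> source, score -> support)."""
    calls = []
    for lineno, fields, start, end in _bed_rows(path):
        source = fields[3] if len(fields) > 3 else ""
        try:
            support = int(float(fields[4])) if len(fields) > 4 else 0
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric score") from exc
        calls.append(DeletionCall(fields[0], start, end, support, source))
    return calls


def write_bed(calls: Iterable[DeletionCall], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for c in calls:
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.source or '.'}\t{c.support}\n")


def read_truth_bed(path: Union[str, Path]) -> list[SVRecord]:
    """Read a truth set of deletions from BED."""
    return [
        SVRecord(fields[0], start, end, "DEL")
        for _, fields, start, end in _bed_rows(path)
    ]


def write_truth_bed(svs: Iterable[SVRecord], path: Union[str, Path]) -> None:
    """Write the DEL records of an SV set as BED (insertions are anchors in
    reference coordinates and are not representable as non-empty intervals)."""
    with open(path, "w") as fh:
        for sv in svs:
            if sv.sv_type == "DEL":
                fh.write(f"{sv.chrom}\t{sv.start}\t{sv.end}\tDEL\t0\n")


# ---------------------------------------------------------------------------
# pair alignments


def write_pairs_tsv(pairs: pd.DataFrame, path: Union[str, Path]) -> None:
    pairs.to_csv(path, sep="\t", index=False, columns=PAIR_COLUMNS)


def _read_pairs_tsv(path: Union[str, Path]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse as pair table: {exc}") from exc
    required = [c for c in PAIR_COLUMNS if c != "proper_orientation"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing pair-table columns {missing}")
    if "proper_orientation" not in df.columns:
        df["proper_orientation"] = True
    return df[PAIR_COLUMNS]


def _read_pairs_sam(path: Union[str, Path]) -> pd.DataFrame:
    mode = "rb" if str(path).endswith(".bam") else "r"
    rows = []
    n_dropped = 0
    pending: dict[str, pysam.AlignedSegment] = {}
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for read in fh.fetch(until_eof=True):
            if read.is_secondary or read.is_supplementary:
                continue
            if not read.is_paired or read.is_unmapped:
                n_dropped += 1
                continue
            mate = pending.pop(read.query_name, None)
            if mate is None:
                pending[read.query_name] = read
                continue
            a, b = (mate, read)
            if b.reference_start < a.reference_start:
                a, b = b, a
            same_chrom = a.reference_name == b.reference_name
            proper = same_chrom and (not a.is_reverse) and b.is_reverse
            rows.append(
                (
                    a.reference_name,
                    a.reference_start,
                    a.reference_start + (a.reference_length or 0),
                    b.reference_start,
                    b.reference_start + (b.reference_length or 0),
                    proper,
                    a.mapping_quality,
                    b.mapping_quality,
                    a.query_name,
                )
            )
    n_dropped += len(pending)
    if n_dropped:
        logger.info("dropped %d unpaired or unmapped SAM records", n_dropped)
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def read_alignments(path: Union[str, Path]) -> pd.DataFrame:
    """Read pair alignments from SAM/BAM or the internal TSV pair table.

    SAM mates are joined by query name; records that are secondary,
    supplementary, unmapped or without a mapped mate are dropped (a count
    is logged).
    """
    suffix = Path(path).suffix.lower()
    if suffix in (".sam", ".bam"):
        return _read_pairs_sam(path)
    return _read_pairs_tsv(path)


def write_sam(
    pairs: pd.DataFrame,
    path: Union[str, Path],
    reference_lengths: dict[str, int],
) -> None:
    """Write a pair table as SAM with correct FLAG/POS/PNEXT/TLEN.

    Properly oriented pairs are written FR (upstream mate forward,
    downstream mate reverse); improper pairs are written RF.  Sequences are
    omitted ('*') since only placements matter downstream.
    """
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [
                {"SN": name, "LN": int(length)}
                for name, length in reference_lengths.items()
            ],
        }
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for row in pairs.itertuples(index=False):
            proper = bool(row.proper_orientation)
            tlen = int(row.down_end - row.up_start)
            for is_up in (True, False):
                seg = pysam.AlignedSegment(header)
                seg.query_name = str(row.pair_id)
                seg.reference_name = row.chrom
                start = int(row.up_start if is_up else row.down_start)
                length = int(
                    (row.up_end - row.up_start)
                    if is_up
                    else (row.down_end - row.down_start)
                )
                seg.reference_start = start
                seg.mapping_quality = int(row.mapq_up if is_up else row.mapq_down)
                seg.cigartuples = [(0, length)]
                flag = 0x1  # paired
                if proper:
                    flag |= 0x2
                    flag |= (0x20 | 0x40) if is_up else (0x10 | 0x80)
                else:  # reference order of mates swapped: RF pattern
                    flag |= (0x10 | 0x40) if is_up else (0x20 | 0x80)
                seg.flag = flag
                seg.next_reference_name = row.chrom
                seg.next_reference_start = int(row.down_start if is_up else row.up_start)
                seg.template_length = tlen if is_up else -tlen
                out.write(seg)


# ---------------------------------------------------------------------------
# coverage


def write_bedgraph(track: CoverageTrack, path: Union[str, Path]) -> None:
    """Write a coverage track as bedGraph (runs of equal coverage, zeros
    included so the span round-trips exactly)."""
    counts = track.counts
    with open(path, "w") as fh:
        if counts.size == 0:
            return
        boundaries = np.flatnonzero(np.diff(counts)) + 1
        starts = np.concatenate([[0], boundaries])
        ends = np.concatenate([boundaries, [counts.size]])
        for s, e in zip(starts, ends):
            fh.write(
                f"{track.chrom}\t{track.offset + s}\t{track.offset + e}\t{int(counts[s])}\n"
            )


def read_bedgraph(path: Union[str, Path], chrom: Optional[str] = None) -> CoverageTrack:
    """Read one contig's coverage from bedGraph into a dense track.

    Gaps between intervals are filled with zeros; ``chrom`` selects the
    contig when the file carries several (required in that case).
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
            try:
                rows.append(
                    (fields[0], int(fields[1]), int(fields[2]), int(float(fields[3])))
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed bedGraph row") from exc
    if not rows:
        raise FormatError(f"{path}: empty bedGraph")
    chroms = {r[0] for r in rows}
    if chrom is None:
        if len(chroms) > 1:
            raise FormatError(
                f"{path}: multiple contigs {sorted(chroms)}; pass chrom="
            )
        chrom = next(iter(chroms))
    rows = [r for r in rows if r[0] == chrom]
    offset = min(r[1] for r in rows)
    end = max(r[2] for r in rows)
    counts = np.zeros(end - offset, dtype=np.int64)
    for _, s, e, v in rows:
        counts[s - offset : e - offset] = v
    return CoverageTrack(chrom=chrom, offset=offset, counts=counts)


# ---------------------------------------------------------------------------
# sequences and reads


def write_fasta(
    sequences: dict[str, np.ndarray], path: Union[str, Path], width: int = 70
) -> None:
    """Write named base-code arrays as FASTA."""
    with open(path, "w") as fh:
        for name, codes in sequences.items():
            fh.write(f">{name}\n")
            seq = codes_to_str(codes)
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: Union[str, Path]) -> dict[str, np.ndarray]:
    """Read FASTA into base-code arrays (via pyfaidx)."""
    from pyfaidx import Fasta

    from .simulate import str_to_codes

    out = {}
    with Fasta(str(path), as_raw=True, sequence_always_upper=True) as fa:
        for name in fa.keys():
            out[name] = str_to_codes(str(fa[name][:]))
    return out


def write_fastq(
    pairs: pd.DataFrame,
    sample: np.ndarray,
    path1: Union[str, Path],
    path2: Union[str, Path],
) -> None:
    """Write the mate sequences of sample-coordinate pair placements.

    Mate 1 is the upstream read on the forward strand; mate 2 is the
    downstream read reverse-complemented, as an FR paired-end protocol
    would deliver them.  Base qualities are constant ('I').
    """
    with open(path1, "w") as fh1, open(path2, "w") as fh2:
        for row in pairs.itertuples(index=False):
            up = sample[int(row.up_start) : int(row.up_end)]
            down = revcomp_codes(sample[int(row.down_start) : int(row.down_end)])
            fh1.write(f"@{row.pair_id}/1\n{codes_to_str(up)}\n+\n{'I' * len(up)}\n")
            fh2.write(f"@{row.pair_id}/2\n{codes_to_str(down)}\n+\n{'I' * len(down)}\n")
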