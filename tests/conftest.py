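"""Shared fixtures: small pair tables and cached end-to-end pipeline runs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from deltrim.core import PAIR_COLUMNS
from deltrim.pipeline import RunConfig, run_pipeline
from deltrim.simulate import SimConfig


def make_pairs(rows, chrom="chr1"):
    """Build a pair-alignment table from (up_start, up_end, down_start,
    down_end[, proper, mapq_up, mapq_down]) tuples."""
    full = []
    for i, row in enumerate(rows):
        row = list(row)
        while len(row) < 7:
            row.append(True if len(row) == 4 else 60)
        up_s, up_e, dn_s, dn_e, proper, mq_up, mq_dn = row
        full.append((chrom, up_s, up_e, dn_s, dn_e, proper, mq_up, mq_dn, f"p{i}"))
    return pd.DataFrame(full, columns=PAIR_COLUMNS)


@pytest.fixture(scope="session")
def pipeline_c5():
    """Standard 10 Mb / 50-deletion experiment at coverage 5 (seed 1)."""
    return run_pipeline(RunConfig(sim=SimConfig(seed=1, coverage=5.0)))


@pytest.fixture(scope="session")
def pipeline_c10():
    """Same experiment at coverage 10."""
    return run_pipeline(RunConfig(sim=SimConfig(seed=1, coverage=10.0)))


def trim_prefix_oracle(cov, k, f):
    """Brute-force largest-qualifying-prefix reference for upstream trimming.

    Enumerates every prefix that ends on a maximal high-coverage run and
    checks, by recomputation from scratch, that the initial run plus every
    committed extension up to that point kept the running mean coverage
    above ``k * f``; returns the longest such prefix.  Deliberately
    independent of the streaming implementation.
    """
    c = np.asarray(cov)
    L = len(c)
    kf = k * f
    high = c > k
    # end positions (exclusive) of maximal high-coverage runs
    run_ends = [
        i + 1 for i in range(L) if high[i] and (i + 1 == L or not high[i + 1])
    ]
    init = 0
    while init < L and high[init]:
        init += 1
    best = init
    for end in run_ends:
        if end <= init:
            continue
        chain_ok = all(
            c[:e].sum() / e > kf for e in run_ends if init < e <= end
        )
        if chain_ok:
            best = max(best, end)
    return best
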