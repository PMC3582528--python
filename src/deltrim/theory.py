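"""Closed-form expected breakpoint resolution of read-pair deletion calling.

Threshold-based read-pair (RP) methods locate the upstream end of a deletion
at the closest upstream discordant read, so the distance between the true
breakpoint ``b`` and the called end is a random variable ``delta_b``.  When
concordant reads are used as well (any read ending closer to ``b`` localizes
the breakpoint further), the relevant distance is ``delta'_b``, the distance
to the closest read of either kind.

The model assumes read pairs are placed uniformly at random on a genome of
length ``G`` with constant read length ``r`` and constant inner pair distance
``d``.  With ``N`` pairs, the probability that no pair's upstream read begins
at a given base is

    q(c) = (1 - 1/G)**N  ~=  exp(-c / (2 r)),

where ``c = 2 r N / G`` is the depth of coverage.  Conditional on the
breakpoint being detected at all (an upstream discordant read within ``d``
bases), the expectations are

    E[delta_b  | b, c] = (1-q)/(1-q**(d+1)) * S(q, d)
    E[delta'_b | b, c] = [ (1-q**2) S(q**2, d) - q**(d+1) (1-q) S(q, d) ]
                         / (1 - q**(d+1))

with the truncated geometric moment sum ``S(q, d) = sum_{j=0..d} j q**j``.
Doubling the coverage substitutes ``q**2`` for ``q``, which yields the
identity (checked numerically by :func:`theorem1_residual`)

    E[delta'_b | b, c] = (1+q**(d+1)) E[delta_b | b, 2c]
                         - q**(d+1) E[delta_b | b, c],

i.e. exploiting concordant reads is, asymptotically at both small and large
coverage, as good as doubling the coverage.

:func:`monte_carlo_resolution` is an independent simulation oracle for the
same generative model, used to validate the closed forms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "TheoryParams",
    "ResolutionResult",
    "MonteCarloResult",
    "q_of_coverage",
    "geometric_moment_sum",
    "detection_probability",
    "expected_resolution_rp",
    "expected_resolution_rp_double",
    "expected_resolution_concordant",
    "theorem1_residual",
    "event_probabilities",
    "resolution",
    "monte_carlo_resolution",
    "resolution_table",
]

# Below this value of (d+1)*(1-q) the closed form of S(q, d) suffers
# catastrophic cancellation in (1-q)**2; the direct series is exact there.
_SERIES_SWITCH = 0.1


@dataclass(frozen=True)
class TheoryParams:
    """Parameters of the resolution model.

    Either ``c`` (depth of coverage) or both ``G`` (genome length) and ``N``
    (number of read pairs) must be given; ``r`` is the read length and ``d``
    the inner distance between the two reads of a pair, both in bases.
    """

    c: Optional[float] = None
    r: int = 100
    d: int = 200
    G: Optional[int] = None
    N: Optional[int] = None

    def __post_init__(self) -> None:
        if self.r < 1:
            raise ValueError(f"read length r must be >= 1, got {self.r}")
        if self.d < 0:
            raise ValueError(f"pair distance d must be >= 0, got {self.d}")
        if self.c is None:
            if self.G is None or self.N is None:
                raise ValueError("either c or both G and N must be given")
            if self.G < 2 or self.N < 0:
                raise ValueError("G must be >= 2 and N >= 0")
        elif self.c < 0:
            raise ValueError(f"coverage c must be >= 0, got {self.c}")

    @property
    def coverage(self) -> float:
        """Depth of coverage, derived from G and N when c is not given."""
        if self.c is not None:
            return self.c
        return 2.0 * self.r * self.N / self.G

    def log_q(self) -> float:
        """log q, computed without forming 1-q explicitly (stable near q=1)."""
        if self.c is not None:
            return -self.c / (2.0 * self.r)
        return self.N * math.log1p(-1.0 / self.G)


@dataclass(frozen=True)
class ResolutionResult:
    """Closed-form resolution quantities for one parameter point."""

    q: float
    p_detect: float
    e_rp: float
    e_rp_2c: float
    e_concordant: float


@dataclass(frozen=True)
class MonteCarloResult:
    """Sample estimates of the two resolution expectations."""

    mean_rp: float
    mean_concordant: float
    se_rp: float
    se_concordant: float
    n_detected: int
    n_trials: int = 0


def q_of_coverage(params: TheoryParams) -> float:
    """Probability that no pair's upstream read begins at a given base.

    Returns ``exp(-c/(2r))`` when coverage is given, else the exact
    ``(1 - 1/G)**N``.
    """
    return math.exp(params.log_q())


def _series_moment_sum(log_q: float, d: int) -> float:
    """sum_{j=0..d} j * exp(j log q), evaluated term by term."""
    j = np.arange(1, d + 1, dtype=float)
    return float(np.sum(j * np.exp(j * log_q)))


def geometric_moment_sum(q: float, d: int) -> float:
    """Truncated geometric moment sum ``S(q, d) = sum_{j=0..d} j q**j``.

    Uses the closed form ``(q - (d+1) q**(d+1) + d q**(d+2)) / (1-q)**2``;
    near ``q = 1`` the closed form cancels catastrophically and the series is
    summed directly, and at ``q = 1`` the limit ``d (d+1) / 2`` is returned.
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"q must be in [0, 1], got {q}")
    if d < 0:
        raise ValueError(f"d must be >= 0, got {d}")
    if q == 0.0 or d == 0:
        return 0.0
    if q == 1.0:
        return d * (d + 1) / 2.0
    if (d + 1) * (1.0 - q) < _SERIES_SWITCH:
        return _series_moment_sum(math.log(q), d)
    return (q - (d + 1) * q ** (d + 1) + d * q ** (d + 2)) / (1.0 - q) ** 2


def _moment_sum_log(log_q: float, d: int) -> float:
    """S(q, d) from log q, dispatching exactly like geometric_moment_sum."""
    if log_q == 0.0:
        return d * (d + 1) / 2.0
    one_minus_q = -math.expm1(log_q)
    if (d + 1) * one_minus_q < _SERIES_SWITCH:
        return _series_moment_sum(log_q, d)
    q = math.exp(log_q)
    return (q - (d + 1) * q ** (d + 1) + d * q ** (d + 2)) / one_minus_q**2


def detection_probability(params: TheoryParams) -> float:
    """Probability P_b = 1 - q**(d+1) that a breakpoint is detected at all.

    Detection requires at least one upstream discordant read within ``d``
    bases of the breakpoint.
    """
    return -math.expm1((params.d + 1) * params.log_q())


def _e_rp_from_log(log_q: float, d: int) -> float:
    """E[delta_b | detected] for a per-base miss log-probability log q."""
    if log_q == 0.0:  # q = 1, i.e. c = 0: conditional law is uniform on 0..d
        return d / 2.0
    one_minus_q = -math.expm1(log_q)
    p_detect = -math.expm1((d + 1) * log_q)
    return one_minus_q / p_detect * _moment_sum_log(log_q, d)


def expected_resolution_rp(params: TheoryParams) -> float:
    """Expected distance from the breakpoint to the closest upstream
    discordant read, conditional on detection:
    ``E[delta_b | b, c] = (1-q)/(1-q**(d+1)) * S(q, d)``."""
    return _e_rp_from_log(params.log_q(), params.d)


def expected_resolution_rp_double(params: TheoryParams) -> float:
    """``E[delta_b | b, 2c]``: the RP resolution at doubled coverage,
    obtained by substituting ``q**2`` for ``q``."""
    return _e_rp_from_log(2.0 * params.log_q(), params.d)


def expected_resolution_concordant(params: TheoryParams) -> float:
    """Expected distance from the breakpoint to the closest upstream read of
    any kind (concordant or discordant), conditional on detection.

    ``E[delta'_b|b,c] = [(1-q^2) S(q^2,d) - q^(d+1) (1-q) S(q,d)] / (1-q^(d+1))``
    """
    log_q = params.log_q()
    d = params.d
    if log_q == 0.0:
        return d / 2.0
    one_minus_q = -math.expm1(log_q)
    one_minus_q2 = -math.expm1(2.0 * log_q)
    q_d1 = math.exp((d + 1) * log_q)
    p_detect = -math.expm1((d + 1) * log_q)
    num = one_minus_q2 * _moment_sum_log(2.0 * log_q, d) - q_d1 * one_minus_q * _moment_sum_log(log_q, d)
    return num / p_detect


def theorem1_residual(params: TheoryParams) -> float:
    """Residual of the coverage-doubling identity.

    Returns ``E[delta'_b|b,c] - [(1+q^(d+1)) E[delta_b|b,2c]
    - q^(d+1) E[delta_b|b,c]]``, which is zero up to rounding for all valid
    parameters.
    """
    log_q = params.log_q()
    q_d1 = math.exp((params.d + 1) * log_q)
    e_conc = expected_resolution_concordant(params)
    e_2c = expected_resolution_rp_double(params)
    e_c = expected_resolution_rp(params)
    return e_conc - ((1.0 + q_d1) * e_2c - q_d1 * e_c)


def event_probabilities(params: TheoryParams) -> tuple[np.ndarray, np.ndarray]:
    """Per-offset detection-event probabilities.

    Returns ``(Pr(A_j), Pr(A'_j))`` for ``j = 0..d``: ``A_j`` is the event
    that the breakpoint is detected and the closest upstream discordant read
    is exactly ``j`` bases away; ``A'_j`` is the analogue for the closest
    read of any kind.  Both arrays sum to the detection probability.
    """
    log_q = params.log_q()
    d = params.d
    j = np.arange(d + 1, dtype=float)
    one_minus_q = -math.expm1(log_q)
    one_minus_q2 = -math.expm1(2.0 * log_q)
    q_pow_j = np.exp(j * log_q)
    q_d1 = math.exp((d + 1) * log_q)
    pr_a = one_minus_q * q_pow_j
    pr_a_prime = one_minus_q2 * q_pow_j**2 - q_d1 * one_minus_q * q_pow_j
    return pr_a, pr_a_prime


def resolution(params: TheoryParams) -> ResolutionResult:
    """All closed-form quantities for one parameter point."""
    return ResolutionResult(
        q=q_of_coverage(params),
        p_detect=detection_probability(params),
        e_rp=expected_resolution_rp(params),
        e_rp_2c=expected_resolution_rp_double(params),
        e_concordant=expected_resolution_concordant(params),
    )


def monte_carlo_resolution(
    params: TheoryParams, n_trials: int, seed: int
) -> MonteCarloResult:
    """Simulation oracle for the two resolution expectations.

    Each trial places, independently at every offset ``j = 0..d`` upstream of
    the breakpoint, a discordant-pair upstream read end with probability
    ``1-q`` and a concordant read end with probability ``1-q``.  Trials are
    conditioned on detection (at least one discordant read within ``d``);
    ``delta_b`` is the smallest offset holding a discordant read and
    ``delta'_b`` the smallest offset holding any read.  Concordant placement
    is truncated at offset ``d`` because, conditional on detection,
    ``delta'_b <= delta_b <= d``.

    Deterministic for a given ``seed``.
    """
    if n_trials < 1:
        raise ValueError(f"n_trials must be >= 1, got {n_trials}")
    d = params.d
    p_hit = -math.expm1(params.log_q())
    rng = np.random.default_rng(seed)
    deltas_rp: list[np.ndarray] = []
    deltas_conc: list[np.ndarray] = []
    chunk = max(1, min(n_trials, (1 << 24) // (d + 1)))
    remaining = n_trials
    while remaining > 0:
        n = min(chunk, remaining)
        remaining -= n
        disc = rng.random((n, d + 1)) < p_hit
        conc = rng.random((n, d + 1)) < p_hit
        detected = disc.any(axis=1)
        if not detected.any():
            continue
        disc = disc[detected]
        both = disc | conc[detected]
        deltas_rp.append(np.argmax(disc, axis=1))
        deltas_conc.append(np.argmax(both, axis=1))
    if not deltas_rp:
        return MonteCarloResult(math.nan, math.nan, math.nan, math.nan, 0, n_trials)
    d_rp = np.concatenate(deltas_rp).astype(float)
    d_conc = np.concatenate(deltas_conc).astype(float)
    n_det = d_rp.size
    se = lambda x: float(np.std(x, ddof=1) / math.sqrt(x.size)) if x.size > 1 else math.nan
    return MonteCarloResult(
        mean_rp=float(d_rp.mean()),
        mean_concordant=float(d_conc.mean()),
        se_rp=se(d_rp),
        se_concordant=se(d_conc),
        n_detected=int(n_det),
        n_trials=n_trials,
    )


def resolution_table(
    coverages,
    r: int = 100,
    d: int = 200,
    monte_carlo: int = 0,
    seed: int = 0,
):
    """Tabulate the resolution model over a range of coverages.

    Returns a pandas DataFrame with one row per coverage value; when
    ``monte_carlo`` is positive, simulation estimates and their standard
    errors are appended for each row.
    """
    import pandas as pd

    rows = []
    for i, c in enumerate(coverages):
        p = TheoryParams(c=float(c), r=r, d=d)
        res = resolution(p)
        row = {
            "c": float(c),
            "r": r,
            "d": d,
            "q": res.q,
            "p_detect": res.p_detect,
            "e_rp": res.e_rp,
            "e_rp_2c": res.e_rp_2c,
            "e_concordant": res.e_concordant,
        }
        if monte_carlo > 0:
            mc = monte_carlo_resolution(p, monte_carlo, seed + i)
            row.update(
                mc_mean_rp=mc.mean_rp,
                mc_se_rp=mc.se_rp,
                mc_mean_concordant=mc.mean_concordant,
                mc_se_concordant=mc.se_concordant,
            )
        rows.append(row)
    return pd.DataFrame(rows)
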