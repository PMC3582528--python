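"""Closed-form resolution model: worked values, identities and the MC oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from deltrim.theory import (
    MonteCarloResult,
    TheoryParams,
    detection_probability,
    event_probabilities,
    expected_resolution_concordant,
    expected_resolution_rp,
    expected_resolution_rp_double,
    geometric_moment_sum,
    monte_carlo_resolution,
    q_of_coverage,
    resolution_table,
    theorem1_residual,
)

GRID = [
    TheoryParams(c=c, r=r, d=d)
    for c in (0.01, 0.1, 1, 2, 5, 10, 20, 50)
    for r in (36, 100)
    for d in (50, 200, 500)
]


class TestQOfCoverage:
    def test_zero_coverage_gives_one(self):
        assert q_of_coverage(TheoryParams(c=0, r=100)) == 1.0

    def test_halving_coverage(self):
        # c = 2 r ln 2 makes the exponent exactly -ln 2
        assert q_of_coverage(TheoryParams(c=200 * math.log(2), r=100)) == pytest.approx(0.5)

    def test_finite_genome_form_matches_exponential(self):
        exact = q_of_coverage(TheoryParams(G=10**6, N=25_000, r=100))
        approx = q_of_coverage(TheoryParams(c=5, r=100))
        assert exact == pytest.approx(approx, abs=1e-5)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            TheoryParams(c=-1, r=100)
        with pytest.raises(ValueError):
            TheoryParams(c=1, r=0)


class TestMomentSum:
    def test_q_zero_vanishes(self):
        assert geometric_moment_sum(0.0, 200) == 0.0

    def test_small_case_by_hand(self):
        # 0 + 1*0.5 + 2*0.25 = 1
        assert geometric_moment_sum(0.5, 2) == pytest.approx(1.0)

    def test_q_one_limit(self):
        assert geometric_moment_sum(1.0, 200) == 20100.0

    def test_rejects_q_outside_unit_interval(self):
        for bad in (-0.1, 1.5):
            with pytest.raises(ValueError):
                geometric_moment_sum(bad, 10)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        q=st.floats(min_value=0.0, max_value=1.0, exclude_max=True),
        d=st.integers(min_value=0, max_value=2000),
    )
    def test_closed_form_equals_brute_force(self, q, d):
        j = np.arange(d + 1, dtype=float)
        brute = float(np.sum(j * q**j))
        assert geometric_moment_sum(q, d) == pytest.approx(brute, rel=1e-9, abs=1e-12)


class TestDetectionProbability:
    def test_limits(self):
        assert detection_probability(TheoryParams(c=0)) == 0.0
        assert detection_probability(TheoryParams(c=1e9)) == pytest.approx(1.0)

    @pytest.mark.parametrize("params", GRID[::5])
    def test_equals_sum_of_event_probabilities(self, params):
        pa, pa_prime = event_probabilities(params)
        pb = detection_probability(params)
        assert pa.sum() == pytest.approx(pb, abs=1e-12)
        assert pa_prime.sum() == pytest.approx(pb, abs=1e-12)


class TestExpectedResolutions:
    def test_vanishing_coverage_gives_half_distance(self):
        p = TheoryParams(c=1e-9, r=100, d=200)
        assert expected_resolution_rp(p) == pytest.approx(100.0, abs=1e-3)
        assert expected_resolution_concordant(p) == pytest.approx(100.0, abs=1e-3)

    def test_deep_coverage_shrinks_resolution(self):
        assert expected_resolution_rp(TheoryParams(c=50, r=100, d=200)) < 5

    @pytest.mark.parametrize("params", GRID[::3])
    def test_rp_matches_brute_force_expectation(self, params):
        pa, _ = event_probabilities(params)
        j = np.arange(params.d + 1)
        brute = float((j * pa).sum() / detection_probability(params))
        assert expected_resolution_rp(params) == pytest.approx(brute, abs=1e-10)

    @pytest.mark.parametrize("params", GRID[::3])
    def test_concordant_matches_brute_force_expectation(self, params):
        _, pa_prime = event_probabilities(params)
        j = np.arange(params.d + 1)
        brute = float((j * pa_prime).sum() / detection_probability(params))
        assert expected_resolution_concordant(params) == pytest.approx(brute, abs=1e-10)

    @pytest.mark.parametrize("params", GRID)
    def test_ordering_invariant(self, params):
        """Using concordant reads never hurts: 0 <= E' <= E <= d."""
        e_conc = expected_resolution_concordant(params)
        e_rp = expected_resolution_rp(params)
        assert 0.0 <= e_conc <= e_rp + 1e-12
        assert e_rp <= params.d


class TestCoverageDoublingIdentity:
    @pytest.mark.parametrize("params", GRID)
    def test_identity_residual_negligible(self, params):
        rel = abs(theorem1_residual(params)) / expected_resolution_concordant(params)
        assert rel < 1e-9

    def test_concordant_approaches_doubled_coverage_at_depth(self):
        p = TheoryParams(c=100, r=100, d=200)
        assert abs(theorem1_residual(p)) < 1e-9
        assert expected_resolution_concordant(p) == pytest.approx(
            expected_resolution_rp_double(p), abs=1e-6
        )

    def test_gap_closes_monotonically_at_both_ends(self):
        """|E' - E[.,2c]| -> 0 as c -> 0 and as c grows large."""
        gap = lambda c: abs(
            expected_resolution_concordant(TheoryParams(c=c, r=100, d=200))
            - expected_resolution_rp_double(TheoryParams(c=c, r=100, d=200))
        )
        low = [gap(c) for c in (1e-6, 1e-4, 1e-2, 0.1, 1)]
        high = [gap(c) for c in (5, 10, 20, 50, 100)]
        assert all(a <= b + 1e-12 for a, b in zip(low, low[1:]))
        assert all(a >= b - 1e-12 for a, b in zip(high, high[1:]))


class TestMonteCarlo:
    def test_rejects_bad_trial_count(self):
        with pytest.raises(ValueError):
            monte_carlo_resolution(TheoryParams(c=5), 0, seed=1)

    def test_deterministic_per_seed(self):
        p = TheoryParams(c=5, r=100, d=200)
        a = monte_carlo_resolution(p, 2000, seed=7)
        b = monte_carlo_resolution(p, 2000, seed=7)
        assert a == b

    def test_means_match_closed_forms_within_3se(self):
        p = TheoryParams(c=5, r=100, d=200)
        mc = monte_carlo_resolution(p, 100_000, seed=1)
        assert mc.n_detected <= 100_000
        assert mc.se_rp >= 0 and mc.se_concordant >= 0
        assert abs(mc.mean_rp - expected_resolution_rp(p)) < 3 * mc.se_rp
        assert (
            abs(mc.mean_concordant - expected_resolution_concordant(p))
            < 3 * mc.se_concordant
        )


def test_resolution_table_columns_and_monotonicity():
    table = resolution_table([1, 2, 5, 10], r=100, d=200, monte_carlo=2000, seed=3)
    assert list(table["c"]) == [1, 2, 5, 10]
    assert (table["e_concordant"] <= table["e_rp"]).all()
    assert table["e_rp"].is_monotonic_decreasing
    assert {"mc_mean_rp", "mc_se_concordant"} <= set(table.columns)
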