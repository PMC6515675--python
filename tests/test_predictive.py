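"""Predictive probabilities of trial success: exact enumeration vs an
independent brute-force oracle, Monte-Carlo consistency, and stopping-rule
sanity properties."""

import itertools
import math

import numpy as np
import pytest

from seqtrial import (
    ArmCounts,
    InterimSnapshot,
    final_success,
    predictive_prob_current,
    predictive_prob_max,
)
from seqtrial.predictive import split_future_patients


def _sequence_mass(seq, alpha, beta):
    """Probability of a binary outcome sequence under the Polya-urn
    (beta-binomial predictive) scheme starting from Beta(alpha, beta)."""
    p = 1.0
    deaths = alive = 0
    for outcome in seq:
        denom = alpha + beta + deaths + alive
        p *= (alpha + deaths) / denom if outcome else (beta + alive) / denom
        deaths += outcome
        alive += 1 - outcome
    return p


def brute_force_predictive(
    snapshot, extra_c, extra_t, n_final_c, n_final_t, prior=(1.0, 1.0), threshold=0.975
):
    """Exhaustive enumeration over every per-patient outcome configuration of
    the outstanding patients, weighted by its posterior-predictive mass.

    Deliberately structured differently from the implementation (per-patient
    sequences rather than beta-binomial totals) to act as an oracle.
    """
    a_c = prior[0] + snapshot.deaths_control
    b_c = prior[1] + snapshot.complete_control - snapshot.deaths_control
    a_t = prior[0] + snapshot.deaths_treatment
    b_t = prior[1] + snapshot.complete_treatment - snapshot.deaths_treatment
    total = 0.0
    for seq_c in itertools.product((0, 1), repeat=extra_c):
        w_c = _sequence_mass(seq_c, a_c, b_c)
        d_c = snapshot.deaths_control + sum(seq_c)
        for seq_t in itertools.product((0, 1), repeat=extra_t):
            w_t = _sequence_mass(seq_t, a_t, b_t)
            d_t = snapshot.deaths_treatment + sum(seq_t)
            if final_success(
                ArmCounts(d_c, n_final_c), ArmCounts(d_t, n_final_t),
                prior=prior, threshold=threshold,
            ):
                total += w_c * w_t
    return total


# a deliberately unbalanced toy interim: 9 randomised per arm, one in-transit
# patient in each arm still inside the follow-up window
TOY = InterimSnapshot(
    randomised_control=9, randomised_treatment=9,
    complete_control=8, complete_treatment=8,
    deaths_control=3, deaths_treatment=1,
)
TOY_THRESHOLD = 0.8  # reachable success region at this tiny sample size


class TestPredictiveCurrent:
    def test_exact_path_matches_brute_force(self):
        res = predictive_prob_current(TOY, final_threshold=TOY_THRESHOLD, seed=0)
        oracle = brute_force_predictive(TOY, 1, 1, 9, 9, threshold=TOY_THRESHOLD)
        assert res.exact
        assert res.probability == pytest.approx(oracle, abs=1e-12)

    def test_wider_transit_matches_brute_force(self):
        snap = InterimSnapshot(10, 9, 6, 5, 1, 0)
        res = predictive_prob_current(snap, final_threshold=0.7, seed=0)
        oracle = brute_force_predictive(snap, 4, 4, 10, 9, threshold=0.7)
        assert res.probability == pytest.approx(oracle, abs=1e-12)

    def test_zero_in_transit_is_an_indicator(self):
        snap = InterimSnapshot(8, 8, 8, 8, 7, 0)
        res = predictive_prob_current(snap, final_threshold=0.9, seed=0)
        expected = final_success(
            ArmCounts(7, 8), ArmCounts(0, 8), threshold=0.9
        )
        assert res.probability == float(expected)
        snap_null = InterimSnapshot(8, 8, 8, 8, 4, 4)
        assert predictive_prob_current(snap_null, final_threshold=0.9, seed=0).probability == 0.0

    def test_monte_carlo_converges_to_enumeration(self):
        exact = predictive_prob_current(TOY, final_threshold=TOY_THRESHOLD, seed=0).probability
        n = 40_000
        mc = predictive_prob_current(
            TOY, final_threshold=TOY_THRESHOLD, n_draws=n, seed=11, exact_limit=0
        )
        assert not mc.exact
        se = math.sqrt(max(exact * (1 - exact), 1e-12) / n)
        assert abs(mc.probability - exact) < 3 * se

    def test_seed_to_seed_agreement(self):
        n = 20_000
        probs = [
            predictive_prob_current(
                TOY, final_threshold=TOY_THRESHOLD, n_draws=n, seed=s, exact_limit=0
            ).probability
            for s in range(5)
        ]
        p = np.mean(probs)
        tol = 4 * math.sqrt(max(p * (1 - p), 1e-12) / n)
        assert max(probs) - min(probs) < 2 * tol


class TestPredictiveMax:
    def test_degenerate_at_n_max_is_an_indicator(self):
        snap = InterimSnapshot(10, 10, 10, 10, 8, 1)
        res = predictive_prob_max(
            snap, n_max=20, dropout=0.0, final_threshold=0.8, seed=0
        )
        expected = final_success(ArmCounts(8, 10), ArmCounts(1, 10), threshold=0.8)
        assert res.probability == float(expected)

    def test_tiny_trial_matches_brute_force(self):
        # 4 patients observed, 4 future to reach n_max = 8, no dropout
        snap = InterimSnapshot(2, 2, 2, 2, 1, 1)
        res = predictive_prob_max(
            snap, n_max=8, dropout=0.0, final_threshold=0.7, seed=0
        )
        assert res.exact
        oracle = brute_force_predictive(snap, 2, 2, 4, 4, threshold=0.7)
        assert res.probability == pytest.approx(oracle, abs=1e-12)

    def test_monte_carlo_with_dropout_near_exact_no_dropout(self):
        # dropout forces the Monte-Carlo path; with dropout ~ 0 it must sit
        # within sampling error of the exact no-dropout enumeration
        snap = InterimSnapshot(6, 6, 5, 5, 3, 1)
        exact = predictive_prob_max(
            snap, n_max=16, dropout=0.0, final_threshold=0.7, seed=0
        ).probability
        n = 40_000
        mc = predictive_prob_max(
            snap, n_max=16, dropout=1e-12, final_threshold=0.7, n_draws=n, seed=5
        )
        assert not mc.exact
        se = math.sqrt(max(exact * (1 - exact), 1e-12) / n)
        assert abs(mc.probability - exact) < 3 * se

    def test_monotone_in_observed_death_split(self):
        # more control deaths / fewer treatment deaths can only help the
        # treatment's predictive chances (exact path over a small grid)
        def pmax(d_c, d_t):
            snap = InterimSnapshot(8, 8, 6, 6, d_c, d_t)
            return predictive_prob_max(
                snap, n_max=20, dropout=0.0, final_threshold=0.7, seed=0
            ).probability

        for d_t in range(3):
            vals = [pmax(d_c, d_t) for d_c in range(4)]
            assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))
        for d_c in range(3):
            vals = [pmax(d_c, d_t) for d_t in range(4)]
            assert all(a + 1e-12 >= b for a, b in zip(vals, vals[1:]))

    def test_n_max_below_randomised_rejected(self):
        snap = InterimSnapshot(10, 10, 10, 10, 4, 4)
        with pytest.raises(ValueError):
            predictive_prob_max(snap, n_max=19, seed=0)


class TestFutureSplit:
    def test_even_split_and_odd_remainder_to_control(self):
        assert split_future_patients(10) == (5, 5)
        assert split_future_patients(503) == (252, 251)
        assert split_future_patients(0) == (0, 0)

    def test_ratio_allocation(self):
        assert split_future_patients(9, allocation=(2, 1)) == (6, 3)

    def test_negative_remaining_rejected(self):
        with pytest.raises(ValueError):
            split_future_patients(-1)
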