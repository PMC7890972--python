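"""Unit and property tests for the steady-state queue analytics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from telequeue import (
    InvalidParameterError,
    QueueParameters,
    SaturationError,
    erlang_c_waiting_probability,
    overburdening_probability,
    solve_arrival_rate,
    state_distribution,
    traffic_density,
)

# ---------------------------------------------------------------------------
# independent brute-force oracle: textbook formulas with explicit factorials
# ---------------------------------------------------------------------------


def oracle_weights(lam, mu, m, n, imax):
    # direct textbook formulas, evaluated in log space so deep tails
    # (i up to 1e4) stay finite
    rho = lam / mu
    k = m * n
    log_rho = math.log(rho)

    def log_term(i):
        if i < k:
            return i * log_rho - math.lgamma(i + 1)
        return i * log_rho - math.lgamma(k + 1) - (i - k) * math.log(k)

    w0 = 1.0 / (
        sum(rho**i / math.factorial(i) for i in range(k))
        + rho**k / (math.factorial(k) * (1.0 - rho / k))
    )
    return [math.exp(log_term(i)) * w0 for i in range(imax + 1)]


def oracle_overburdening(lam, mu, m, n):
    k = m * n
    if lam / mu >= k:
        return 1.0
    return 1.0 - sum(oracle_weights(lam, mu, m, n, k))


class TestTrafficDensity:
    def test_zero_arrivals(self):
        assert traffic_density(0.0, 2.53) == 0.0

    def test_identity(self):
        assert traffic_density(2.53, 2.53) == 1.0

    def test_direct_division(self):
        assert traffic_density(0.27, 2.57) == pytest.approx(0.10505836575875488, abs=1e-15)

    def test_invalid_service_rate(self):
        with pytest.raises(InvalidParameterError):
            traffic_density(1.0, 0.0)
        with pytest.raises(InvalidParameterError):
            traffic_density(1.0, -2.0)

    def test_negative_arrival_rate(self):
        with pytest.raises(InvalidParameterError):
            traffic_density(-0.1, 2.0)


class TestQueueParameters:
    def test_derived_fields(self):
        p = QueueParameters(0.27, 2.57, calls_per_doctor=2, doctors=3)
        assert p.channels == 6
        assert p.traffic_density == 0.27 / 2.57

    def test_validation(self):
        with pytest.raises(InvalidParameterError):
            QueueParameters(-1.0, 2.0)
        with pytest.raises(InvalidParameterError):
            QueueParameters(1.0, 2.0, calls_per_doctor=0)
        with pytest.raises(InvalidParameterError):
            QueueParameters(1.0, 2.0, doctors=0)


class TestStateDistribution:
    def test_empty_system(self):
        dist = state_distribution(QueueParameters(0.0, 2.0, 2, 1), imax=10)
        assert dist.probabilities[0] == pytest.approx(1.0)
        assert np.allclose(dist.probabilities[1:], 0.0)
        assert dist.tail_mass == pytest.approx(0.0)

    def test_mm1_closed_form(self):
        # M/M/1 with rho = 0.5: w_i = (1 - rho) rho^i
        dist = state_distribution(QueueParameters(1.0, 2.0, 1, 1), imax=30)
        expected = 0.5 * 0.5 ** np.arange(31)
        assert np.allclose(dist.probabilities, expected, atol=1e-15)

    def test_single_district_w0(self):
        # evaluating the normalisation formula with the published inputs
        dist = state_distribution(QueueParameters(0.27, 2.57, 2, 1))
        assert dist.probabilities[0] == pytest.approx(0.900184842883549, abs=1e-12)

    def test_geometric_decay_above_k(self):
        p = QueueParameters(2.0, 1.5, 2, 1)
        dist = state_distribution(p, imax=20)
        r = p.traffic_density / p.channels
        ratios = dist.probabilities[3:] / dist.probabilities[2:-1]
        assert np.allclose(ratios, r, atol=1e-12)

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            state_distribution(QueueParameters(6.0, 2.0, 2, 1))

    def test_imax_below_k_rejected(self):
        with pytest.raises(InvalidParameterError):
            state_distribution(QueueParameters(0.2, 2.0, 2, 2), imax=2)

    def test_matches_oracle(self, random_stable_params):
        for p in random_stable_params:
            dist = state_distribution(p, imax=p.channels + 10)
            expected = oracle_weights(
                p.arrival_rate, p.service_rate, p.calls_per_doctor, p.doctors,
                p.channels + 10,
            )
            assert np.allclose(dist.probabilities, expected, atol=1e-12)


class TestOverburdeningProbability:
    @pytest.mark.parametrize(
        "lam, expected_pct",
        [(0.54, 0.22), (4.05, 56.96)],
    )
    def test_published_values(self, lam, expected_pct):
        p = QueueParameters(lam, 2.53, 2, 1)
        assert round(100 * overburdening_probability(p), 2) == expected_pct

    def test_no_arrivals(self):
        assert overburdening_probability(QueueParameters(0.0, 1.0, 2, 1)) == 0.0

    def test_saturated_system_is_certain(self):
        assert overburdening_probability(QueueParameters(5.13, 2.53, 2, 1)) == 1.0

    def test_mm1_equals_rho_squared(self):
        for rho in (0.1, 0.5, 0.9):
            p = QueueParameters(rho * 2.0, 2.0, 1, 1)
            assert overburdening_probability(p) == pytest.approx(rho**2, abs=1e-14)

    def test_brute_force_oracle_agreement(self, random_stable_params):
        for p in random_stable_params:
            weights = oracle_weights(
                p.arrival_rate, p.service_rate, p.calls_per_doctor, p.doctors, 10_000
            )
            brute = 1.0 - sum(weights[: p.channels + 1])
            assert overburdening_probability(p) == pytest.approx(brute, abs=1e-10)

    def test_monotone_in_arrival_rate(self):
        probs = [
            overburdening_probability(QueueParameters(lam, 2.53, 2, 1))
            for lam in np.linspace(0.1, 4.9, 25)
        ]
        assert all(a < b for a, b in zip(probs, probs[1:]))

    def test_monotone_in_service_rate(self):
        probs = [
            overburdening_probability(QueueParameters(2.0, mu, 2, 1))
            for mu in np.linspace(1.2, 5.0, 20)
        ]
        assert all(a > b for a, b in zip(probs, probs[1:]))

    def test_monotone_in_doctors(self):
        probs = [
            overburdening_probability(QueueParameters(2.0, 2.53, 2, n))
            for n in range(1, 7)
        ]
        assert all(a > b for a, b in zip(probs, probs[1:]))


class TestErlangC:
    def test_mm1_equals_rho(self):
        p = QueueParameters(1.0, 2.0, 1, 1)
        assert erlang_c_waiting_probability(p) == pytest.approx(0.5, abs=1e-14)

    def test_zero_arrivals(self):
        assert erlang_c_waiting_probability(QueueParameters(0.0, 2.0, 2, 1)) == 0.0

    def test_single_district_value(self):
        p = QueueParameters(0.27, 2.57, 2, 1)
        assert erlang_c_waiting_probability(p) == pytest.approx(0.00524320864230385, abs=1e-12)

    def test_saturation(self):
        assert erlang_c_waiting_probability(QueueParameters(10.0, 2.0, 2, 1)) == 1.0

    def test_dominates_overburdening(self, random_stable_params):
        for p in random_stable_params:
            assert erlang_c_waiting_probability(p) >= overburdening_probability(p)


class TestSolveArrivalRate:
    def test_published_ten_percent(self):
        lam = solve_arrival_rate(0.10, 2.53, 2, 1)
        assert lam == pytest.approx(2.0920240242, abs=1e-8)
        assert 2.092 <= lam <= 2.093

    def test_round_trip(self):
        lam = solve_arrival_rate(0.5696, 2.53, 2, 1)
        assert lam == pytest.approx(4.05, abs=1e-3)
        p = QueueParameters(lam, 2.53, 2, 1)
        assert overburdening_probability(p) == pytest.approx(0.5696, abs=1e-10)

    def test_small_target_small_rate(self):
        lam = solve_arrival_rate(1e-8, 2.53, 2, 1)
        assert 0.0 < lam < 0.01

    def test_invalid_targets(self):
        for bad in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(InvalidParameterError):
                solve_arrival_rate(bad, 2.53)


# ---------------------------------------------------------------------------
# property tests
# ---------------------------------------------------------------------------

stable_params = st.tuples(
    st.integers(1, 3),  # m
    st.integers(1, 4),  # n
    st.floats(0.3, 5.0),  # mu
    st.floats(0.01, 0.97),  # load fraction
).map(
    lambda t: QueueParameters(
        arrival_rate=t[3] * t[0] * t[1] * t[2],
        service_rate=t[2],
        calls_per_doctor=t[0],
        doctors=t[1],
    )
)


@settings(max_examples=150, deadline=None)
@given(stable_params)
def test_normalization_with_tail(p):
    dist = state_distribution(p, imax=p.channels + 40)
    assert dist.total == pytest.approx(1.0, abs=1e-12)


@settings(max_examples=150, deadline=None)
@given(stable_params)
def test_overburdening_in_unit_interval_and_dominated(p):
    ob = overburdening_probability(p)
    ec = erlang_c_waiting_probability(p)
    assert 0.0 <= ob <= ec <= 1.0


@settings(max_examples=80, deadline=None)
@given(stable_params, st.floats(1.01, 3.0))
def test_more_arrivals_more_overburdening(p, factor):
    lam2 = min(p.arrival_rate * factor, p.channels * p.service_rate * 0.999)
    p2 = QueueParameters(lam2, p.service_rate, p.calls_per_doctor, p.doctors)
    if lam2 > p.arrival_rate:
        assert overburdening_probability(p2) > overburdening_probability(p)


@settings(max_examples=60, deadline=None)
@given(st.floats(0.001, 0.999), st.floats(0.5, 4.0), st.integers(1, 3), st.integers(1, 3))
def test_solve_inverts_forward_map(target, mu, m, n):
    lam = solve_arrival_rate(target, mu, m, n)
    p = QueueParameters(lam, mu, m, n)
    assert overburdening_probability(p) == pytest.approx(target, abs=1e-9)
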