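"""Markov engine: rate conversion, transition structure, cohort trace."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ocddi import (
    OutcomeDistribution,
    RunSettings,
    build_transition_matrix,
    closed_form_up,
    expected_events,
    rate_to_prob,
    round_display,
    run_cohort_trace,
)

BASE_OUTCOMES = OutcomeDistribution(0.492, 0.350, 0.153, 0.005)


class TestRateToProb:
    def test_zero_rate_gives_zero(self):
        assert rate_to_prob(0.0, 1 / 12) == 0.0
        assert rate_to_prob(0.0, 10.0) == 0.0

    def test_monthly_probability_matches_arbitrary_precision_value(self):
        # independent evaluation of 1 - exp(-0.023/12) at high precision
        assert rate_to_prob(2.3, 1 / 12) == pytest.approx(
            0.00191483103406368, rel=1e-12
        )

    def test_annual_failures_round_to_published_count(self):
        assert round_display(1000 * rate_to_prob(2.3, 1.0)) == 23

    @pytest.mark.parametrize("rate, t", [(-1.0, 1.0), (1.0, 0.0), (1.0, -0.5)])
    def test_domain_errors(self, rate, t):
        with pytest.raises(ValueError):
            rate_to_prob(rate, t)

    @given(
        r1=st.floats(0, 100), r2=st.floats(0, 100),
        t=st.floats(1e-3, 10), dt=st.floats(0, 10),
    )
    @settings(max_examples=100, derandomize=True)
    def test_monotone_in_rate_and_time(self, r1, r2, t, dt):
        lo, hi = sorted((r1, r2))
        assert rate_to_prob(lo, t) <= rate_to_prob(hi, t)
        assert rate_to_prob(r1, t) <= rate_to_prob(r1, t + dt) < 1.0


class TestTransitionMatrix:
    def test_zero_failure_gives_identity(self):
        m = build_transition_matrix(0.0, BASE_OUTCOMES)
        assert np.array_equal(m.values, np.eye(5))

    def test_certain_failure_single_outcome(self):
        m = build_transition_matrix(1.0, OutcomeDistribution(1.0, 0.0, 0.0, 0.0))
        assert np.array_equal(m.values[0], [0.0, 1.0, 0.0, 0.0, 0.0])

    def test_base_case_row_entries_match_elementwise_products(self):
        # products recomputed independently at high precision
        m = build_transition_matrix(rate_to_prob(2.3, 1 / 12), BASE_OUTCOMES)
        assert m.values[0, 1:] == pytest.approx(
            [9.42096868759e-4, 6.70190861922e-4, 2.92969148212e-4, 9.57415517032e-6],
            rel=1e-9,
        )

    def test_rows_sum_to_one_and_absorbing(self):
        m = build_transition_matrix(0.37, BASE_OUTCOMES)
        assert np.allclose(m.values.sum(axis=1), 1.0, atol=1e-12)
        assert np.array_equal(m.values[1:], np.eye(5)[1:])

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            build_transition_matrix(1.5, BASE_OUTCOMES)
        with pytest.raises(ValueError):
            build_transition_matrix(0.5, OutcomeDistribution(0.5, 0.5, 0.5, 0.5))


class TestCohortTrace:
    def test_identity_matrix_trace_is_constant(self):
        m = build_transition_matrix(0.0, BASE_OUTCOMES)
        trace = run_cohort_trace(m, RunSettings())
        assert np.array_equal(trace.occupancy, np.tile(trace.occupancy[0], (13, 1)))

    def test_final_transient_occupancy_matches_geometric_decay(self):
        m = build_transition_matrix(rate_to_prob(2.3, 1 / 12), BASE_OUTCOMES)
        trace = run_cohort_trace(m, RunSettings())
        assert trace.occupancy[-1, 0] == pytest.approx(977.262483773, rel=1e-9)

    def test_trace_frame_exports_cycle_and_state_columns(self, tmp_path):
        m = build_transition_matrix(rate_to_prob(1.6, 1 / 12), BASE_OUTCOMES)
        trace = run_cohort_trace(m, RunSettings())
        path = tmp_path / "trace.csv"
        trace.to_csv(path)
        header = path.read_text().splitlines()[0]
        assert header == "cycle,initial,birth,induced_abortion,spontaneous_abortion,ectopic_pregnancy"

    @given(rate=st.floats(0, 100), n_cycles=st.integers(1, 120))
    @settings(max_examples=150, derandomize=True)
    def test_trace_equals_closed_form_conserves_and_monotone(self, rate, n_cycles):
        settings_ = RunSettings(cohort_size=1000, cycle_length=1 / 12, n_cycles=n_cycles)
        m = build_transition_matrix(
            rate_to_prob(rate, settings_.cycle_length), BASE_OUTCOMES
        )
        trace = run_cohort_trace(m, settings_)
        # conservation
        assert np.allclose(trace.occupancy.sum(axis=1), 1000.0, atol=1e-9)
        # absorbing occupancies non-decreasing, transient non-increasing
        diffs = np.diff(trace.occupancy, axis=0)
        assert (diffs[:, 1:] >= -1e-12).all()
        assert (diffs[:, 0] <= 1e-12).all()
        # closed-form equivalence
        up = expected_events(trace).total_up
        assert up == pytest.approx(closed_form_up(rate, settings_), rel=1e-9, abs=1e-12)
        # outcome shares equal the distribution at every cycle with absorption
        absorbed = trace.occupancy[:, 1:].sum(axis=1)
        mask = absorbed > 1e-12
        shares = trace.occupancy[mask][:, 1:] / absorbed[mask, None]
        assert np.allclose(shares, BASE_OUTCOMES.as_tuple(), atol=1e-9)


class TestExpectedEvents:
    def test_strategy2_births_and_ectopic_display(self):
        m = build_transition_matrix(rate_to_prob(2.3, 1 / 12), BASE_OUTCOMES)
        events = expected_events(run_cohort_trace(m, RunSettings()))
        assert events.by_outcome["birth"] == pytest.approx(11.19, abs=0.005)
        assert events.displayed_by_outcome["birth"] == 11
        assert events.by_outcome["ectopic_pregnancy"] == pytest.approx(0.114, abs=0.001)
        assert events.displayed_by_outcome["ectopic_pregnancy"] == 0

    def test_strategy1_total_up_displays_three(self):
        m = build_transition_matrix(rate_to_prob(0.3, 1 / 12), BASE_OUTCOMES)
        events = expected_events(run_cohort_trace(m, RunSettings()))
        assert events.displayed_total_up == 3

    def test_outcome_sum_equals_total(self):
        m = build_transition_matrix(rate_to_prob(1.8, 1 / 12), BASE_OUTCOMES)
        events = expected_events(run_cohort_trace(m, RunSettings()))
        assert math.fsum(events.by_outcome.values()) == pytest.approx(
            events.total_up, abs=1e-9
        )


class TestClosedForm:
    @pytest.mark.parametrize(
        "rate, expected, displayed",
        [(2.3, 22.7375162267, 23), (1.6, 15.8726799447, 16), (0.0, 0.0, 0)],
    )
    def test_values_and_display(self, rate, expected, displayed):
        up = closed_form_up(rate, RunSettings())
        assert up == pytest.approx(expected, rel=1e-9, abs=1e-12)
        assert round_display(up) == displayed

    @given(st.floats(0.01, 99), st.floats(0.02, 1))
    @settings(max_examples=50, derandomize=True)
    def test_strictly_increasing_in_rate(self, rate, bump):
        s = RunSettings()
        assert closed_form_up(rate + bump, s) > closed_form_up(rate, s)


class TestRoundDisplay:
    @pytest.mark.parametrize(
        "x, expected",
        [(0.4, 0), (0.5, 1), (1.5, 2), (2.5, 3), (11.19, 11), (3.48, 3), (-1.5, -2)],
    )
    def test_half_away_from_zero(self, x, expected):
        assert round_display(x) == expected
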