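"""Staircase engine: update rules, practice gate, traces, trial-log IO."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vibrodev.cohort import chance_observer, make_observer, perfect_observer
from vibrodev.config import ObserverConfig
from vibrodev.scoring import discrimination_threshold
from vibrodev.staircase import (
    TASK_ORDER,
    default_task_specs,
    read_trial_log,
    run_battery,
    run_practice,
    run_rt_task,
    run_staircase,
    simulate_trace_from_flags,
    update_staircase,
    write_trial_log,
)


class TestDefaultSpecs:
    def test_printed_parameters(self, specs):
        sq = specs["sqAD"]
        assert (sq.standard_amplitude, sq.comparison_start) == (200.0, 400.0)
        assert (sq.step_rule.kind, sq.step_rule.value) == ("additive", 20.0)
        assert (sq.start_value, sq.n_trials) == (200.0, 20)
        toj = specs["TOJ"]
        assert (toj.start_value, toj.n_trials) == (150.0, 20)
        assert (toj.step_rule.kind, toj.step_rule.value) == ("multiplicative", 0.15)
        dd = specs["DD"]
        assert (dd.standard_duration, dd.comparison_start) == (500.0, 750.0)
        assert (dd.step_rule.value, dd.start_value) == (25.0, 250.0)
        rt = specs["RT"]
        assert (rt.n_trials, rt.iti_range) == (10, (4000.0, 7000.0))
        assert (rt.stimulus_frequency, rt.standard_amplitude) == (25.0, 300.0)
        assert dd.stimulus_frequency == 40.0

    def test_trial_counts(self, specs):
        for name, spec in specs.items():
            assert spec.n_trials == (10 if name == "RT" else 20)


class TestUpdateStaircase:
    def test_multiplicative_decrease(self, specs):
        assert update_staircase(150.0, True, specs["TOJ"]) == pytest.approx(127.5)

    def test_additive_increase(self, specs):
        assert update_staircase(250.0, False, specs["DD"]) == pytest.approx(275.0)

    def test_clamped_at_floor(self, specs):
        assert update_staircase(40.0, True, specs["sqAD"]) == 20.0
        assert update_staircase(20.0, True, specs["sqAD"]) == 20.0

    @settings(derandomize=True, max_examples=200)
    @given(
        task=st.sampled_from(["sqAD", "smAD", "TOJ", "DD"]),
        value=st.floats(1.0, 500.0),
        correct=st.booleans(),
    )
    def test_update_stays_within_bounds(self, task, value, correct):
        spec = default_task_specs()[task]
        value = min(max(value, spec.lower_bound), spec.upper_bound)
        nxt = update_staircase(value, correct, spec)
        assert spec.lower_bound <= nxt <= spec.upper_bound


class TestPractice:
    def test_perfect_observer_passes_in_three(self, perfect, specs, rng):
        passed, attempts = run_practice(perfect, specs["TOJ"], rng)
        assert passed and attempts == 3

    def test_zero_comprehension_never_passes(self, specs, rng):
        obs = perfect_observer()
        obs = type(obs)(**{**obs.__dict__, "comprehension": {t: 0.0 for t in TASK_ORDER}})
        passed, attempts = run_practice(obs, specs["TOJ"], rng)
        assert not passed and attempts == 15
        trace = run_staircase(obs, specs["TOJ"], seed=0)
        assert not trace.completed and trace.failure_reason == "failed_practice"

    def test_practice_is_deterministic(self, specs):
        obs = make_observer(5.0, ObserverConfig(), seed=4)
        runs = [run_practice(obs, specs["TOJ"], np.random.default_rng(9)) for _ in range(2)]
        assert runs[0] == runs[1]


class TestRunStaircase:
    def test_perfect_toj_final_isis_are_geometric(self, perfect, specs):
        trace = run_staircase(perfect, specs["TOJ"], seed=0)
        expected = 150.0 * 0.85 ** np.arange(15, 20)
        assert trace.tracked_values[-5:] == pytest.approx(expected)

    def test_perfect_sqad_descends_and_clamps(self, perfect, specs):
        trace = run_staircase(perfect, specs["sqAD"], seed=0)
        values = trace.tracked_values
        assert values[:10] == pytest.approx(200.0 - 20.0 * np.arange(10))
        assert values[9:] == pytest.approx(np.full(11, 20.0))

    def test_always_wrong_replay_clamps_at_ceiling(self, specs):
        trace = simulate_trace_from_flags([False] * 20, specs["DD"])
        values = trace.tracked_values
        assert values[:11] == pytest.approx(250.0 + 25.0 * np.arange(11))
        assert values[10:] == pytest.approx(np.full(10, 500.0))

    def test_trace_is_deterministic_and_bounded(self, specs):
        obs = make_observer(6.0, ObserverConfig(), seed=13)
        t1 = run_staircase(obs, specs["DD"], seed=21)
        t2 = run_staircase(obs, specs["DD"], seed=21)
        assert t1.trials == t2.trials
        if t1.completed:
            assert np.all(t1.tracked_values >= specs["DD"].lower_bound)
            assert np.all(t1.tracked_values <= specs["DD"].upper_bound)

    def test_update_consistency_replay(self, specs):
        """Replaying the correctness flags reproduces the tracked sequence."""
        for seed in range(10):
            obs = make_observer(3.0 + seed * 2, ObserverConfig(), seed=seed)
            for task in ("sqAD", "TOJ", "DD"):
                trace = run_staircase(obs, specs[task], seed=[seed, 7])
                if not trace.completed:
                    continue
                flags = [t.correct for t in trace.trials]
                replay = simulate_trace_from_flags(flags, specs[task])
                assert replay.tracked_values == pytest.approx(trace.tracked_values)

    def test_finger_assignment_is_balanced(self, perfect, specs):
        trace = run_staircase(perfect, specs["TOJ"], seed=3)
        assigned = [t.assigned_finger for t in trace.trials]
        assert assigned.count("index") == assigned.count("middle") == 10

    def test_chance_vs_perfect_separation(self, specs):
        """A guessing observer's threshold estimate is far above a perfect
        observer's for every discrimination task (here >= 5x)."""
        perfect_vals = {
            task: discrimination_threshold(run_staircase(perfect_observer(), specs[task], seed=0))
            for task in ("sqAD", "smAD", "TOJ", "DD")
        }
        for task in ("sqAD", "smAD", "TOJ", "DD"):
            estimates = []
            for i in range(150):
                trace = run_staircase(chance_observer(observer_id=i), specs[task], seed=[40, i])
                if trace.completed:
                    estimates.append(discrimination_threshold(trace))
            assert np.mean(estimates) >= 5.0 * perfect_vals[task]


class TestRTTask:
    def test_degenerate_distribution_gives_identical_latencies(self, mid_child, specs):
        trace = run_rt_task(mid_child, specs["RT"], seed=0)
        assert trace.completed and len(trace.trials) == 10
        assert np.ptp(trace.latencies) == 0.0
        assert np.all(trace.latencies > 0)

    def test_itis_in_configured_range(self, mid_child, specs):
        trace = run_rt_task(mid_child, specs["RT"], seed=5)
        itis = np.array([t.iti_ms for t in trace.trials])
        assert np.all((itis >= 4000.0) & (itis <= 7000.0))

    def test_latency_vector_is_seed_deterministic(self, specs):
        obs = make_observer(8.0, ObserverConfig(), seed=2)
        a = run_rt_task(obs, specs["RT"], seed=77)
        b = run_rt_task(obs, specs["RT"], seed=77)
        assert a.latencies == pytest.approx(b.latencies)


class TestBattery:
    def test_full_battery_in_fixed_order(self, perfect):
        battery = run_battery(perfect, seed=0)
        assert list(battery.traces) == list(TASK_ORDER)
        assert all(t.completed for t in battery.traces.values())

    def test_failed_task_carries_reason(self):
        obs = perfect_observer()
        comp = {t: 1.0 for t in TASK_ORDER}
        comp["TOJ"] = 0.0
        obs = type(obs)(**{**obs.__dict__, "comprehension": comp})
        battery = run_battery(obs, seed=0)
        assert not battery.traces["TOJ"].completed
        assert battery.traces["TOJ"].failure_reason == "failed_practice"
        assert sum(t.completed for t in battery.traces.values()) == 4

    def test_battery_determinism(self):
        obs = make_observer(12.0, ObserverConfig(), seed=6)
        assert run_battery(obs, seed=5) == run_battery(obs, seed=5)


class TestTrialLogRoundTrip:
    def test_write_read_preserves_traces(self, tmp_path):
        observers = [make_observer(a, ObserverConfig(), seed=i, observer_id=i)
                     for i, a in enumerate([5.0, 11.0, 21.0])]
        batteries = [run_battery(obs, seed=3) for obs in observers]
        path = tmp_path / "log.csv"
        write_trial_log(batteries, path)
        restored = read_trial_log(path)
        assert len(restored) == 3
        for orig, back in zip(batteries, restored):
            assert back.age == pytest.approx(orig.age)
            for task, trace in orig.traces.items():
                if not trace.completed:
                    assert task not in back.traces or not back.traces[task].completed
                    continue
                rt = back.traces[task]
                assert rt.completed
                assert rt.tracked_values == pytest.approx(trace.tracked_values, nan_ok=True)
                assert rt.response_fingers == trace.response_fingers
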