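"""Tests for staircases, sessions, psychometric fits, and trial-log I/O."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import ndtr

from oriband.observers import analytic_threshold, ideal_template
from oriband.trials import (
    SessionConfig,
    TrialRecord,
    fit_psychometric,
    load_trials,
    make_staircase,
    run_fixed_contrast_session,
    run_session,
    save_trials,
    staircase_convergence,
    staircase_update,
    trials_to_frame,
)


def known_psychometric(mu=-1.0, sigma=0.15):
    return lambda x: 0.5 + 0.5 * ndtr((x - mu) / sigma)


class TestStaircaseUpdate:
    def test_two_down_one_up(self):
        s = make_staircase(2, -1.0)
        s = staircase_update(s, True)
        assert s.log_contrast == -1.0  # one correct is not enough
        s = staircase_update(s, True)
        assert s.log_contrast == pytest.approx(-1.1)  # second correct steps down

    def test_any_error_steps_up(self):
        s = make_staircase(4, -1.0)
        s = staircase_update(s, True)
        s = staircase_update(s, False)
        assert s.log_contrast == pytest.approx(-0.9)
        assert s.run_correct == 0

    def test_step_shrinks_after_two_reversals(self):
        s = make_staircase(2, -1.0, initial_step=0.1, final_step=0.05)
        for correct in (True, True, False, True, True):  # down, up (rev 1), down (rev 2)
            s = staircase_update(s, correct)
        assert s.n_reversals >= 2
        assert s.step == 0.05

    def test_update_after_completion_rejected(self):
        s = make_staircase(2, -1.0, max_trials=2)
        s = staircase_update(s, True)
        s = staircase_update(s, False)
        with pytest.raises(ValueError):
            staircase_update(s, True)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(outcomes=st.lists(st.booleans(), min_size=1, max_size=75))
    def test_invariants_hold_along_any_path(self, outcomes):
        s = make_staircase(2, -1.0)
        for correct in outcomes:
            s = staircase_update(s, correct)
            assert s.min_log_contrast <= s.log_contrast <= s.max_log_contrast
            assert 0 <= s.run_correct < s.n_down
            assert s.n_trials <= 75
        assert s.n_trials == len(outcomes)

    def test_fixed_points(self):
        """2-down/1-up converges on ~70.7% correct, 4-down/1-up on ~84.1%."""
        pc = known_psychometric()
        assert staircase_convergence(2, pc, rng=0) == pytest.approx(70.7, abs=1.5)
        assert staircase_convergence(4, pc, rng=0) == pytest.approx(84.1, abs=1.5)


class TestSessions:
    def test_session_structure(self, cond128, rng):
        obs = ideal_template(cond128.grid, cond128.filter_spec)
        trials = run_session(obs, cond128, SessionConfig(n_per_staircase=10), rng)
        assert len(trials) == 40
        ids, counts = np.unique([t.staircase for t in trials], return_counts=True)
        assert list(ids) == [0, 1, 2, 3]
        assert all(c == 10 for c in counts)
        assert all(t.correct == (t.choice == t.signal_interval) for t in trials)

    def test_balanced_intervals(self, cond128, rng):
        obs = ideal_template(cond128.grid, cond128.filter_spec)
        trials = run_session(obs, cond128, SessionConfig(n_per_staircase=10), rng)
        intervals = [t.signal_interval for t in trials]
        assert intervals.count(1) == intervals.count(2) == 20

    def test_deterministic_replay(self, cond128):
        obs = ideal_template(cond128.grid, cond128.filter_spec)
        cfg = SessionConfig(n_per_staircase=5)
        a = run_session(obs, cond128, cfg, rng=99)
        b = run_session(obs, cond128, cfg, rng=99)
        assert a == b

    def test_fixed_contrast_session_count_and_accuracy(self, cond128, rng):
        obs = ideal_template(cond128.grid, cond128.filter_spec)
        thr = analytic_threshold(obs, cond128)
        trials = run_fixed_contrast_session(obs, cond128, thr, 800, rng)
        assert len(trials) == 800
        acc = np.mean([t.correct for t in trials])
        assert acc == pytest.approx(0.75, abs=3 * np.sqrt(0.75 * 0.25 / 800) + 0.01)

    def test_no_interval_effect(self, cond128, rng):
        from scipy.stats import fisher_exact

        obs = ideal_template(cond128.grid, cond128.filter_spec)
        thr = analytic_threshold(obs, cond128)
        trials = run_fixed_contrast_session(obs, cond128, thr, 1500, rng)
        table = np.zeros((2, 2), dtype=int)
        for t in trials:
            table[t.signal_interval - 1, 0 if t.correct else 1] += 1
        assert fisher_exact(table).pvalue > 0.01

    def test_zero_weight_observer_at_chance(self, cond128, rng):
        from oriband.observers import TemplateObserver

        obs = TemplateObserver(np.zeros((128, 128)))
        trials = run_fixed_contrast_session(obs, cond128, 0.05, 1000, rng)
        acc = np.mean([t.correct for t in trials])
        # zero template always answers interval 1; balanced design gives 50%
        assert acc == pytest.approx(0.5, abs=0.02)


class TestPsychometricFit:
    @staticmethod
    def _simulate(mu, sigma, rng, n=300, levels=None):
        pc = known_psychometric(mu, sigma)
        if levels is None:
            levels = mu + sigma * np.array([-2, -1, 0, 1, 2])
        recs = []
        for x in levels:
            for _ in range(n // len(levels)):
                correct = bool(rng.random() < pc(x))
                recs.append(
                    TrialRecord("c", 0, 10.0**x, 1, 1 if correct else 2, correct, 0, 0, 0)
                )
        return recs

    def test_parameter_recovery(self, rng):
        fits = [
            fit_psychometric(self._simulate(-1.0, 0.15, rng, n=300)) for _ in range(10)
        ]
        mus = np.array([f.mu for f in fits])
        se = np.mean([f.se_mu for f in fits])
        assert abs(mus.mean() - (-1.0)) < 3 * se / np.sqrt(len(fits))

    def test_threshold_of_known_curve(self, rng):
        # with guess 0.5 and no lapses the 75% point is the location parameter
        recs = self._simulate(-1.0, 0.15, rng, n=4000)
        fit = fit_psychometric(recs, lapse=0.0)
        assert np.log10(fit.threshold_75) == pytest.approx(-1.0, abs=0.03)

    def test_more_trials_shrink_se(self, rng):
        se_small = np.mean(
            [fit_psychometric(self._simulate(-1.0, 0.15, rng, n=200)).se_mu for _ in range(5)]
        )
        se_large = np.mean(
            [fit_psychometric(self._simulate(-1.0, 0.15, rng, n=3200)).se_mu for _ in range(5)]
        )
        assert se_large < se_small

    def test_degenerate_data_raise(self):
        recs = [TrialRecord("c", 0, 0.1, 1, 1, True, 0, 0, 0)] * 10
        with pytest.raises(ValueError):
            fit_psychometric(recs)
        two_level = [
            TrialRecord("c", 0, 0.1, 1, 1, True, 0, 0, 0),
            TrialRecord("c", 0, 0.2, 1, 2, False, 0, 0, 0),
        ]
        # both outcomes at >= 2 levels is fittable
        fit_psychometric(two_level * 10)

    def test_single_level_raises(self):
        recs = [
            TrialRecord("c", 0, 0.1, 1, 1, bool(i % 2), 0, 0, 0) for i in range(20)
        ]
        with pytest.raises(ValueError, match="levels"):
            fit_psychometric(recs)


class TestTrialIO:
    def test_roundtrip(self, cond128, rng):
        obs = ideal_template(cond128.grid, cond128.filter_spec)
        trials = run_fixed_contrast_session(obs, cond128, 0.05, 20, rng)
        buf = io.StringIO()
        save_trials(trials, buf)
        buf.seek(0)
        assert load_trials(buf) == trials

    def test_frame_columns(self, cond128, rng):
        obs = ideal_template(cond128.grid, cond128.filter_spec)
        trials = run_fixed_contrast_session(obs, cond128, 0.05, 5, rng)
        df = trials_to_frame(trials)
        assert list(df.columns) == [
            "condition", "staircase", "contrast", "signal_interval",
            "choice", "correct", "seed1", "seed2", "signal_seed",
        ]
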