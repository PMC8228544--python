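"""Behavioral protocol: session structure, scoring, crossover, staircase."""

import numpy as np
import pandas as pd
import pytest

from soundsight.protocol import (GROUP_DURATIONS, GroupAssignment,
                                 SimulatedObserver, aggregate_groups,
                                 build_session, run_crossover,
                                 score_session, simulate_session,
                                 staircase_sensitivity)


class TestSessionPlan:
    def test_trial_counts(self, shape_set):
        plan = build_session(1, shape_set, seed=0)
        assert len(plan.training_trials) == 150
        assert len(plan.eval_trials) == 125

    def test_training_uses_15_images_10_times_each(self, shape_set):
        plan = build_session(2, shape_set, seed=1)
        ids, counts = np.unique(plan.training_trials, return_counts=True)
        assert len(ids) == 15
        assert np.all(counts == 10)
        basics = [i for i in plan.training_images
                  if shape_set.labels[i] % 5 == 0]
        assert len(basics) == 5

    def test_no_immediate_repetition_in_training(self, shape_set):
        plan = build_session(3, shape_set, seed=2)
        t = plan.training_trials
        assert all(t[i] != t[i - 1] for i in range(1, len(t)))

    def test_eval_covers_all_25_images_5_times(self, shape_set):
        plan = build_session(1, shape_set, seed=5)
        targets = [t.target for t in plan.eval_trials]
        ids, counts = np.unique(targets, return_counts=True)
        assert len(ids) == 25
        assert np.all(counts == 5)

    def test_options_distinct_and_contain_target(self, shape_set):
        plan = build_session(4, shape_set, seed=3)
        for trial in plan.eval_trials:
            assert len(set(trial.options)) == 4
            assert trial.options[trial.correct_option] == trial.target

    def test_target_slot_close_to_uniform(self, shape_set):
        slots = []
        for s in range(1, 6):
            plan = build_session(s, shape_set, seed=6)
            slots += [t.correct_option for t in plan.eval_trials]
        counts = np.bincount(slots, minlength=4)
        # 625 trials over 4 slots: each within 5 sd of 156.25
        assert np.all(np.abs(counts - len(slots) / 4)
                      < 5 * np.sqrt(len(slots) * 0.25 * 0.75))

    def test_deterministic_given_seed(self, shape_set):
        a = build_session(1, shape_set, seed=9)
        b = build_session(1, shape_set, seed=9)
        assert a.training_trials == b.training_trials
        assert [t.options for t in a.eval_trials] == \
            [t.options for t in b.eval_trials]

    def test_wrong_family_rejected(self):
        import soundsight as ss
        digits = ss.generate_digit_glyphs(3, seed=0, size=16)
        with pytest.raises(ValueError):
            build_session(1, digits, seed=0)


class TestScoring:
    def test_all_correct_scores_one(self, shape_set):
        plan = build_session(1, shape_set, seed=0)
        responses = [t.correct_option for t in plan.eval_trials]
        score = score_session(responses, plan)
        assert score.proportion_correct == 1.0
        assert score.n_trials == 125

    def test_missing_responses_listed(self, shape_set):
        plan = build_session(1, shape_set, seed=0)
        with pytest.raises(ValueError, match="missing responses"):
            score_session([0, 1, 2], plan)

    def test_uniform_random_observer_matches_binomial(self, shape_set):
        """Long-run mean 0.25 with binomial spread sqrt(.25*.75/125)."""
        plan = build_session(1, shape_set, seed=1)
        rng = np.random.default_rng(0)
        props = []
        for _ in range(400):
            responses = rng.integers(0, 4, 125).tolist()
            props.append(score_session(responses, plan).proportion_correct)
        assert np.mean(props) == pytest.approx(0.25, abs=0.01)
        assert np.std(props) == pytest.approx(np.sqrt(0.25 * 0.75 / 125),
                                              rel=0.25)

    def test_fixed_answer_exploits_nothing(self, shape_set):
        """Always answering slot 0 scores ~0.25 because the target slot is
        uniform."""
        correct = []
        for s in range(1, 6):
            for seed in range(10):
                plan = build_session(s, shape_set, seed=seed)
                correct.append(
                    score_session([0] * 125, plan).proportion_correct)
        assert np.mean(correct) == pytest.approx(0.25, abs=0.03)


class TestObserverAndCrossover:
    def test_naive_observer_is_at_chance(self, shape_set):
        plan = build_session(1, shape_set, seed=0)
        obs = SimulatedObserver(seed=0)          # skill 0, no training
        scores = run_crossover(obs, 1.0, [0.5, 1.0, 2.0], plan, seed=1)
        for s in scores.values():
            assert abs(s.proportion_correct - 0.25) < 0.15

    def test_training_raises_performance(self, shape_set):
        obs = SimulatedObserver(sensitivity=0.2, duration_midpoint=0.4,
                                learning_rate=0.02, seed=0)
        scores = []
        for s in range(1, 6):
            plan = build_session(s, shape_set, seed=3)
            scores.append(simulate_session(obs, plan, 1.0, seed=s)
                          .proportion_correct)
        assert scores[-1] > scores[0]
        assert scores[-1] > 0.5

    def test_duration_independent_observer_equal_within_binomial(self,
                                                                 shape_set):
        plan = build_session(1, shape_set, seed=2)
        obs = SimulatedObserver(sensitivity=np.inf, lapse=0.0, seed=0)
        obs.skill = 1.0
        scores = run_crossover(obs, 1.0, [0.5, 1.0, 2.0], plan, seed=4)
        vals = [s.proportion_correct for s in scores.values()]
        margin = 4 * np.sqrt(0.5 * 0.5 / 125)
        assert max(vals) - min(vals) < 2 * margin

    def test_three_durations_three_scores(self, shape_set):
        plan = build_session(1, shape_set, seed=0)
        obs = SimulatedObserver(seed=0)
        scores = run_crossover(obs, 0.5, [0.5, 1.0, 2.0], plan, seed=0)
        assert sorted(scores) == [0.5, 1.0, 2.0]
        assert all(s.proportion_correct >= 0.0 for s in scores.values())

    def test_unknown_duration_rejected(self, shape_set):
        plan = build_session(1, shape_set, seed=0)
        with pytest.raises(ValueError):
            run_crossover(SimulatedObserver(), 1.0, [0.7], plan, seed=0)


GRID = [0.7, 0.6, 0.5, 0.4, 0.3]


class TestStaircase:
    def test_hard_threshold_at_half_records_half(self):
        """Deterministic observer that recognizes durations >= 0.5 s fails
        at 70% and 60% compression and first succeeds at 50%."""
        obs = SimulatedObserver(sensitivity=0.0, duration_midpoint=0.5)
        df = staircase_sensitivity(obs, GRID, items_per_level=5, seed=0)
        assert np.all(df["sensitivity_score"] == 0.5)
        assert not df["floor_censored"].any()

    def test_always_recognizing_observer_scores_grid_top(self):
        obs = SimulatedObserver(sensitivity=0.0, duration_midpoint=0.0)
        df = staircase_sensitivity(obs, GRID, items_per_level=4, seed=0)
        assert np.all(df["sensitivity_score"] == 0.7)

    def test_never_recognizing_observer_is_floor_censored(self):
        obs = SimulatedObserver(sensitivity=0.0, duration_midpoint=10.0)
        df = staircase_sensitivity(obs, GRID, items_per_level=4, seed=0)
        assert np.all(df["sensitivity_score"] == 0.3)
        assert df["floor_censored"].all()

    def test_monotone_in_observer_sensitivity(self):
        """A strictly more sensitive observer (recognizes shorter
        durations) never scores lower on the same seed and grid."""
        for seed in range(5):
            strong = staircase_sensitivity(
                SimulatedObserver(sensitivity=0.1, duration_midpoint=0.3),
                GRID, items_per_level=20, seed=seed)
            weak = staircase_sensitivity(
                SimulatedObserver(sensitivity=0.1, duration_midpoint=0.6),
                GRID, items_per_level=20, seed=seed)
            assert np.all(strong["sensitivity_score"].to_numpy()
                          >= weak["sensitivity_score"].to_numpy())

    def test_empty_or_ascending_grid_rejected(self):
        with pytest.raises(ValueError):
            staircase_sensitivity(SimulatedObserver(), [], 3, seed=0)
        with pytest.raises(ValueError):
            staircase_sensitivity(SimulatedObserver(), [0.3, 0.5], 3, seed=0)


class TestAggregation:
    def _assignment(self):
        return GroupAssignment(entries=pd.DataFrame({
            "participant": ["p1", "p2", "p3", "p4", "p5"],
            "group": ["A", "A", "B", "B", "B"],
            "population": ["CB", "CB", "SU", "SU", "LB"],
        }))

    def test_known_means(self):
        scores = pd.DataFrame({
            "participant": ["p1", "p2", "p3", "p4", "p5"],
            "score": [0.5, 0.7, 0.4, 0.6, 0.9],
        })
        table = aggregate_groups(scores, self._assignment())
        cb_a = table[(table.group == "A") & (table.population == "CB")]
        assert cb_a["mean"].item() == pytest.approx(0.6)
        assert cb_a["n"].item() == 2
        su_b = table[(table.group == "B") & (table.population == "SU")]
        assert su_b["mean"].item() == pytest.approx(0.5)

    def test_identical_scores_zero_se(self):
        scores = pd.DataFrame({
            "participant": ["p1", "p2"],
            "score": [0.8, 0.8],
        })
        table = aggregate_groups(scores, self._assignment())
        assert table["se"].iloc[0] == 0.0

    def test_sighted_users_only_in_group_b(self):
        with pytest.raises(ValueError, match="Group B"):
            GroupAssignment(entries=pd.DataFrame({
                "participant": ["x"], "group": ["A"], "population": ["SU"],
            }))

    def test_group_durations_fixed(self):
        assert GROUP_DURATIONS == {"A": 0.5, "B": 1.0, "C": 2.0}
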