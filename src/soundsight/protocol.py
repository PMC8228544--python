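"""Behavioral-protocol machinery: training sessions, 4-AFC evaluation,
crossover testing and the descending-compression staircase.

The protocol mirrors a five-session training study on the 25-shape
stimulus set: each session trains on the 5 basic shapes plus 10 randomly
selected variants, each repeated 10 times (150 training trials), and
evaluates with 125 four-alternative forced-choice trials (all 25 shapes,
5 times each; chance level 0.25).  A parametric simulated observer stands
in for human participants so the machinery is testable end to end; it
models recognition probability as a logistic function of soundscape
duration scaled by a learned skill level, with a lapse rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stimuli import StimulusSet

__all__ = [
    "Trial4AFC",
    "SessionPlan",
    "GroupAssignment",
    "BehaviorScore",
    "SimulatedObserver",
    "build_session",
    "score_session",
    "simulate_session",
    "run_crossover",
    "staircase_sensitivity",
    "aggregate_groups",
    "GROUP_DURATIONS",
]

GROUP_DURATIONS = {"A": 0.5, "B": 1.0, "C": 2.0}
CHANCE_LEVEL = 0.25


@dataclass
class Trial4AFC:
    trial_id: int
    target: int                  # stimulus id
    options: tuple[int, int, int, int]   # 4 distinct stimulus ids
    correct_option: int          # index 0-3 of the target within options


@dataclass
class SessionPlan:
    session_index: int
    training_trials: list[int]          # 150 stimulus ids
    eval_trials: list[Trial4AFC]        # 125 4-AFC items
    training_images: list[int]          # the 15 ids used this session
    seed: int


@dataclass
class GroupAssignment:
    """Participant-to-group table: group letter -> soundscape duration."""

    entries: pd.DataFrame  # columns: participant, group, population

    def __post_init__(self):
        bad = set(self.entries["group"]) - set(GROUP_DURATIONS)
        if bad:
            raise ValueError(f"unknown groups {sorted(bad)}")
        su = self.entries[self.entries["population"] == "SU"]
        if not (su["group"] == "B").all():
            raise ValueError("sighted users (SU) appear only in Group B")


@dataclass
class BehaviorScore:
    proportion_correct: float
    n_trials: int
    chance_level: float = CHANCE_LEVEL
    per_image: dict = field(default_factory=dict)


@dataclass
class SimulatedObserver:
    """Parametric stand-in for a human participant.

    Recognition probability rises with soundscape duration through a
    logistic with midpoint ``duration_midpoint`` (seconds) and half-width
    ``sensitivity`` (seconds; 0 gives a hard threshold, ``inf`` gives
    duration-independent performance), scaled by a skill level in [0, 1]
    that grows with training exposure.  ``lapse`` caps performance below
    1.  In a 4-AFC trial the observer answers correctly with probability
    ``chance + (1 - chance - lapse) * skill * p_rec`` and otherwise guesses
    uniformly among the distractors.
    """

    sensitivity: float = 0.2
    duration_midpoint: float = 0.4
    learning_rate: float = 0.01
    lapse: float = 0.02
    chance: float = CHANCE_LEVEL
    seed: int = 0
    skill: float = 0.0

    def _p_recognize(self, duration: float) -> float:
        if self.sensitivity == 0:
            return 1.0 if duration >= self.duration_midpoint else 0.0
        if not np.isfinite(self.sensitivity):
            return 0.5
        x = (duration - self.duration_midpoint) / self.sensitivity
        return float(1.0 / (1.0 + np.exp(-x)))

    def p_correct_4afc(self, duration: float) -> float:
        return self.chance + (1.0 - self.chance - self.lapse) * \
            self.skill * self._p_recognize(duration)

    def train(self, plan: SessionPlan) -> None:
        """Exposure-driven skill growth over a session's training trials."""
        for _ in plan.training_trials:
            self.skill += (1.0 - self.skill) * self.learning_rate

    def respond(self, trial: Trial4AFC, duration: float,
                rng: np.random.Generator) -> int:
        if rng.uniform() < self.p_correct_4afc(duration):
            return trial.correct_option
        wrong = [i for i in range(4) if i != trial.correct_option]
        return int(rng.choice(wrong))

    def recognizes(self, duration: float, u: float) -> bool:
        """Single recognition attempt given a uniform draw ``u``."""
        return u < (1.0 - self.lapse) * self._p_recognize(duration) \
            if self.sensitivity != 0 else self._p_recognize(duration) >= 1.0


def _shuffle_no_repeat(items: list[int], rng: np.random.Generator,
                       max_tries: int = 200) -> list[int]:
    """Seeded shuffle with no identical neighbours (pseudo-random order)."""
    arr = list(items)
    for _ in range(max_tries):
        rng.shuffle(arr)
        bad = [i for i in range(1, len(arr)) if arr[i] == arr[i - 1]]
        if not bad:
            return arr
        # local repair: swap offenders with a random compatible slot
        for i in bad:
            for j in rng.permutation(len(arr)):
                if (arr[j] != arr[i]
                        and (j == 0 or arr[j - 1] != arr[i])
                        and (j + 1 >= len(arr) or arr[j + 1] != arr[i])
                        and (i == 0 or arr[i - 1] != arr[j])
                        and (i + 1 >= len(arr) or arr[i + 1] != arr[j])):
                    arr[i], arr[j] = arr[j], arr[i]
                    break
        if all(arr[i] != arr[i - 1] for i in range(1, len(arr))):
            return arr
    raise RuntimeError("could not build a no-repeat order")


def build_session(session_index: int, stimulus_set: StimulusSet,
                  seed: int) -> SessionPlan:
    """Build one training session plan.

    150 training trials (5 basic shapes + 10 seeded-random variants, each
    10 times, pseudo-random order without immediate repetition) and 125
    4-AFC evaluation trials (all 25 shapes 5 times each, three distractors
    drawn without replacement from the other 24, target slot uniform).
    """
    if stimulus_set.family != "shape":
        raise ValueError("session plans require the shape stimulus family")
    if len(stimulus_set) != 25:
        raise ValueError("shape stimulus set must contain 25 images")
    rng = np.random.default_rng([seed, session_index])
    basic_ids = [i for i, lab in enumerate(stimulus_set.labels)
                 if lab % 5 == 0]
    variant_ids = [i for i in range(25) if i not in basic_ids]
    chosen = sorted(rng.choice(variant_ids, size=10, replace=False).tolist())
    training_images = basic_ids + chosen
    training = _shuffle_no_repeat(training_images * 10, rng)

    eval_targets = _shuffle_no_repeat(list(range(25)) * 5, rng)
    trials = []
    for t, target in enumerate(eval_targets):
        others = [i for i in range(25) if i != target]
        distractors = rng.choice(others, size=3, replace=False).tolist()
        slot = int(rng.integers(4))
        options = distractors[:slot] + [target] + distractors[slot:]
        trials.append(Trial4AFC(trial_id=t, target=target,
                                options=tuple(options),
                                correct_option=slot))
    return SessionPlan(session_index=session_index,
                       training_trials=training, eval_trials=trials,
                       training_images=training_images, seed=seed)


def score_session(responses: list[int], plan: SessionPlan) -> BehaviorScore:
    """Proportion of correct 4-AFC answers, with per-image breakdown."""
    if len(responses) != len(plan.eval_trials):
        missing = [t.trial_id for t in plan.eval_trials[len(responses):]]
        raise ValueError(f"missing responses for trials {missing}")
    per_image: dict[int, list[int]] = {}
    n_correct = 0
    for resp, trial in zip(responses, plan.eval_trials):
        ok = int(resp == trial.correct_option)
        n_correct += ok
        per_image.setdefault(trial.target, []).append(ok)
    return BehaviorScore(
        proportion_correct=n_correct / len(plan.eval_trials),
        n_trials=len(plan.eval_trials),
        per_image={k: float(np.mean(v)) for k, v in per_image.items()})


def simulate_session(observer: SimulatedObserver, plan: SessionPlan,
                     duration: float, seed: int) -> BehaviorScore:
    """Train the observer on the plan, then run its evaluation phase."""
    observer.train(plan)
    rng = np.random.default_rng([seed, plan.session_index])
    responses = [observer.respond(t, duration, rng)
                 for t in plan.eval_trials]
    return score_session(responses, plan)


def run_crossover(observer: SimulatedObserver, trained_duration: float,
                  test_durations: list[float], plan: SessionPlan,
                  seed: int) -> dict[float, BehaviorScore]:
    """Evaluate a trained observer at every group's soundscape duration.

    The observer's state is frozen (no learning between blocks); one
    BehaviorScore per duration.
    """
    allowed = set(GROUP_DURATIONS.values())
    if not set(test_durations) <= allowed:
        raise ValueError(f"test durations must be within {sorted(allowed)}")
    scores = {}
    for di, duration in enumerate(test_durations):
        rng = np.random.default_rng([seed, di])
        responses = [observer.respond(t, duration, rng)
                     for t in plan.eval_trials]
        scores[duration] = score_session(responses, plan)
    return scores


def staircase_sensitivity(observer: SimulatedObserver,
                          ratio_grid: list[float], items_per_level: int,
                          seed: int, base_duration: float = 1.0
                          ) -> pd.DataFrame:
    """Descending-compression staircase.

    For each item, start at the highest compression ratio and step down
    the grid until the observer recognizes the item; record that ratio as
    the item's sensitivity score (grid floor, flagged ``floor_censored``,
    if recognition never succeeds).  Uniform draws are indexed by
    ``(seed, item, level)`` so that a strictly more sensitive observer
    can never score lower on the same seed and grid.
    """
    grid = [float(r) for r in ratio_grid]
    if not grid:
        raise ValueError("ratio grid is empty")
    if any(b >= a for a, b in zip(grid, grid[1:])):
        raise ValueError("ratio grid must be strictly descending")
    records = []
    for item in range(items_per_level):
        recorded, censored = grid[-1], True
        for level, ratio in enumerate(grid):
            u = float(np.random.default_rng([seed, item, level]).uniform())
            duration = base_duration * (1.0 - ratio)
            if observer.recognizes(duration, u):
                recorded, censored = ratio, False
                break
        records.append({"item": item, "sensitivity_score": recorded,
                        "floor_censored": censored})
    return pd.DataFrame(records)


def aggregate_groups(scores: pd.DataFrame, assignment: GroupAssignment
                     ) -> pd.DataFrame:
    """Mean and standard error per (group, population) cell.

    ``scores`` must have columns ``participant`` and ``score``; cells
    with no participants are omitted.
    """
    merged = scores.merge(assignment.entries, on="participant")
    rows = []
    for (group, pop), cell in merged.groupby(["group", "population"]):
        vals = cell["score"].to_numpy(dtype=float)
        se = float(vals.std(ddof=1) / np.sqrt(len(vals))) \
            if len(vals) > 1 else 0.0
        rows.append({"group": group, "population": pop,
                     "duration_s": GROUP_DURATIONS[group],
                     "n": len(vals), "mean": float(vals.mean()), "se": se})
    return pd.DataFrame(rows).sort_values(["group", "population"],
                                          ignore_index=True)
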