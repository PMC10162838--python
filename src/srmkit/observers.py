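"""Simulated listeners.

These close the loop for testing the procedures without human subjects.
Observers operate on trial parameters (gap in ms, modulation depth, TMR in
dB), not on rendered audio: they model the decision, not the ear.

* :class:`LogisticObserver` draws correct/incorrect from a logistic
  psychometric function with a guess rate (0.5 for the four-interval
  two-alternative tasks, 1/32 for the color x number response grid) and a
  lapse rate.  For log-domain tasks the logistic lives on the log of the
  parameter.
* :class:`StepObserver` is deterministic: correct iff the stimulus is at
  or easier than its true threshold.  It is the enumeration oracle for the
  progressive-track heuristic.

:func:`simulate_cohort` runs a whole battery twice per simulated
participant with between-subject and within-session parameter variance, so
the reliability statistics can be exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "LogisticObserver",
    "StepObserver",
    "respond",
    "simulate_cohort",
]


@dataclass(frozen=True)
class LogisticObserver:
    """Stochastic psychometric responder.

    ``midpoint`` is on the adapted scale (log of the parameter when
    ``log_domain``); ``spread`` is the logistic scale parameter on that
    same axis.  P(correct) = guess + (1 - guess - lapse) * F(x), with F
    the logistic cdf rising in ``easier_is_larger`` direction.
    """

    midpoint: float
    spread: float = 0.3
    guess: float = 0.5
    lapse: float = 0.0
    log_domain: bool = True
    easier_is_larger: bool = True

    def p_correct(self, value: float) -> float:
        x = np.log(value) if self.log_domain else value
        z = (x - self.midpoint) / self.spread
        if not self.easier_is_larger:
            z = -z
        f = 1.0 / (1.0 + np.exp(-z))
        return float(self.guess + (1.0 - self.guess - self.lapse) * f)


@dataclass(frozen=True)
class StepObserver:
    """Deterministic threshold rule: correct iff at-or-easier-than
    ``threshold`` (>= for TMR-like axes, <= would be a harder-is-larger
    axis flipped through ``easier_is_larger``)."""

    threshold: float
    easier_is_larger: bool = True

    def p_correct(self, value: float) -> float:
        if self.easier_is_larger:
            return 1.0 if value >= self.threshold else 0.0
        return 1.0 if value <= self.threshold else 0.0


def respond(
    observer,
    value: float,
    rng: np.random.Generator,
    grid: bool = False,
    answer_key: tuple | None = None,
    choices: list | None = None,
):
    """Draw one response from an observer.

    Returns a bare correct/incorrect flag for interval tasks.  With
    ``grid=True`` (the color/number response grid) an incorrect draw picks
    uniformly among the wrong cells, and the (response, correct) pair is
    returned; ``answer_key`` is the correct cell and ``choices`` the full
    grid.
    """
    correct = bool(rng.random() < observer.p_correct(value))
    if not grid:
        return correct
    if answer_key is None or choices is None:
        raise ValueError("grid responses need answer_key and choices")
    if correct:
        return answer_key, True
    wrong = [c for c in choices if c != answer_key]
    return wrong[rng.integers(len(wrong))], False


# ---------------------------------------------------------------------------
# Cohorts


@dataclass(frozen=True)
class CohortSpec:
    """Population of logistic observers for a battery of tasks.

    ``task_midpoints`` maps task id to the population-mean observer
    midpoint on the adapted scale.  Each simulated participant draws one
    midpoint offset per task (sd ``between_sd``), and each session adds an
    independent perturbation (sd ``within_sd``).
    """

    task_midpoints: dict[str, float]
    between_sd: float = 0.5
    within_sd: float = 0.1
    spread: float = 0.3
    lapse: float = 0.0
    #: "logistic" for stochastic responders, "step" for deterministic ones
    #: (step thresholds sit at the midpoint, back-transformed for log tasks)
    observer_kind: str = "logistic"


def simulate_cohort(
    battery_config,
    cohort: CohortSpec,
    n_participants: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Run every participant through the battery twice.

    Returns a tidy frame with one row per participant x session x task
    threshold (columns: participant, session, task, threshold), suitable
    for the test-retest reliability statistics.
    """
    from .battery import SPEECH_TASKS, run_battery, task_domain  # deferred import

    if n_participants < 2:
        raise ValueError("need at least 2 participants")
    # restrict the battery to the tasks the cohort models, and build the
    # corpus once so every session shares it
    covered = tuple(t for t in battery_config.tasks if t in cohort.task_midpoints)
    battery_config = replace(
        battery_config,
        tasks=covered,
        familiarization=tuple(
            t for t in battery_config.familiarization if t in cohort.task_midpoints
        ),
    )
    battery_config.ensure_corpus()
    root = np.random.SeedSequence(seed)
    rows = []
    for p_idx, p_seq in enumerate(root.spawn(n_participants)):
        p_rng = np.random.default_rng(p_seq)
        subject_offsets = {
            task: p_rng.normal(0.0, cohort.between_sd)
            for task in cohort.task_midpoints
        }
        for session in (1, 2):
            s_rng = np.random.default_rng(
                np.random.SeedSequence([seed, p_idx, session])
            )
            observers = {}
            for task, mid in cohort.task_midpoints.items():
                jitter = s_rng.normal(0.0, cohort.within_sd) if cohort.within_sd else 0.0
                guess = 1.0 / 32.0 if task in SPEECH_TASKS else 0.5
                log_dom = task_domain(task) == "log"
                midpoint = mid + subject_offsets[task] + jitter
                if cohort.observer_kind == "step":
                    observers[task] = StepObserver(
                        threshold=float(np.exp(midpoint)) if log_dom else midpoint
                    )
                else:
                    observers[task] = LogisticObserver(
                        midpoint=midpoint,
                        spread=cohort.spread,
                        guess=guess,
                        lapse=cohort.lapse,
                        log_domain=log_dom,
                    )
            result = run_battery(
                battery_config,
                observers,
                participant=p_idx,
                session=session,
                seed=int(s_rng.integers(2**31 - 1)),
            )
            for task, thr in result.thresholds.items():
                rows.append(
                    {"participant": p_idx, "session": session,
                     "task": task, "threshold": thr}
                )
            if result.srm is not None:
                rows.append(
                    {"participant": p_idx, "session": session,
                     "task": "srm", "threshold": result.srm}
                )
    return pd.DataFrame(rows)
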