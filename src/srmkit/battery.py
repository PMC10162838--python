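"""Task definitions, trial construction, and session orchestration.

Binds stimuli and adaptive procedures into the battery's tasks:

====================  =============================================  ============
task id               stimulus / adapted parameter                   procedure
====================  =============================================  ============
tone_quiet            2 kHz tone level in quiet (dB)                 staircase
tone_in_noise         2 kHz tone level in white noise (dB)           staircase
gap                   silent gap between two clicks (ms)             staircase
fm_diotic             FM depth, same modulator both ears (Hz)        staircase
fm_dichotic           FM depth, antiphase modulators (Hz)            staircase
tm / sm / stm         noise modulation depth M (dB)                  staircase
srm_colocated         speech-on-speech TMR, maskers at 0 deg         progressive
srm_separated         speech-on-speech TMR, maskers at +/-45 deg     progressive
====================  =============================================  ============

The non-speech tasks use a four-interval two-alternative trial (intervals
1 and 4 are standards; the target hides in interval 2 or 3).  The speech
tasks use the color x number response grid, a fixed "Carlos" target
callsign, and two masker sentences that share no callsign, color, number,
or talker with the target or each other.

Sessions are fully reproducible: (config, participant, session, seed)
determines every stimulus parameter and log row.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

from .adaptive import (
    ProgressiveConfig,
    StaircaseConfig,
    StaircaseState,
    progressive_schedule,
    progressive_threshold,
    staircase_threshold,
    staircase_update,
)
from .audio import DEFAULT_CONVENTION, DEFAULT_RATE, AudioBuffer, LevelConvention
from .corpus import (
    COLORS,
    NUMBERS,
    TARGET_CALLSIGN,
    CorpusManifest,
    SentenceKey,
    build_corpus,
)
from .signals import (
    ClickSpec,
    FMSpec,
    FM_ROVE_HI,
    FM_ROVE_LO,
    RippleSpec,
    synth_fm_tone,
    synth_gap_stimulus,
    synth_ripple_noise,
    synth_tone,
)
from .spatial import HRIRSet, SpatialScene, make_fixture_hrir, mix_scene

__all__ = [
    "NONSPEECH_TASKS",
    "SPEECH_TASKS",
    "TaskSpec",
    "TrialRecord",
    "SessionResult",
    "BatteryConfig",
    "default_task",
    "make_afc_trial",
    "make_srm_trial",
    "score_srm_response",
    "run_task",
    "run_battery",
]

GRID_CHOICES = [(c, n) for c in COLORS for n in NUMBERS]

NONSPEECH_TASKS = (
    "tone_quiet", "tone_in_noise", "gap", "fm_diotic", "fm_dichotic",
    "tm", "sm", "stm",
)
SPEECH_TASKS = ("srm_colocated", "srm_separated")
FAMILIARIZATION_TASKS = ("tone_quiet", "tone_in_noise")

ONE_SAMPLE_MS = 1000.0 / DEFAULT_RATE


@dataclass(frozen=True)
class TaskSpec:
    """One task: its id, procedure, and stimulus parameters."""

    task_id: str
    procedure: str  # "staircase" | "progressive"
    staircase: StaircaseConfig | None = None
    progressive: ProgressiveConfig | None = None
    structure: str = "4I-2AFC"  # or "grid"


def default_task(task_id: str) -> TaskSpec:
    """Task parameterized at the battery's standard values."""
    if task_id == "gap":
        cfg = StaircaseConfig(
            start_value=20.0, domain="log",
            stage1_down_step=2.0**0.5, stage2_down_step=2.0**0.1,
            floor=ONE_SAMPLE_MS, ceiling=500.0,
        )
    elif task_id in ("fm_diotic", "fm_dichotic"):
        cfg = StaircaseConfig(
            start_value=6.0, domain="log",
            stage1_down_step=2.0**0.5, stage2_down_step=2.0**0.1,
            floor=0.01, ceiling=400.0,
        )
    elif task_id in ("tm", "sm", "stm"):
        cfg = StaircaseConfig(
            start_value=6.0, domain="linear",
            stage1_down_step=0.5, stage2_down_step=0.1,
            floor=0.01, ceiling=40.0,
        )
    elif task_id in ("tone_quiet", "tone_in_noise"):
        # familiarization defaults (level dB above reference threshold);
        # not specified by the validated battery, chosen here
        cfg = StaircaseConfig(
            start_value=40.0, domain="linear",
            stage1_down_step=4.0, stage2_down_step=1.0,
            floor=1.0, ceiling=90.0,
        )
    elif task_id in SPEECH_TASKS:
        return TaskSpec(task_id, "progressive",
                        progressive=ProgressiveConfig(), structure="grid")
    else:
        raise ValueError(f"unknown task id {task_id!r}")
    return TaskSpec(task_id, "staircase", staircase=cfg)


def task_domain(task_id: str) -> str:
    """Adapted-parameter domain of a task ('log' or 'linear')."""
    spec = default_task(task_id)
    if spec.procedure == "progressive":
        return "linear"
    return spec.staircase.domain


# ---------------------------------------------------------------------------
# Non-speech trials


@dataclass(frozen=True)
class AfcTrial:
    """Four-interval trial: parameter value per interval plus target slot."""

    values: tuple[float, float, float, float]
    target_position: int  # 1 or 2 (0-based index into the four intervals)
    carriers: tuple[float, float, float, float] | None = None
    seed: int = 0


def make_afc_trial(
    task: TaskSpec, value: float, seed: int
) -> AfcTrial:
    """Lay out the four intervals [standard, X, Y, standard].

    The target (parameter at ``value``) lands at position 2 or 3 (indices
    1 or 2) uniformly at random; the other test interval is a standard.
    For the FM tasks a carrier frequency is re-drawn per interval from the
    460-550 Hz rove.
    """
    rng = np.random.default_rng(np.random.SeedSequence([abs(seed), 17]))
    pos = int(rng.integers(1, 3))
    values = [0.0, 0.0, 0.0, 0.0]
    values[pos] = value
    carriers = None
    if task.task_id.startswith("fm"):
        carriers = tuple(float(rng.uniform(FM_ROVE_LO, FM_ROVE_HI)) for _ in range(4))
    return AfcTrial(tuple(values), pos, carriers, seed)


def render_afc_interval(
    task: TaskSpec,
    trial: AfcTrial,
    interval: int,
    convention: LevelConvention = DEFAULT_CONVENTION,
    rate: int = DEFAULT_RATE,
) -> AudioBuffer:
    """Synthesize the audio for one interval of a non-speech trial."""
    value = trial.values[interval]
    tid = task.task_id
    if tid == "gap":
        return synth_gap_stimulus(ClickSpec(), value, convention, rate)
    if tid.startswith("fm"):
        carrier = trial.carriers[interval]
        spec = FMSpec(carrier_hz=carrier, depth_hz=value,
                      dichotic=(tid == "fm_dichotic"))
        return synth_fm_tone(spec, 400.0, 75.0, convention, rate)
    if tid in ("tm", "sm", "stm"):
        spec = RippleSpec(
            tm_rate_hz=4.0 if tid in ("tm", "stm") else 0.0,
            sm_density_cpo=2.0 if tid in ("sm", "stm") else 0.0,
            depth_m_db=value,
        )
        return synth_ripple_noise(
            spec, seed=np.random.SeedSequence([abs(trial.seed), interval]),
            rate=rate, convention=convention,
        )
    if tid in ("tone_quiet", "tone_in_noise"):
        if value <= 0:
            return AudioBuffer(np.zeros(int(0.5 * rate)), rate)
        return synth_tone(2000.0, 500.0, value, convention, rate)
    raise ValueError(f"no renderer for task {tid!r}")


# ---------------------------------------------------------------------------
# Speech trials


@dataclass(frozen=True)
class SrmTrial:
    """One speech trial: the scene, its answer key, and bookkeeping."""

    scene: SpatialScene
    answer_key: tuple[str, int]  # (color, number) of the target sentence
    target_key: SentenceKey
    masker_keys: tuple[SentenceKey, SentenceKey]
    tmr_db: float


def make_srm_trial(
    manifest: CorpusManifest,
    condition: str,
    trial_index: int,
    config: ProgressiveConfig,
    seed: int,
) -> SrmTrial:
    """Draw target and masker sentences for one progressive-track trial.

    The target talker, color, and number are uniform draws with the fixed
    "Carlos" callsign; the two maskers are drawn without repetition so the
    three sentences share no callsign, color, number, or talker.  Levels
    come from the schedule row for ``trial_index`` (1-based); azimuths are
    0/0/0 (colocated) or 0/-45/+45 (separated).
    """
    if condition not in ("colocated", "separated"):
        raise ValueError(f"condition must be colocated|separated, got {condition!r}")
    talkers = manifest.talkers
    if len(talkers) < 3:
        raise ValueError(f"corpus has {len(talkers)} talkers; need >= 3")
    rng = np.random.default_rng(np.random.SeedSequence([abs(seed), trial_index]))

    callsigns = sorted(set(manifest.entries.callsign))
    colors = sorted(set(manifest.entries.color))
    numbers = sorted(set(manifest.entries.number))

    t_key = SentenceKey(
        TARGET_CALLSIGN,
        colors[rng.integers(len(colors))],
        int(numbers[rng.integers(len(numbers))]),
        int(talkers[rng.integers(len(talkers))]),
    )
    used_callsigns = {t_key.callsign}
    used_colors = {t_key.color}
    used_numbers = {t_key.number}
    used_talkers = {t_key.talker}
    masker_keys = []
    for _ in range(2):
        cs = rng.choice(sorted(set(callsigns) - used_callsigns))
        col = rng.choice(sorted(set(colors) - used_colors))
        num = int(rng.choice(sorted(set(numbers) - used_numbers)))
        tal = int(rng.choice(sorted(set(talkers) - used_talkers)))
        masker_keys.append(SentenceKey(str(cs), str(col), num, tal))
        used_callsigns.add(str(cs))
        used_colors.add(str(col))
        used_numbers.add(num)
        used_talkers.add(tal)

    sched = progressive_schedule(config)
    row = sched[sched.trial == trial_index]
    if row.empty:
        raise ValueError(f"trial_index {trial_index} outside the schedule")
    masker_level = float(row.iloc[0].masker_db_spl)
    tmr = float(row.iloc[0].tmr_db)

    masker_az = (0.0, 0.0) if condition == "colocated" else (-45.0, 45.0)
    scene = SpatialScene(
        target=(manifest.get_audio(t_key), 0.0, config.target_level_db_spl),
        maskers=[
            (manifest.get_audio(masker_keys[0]), masker_az[0], masker_level),
            (manifest.get_audio(masker_keys[1]), masker_az[1], masker_level),
        ],
    )
    return SrmTrial(scene, (t_key.color, t_key.number), t_key,
                    tuple(masker_keys), tmr)


def score_srm_response(answer_key: tuple[str, int], response: tuple[str, int]) -> bool:
    """Correct iff both the color and the number match the target."""
    if (
        not isinstance(response, tuple)
        or len(response) != 2
        or response[0] not in COLORS
        or response[1] not in NUMBERS
    ):
        raise ValueError(f"response must be a (color, number) grid cell, got {response!r}")
    return tuple(answer_key) == tuple(response)


# ---------------------------------------------------------------------------
# Running tasks and sessions


@dataclass
class TrialRecord:
    """One logged trial."""

    task: str
    trial: int
    value: float  # adapted parameter (gap ms, depth, or TMR dB)
    target: str
    response: str
    correct: bool
    seed: int


def run_task(
    task: TaskSpec,
    responder,
    seed: int,
    corpus: CorpusManifest | None = None,
    hrirs: HRIRSet | None = None,
) -> tuple[float, list[TrialRecord]]:
    """Run one task to completion against a responder.

    ``responder`` is an observer with a ``p_correct(value)`` method (see
    :mod:`srmkit.observers`) or any object exposing that interface.
    Staircase tasks run until the track finishes and report the
    geometric-mean threshold; speech tasks run the 20-trial progressive
    schedule and report the error-count heuristic.
    """
    from .observers import respond  # local import keeps module layering simple

    rng = np.random.default_rng(np.random.SeedSequence([abs(seed), 101]))
    records: list[TrialRecord] = []

    if task.procedure == "staircase":
        cfg = task.staircase
        state = StaircaseState.fresh(cfg)
        while not state.finished:
            trial_seed = int(rng.integers(2**31 - 1))
            trial = make_afc_trial(task, state.value, trial_seed)
            correct = respond(responder, state.value, rng)
            records.append(
                TrialRecord(task.task_id, state.n_trials + 1, state.value,
                            f"interval_{trial.target_position + 1}",
                            "correct" if correct else "incorrect",
                            correct, trial_seed)
            )
            staircase_update(state, cfg, correct)
        return staircase_threshold(state, cfg), records

    if task.procedure == "progressive":
        if corpus is None:
            raise ValueError("speech tasks need a corpus manifest")
        cfg = task.progressive
        condition = "colocated" if task.task_id == "srm_colocated" else "separated"
        n_errors = 0
        for i in range(1, cfg.n_trials + 1):
            trial_seed = int(rng.integers(2**31 - 1))
            srm_trial = make_srm_trial(corpus, condition, i, cfg, trial_seed)
            response, correct = respond(
                responder, srm_trial.tmr_db, rng, grid=True,
                answer_key=srm_trial.answer_key, choices=GRID_CHOICES,
            )
            if not correct:
                n_errors += 1
            records.append(
                TrialRecord(task.task_id, i, srm_trial.tmr_db,
                            f"{srm_trial.answer_key[0]}_{srm_trial.answer_key[1]}",
                            f"{response[0]}_{response[1]}", correct, trial_seed)
            )
        return progressive_threshold(n_errors, cfg), records

    raise ValueError(f"unknown procedure {task.procedure!r}")


@dataclass
class SessionResult:
    """Per-task thresholds for one (participant, session) run."""

    participant: int
    session: int
    thresholds: dict[str, float]
    srm: float | None
    task_order: list[str]
    trials: pd.DataFrame
    failures: dict[str, str] = field(default_factory=dict)
    schema_version: str = "1"


@dataclass
class BatteryConfig:
    """Which tasks to run and how to source the corpus."""

    tasks: tuple[str, ...] = NONSPEECH_TASKS[2:] + SPEECH_TASKS  # post-familiarization
    familiarization: tuple[str, ...] = FAMILIARIZATION_TASKS
    talkers: int = 4
    corpus_seed: int = 0
    corpus: CorpusManifest | None = None
    schema_version: str = "1"

    def ensure_corpus(self) -> CorpusManifest | None:
        if any(t in SPEECH_TASKS for t in self.tasks) and self.corpus is None:
            self.corpus = build_corpus(self.talkers, self.corpus_seed)
        return self.corpus


def counterbalanced_order(config: BatteryConfig, participant: int, session: int) -> list[str]:
    """Deterministic task order: familiarization first, then the speech and
    non-speech blocks swapped by (participant + session) parity."""
    speech = [t for t in config.tasks if t in SPEECH_TASKS]
    nonspeech = [t for t in config.tasks if t not in SPEECH_TASKS]
    blocks = [nonspeech, speech] if (participant + session) % 2 == 0 else [speech, nonspeech]
    return list(config.familiarization) + [t for block in blocks for t in block]


def run_battery(
    config: BatteryConfig,
    responders,
    participant: int = 0,
    session: int = 1,
    seed: int = 0,
) -> SessionResult:
    """Run a full session.

    ``responders`` maps task id to an observer (a single observer is
    broadcast to every task).  Familiarization tone tasks run first; the
    remaining blocks follow the counterbalanced order.  SRM = colocated
    threshold - separated threshold is attached when both speech
    conditions completed.  A task failure is recorded and the battery
    continues.
    """
    corpus = config.ensure_corpus()
    order = counterbalanced_order(config, participant, session)
    thresholds: dict[str, float] = {}
    failures: dict[str, str] = {}
    all_records: list[TrialRecord] = []
    root = np.random.SeedSequence([abs(seed), participant, session])
    task_seeds = {t: int(s.generate_state(1)[0] % (2**31 - 1))
                  for t, s in zip(order, root.spawn(len(order)))}
    for task_id in order:
        responder = responders[task_id] if isinstance(responders, dict) else responders
        try:
            thr, records = run_task(
                default_task(task_id), responder, task_seeds[task_id], corpus=corpus
            )
        except Exception as exc:  # record and continue with the rest
            failures[task_id] = f"{type(exc).__name__}: {exc}"
            continue
        thresholds[task_id] = thr
        all_records.extend(records)

    srm = None
    if "srm_colocated" in thresholds and "srm_separated" in thresholds:
        srm = thresholds["srm_colocated"] - thresholds["srm_separated"]
    trials = pd.DataFrame([r.__dict__ for r in all_records])
    return SessionResult(participant, session, thresholds, srm, order,
                         trials, failures, config.schema_version)
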