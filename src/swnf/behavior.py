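"""Color-word Stroop task (CWST) scheduling and scoring.

The behavioral test runs 18 blocks of 5 trials.  Each block shows an
emotional priming picture (2 s), a blank (1 s), then trials of fixation
(0.5 s) + colored word (1.1 s); blocks end with a 17-21 s rest.  Positive
and negative primes are balanced 9/9.  With the mean rest of 19 s the whole
test takes 9 minutes.

Scoring: accuracy in percent over all trials; per-condition mean RT over
correct trials only (no outlier trimming); Stroop effect = mean incongruent
RT - mean congruent RT; Delta metrics subtract pretest from a later test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TaskSchedule",
    "StroopSummary",
    "TRIAL_TIMINGS_S",
    "build_schedule",
    "schedule_duration",
    "score_test",
    "score_dataset",
    "delta_metrics",
]

N_BLOCKS = 18
TRIALS_PER_BLOCK = 5
CONDITIONS = ("congruent", "incongruent", "neutral")

TRIAL_TIMINGS_S = {
    "prime": 2.0,
    "blank": 1.0,
    "fixation": 0.5,   # per trial (see docs/methods.md for the alternative)
    "word": 1.1,
    "rest_range": (17.0, 21.0),
}


@dataclass(frozen=True)
class TaskSchedule:
    conditions: tuple      # N_BLOCKS x TRIALS_PER_BLOCK condition labels
    valences: tuple        # one prime valence per block, 9/9 balanced
    rests_s: tuple         # one rest duration per block
    fixation_per_trial: bool
    seed: int


def build_schedule(seed: int = 0,
                   fixation_per_trial: bool = True) -> TaskSchedule:
    """Pseudorandom, valence-balanced CWST schedule (90 trials)."""
    rng = np.random.default_rng(seed)
    conds = np.repeat(CONDITIONS, N_BLOCKS * TRIALS_PER_BLOCK // 3)
    rng.shuffle(conds)
    conds = conds.reshape(N_BLOCKS, TRIALS_PER_BLOCK)
    valence = np.repeat(["positive", "negative"], N_BLOCKS // 2)
    rng.shuffle(valence)
    rests = rng.uniform(*TRIAL_TIMINGS_S["rest_range"], size=N_BLOCKS)
    return TaskSchedule(tuple(map(tuple, conds)), tuple(valence),
                        tuple(rests), fixation_per_trial, int(seed))


def schedule_duration(schedule: TaskSchedule | None = None,
                      mean_rest_s: float | None = 19.0,
                      n_blocks: int = N_BLOCKS) -> float:
    """Total duration in minutes.

    With ``mean_rest_s`` given, that value replaces the schedule's drawn
    rests (the protocol-arithmetic view); pass None to sum the actual
    rests.  ``mean_rest_s=0`` gives the task-only duration.
    """
    t = TRIAL_TIMINGS_S
    per_trial = t["fixation"] + t["word"]
    fixed = t["prime"] + t["blank"] + TRIALS_PER_BLOCK * per_trial
    if schedule is not None and not schedule.fixation_per_trial:
        fixed = (t["prime"] + t["blank"] + t["fixation"]
                 + TRIALS_PER_BLOCK * t["word"])
    if mean_rest_s is None:
        if schedule is None:
            raise ValueError("need a schedule to sum drawn rests")
        total = fixed * n_blocks + sum(schedule.rests_s[:n_blocks])
    else:
        total = (fixed + mean_rest_s) * n_blocks
    return total / 60.0


@dataclass(frozen=True)
class StroopSummary:
    subject: int
    day: str
    accuracy_pct: float
    rt_ms: dict            # condition -> mean correct-trial RT
    stroop_effect_ms: float


def score_test(trials: pd.DataFrame) -> StroopSummary:
    """Score one subject's one test day from its trial table."""
    for col in ("subject", "day", "condition", "rt_ms", "correct"):
        if col not in trials.columns:
            raise ValueError(f"trial table lacks column {col!r}")
    subjects = trials["subject"].unique()
    days = trials["day"].unique()
    if len(subjects) != 1 or len(days) != 1:
        raise ValueError("score_test expects a single subject and day")
    acc = 100.0 * trials["correct"].mean()
    correct = trials[trials["correct"] == 1]
    rt = {}
    for cond in CONDITIONS:
        sel = correct[correct["condition"] == cond]
        if sel.empty:
            raise ValueError(f"no correct trials in condition {cond!r}")
        rt[cond] = float(sel["rt_ms"].mean())
    return StroopSummary(subject=int(subjects[0]), day=str(days[0]),
                         accuracy_pct=float(acc), rt_ms=rt,
                         stroop_effect_ms=rt["incongruent"] - rt["congruent"])


def score_dataset(trials: pd.DataFrame) -> pd.DataFrame:
    """Score every (subject, day) cell of a trial table."""
    rows = []
    for (subject, day), grp in trials.groupby(["subject", "day"],
                                              sort=False):
        s = score_test(grp)
        rows.append({"subject": subject, "day": day,
                     "accuracy_pct": s.accuracy_pct,
                     "rt_congruent": s.rt_ms["congruent"],
                     "rt_incongruent": s.rt_ms["incongruent"],
                     "rt_neutral": s.rt_ms["neutral"],
                     "stroop_effect_ms": s.stroop_effect_ms})
    return pd.DataFrame(rows)


def delta_metrics(pre: StroopSummary, post: StroopSummary) -> dict:
    """post - pre changes: accuracy, neutral RT, Stroop effect."""
    if pre.subject != post.subject:
        raise ValueError(f"subject mismatch: {pre.subject} vs {post.subject}")
    return {
        "subject": pre.subject,
        "delta_acc_pct": post.accuracy_pct - pre.accuracy_pct,
        "delta_rt_neutral_ms": post.rt_ms["neutral"] - pre.rt_ms["neutral"],
        "delta_stroop_ms": post.stroop_effect_ms - pre.stroop_effect_ms,
    }
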