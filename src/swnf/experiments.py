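"""End-to-end experiment recipes combining generator, engine and scoring.

These are the entry points the analysis scripts and the reproduction
script share: Monte-Carlo recovery of the behavioral group effects, and
the calibrated day-5 online-feedback simulation.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import behavior, feedback, synthgen

__all__ = [
    "cohort_delta_table",
    "behavior_recovery",
    "day5_feedback_experiment",
]


def cohort_delta_table(cohort: synthgen.CohortConfig,
                       seed: int) -> pd.DataFrame:
    """Generate one cohort's trials and score per-subject Delta metrics.

    Returns one row per subject and post-pretest contrast (posttest,
    followup) with delta_stroop_ms, delta_rt_neutral_ms, delta_acc_pct.
    """
    trials = synthgen.gen_behavior(cohort, seed=seed)
    scored = behavior.score_dataset(trials)
    wide = scored.set_index(["subject", "day"])
    rows = []
    for subject in scored["subject"].unique():
        pre = wide.loc[(subject, "pretest")]
        for test in ("posttest", "followup"):
            post = wide.loc[(subject, test)]
            rows.append({
                "subject": subject,
                "contrast": test,
                "delta_stroop_ms": post["stroop_effect_ms"]
                - pre["stroop_effect_ms"],
                "delta_rt_neutral_ms": post["rt_neutral"] - pre["rt_neutral"],
                "delta_acc_pct": post["accuracy_pct"] - pre["accuracy_pct"],
            })
    return pd.DataFrame(rows)


def behavior_recovery(cohort: synthgen.CohortConfig, contrast: str,
                      metric: str, n_cohorts: int = 500,
                      seed: int = 0) -> float:
    """Grand mean of per-cohort mean Delta metrics over simulated cohorts.

    ``contrast`` is ``posttest`` or ``followup``; ``metric`` one of
    ``delta_stroop_ms`` / ``delta_rt_neutral_ms`` / ``delta_acc_pct``.
    Each cohort draws ``cohort.n_subjects`` subjects, expands to trials,
    and is scored through the full behavioral pipeline.
    """
    means = np.empty(n_cohorts)
    for c in range(n_cohorts):
        table = cohort_delta_table(cohort, seed=seed * n_cohorts + c)
        sel = table[table["contrast"] == contrast]
        means[c] = sel[metric].mean()
    return float(means.mean())


def day5_feedback_experiment(seed: int = 0, target: float = 2.813,
                             cohort: synthgen.CohortConfig | None = None,
                             spec=feedback.SCALED_WINDOW, n_nulls: int = 10,
                             probe_blocks: int = 144,
                             pilot_blocks: int = 1044) -> dict:
    """Calibrated day-5 UP-group online simulation.

    Calibrates the day-5 latent drift so the mean session statistic of the
    online engine targets ``target`` baseline-relative points, then runs
    the full 17-subject x 18-block day through the scaled online chain and
    reports the group mean of per-subject session statistics.
    """
    cohort = cohort or synthgen.CohortConfig(seed=seed)
    signal = synthgen.SignalGenConfig(seed=seed).clean()
    p_star = feedback.calibrate_regulation_p(
        cohort, signal, target, spec=spec, n_nulls=n_nulls, seed=seed,
        probe_blocks=probe_blocks, pilot_blocks=pilot_blocks)
    final = replace(cohort, seed=cohort.seed + 1)
    stats = feedback.simulate_cohort_day(final, signal, day=5, spec=spec,
                                         n_nulls=n_nulls,
                                         engine_seed=seed + 17,
                                         p_override=p_star)
    return {
        "group_mean": float(stats.mean()),
        "group_sd": float(stats.std(ddof=1)),
        "per_subject": stats,
        "p_calibrated": float(p_star),
    }
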