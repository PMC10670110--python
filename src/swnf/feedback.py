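"""The online neurofeedback engine.

Per block, the engine computes the small-worldness sequence of the 15 s
continuous-subtraction baseline, takes its mean and SD, and maps each
regulation-window sigma to a 0-100 score:

    score_i = 50 * (sigma_i + 3 SD - sigma_base) / (3 SD),  clamped to [0, 100]

so baseline performance reads 50, and +-3 baseline SDs saturate the scale.
The thermometer the subject sees is the running mean of the block's
regulation scores; the per-session learning-curve statistic is the mean
regulation score minus 50 (baseline-relative points) across the day's 18
blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .netbuild import (WindowSpec, ONLINE_WINDOW, correlation_matrix,
                       fisher_z, threshold_binarize)
from .swmetrics import sigma_of_graph
from . import synthgen

__all__ = [
    "BaselineStats",
    "BlockTimeline",
    "SessionResult",
    "SCALED_WINDOW",
    "baseline_stats",
    "feedback_score",
    "sigma_online",
    "sigma_series",
    "run_block",
    "session_summary",
    "run_session",
    "simulate_cohort_day",
    "calibrate_regulation_p",
]

#: every 4th online update (step 32 instead of 8) for scaled simulations
SCALED_WINDOW = WindowSpec(length=128, step=32)


@dataclass(frozen=True)
class BaselineStats:
    sigma_base: float
    sd: float


@dataclass
class BlockTimeline:
    baseline: BaselineStats
    baseline_sigmas: np.ndarray
    regulation_sigmas: np.ndarray
    scores: np.ndarray
    thermometer: np.ndarray

    @property
    def statistic(self) -> float:
        """Baseline-relative block score (mean regulation score - 50)."""
        return float(self.scores.mean() - 50.0)


@dataclass
class SessionResult:
    subject: int
    group: str
    day: int
    blocks: list

    @property
    def statistic(self) -> float:
        return float(np.mean([b.statistic for b in self.blocks]))


def baseline_stats(sigma_sequence) -> BaselineStats:
    """Mean and sample SD of the baseline sigma sequence.

    A degenerate baseline (fewer than two values, or zero spread) leaves
    the score map undefined and is refused.
    """
    seq = np.asarray(sigma_sequence, dtype=float)
    if seq.size < 2:
        raise ValueError("need at least 2 baseline sigma values")
    sd = float(seq.std(ddof=1))
    if sd == 0:
        raise ValueError("degenerate baseline: sigma SD is zero")
    return BaselineStats(sigma_base=float(seq.mean()), sd=sd)


def feedback_score(sigma_i, baseline: BaselineStats):
    """Linear baseline-normalized score, clamped to [0, 100]."""
    sigma_i = np.asarray(sigma_i, dtype=float)
    raw = 50.0 * (sigma_i + 3 * baseline.sd - baseline.sigma_base) / (
        3 * baseline.sd)
    return np.clip(raw, 0.0, 100.0)[()]


def sigma_online(window: np.ndarray, sparsity: float = 0.3,
                 n_nulls: int = 30, seed: int = 0) -> float:
    """Sigma of one trailing window through the online chain."""
    z = fisher_z(correlation_matrix(window))
    adj = threshold_binarize(z, sparsity)
    return sigma_of_graph(adj, n_nulls=n_nulls, seed=seed).sigma


def sigma_series(data: np.ndarray, spec: WindowSpec = ONLINE_WINDOW,
                 sparsity: float = 0.3, n_nulls: int = 30,
                 rng=None) -> np.ndarray:
    """Sigma at every trailing window of a channels x time span."""
    rng = np.random.default_rng(rng)
    n = spec.count(data.shape[-1])
    out = np.empty(n)
    for i in range(n):
        start = i * spec.step
        out[i] = sigma_online(data[..., start:start + spec.length],
                              sparsity, n_nulls,
                              seed=int(rng.integers(2 ** 31 - 64)))
    return out


def run_block(segment: np.ndarray,
              spec: WindowSpec = ONLINE_WINDOW,
              sparsity: float = 0.3, n_nulls: int = 30, rng=None,
              baseline_samples: int = synthgen.BASELINE_SAMPLES,
              gap_samples: int = synthgen.GAP_SAMPLES,
              regulation_samples: int = synthgen.REGULATION_SAMPLES,
              sigma_sequences=None) -> BlockTimeline:
    """Score one feedback block (baseline + stimulus gap + regulation).

    The 2 s stimulus gap separates the spans and enters neither statistic.
    ``sigma_sequences`` (baseline, regulation) bypasses the signal chain,
    which keeps score-path behavior testable in isolation.
    """
    rng = np.random.default_rng(rng)
    if sigma_sequences is None:
        total = baseline_samples + gap_samples + regulation_samples
        if segment.shape[-1] < total:
            raise ValueError(
                f"segment has {segment.shape[-1]} samples; block needs "
                f"{total}")
        base_span = segment[..., :baseline_samples]
        reg_span = segment[..., baseline_samples + gap_samples:total]
        if baseline_samples < spec.length or regulation_samples < spec.length:
            raise ValueError("spans shorter than one analysis window")
        sig_base = sigma_series(base_span, spec, sparsity, n_nulls, rng)
        sig_reg = sigma_series(reg_span, spec, sparsity, n_nulls, rng)
    else:
        sig_base, sig_reg = (np.asarray(s, dtype=float)
                             for s in sigma_sequences)
    stats = baseline_stats(sig_base)
    scores = np.atleast_1d(feedback_score(sig_reg, stats))
    thermometer = np.cumsum(scores) / np.arange(1, scores.size + 1)
    return BlockTimeline(baseline=stats, baseline_sigmas=sig_base,
                         regulation_sigmas=sig_reg, scores=scores,
                         thermometer=thermometer)


def session_summary(block_timelines) -> float:
    """Per-day relative score: mean regulation score - 50 over blocks."""
    blocks = list(block_timelines)
    if not blocks:
        raise ValueError("no blocks")
    return float(np.mean([b.statistic for b in blocks]))


def run_session(session: synthgen.SubjectDaySession,
                spec: WindowSpec = ONLINE_WINDOW, sparsity: float = 0.3,
                n_nulls: int = 30, rng=None) -> SessionResult:
    """Run the engine over every block of a generated subject-day."""
    rng = np.random.default_rng(rng)
    data = session.recording.data
    blocks = [
        run_block(data[:, span.baseline.start:span.regulation.stop],
                  spec, sparsity, n_nulls, rng)
        for span in session.blocks
    ]
    return SessionResult(session.subject, session.group, session.day, blocks)


def simulate_cohort_day(cohort: synthgen.CohortConfig,
                        signal: synthgen.SignalGenConfig, day: int,
                        spec: WindowSpec = SCALED_WINDOW,
                        n_nulls: int = 10, sparsity: float = 0.3,
                        engine_seed: int = 0,
                        p_override: float | None = None) -> np.ndarray:
    """Per-subject session statistics for one training day."""
    out = np.empty(cohort.n_subjects)
    for subject in range(cohort.n_subjects):
        session = synthgen.gen_subject_day(cohort, signal, subject, day,
                                           p_override=p_override,
                                           include_rest=False)
        rng = np.random.default_rng([int(engine_seed), subject, day])
        out[subject] = run_session(session, spec, sparsity, n_nulls,
                                   rng).statistic
    return out


def _pilot_statistic(cohort, signal, p_eff, n_blocks, spec, n_nulls, seed):
    """Mean block statistic over freshly generated pilot blocks."""
    pilot = replace(cohort, seed=cohort.seed + 7_654_321 + seed,
                    subject_p_sd=0.0)
    stats = []
    subject = 0
    while len(stats) < n_blocks:
        session = synthgen.gen_subject_day(pilot, signal, subject, 5,
                                           p_override=p_eff,
                                           include_rest=False)
        rng = np.random.default_rng([int(seed) + 13, subject])
        res = run_session(session, spec, sparsity=0.3, n_nulls=n_nulls,
                          rng=rng)
        stats.extend(b.statistic for b in res.blocks)
        subject += 1
    return float(np.mean(stats[:n_blocks]))


def calibrate_regulation_p(cohort: synthgen.CohortConfig,
                           signal: synthgen.SignalGenConfig,
                           target_statistic: float,
                           spec: WindowSpec = SCALED_WINDOW,
                           n_nulls: int = 10, seed: int = 0,
                           probe_blocks: int = 144,
                           pilot_blocks: int = 1044) -> float:
    """Closed-loop calibration of the day-5 effective rewiring probability.

    The session statistic responds linearly (through the origin) to the
    latent covariance mixing weight for small targets, so two pilot stages
    suffice: a probe locates the response slope, a larger pilot refines it
    at a mid-scale operating point, and the target is hit by proportional
    inversion.  Pilot streams are seeded independently of any final cohort
    simulation.
    """
    if target_statistic == 0:
        return cohort.p_baseline
    sign = 1.0 if target_statistic > 0 else -1.0
    p_base = cohort.p_baseline

    def p_of_t(t):
        # mixing weight -> effective p (toward lattice for positive targets)
        if sign > 0:
            return p_base * (1.0 - t)
        return p_base + t * (1.0 - p_base)

    t_probe = 0.06
    g0 = sign * _pilot_statistic(cohort, signal, p_of_t(t_probe),
                                 probe_blocks, spec, n_nulls, seed)
    if g0 < 0.5:  # response too shallow to trust; probe further out
        t_probe = 0.15
        g0 = sign * _pilot_statistic(cohort, signal, p_of_t(t_probe),
                                     probe_blocks, spec, n_nulls, seed + 1)
        g0 = max(g0, 0.5)
    # operating point near 5 baseline-relative points: low relative error
    # while staying in the near-linear range of the response
    t1 = float(np.clip(t_probe * 5.0 / g0, 0.005, 0.6))
    g1 = sign * _pilot_statistic(cohort, signal, p_of_t(t1), pilot_blocks,
                                 spec, n_nulls, seed + 2)
    if g1 <= 0:
        raise RuntimeError("calibration pilot shows no response; "
                           "check generator configuration")
    t_star = float(np.clip(t1 * abs(target_statistic) / g1, 0.0, 1.0))
    return p_of_t(t_star)
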