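"""Synthetic data with known ground truth for the whole pipeline.

Everything the analyses consume can be produced here: Watts-Strogatz
latent connectivity graphs, multichannel hemodynamic signals whose pairwise
correlations reflect those graphs, raw three-wavelength intensities that
invert through the preprocessing chain, multi-day two-group training
cohorts, and color-word Stroop behavioral tables with configurable
group-by-day effects.

The signal model: channels are drawn from a zero-mean multivariate normal
with covariance  I + coupling * A  (eigenvalues clipped to keep it positive
definite), so channel pairs joined in the latent graph correlate more
strongly than unjoined pairs.  Physiological oscillations (cardiac,
respiratory, Mayer waves), pink noise, linear drift and spike artifacts are
added on top with per-channel random phases.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import networkx as nx
import pandas as pd
from scipy import signal as sps

from .preprocess import (HemodynamicRecording, PreprocessConfig,
                         SAMPLING_RATE, _UM_PER_MM)

__all__ = [
    "GroundTruthNetwork",
    "SignalGenConfig",
    "CohortConfig",
    "BehaviorEffects",
    "SubjectDaySession",
    "BlockSpan",
    "make_ws_graph",
    "latent_covariance",
    "gen_oxyhb",
    "gen_raw_intensity",
    "gen_training_cohort",
    "gen_subject_day",
    "gen_behavior",
    "REST_SAMPLES",
    "BASELINE_SAMPLES",
    "GAP_SAMPLES",
    "REGULATION_SAMPLES",
    "BLOCKS_PER_DAY",
]

N_CHANNELS = 35

# daily session layout at 25.6 Hz: 120 s rest, then 18 blocks of
# (15 s continuous-subtraction baseline, 2 s stimulus, 25 s regulation)
REST_SAMPLES = int(120 * SAMPLING_RATE)          # 3072
BASELINE_SAMPLES = int(15 * SAMPLING_RATE)       # 384
GAP_SAMPLES = int(2 * SAMPLING_RATE)             # 51 (2 s floor-rounded)
REGULATION_SAMPLES = int(25 * SAMPLING_RATE)     # 640
BLOCKS_PER_DAY = 18


@dataclass(frozen=True)
class GroundTruthNetwork:
    n_nodes: int
    neighbor_k: int
    rewiring_p: float
    adjacency: np.ndarray
    seed: int


def make_ws_graph(n_nodes: int = N_CHANNELS, neighbor_k: int = 10,
                  rewiring_p: float = 0.1, seed: int = 0) -> GroundTruthNetwork:
    """Watts-Strogatz graph: ring lattice with independent edge rewiring.

    Edge count n*k/2 is conserved for every rewiring probability; rewiring
    avoids self-loops and duplicate edges.
    """
    if neighbor_k % 2 != 0:
        raise ValueError("neighbor_k must be even (lattice half-width * 2)")
    if not 0 < neighbor_k < n_nodes:
        raise ValueError("need 0 < neighbor_k < n_nodes")
    if not 0 <= rewiring_p <= 1:
        raise ValueError("rewiring_p must be a probability")
    g = nx.watts_strogatz_graph(n_nodes, neighbor_k, rewiring_p,
                                seed=int(seed))
    adj = nx.to_numpy_array(g, dtype=bool)
    return GroundTruthNetwork(n_nodes, neighbor_k, float(rewiring_p),
                              adj, int(seed))


@dataclass(frozen=True)
class SignalGenConfig:
    sampling_rate: float = SAMPLING_RATE
    coupling_strength: float = 1.2
    #: (frequency Hz, amplitude) sinusoids: cardiac, respiratory, Mayer
    physio_components: tuple = ((1.2, 0.4), (0.25, 0.3), (0.1, 0.15))
    noise_sd: float = 0.3
    pink_sd: float = 0.2
    drift_slope: float = 0.005   # units per second
    artifact_rate: float = 0.5   # spike events per minute
    seed: int = 0

    def __post_init__(self):
        for f, a in self.physio_components:
            if a < 0:
                raise ValueError("physio amplitudes must be >= 0")
            if self.sampling_rate <= 2 * f:
                raise ValueError(
                    f"sampling rate {self.sampling_rate} Hz cannot carry a "
                    f"{f} Hz component")

    def clean(self) -> "SignalGenConfig":
        """Coupling-only variant: no physiology, drift or artifacts."""
        return replace(self, physio_components=(), noise_sd=0.0,
                       pink_sd=0.0, drift_slope=0.0, artifact_rate=0.0)


def latent_covariance(adjacency: np.ndarray, coupling: float) -> np.ndarray:
    """I + coupling*A, eigenvalue-clipped to positive definite."""
    cov = np.eye(adjacency.shape[0]) + coupling * adjacency
    w, v = np.linalg.eigh(cov)
    if w.min() <= 0:
        w = np.clip(w, 1e-6, None)
        cov = (v * w) @ v.T
    if np.linalg.eigvalsh(cov).min() <= 0:  # pragma: no cover
        raise ValueError("covariance not positive definite after projection")
    return cov


# pink (1/f) shaping filter coefficients (Paul Kellet's economy method)
_PINK_B = np.array([0.049922035, -0.095993537, 0.050612699, -0.004408786])
_PINK_A = np.array([1.0, -2.494956002, 2.017265875, -0.522189400])


def _structured_noise(n_channels, n_samples, config: SignalGenConfig, rng):
    """Physiology + pink noise + drift + spikes, channels x samples."""
    t = np.arange(n_samples) / config.sampling_rate
    out = np.zeros((n_channels, n_samples))
    for freq, amp in config.physio_components:
        if amp == 0:
            continue
        phase = rng.uniform(0, 2 * np.pi, size=n_channels)
        out += amp * np.sin(2 * np.pi * freq * t[None, :] + phase[:, None])
    if config.noise_sd > 0:
        out += config.noise_sd * rng.standard_normal((n_channels, n_samples))
    if config.pink_sd > 0:
        white = rng.standard_normal((n_channels, n_samples))
        pink = sps.lfilter(_PINK_B, _PINK_A, white, axis=-1)
        sd = pink.std(axis=-1, keepdims=True)
        sd[sd == 0] = 1.0
        out += config.pink_sd * pink / sd
    if config.drift_slope != 0:
        slopes = config.drift_slope * rng.uniform(-1, 1, size=n_channels)
        out += slopes[:, None] * t[None, :]
    if config.artifact_rate > 0:
        duration_min = n_samples / config.sampling_rate / 60
        n_events = rng.poisson(config.artifact_rate * duration_min)
        tau = 0.3 * config.sampling_rate
        for _ in range(n_events):
            onset = rng.integers(0, n_samples)
            length = min(n_samples - onset, int(5 * tau))
            shape = np.exp(-np.arange(length) / tau)
            amps = 8 * max(config.noise_sd, 0.1) * rng.standard_normal(
                n_channels)
            out[:, onset:onset + length] += amps[:, None] * shape[None, :]
    return out


def gen_oxyhb(network: GroundTruthNetwork, config: SignalGenConfig,
              duration_s: float, rng=None) -> HemodynamicRecording:
    """OxyHb series whose window correlations reflect the latent graph."""
    n_samples = int(round(duration_s * config.sampling_rate))
    if n_samples < 128:
        raise ValueError("duration shorter than one analysis window (5 s)")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    cov = latent_covariance(network.adjacency, config.coupling_strength)
    chol = np.linalg.cholesky(cov)
    data = chol @ rng.standard_normal((network.n_nodes, n_samples))
    data += _structured_noise(network.n_nodes, n_samples, config, rng)
    return HemodynamicRecording(data, sampling_rate=config.sampling_rate)


def gen_raw_intensity(hbo: np.ndarray, hbr: np.ndarray,
                      config: PreprocessConfig | None = None) -> np.ndarray:
    """Inverse modified Beer-Lambert: concentrations -> raw intensities.

    Uses the same extinction table and DPF as :func:`preprocess.od_to_conc`,
    so generate -> preprocess round-trips to identity (before filtering).
    Output shape: channels x wavelengths x time.
    """
    config = config or PreprocessConfig()
    hbo = np.atleast_2d(np.asarray(hbo, dtype=float))
    hbr = np.atleast_2d(np.asarray(hbr, dtype=float))
    if hbo.shape != hbr.shape:
        raise ValueError("hbo and hbr must have identical shapes")
    if not (np.isfinite(hbo).all() and np.isfinite(hbr).all()):
        raise ValueError("concentrations must be finite")
    if config.baseline_intensity <= 0:
        raise ValueError("baseline intensity must be positive")
    E = config.extinction_matrix() * _UM_PER_MM
    scale = config.distance_cm * np.asarray(config.dpf)
    conc = np.stack([hbo, hbr], axis=-1)                # c x t x 2
    od = np.einsum("w,wk,ctk->cwt", scale, E, conc)
    return config.baseline_intensity * np.exp(-od)


# --------------------------------------------------------------------------
# training cohorts


@dataclass(frozen=True)
class BehaviorEffects:
    """Group-level behavioral effect parameters (means and SDs).

    Deltas are posttest-minus-pretest / follow-up-minus-pretest at the
    subject level; reaction times in ms, accuracies in percent.
    """

    stroop_delta: dict = field(default_factory=lambda: {
        "posttest": (-60.0, 45.0), "followup": (-40.0, 50.0)})
    acc_delta: dict = field(default_factory=lambda: {
        "posttest": (1.5, 4.7), "followup": (2.48, 4.69)})
    neutral_practice: dict = field(default_factory=lambda: {
        "posttest": (-30.0, 35.0), "followup": (-30.0, 35.0)})
    pretest_stroop: tuple = (80.0, 40.0)
    pretest_neutral_rt: tuple = (600.0, 60.0)
    pretest_acc: tuple = (85.0, 4.0)
    congruent_facilitation: float = 20.0
    trial_rt_sd: float = 100.0

    def __post_init__(self):
        for d in (self.stroop_delta, self.acc_delta, self.neutral_practice):
            for mean, sd in d.values():
                if sd <= 0:
                    raise ValueError("effect SDs must be positive")


DOWN_BEHAVIOR = BehaviorEffects(
    stroop_delta={"posttest": (9.0, 77.0), "followup": (0.0, 70.0)},
    acc_delta={"posttest": (0.5, 4.7), "followup": (1.0, 4.7)},
)


@dataclass(frozen=True)
class CohortConfig:
    group: str = "UP"
    n_subjects: int = 17
    #: effective regulation-state rewiring probability, one entry per day.
    #: The score response to the latent mixing is steep (~1.5 baseline-
    #: relative points per 0.001 of p), so learning-curve-sized effects
    #: correspond to per-mil shifts around the baseline state.
    p_schedule: tuple = (0.1498, 0.1494, 0.1490, 0.1483, 0.1462)
    p_baseline: float = 0.15
    neighbor_k: int = 12
    subject_p_sd: float = 0.0005
    behavior: BehaviorEffects = field(default_factory=BehaviorEffects)
    seed: int = 0

    def __post_init__(self):
        if self.group not in ("UP", "DOWN"):
            raise ValueError("group must be UP or DOWN")
        if len(self.p_schedule) != 5:
            raise ValueError("p_schedule needs one entry per training day")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")


DOWN_COHORT = CohortConfig(
    group="DOWN",
    p_schedule=(0.1500, 0.1540, 0.1570, 0.1585, 0.1515),
    behavior=DOWN_BEHAVIOR,
)


@dataclass(frozen=True)
class BlockSpan:
    baseline: slice
    gap: slice
    regulation: slice


@dataclass
class SubjectDaySession:
    subject: int
    group: str
    day: int
    recording: HemodynamicRecording
    blocks: list
    p_regulation: float


def _subject_rng(master_seed: int, subject: int, day: int):
    return np.random.default_rng([int(master_seed), int(subject), int(day)])


def _mixing_weight(p_eff: float, p_base: float) -> tuple:
    """Map an effective rewiring p to (anchor, weight) around the baseline.

    p below baseline mixes the covariance toward the ring lattice (more
    regular), p above toward a fully rewired graph (more random); the
    weight is the linear position between the two.
    """
    if p_eff <= p_base:
        return "lattice", (p_base - p_eff) / p_base if p_base else 0.0
    return "random", (p_eff - p_base) / (1.0 - p_base)


def gen_subject_day(cohort: CohortConfig, signal: SignalGenConfig,
                    subject: int, day: int,
                    p_override: float | None = None,
                    include_rest: bool = True) -> SubjectDaySession:
    """One subject's one training day: rest + 18 feedback blocks.

    The latent graph is drawn once per subject-day and shared by the
    baseline and regulation spans of every block; during regulation the
    covariance is interpolated toward the lattice (UP) or a random graph
    (DOWN) according to the day's effective rewiring probability.
    """
    if not 1 <= day <= len(cohort.p_schedule):
        raise ValueError(f"day {day} outside the {len(cohort.p_schedule)}-day "
                         "schedule")
    rng = _subject_rng(cohort.seed, subject, day)
    # per-subject offset fixed across days so schedules stay monotone
    off_rng = _subject_rng(cohort.seed, subject, 0)
    p_off = off_rng.normal(0.0, cohort.subject_p_sd)
    p_eff = cohort.p_schedule[day - 1] if p_override is None else p_override
    p_eff = float(np.clip(p_eff + p_off, 0.0, 1.0))

    net = make_ws_graph(N_CHANNELS, cohort.neighbor_k, cohort.p_baseline,
                        seed=int(rng.integers(2 ** 31 - 1)))
    anchor_kind, weight = _mixing_weight(p_eff, cohort.p_baseline)
    # one draw in either branch keeps the stream aligned, so UP and DOWN
    # sessions with matched seeds share graphs and signal innovations
    anchor_seed = int(rng.integers(2 ** 31 - 1))
    if anchor_kind == "lattice":
        anchor = make_ws_graph(N_CHANNELS, cohort.neighbor_k, 0.0, seed=0)
    else:
        anchor = make_ws_graph(N_CHANNELS, cohort.neighbor_k, 1.0,
                               seed=anchor_seed)
    adj_reg = ((1 - weight) * net.adjacency.astype(float)
               + weight * anchor.adjacency.astype(float))
    cov_base = latent_covariance(net.adjacency, signal.coupling_strength)
    cov_reg = latent_covariance(adj_reg, signal.coupling_strength)
    chol_base = np.linalg.cholesky(cov_base)
    chol_reg = np.linalg.cholesky(cov_reg)

    block_len = BASELINE_SAMPLES + GAP_SAMPLES + REGULATION_SAMPLES
    rest = REST_SAMPLES if include_rest else 0
    total = rest + BLOCKS_PER_DAY * block_len
    data = np.empty((N_CHANNELS, total))
    if rest:
        data[:, :rest] = chol_base @ rng.standard_normal((N_CHANNELS, rest))
    blocks = []
    pos = rest
    for _ in range(BLOCKS_PER_DAY):
        b = slice(pos, pos + BASELINE_SAMPLES)
        g = slice(b.stop, b.stop + GAP_SAMPLES)
        r = slice(g.stop, g.stop + REGULATION_SAMPLES)
        data[:, b] = chol_base @ rng.standard_normal(
            (N_CHANNELS, BASELINE_SAMPLES))
        data[:, g] = chol_base @ rng.standard_normal(
            (N_CHANNELS, GAP_SAMPLES))
        data[:, r] = chol_reg @ rng.standard_normal(
            (N_CHANNELS, REGULATION_SAMPLES))
        blocks.append(BlockSpan(b, g, r))
        pos = r.stop
    data += _structured_noise(N_CHANNELS, total, signal, rng)
    rec = HemodynamicRecording(data, sampling_rate=signal.sampling_rate)
    return SubjectDaySession(subject, cohort.group, day, rec, blocks, p_eff)


def gen_training_cohort(cohort: CohortConfig, signal: SignalGenConfig,
                        days=None, include_rest: bool = True):
    """Lazily yield every subject-day session of a cohort."""
    days = range(1, len(cohort.p_schedule) + 1) if days is None else days
    for subject in range(cohort.n_subjects):
        for day in days:
            yield gen_subject_day(cohort, signal, subject, day,
                                  include_rest=include_rest)


# --------------------------------------------------------------------------
# behavioral data

TEST_DAYS = ("pretest", "posttest", "followup")
_CONDITIONS = ("congruent", "incongruent", "neutral")


def gen_behavior(cohort: CohortConfig, trial_level: bool = True,
                 seed: int | None = None) -> pd.DataFrame:
    """Stroop trial tables for pretest / posttest / follow-up.

    Subject-level condition-mean RTs are drawn so that the posttest- and
    follow-up-minus-pretest Stroop differences are normal with the
    configured group mean/SD; the neutral RT carries a shared practice
    decrease; accuracy changes follow the configured mean/SD, truncated to
    [0, 100]%.  With ``trial_level`` each subject-day expands to 90 trials
    (18 blocks x 5) with RT noise and Bernoulli correctness.
    """
    eff = cohort.behavior
    rng = np.random.default_rng(cohort.seed if seed is None else seed)
    rows = []
    for subject in range(cohort.n_subjects):
        stroop0 = rng.normal(*eff.pretest_stroop)
        neutral0 = rng.normal(*eff.pretest_neutral_rt)
        acc0 = float(np.clip(rng.normal(*eff.pretest_acc), 0, 100))
        per_day = {"pretest": (stroop0, neutral0, acc0)}
        for test in ("posttest", "followup"):
            stroop = stroop0 + rng.normal(*eff.stroop_delta[test])
            neutral = neutral0 + rng.normal(*eff.neutral_practice[test])
            acc = float(np.clip(acc0 + rng.normal(*eff.acc_delta[test]),
                                0, 100))
            per_day[test] = (stroop, neutral, acc)
        for test, (stroop, neutral, acc) in per_day.items():
            cond_rt = {
                "neutral": neutral,
                "congruent": neutral - eff.congruent_facilitation,
                "incongruent": neutral - eff.congruent_facilitation + stroop,
            }
            if not trial_level:
                for cond, rt in cond_rt.items():
                    rows.append((subject, cohort.group, test, 0, 0, cond,
                                 "none", rt, 1))
                continue
            conds = np.repeat(_CONDITIONS, 30)
            rng.shuffle(conds)
            valence = np.repeat(["positive", "negative"], 9)
            rng.shuffle(valence)
            for i, cond in enumerate(conds):
                block, trial = divmod(i, 5)
                rt = max(150.0, cond_rt[cond]
                         + rng.normal(0.0, eff.trial_rt_sd))
                correct = int(rng.random() < acc / 100)
                rows.append((subject, cohort.group, test, block, trial,
                             cond, valence[block], rt, correct))
    return pd.DataFrame(rows, columns=[
        "subject", "group", "day", "block", "trial", "condition",
        "valence", "rt_ms", "correct"])
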