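"""Raw fNIRS intensities to filtered hemoglobin concentrations.

Offline chain (the field's standard five-step recipe):

1. intensity -> optical density (OD),
2. motion-artifact detection by amplitude / moving-SD thresholds,
3. cubic-spline correction of flagged intervals,
4. 5th-order Butterworth band pass 0.01-0.2 Hz (zero-phase offline,
   causal online),
5. OD -> concentration via the modified Beer-Lambert law
   (three wavelengths 780/805/830 nm, DPF [6, 6, 6], 3 cm separation).

Concentrations are expressed in uM-equivalent arbitrary units; only their
relative fluctuations feed the downstream correlation analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.interpolate import LSQUnivariateSpline

__all__ = [
    "HemodynamicRecording",
    "PreprocessConfig",
    "EXTINCTION_MM_CM",
    "WAVELENGTHS_NM",
    "intensity_to_od",
    "detect_motion",
    "spline_correct",
    "bandpass",
    "od_to_conc",
    "run_offline",
    "write_recording",
    "read_recording",
]

SAMPLING_RATE = 25.6

WAVELENGTHS_NM = (780, 805, 830)

#: molar extinction coefficients [1/(mM*cm)] for (HbO2, HbR); a published
#: tabulation pinned as a constant so tests are deterministic.  805 nm sits
#: at the isosbestic point where both species absorb almost equally.
EXTINCTION_MM_CM = {
    780: (0.710, 1.075),
    805: (0.830, 0.780),
    830: (0.974, 0.693),
}

#: uM concentrations against mM-based extinction coefficients
_UM_PER_MM = 1e-3


@dataclass
class HemodynamicRecording:
    """Channels x time concentration series (uM-equivalent units)."""

    data: np.ndarray
    sampling_rate: float = SAMPLING_RATE
    species: str = "OxyHb"

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass
class PreprocessConfig:
    filter_order: int = 5
    passband_hz: tuple = (0.01, 0.2)
    dpf: tuple = (6.0, 6.0, 6.0)
    wavelengths_nm: tuple = WAVELENGTHS_NM
    extinction: dict = field(default_factory=lambda: dict(EXTINCTION_MM_CM))
    distance_cm: float = 3.0
    baseline_intensity: float = 1.0
    # motion detection
    motion_window_s: float = 0.5
    motion_amp_threshold: float = 0.5
    motion_sd_multiplier: float = 50.0
    motion_pad_s: float = 1.0
    mode: str = "offline"  # offline (zero-phase) | online (causal)

    def __post_init__(self):
        low, high = self.passband_hz
        if not 0 < low < high:
            raise ValueError("passband must satisfy 0 < low < high")
        if any(d <= 0 for d in self.dpf):
            raise ValueError("DPF values must be positive")

    def extinction_matrix(self) -> np.ndarray:
        """(n_wavelengths x 2) matrix of (eps_HbO, eps_HbR)."""
        try:
            return np.array([self.extinction[w] for w in self.wavelengths_nm],
                            dtype=float)
        except KeyError as e:  # pragma: no cover - config error path
            raise ValueError(f"no extinction entry for {e} nm") from None


def intensity_to_od(intensity: np.ndarray) -> np.ndarray:
    """OD(t) = -ln(I(t) / mean(I)), per channel-wavelength trace.

    ``intensity`` has shape (..., time); any non-positive sample is a
    hard error because its logarithm is meaningless.
    """
    intensity = np.asarray(intensity, dtype=float)
    bad = np.argwhere(intensity <= 0)
    if bad.size:
        raise ValueError(
            f"non-positive intensity at (channel.., sample) {bad[0].tolist()}")
    ref = intensity.mean(axis=-1, keepdims=True)
    return -np.log(intensity / ref)


def _merge_intervals(intervals, pad, n):
    merged = []
    for a, b in sorted(intervals):
        a, b = max(0, a - pad), min(n, b + pad)
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [tuple(iv) for iv in merged]


def detect_motion(od: np.ndarray, config: PreprocessConfig,
                  sampling_rate: float = SAMPLING_RATE):
    """Flag motion artifacts per channel.

    A sample is flagged when the signal excursion (max-min) inside the
    trailing ``motion_window_s`` window exceeds the amplitude threshold or
    ``motion_sd_multiplier`` times the channel's median windowed SD.
    Flags are padded by ``motion_pad_s`` and overlapping intervals merged.

    Returns a list (one entry per channel trace) of (start, stop) sample
    intervals; 2-D input (channels x time) gives one list per channel,
    3-D input (channels x wavelengths x time) flags on any wavelength.
    """
    od = np.asarray(od, dtype=float)
    if od.ndim == 3:
        collapsed = od.reshape(-1, od.shape[-1])
        per_trace = detect_motion(collapsed, config, sampling_rate)
        nw = od.shape[1]
        out = []
        for c in range(od.shape[0]):
            ivs = [iv for w in range(nw) for iv in per_trace[c * nw + w]]
            out.append(_merge_intervals(ivs, 0, od.shape[-1]))
        return out
    win = max(2, int(round(config.motion_window_s * sampling_rate)))
    n = od.shape[-1]
    if win >= n:
        raise ValueError("motion window must be shorter than the recording")
    pad = int(round(config.motion_pad_s * sampling_rate))
    masks = []
    for trace in np.atleast_2d(od):
        s = pd.Series(trace)
        roll = s.rolling(win, min_periods=1)
        excursion = (roll.max() - roll.min()).to_numpy()
        roll_sd = s.rolling(win, min_periods=2).std().bfill()
        ref_sd = float(np.median(roll_sd))
        flagged = (excursion > config.motion_amp_threshold)
        if ref_sd > 0:
            flagged |= roll_sd.to_numpy() > config.motion_sd_multiplier * ref_sd
        intervals = []
        in_run = False
        for i, f in enumerate(flagged):
            if f and not in_run:
                start, in_run = i, True
            elif not f and in_run:
                intervals.append((start, i))
                in_run = False
        if in_run:
            intervals.append((start, n))
        masks.append(_merge_intervals(intervals, pad, n))
    return masks


def spline_correct(od: np.ndarray, mask,
                   sampling_rate: float = SAMPLING_RATE) -> np.ndarray:
    """Replace flagged intervals by their spline-modelled slow component.

    Within each interval the cubic-spline trend (knots every ~0.5 s) is
    subtracted, removing the artifact's jump, and the residual is
    re-anchored linearly between the interval's neighbouring samples so the
    series stays continuous.  Unflagged samples are untouched; an interval
    touching a boundary is anchored one-sided (with a warning).
    """
    od = np.asarray(od, dtype=float)
    out = od.copy()
    traces = out.reshape(-1, out.shape[-1]) if out.ndim > 1 else out[None, :]
    if not mask:
        return out
    if isinstance(mask[0], list):
        mask_list = list(mask)
        if out.ndim == 3 and len(mask_list) == out.shape[0]:
            # per-channel masks apply to every wavelength of the channel
            mask_list = [m for m in mask_list
                         for _ in range(out.shape[1])]
        if len(mask_list) != len(traces):
            raise ValueError("mask count does not match trace count")
    else:
        mask_list = [mask] * len(traces)
    knot_step = max(4, int(round(0.5 * sampling_rate)))
    for trace, intervals in zip(traces, mask_list):
        n = trace.shape[0]
        for a, b in intervals:
            if not 0 <= a < b <= n:
                raise ValueError(f"interval ({a}, {b}) outside recording")
            seg = trace[a:b]
            x = np.arange(b - a)
            if len(seg) > 2 * knot_step:
                knots = x[knot_step:-knot_step:knot_step]
                trend = LSQUnivariateSpline(x, seg, knots, k=3)(x)
            else:
                trend = np.linspace(seg[0], seg[-1], len(seg))
            resid = seg - trend
            left = trace[a - 1] if a > 0 else None
            right = trace[b] if b < n else None
            if left is None or right is None:
                warnings.warn("artifact interval touches a recording "
                              "boundary; one-sided anchoring")
            if left is None:
                left = right if right is not None else resid[0]
            if right is None:
                right = left
            ramp = np.linspace(left - resid[0], right - resid[-1],
                               len(seg))
            trace[a:b] = resid + ramp
    return out


def _sos(config: PreprocessConfig, sampling_rate: float):
    low, high = config.passband_hz
    nyq = sampling_rate / 2
    if high >= nyq:
        raise ValueError(f"passband upper edge {high} Hz >= Nyquist {nyq} Hz")
    return sps.butter(config.filter_order, [low, high], btype="bandpass",
                      fs=sampling_rate, output="sos")


def bandpass(series: np.ndarray, config: PreprocessConfig,
             sampling_rate: float = SAMPLING_RATE) -> np.ndarray:
    """Band-pass filter along the last axis.

    ``offline`` mode is zero-phase (forward-backward); ``online`` mode is
    the causal single pass a real-time system would run, with the filter
    state implicit in the sample history.
    """
    series = np.asarray(series, dtype=float)
    sos = _sos(config, sampling_rate)
    if config.mode == "online":
        return sps.sosfilt(sos, series, axis=-1)
    return sps.sosfiltfilt(sos, series, axis=-1)


def od_to_conc(od: np.ndarray, config: PreprocessConfig):
    """Modified Beer-Lambert inversion: OD -> (OxyHb, DeoxyHb).

    ``od`` has shape (channels, wavelengths, time).  Per sample the
    least-squares solution of  OD = d * DPF * E c  is returned, in uM.
    Because OD is referenced to the recording-mean intensity, the
    concentrations are *changes* relative to that reference: a generate ->
    preprocess round trip reproduces the input up to a per-channel
    constant (exactly, once both sides are mean-centered).
    """
    od = np.asarray(od, dtype=float)
    if od.ndim != 3 or od.shape[1] != len(config.wavelengths_nm):
        raise ValueError("od must be channels x wavelengths x time")
    E = config.extinction_matrix() * _UM_PER_MM
    scale = config.distance_cm * np.asarray(config.dpf)
    if np.linalg.matrix_rank(E) < 2:
        raise ValueError("extinction system is singular")
    design = E * scale[:, None]
    pinv = np.linalg.pinv(design)
    conc = np.einsum("kw,cwt->ckt", pinv, od)
    hbo = HemodynamicRecording(conc[:, 0, :], species="OxyHb")
    hbr = HemodynamicRecording(conc[:, 1, :], species="DeoxyHb")
    return hbo, hbr


def run_offline(intensity: np.ndarray, config: PreprocessConfig | None = None,
                sampling_rate: float = SAMPLING_RATE):
    """Full offline chain from raw intensities to filtered concentrations."""
    config = config or PreprocessConfig()
    od = intensity_to_od(intensity)
    mask = detect_motion(od, config, sampling_rate)
    od = spline_correct(od, mask, sampling_rate)
    od = bandpass(od, config, sampling_rate)
    return od_to_conc(od, config)


def write_recording(path, recording: HemodynamicRecording) -> None:
    """One row per sample, one column per channel, sampling rate in header."""
    df = pd.DataFrame(
        recording.data.T,
        columns=[f"ch{c + 1:02d}" for c in range(recording.n_channels)])
    with open(path, "w") as fh:
        fh.write(f"# sampling_rate_hz={recording.sampling_rate}"
                 f" species={recording.species}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_recording(path) -> HemodynamicRecording:
    with open(path) as fh:
        header = fh.readline().lstrip("# ").split()
        meta = dict(kv.split("=") for kv in header)
        df = pd.read_csv(fh, sep="\t")
    return HemodynamicRecording(df.to_numpy().T,
                                sampling_rate=float(meta["sampling_rate_hz"]),
                                species=meta.get("species", "OxyHb"))
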