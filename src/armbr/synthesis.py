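"""Synthetic and semi-synthetic blink-contaminated EEG with ground truth.

Artifact-removal methods are hard to score on real data because the
uncontaminated signal is unknown.  This module builds recordings where
it *is* known: the contaminated signal is constructed channel-wise as

    S = S_clean + S_blink

so every evaluation metric can be computed against S_clean exactly.

:func:`make_scene` is fully synthetic: band-limited (1-40 Hz) Gaussian
background per channel, plus a train of positive monophasic raised-cosine
blink pulses (peak 50-100 uV above the eyes) projected across channels
through a front-loaded spatial pattern that decays with nominal distance
from the eyes (frontal weight ~1, occipital ~0.02).  Blink count follows
the blinking-rate relation rate = R / D * 60 (R blinks over D seconds).

:func:`semi_synthetic_from_recording` reproduces the semi-synthetic
construction used with real data: band-pass 1-15 Hz a blink-contaminated
record, zero it outside manually labeled blink intervals, smooth with a
centered moving average to suppress brain-wave residue, and add the
result onto a blink-free record.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import OverlapError, TooShortError
from .signal_core import BandSpec, Recording, bandpass

__all__ = [
    "SyntheticScene",
    "blink_rate",
    "blink_template",
    "make_scene",
    "semi_synthetic_from_recording",
    "moving_average",
]

BACKGROUND_BAND = BandSpec(1.0, 40.0, order=4)
SEMISYNTH_BLINK_BAND = BandSpec(1.0, 15.0, order=4)

#: Default blink pulse peak, middle of the physiological 50-100 uV range.
DEFAULT_PEAK_UV = 75.0
#: Default blink pulse duration in seconds (typical blink: 0.1-0.4 s).
DEFAULT_BLINK_DURATION_S = 0.3
#: Occipital-to-frontal attenuation of the blink projection.
PATTERN_FLOOR = 0.02


@dataclass
class SyntheticScene:
    """Ground-truth decomposition of a contaminated recording.

    ``mixed.data == clean.data + blink.data`` holds exactly, by
    construction; ``blink_intervals`` are the planted pulse supports in
    seconds; ``pattern`` is the planted scalp projection (length C).
    """

    clean: Recording
    blink: Recording
    mixed: Recording
    blink_intervals: list[tuple[float, float]]
    pattern: np.ndarray
    blink_rate_per_min: float
    seed: int | None


def blink_rate(R: int, D_s: float) -> float:
    """Blinking rate in blinks/min for R blinks over a D-second record."""
    if D_s <= 0:
        raise ValueError("duration must be positive")
    return R / D_s * 60.0


def blink_template(
    fs: float,
    duration_s: float = DEFAULT_BLINK_DURATION_S,
    peak_uV: float = DEFAULT_PEAK_UV,
) -> np.ndarray:
    """Raised-cosine blink pulse: smooth, non-negative, single-peaked.

    The waveform is ``peak * 0.5 * (1 - cos(2 pi t / T))``, normalized so
    its maximum equals ``peak_uV`` exactly and its endpoints are zero.
    Its energy is ``0.375 * peak^2 * n`` samples (integral of the squared
    raised cosine over one period).
    """
    n = int(round(duration_s * fs))
    if n < 8:
        raise TooShortError("blink template needs at least 8 samples")
    t = np.arange(n) / (n - 1)
    w = 0.5 * (1.0 - np.cos(2.0 * np.pi * t))
    w *= peak_uV / w.max()
    return w


def _channel_labels(c: int) -> list[str]:
    base = ["Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2"]
    if c <= len(base):
        return base[:c]
    return base + [f"EEG{i:03d}" for i in range(len(base) + 1, c + 1)]


def make_scene(
    C: int,
    fs: float,
    duration_s: float,
    rate_per_min: float,
    peak_uV: float = DEFAULT_PEAK_UV,
    background_rms_uV: float = 10.0,
    seed: int | None = 0,
    blink_duration_s: float = DEFAULT_BLINK_DURATION_S,
) -> SyntheticScene:
    """Generate a fully synthetic blink-contaminated scene.

    Channels are ordered front to back: channel 0 is closest to the eyes
    (weight ~1) and the last channel the farthest (weight ~0.02), with a
    +/-10% seeded jitter on the exponential decay.  Blink onsets are
    jittered uniformly inside equal slots so pulses never overlap; an
    infeasible rate (pulses longer than their slots) raises.

    The scene is reproducible: the same seed gives a bit-identical scene.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    labels = _channel_labels(C)

    # background: per-channel white noise band-limited to 1-40 Hz,
    # rescaled to the requested rms
    noise = rng.standard_normal((n, C))
    clean_data = bandpass(Recording(noise, fs, labels), BACKGROUND_BAND).data
    rms = np.sqrt(np.mean(clean_data**2, axis=0))
    clean_data = clean_data / rms * background_rms_uV

    # planted scalp projection: exponential decay over channel index
    if C > 1:
        decay = np.exp(np.linspace(0.0, np.log(PATTERN_FLOOR), C))
    else:
        decay = np.ones(1)
    pattern = decay * rng.uniform(0.9, 1.1, size=C)

    # blink pulse train
    n_blinks = int(round(rate_per_min * duration_s / 60.0))
    train = np.zeros(n)
    intervals: list[tuple[float, float]] = []
    if n_blinks > 0:
        slot_s = duration_s / n_blinks
        if blink_duration_s > slot_s:
            raise OverlapError(
                f"{n_blinks} blinks of {blink_duration_s} s do not fit in "
                f"{duration_s} s without overlap"
            )
        pulse = blink_template(fs, blink_duration_s, peak_uV)
        for i in range(n_blinks):
            onset_s = i * slot_s + rng.uniform(0.0, slot_s - blink_duration_s)
            start = int(round(onset_s * fs))
            stop = min(start + pulse.size, n)
            train[start:stop] = pulse[: stop - start]
            intervals.append((start / fs, (stop - start) / fs))

    blink_data = np.outer(train, pattern)
    mixed_data = clean_data + blink_data
    ann = [(on, du, "blink") for on, du in intervals]
    return SyntheticScene(
        clean=Recording(clean_data, fs, labels),
        blink=Recording(blink_data, fs, labels),
        mixed=Recording(mixed_data, fs, labels, annotations=ann),
        blink_intervals=intervals,
        pattern=pattern,
        blink_rate_per_min=rate_per_min,
        seed=seed,
    )


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge truncation.

    At each sample the mean is taken over the window samples centered on
    it, truncated at the record edges (the divisor shrinks accordingly).
    ``window`` is forced odd by rounding down, matching the convention of
    common smoothing routines whose default is a 5-point moving average.
    """
    x = np.asarray(x, dtype=np.float64)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window % 2 == 0:
        window -= 1
    if window == 1:
        return x.copy()
    h = window // 2
    out = np.empty_like(x)
    csum = np.concatenate(([0.0], np.cumsum(x, axis=0)))
    n = x.shape[0]
    for i in range(n):
        lo, hi = max(0, i - h), min(n, i + h + 1)
        out[i] = (csum[hi] - csum[lo]) / (hi - lo)
    return out


def semi_synthetic_from_recording(
    blinky: Recording,
    clean: Recording,
    blink_intervals: list[tuple[float, float]],
    smooth_window_s: float | None = None,
) -> SyntheticScene:
    """Semi-synthetic scene from a blink-contaminated + a blink-free record.

    The blink component is the blinky record band-passed 1-15 Hz, zeroed
    outside the given (onset_s, duration_s) intervals, then smoothed
    per channel with a centered moving average (default window: 5
    samples) to attenuate residual brain waves; it is added onto the
    clean record to form the mixed signal.
    """
    if blinky.data.shape != clean.data.shape or blinky.fs != clean.fs:
        raise ValueError("blinky and clean recordings must have identical shape and fs")
    if blinky.channel_labels != clean.channel_labels:
        raise ValueError("blinky and clean recordings must share channel labels")
    fs, n = blinky.fs, blinky.n_samples
    filt = bandpass(blinky, SEMISYNTH_BLINK_BAND).data
    keep = np.zeros(n, dtype=bool)
    for onset_s, dur_s in blink_intervals:
        start = int(round(onset_s * fs))
        stop = int(round((onset_s + dur_s) * fs))
        if start < 0 or stop > n:
            raise ValueError(f"interval ({onset_s}, {dur_s}) outside record")
        keep[start:stop] = True
    blink_data = np.where(keep[:, None], filt, 0.0)
    window = 5 if smooth_window_s is None else max(1, int(round(smooth_window_s * fs)))
    for j in range(blink_data.shape[1]):
        blink_data[:, j] = moving_average(blink_data[:, j], window)
    mixed_data = clean.data + blink_data
    peaks = np.abs(blink_data).max(axis=0)
    pattern = peaks / peaks.max() if peaks.max() > 0 else peaks
    intervals = [(float(a), float(b)) for a, b in blink_intervals]
    rate = blink_rate(len(intervals), n / fs)
    return SyntheticScene(
        clean=clean,
        blink=Recording(blink_data, fs, list(blinky.channel_labels)),
        mixed=Recording(mixed_data, fs, list(blinky.channel_labels)),
        blink_intervals=intervals,
        pattern=pattern,
        blink_rate_per_min=rate,
        seed=None,
    )
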