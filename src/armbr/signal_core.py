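"""Signal container and filtering primitives shared by the whole pipeline.

The universal in-memory object is :class:`Recording`: an ``N x C`` float64
matrix of microvolt samples with a sampling rate and unique channel labels.
All downstream stages (blink detection, spatial-filter fitting, purging,
evaluation) operate on this container.

Conventions fixed here and relied upon everywhere else:

* sample indexing is 0-based; epoch windows are half-open ``[start, stop)``;
* all filtering is zero-phase (forward-backward), so blink peak latencies
  are never shifted between the reference trace and the data it was
  derived from -- the backward regression implicitly assumes this
  alignment (note that forward-backward application doubles the effective
  filter order);
* units are microvolts throughout; file readers convert on ingest.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .exceptions import InvalidBandError, MissingChannelError, TooShortError

__all__ = [
    "Recording",
    "BandSpec",
    "bandpass",
    "flag_bad_channels",
    "slice_epochs",
]


@dataclass
class Recording:
    """Multichannel time series in microvolts.

    Parameters
    ----------
    data : ndarray, shape (N, C)
        One column per channel, microvolts.
    fs : float
        Sampling rate in Hz, strictly positive.
    channel_labels : list of str
        Unique labels, one per column.
    annotations : list of (onset_s, duration_s, label), optional
        Free-form event markers, e.g. detected blink intervals.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    annotations: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim == 1:
            self.data = self.data[:, None]
        if self.data.ndim != 2 or self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise ValueError("data must be a non-empty N x C matrix")
        if not np.isfinite(self.data).all():
            raise ValueError("data contains NaN or Inf")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.channel_labels = [str(c) for c in self.channel_labels]
        if len(self.channel_labels) != self.data.shape[1]:
            raise ValueError("channel_labels length must equal channel count")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise MissingChannelError(
                f"channel {label!r} not in recording (have {self.channel_labels})"
            ) from None

    def pick(self, labels: list[str]) -> "Recording":
        """Sub-recording restricted to ``labels`` (order preserved)."""
        idx = [self.channel_index(lab) for lab in labels]
        return Recording(self.data[:, idx], self.fs, [self.channel_labels[i] for i in idx])

    def copy_with(self, data: np.ndarray) -> "Recording":
        return replace(self, data=np.asarray(data, dtype=np.float64))


@dataclass(frozen=True)
class BandSpec:
    """Butterworth band edges in Hz; ``low_hz == 0`` means pure low-pass."""

    low_hz: float
    high_hz: float
    order: int = 4

    def __post_init__(self) -> None:
        if self.low_hz < 0:
            raise InvalidBandError("low edge must be >= 0")
        if self.high_hz <= self.low_hz:
            raise InvalidBandError("high edge must exceed low edge")
        if self.order < 1:
            raise InvalidBandError("order must be a positive integer")

    def sos(self, fs: float) -> np.ndarray:
        """Second-order-sections design of this band at sampling rate ``fs``."""
        if self.high_hz >= fs / 2:
            raise InvalidBandError(
                f"high edge {self.high_hz} Hz >= Nyquist {fs / 2} Hz"
            )
        if self.low_hz == 0:
            return sps.butter(self.order, self.high_hz, btype="lowpass", fs=fs, output="sos")
        return sps.butter(
            self.order, [self.low_hz, self.high_hz], btype="bandpass", fs=fs, output="sos"
        )


def _sosfiltfilt(sos: np.ndarray, x: np.ndarray) -> np.ndarray:
    try:
        return sps.sosfiltfilt(sos, x, axis=0)
    except ValueError as exc:  # padlen exceeds signal length
        raise TooShortError(f"record too short for zero-phase filtering: {exc}") from exc


def bandpass(rec: Recording, band: BandSpec) -> Recording:
    """Zero-phase Butterworth band-pass, applied per channel.

    Forward-backward application squares the magnitude response and
    cancels the phase, so narrow transients (blink peaks) stay aligned
    across the filtered and unfiltered versions of the data.
    """
    sos = band.sos(rec.fs)
    return rec.copy_with(_sosfiltfilt(sos, rec.data))


def filter_trace(x: np.ndarray, fs: float, band: BandSpec) -> np.ndarray:
    """Zero-phase filter a single 1-D trace (same design as :func:`bandpass`)."""
    return _sosfiltfilt(band.sos(fs), np.asarray(x, dtype=np.float64))


def flag_bad_channels(rec: Recording) -> list[str]:
    """Flag channels whose amplitude deviates grossly from the ensemble.

    A channel is flagged when its standard deviation across time exceeds
    4x, or falls below 1/6 of, the mean standard deviation over all
    channels.  The decision is scale-free: rescaling every channel by a
    common positive factor leaves the flags unchanged.  Flagging is
    reported only; no interpolation or removal is applied.
    """
    if rec.n_samples < 2:
        raise TooShortError("need at least 2 samples to estimate channel std")
    stds = rec.data.std(axis=0)
    mean_std = stds.mean()
    if mean_std == 0:
        return []
    bad = (stds > 4.0 * mean_std) | (stds < mean_std / 6.0)
    return [lab for lab, b in zip(rec.channel_labels, bad) if b]


def slice_epochs(
    rec: Recording, centers: list[int], half_width_s: float
) -> list[Recording]:
    """Fixed-length windows centered on sample indices.

    Every returned epoch has exactly ``round(2 * half_width_s * fs)``
    samples, spanning ``[center - w//2, center - w//2 + w)``.  Windows
    that would cross either record boundary are dropped, not padded.
    """
    if half_width_s <= 0:
        raise ValueError("half_width_s must be positive")
    width = int(round(2.0 * half_width_s * rec.fs))
    out: list[Recording] = []
    for c in centers:
        start = int(c) - width // 2
        stop = start + width
        if start < 0 or stop > rec.n_samples:
            continue
        out.append(Recording(rec.data[start:stop].copy(), rec.fs, list(rec.channel_labels)))
    return out
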