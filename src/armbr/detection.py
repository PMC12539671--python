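"""Blink detection: reference trace, robust statistics, mask, segment rejection.

The blink reference ``B_ref`` is the average of the designated
blink-affected channels (typically Fp1 and Fp2).  Blinks show up as large
positive monophasic deflections, so the reference distribution is heavily
right-skewed; thresholding its upper tail yields a binary blink mask that
serves as the regression target for the spatial-filter fit.

The robust scale estimate nu = (Q_0.841 - Q_0.159) / 2 equals sigma for a
Gaussian, but being quantile-based it is insensitive to the isolated
high-voltage excursions the mask is meant to find.  The threshold is
T0 = Q_2 + alpha0 * nu for a multiplier alpha0 (chosen automatically by
:mod:`armbr.autothreshold` or given manually).

High-voltage non-blink transients would corrupt both the quantiles and
the regression; :func:`reject_segments` drops 15 s segments whose maximum
absolute first derivative is an outlier relative to the preceding
segments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats as spstats

from .exceptions import MissingChannelError, TooShortError
from .signal_core import Recording

__all__ = [
    "BlinkReference",
    "RobustStats",
    "BlinkMask",
    "SegmentRejection",
    "build_blink_reference",
    "orient_right_skew",
    "robust_stats",
    "compute_threshold",
    "make_mask",
    "reject_segments",
]


@dataclass
class BlinkReference:
    """Single blink-summary trace plus its provenance.

    ``orientation_sign`` is -1 when the trace was negated to make its
    distribution right-skewed (blinks must sit in the upper tail).
    """

    trace: np.ndarray
    source_labels: list[str]
    orientation_sign: int = 1

    def __post_init__(self) -> None:
        self.trace = np.asarray(self.trace, dtype=np.float64).ravel()


@dataclass(frozen=True)
class RobustStats:
    """Quantile-based location/scale summary of the blink reference."""

    q_a: float  # 0.159 quantile
    q_b: float  # 0.841 quantile
    q2: float  # median
    nu: float  # (q_b - q_a) / 2; equals sigma for a Gaussian


@dataclass
class BlinkMask:
    """Binary per-sample blink indicator with the threshold that produced it."""

    mask: np.ndarray
    threshold: float
    stats: RobustStats | None = None
    alpha0: float | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=np.float64).ravel()

    @property
    def n_active(self) -> int:
        return int(self.mask.sum())

    def intervals(self, fs: float) -> list[tuple[float, float]]:
        """Contiguous mask runs as (onset_s, duration_s) pairs."""
        out = []
        for start, stop in _runs(self.mask > 0):
            out.append((start / fs, (stop - start) / fs))
        return out


@dataclass
class SegmentRejection:
    """Outcome of the derivative-based high-voltage segment screen."""

    segment_len_s: float
    k_sigma: float
    rejected: list[int]
    per_segment_max_abs_derivative: np.ndarray
    segment_len_samples: int
    n_segments: int

    def retained_samples(self, n_samples: int) -> np.ndarray:
        """Boolean vector, False inside rejected segments.

        Samples past the last full segment are always retained.
        """
        keep = np.ones(n_samples, dtype=bool)
        L = self.segment_len_samples
        for s in self.rejected:
            keep[s * L : (s + 1) * L] = False
        return keep


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) runs of True in a boolean vector."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[::2], idx[1::2]))


def build_blink_reference(rec: Recording, blink_channels: list[str]) -> BlinkReference:
    """Average the designated blink-affected channels into one trace."""
    if not blink_channels:
        raise MissingChannelError("blink_channels must be non-empty")
    idx = [rec.channel_index(lab) for lab in blink_channels]
    trace = rec.data[:, idx].mean(axis=1)
    return BlinkReference(trace=trace, source_labels=list(blink_channels))


def orient_right_skew(ref: BlinkReference) -> BlinkReference:
    """Negate the trace if its sample skewness is negative.

    Blinks are positive deflections above the eyes, so after averaging,
    the reference should carry its artifact mass in the right tail.  If a
    montage or referencing flip produced a left-skewed trace, negation
    restores the convention.  Exactly-zero skewness (including constant
    traces) is left untouched; the operation is idempotent.
    """
    t = ref.trace
    if t.std() == 0:
        return ref
    skew = spstats.skew(t)
    if skew < 0:
        return replace(ref, trace=-t, orientation_sign=-ref.orientation_sign)
    return ref


def robust_stats(ref: BlinkReference, retain: np.ndarray | None = None) -> RobustStats:
    """Empirical 0.159 / 0.5 / 0.841 quantiles and the derived scale nu.

    Quantiles use linear interpolation between order statistics.  When a
    ``retain`` boolean vector is given (from segment rejection), only the
    retained samples enter the quantile estimate.
    """
    t = ref.trace if retain is None else ref.trace[retain]
    if t.size < 2:
        raise TooShortError("need at least 2 samples for quantile statistics")
    q_a, q2, q_b = np.quantile(t, [0.159, 0.5, 0.841])
    return RobustStats(q_a=float(q_a), q_b=float(q_b), q2=float(q2), nu=float((q_b - q_a) / 2.0))


def compute_threshold(stats: RobustStats, alpha0: float) -> float:
    """Blink threshold T0 = median + alpha0 * nu."""
    if alpha0 <= 0:
        raise ValueError("alpha0 must be positive")
    return stats.q2 + alpha0 * stats.nu


def make_mask(
    ref: BlinkReference,
    threshold: float,
    stats: RobustStats | None = None,
    alpha0: float | None = None,
    retain: np.ndarray | None = None,
) -> BlinkMask:
    """Binarize the reference: 1 where trace strictly exceeds the threshold.

    Samples inside rejected segments (``retain`` False) are forced to 0 so
    they never enter the regression target.
    """
    mask = (ref.trace > threshold).astype(np.float64)
    if retain is not None:
        mask[~np.asarray(retain, dtype=bool)] = 0.0
    return BlinkMask(mask=mask, threshold=float(threshold), stats=stats, alpha0=alpha0)


def reject_segments(
    ref: BlinkReference,
    fs: float,
    segment_len_s: float = 15.0,
    k_sigma: float = 5.0,
) -> SegmentRejection:
    """Screen fixed-length segments for abrupt high-voltage transients.

    The record is cut into ``segment_len_s`` segments; for each, the
    maximum absolute first difference of the reference trace, A_max, is
    computed.  Segment s is rejected when ``|A_max(s) - mu| > k_sigma *
    sigma``, with mu and sigma the mean and (population) standard
    deviation of A_max over all *previous* segments.  The first segment
    can never be rejected (no prior statistics) and, to avoid the
    degenerate sigma = 0 situation with a single predecessor, rejection
    only triggers from the third segment on.
    """
    L = int(round(segment_len_s * fs))
    n = ref.trace.size
    n_seg = n // L
    if n_seg < 1:
        raise TooShortError(
            f"record ({n} samples) shorter than one {segment_len_s} s segment ({L} samples)"
        )
    a_max = np.empty(n_seg)
    for s in range(n_seg):
        seg = ref.trace[s * L : (s + 1) * L]
        a_max[s] = np.abs(np.diff(seg)).max() if seg.size > 1 else 0.0
    rejected: list[int] = []
    for s in range(2, n_seg):
        prev = a_max[:s]
        mu, sigma = prev.mean(), prev.std()
        if np.abs(a_max[s] - mu) > k_sigma * sigma:
            rejected.append(s)
    if rejected:
        warnings.warn(
            f"rejected {len(rejected)} high-voltage segment(s): {rejected}",
            stacklevel=2,
        )
    return SegmentRejection(
        segment_len_s=segment_len_s,
        k_sigma=k_sigma,
        rejected=rejected,
        per_segment_max_abs_derivative=a_max,
        segment_len_samples=L,
        n_segments=n_seg,
    )
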