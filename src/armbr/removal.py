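"""Spatial-filter fitting and blink purging by backward regression.

Given the data matrix ``X`` (N samples x C channels) and the binary blink
mask ``B_mask`` (N x P, P = 1 for blinks), the spatial filter solves the
backward least-squares problem

    [X, 1] . W* = B_mask,      W*^T = [W^T, k]

i.e. the mask is regressed *on* the multichannel data (hence "backward":
the artifact reference is the target, not a regressor).  The appended
ones column estimates the intercept k, so any common DC offset in the
channels is absorbed and does not tilt the filter.

Each filter column is rescaled so that the spatially filtered training
signal X.W has unit (population) variance.  With the sensor covariance
Sigma of the training data, the spatial pattern is

    A = Sigma . W

(valid under the assumption that the artifact source is uncorrelated
with the remaining sources), and the purge matrix

    M_purge = I - W . W^T . Sigma

is an oblique projector: the unit-variance rescale makes W^T.Sigma.W the
identity, so M_purge is idempotent and removes exactly the P-dimensional
artifact subspace.  Cleaning is a single right-multiplication,

    X_purged = X . M_purge,        B_c = X . W,

and because the map is per-sample linear, a fitted model can be applied
to streamed chunks with output identical to batch processing.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import linalg as spla

from .detection import (
    BlinkMask,
    BlinkReference,
    SegmentRejection,
    build_blink_reference,
    compute_threshold,
    make_mask,
    orient_right_skew,
    reject_segments,
    robust_stats,
)
from .exceptions import (
    ChannelMismatchError,
    DegenerateMaskError,
    NoBlinkError,
    TooShortError,
)
from .signal_core import Recording

__all__ = [
    "SpatialModel",
    "PurgeResult",
    "fit_spatial_filter",
    "purge",
    "apply_pretrained",
    "fit_and_purge",
    "save_model",
    "load_model",
]


@dataclass
class SpatialModel:
    """Fitted blink spatial filter, pattern, covariance and purge matrix.

    Invariants (on the training data, P = 1):

    * var(X . W) == 1 per column,
    * A == Sigma . W,
    * M_purge == I - W . W^T . Sigma and M_purge is idempotent,
    * X_purged . W == 0.
    """

    W: np.ndarray  # C x P spatial filters, unit-variance scaled
    A: np.ndarray  # C x P spatial patterns
    Sigma: np.ndarray  # C x C training sensor covariance (centered, population)
    intercept: np.ndarray  # length P, rescaled with its filter column
    M_purge: np.ndarray  # C x C oblique projector
    training_fs: float
    channel_labels: list[str]

    @property
    def n_components(self) -> int:
        return self.W.shape[1]


@dataclass
class PurgeResult:
    """Purged recording plus the extracted blink component time course."""

    purged: Recording
    blink_component: np.ndarray  # N x P


def _as_mask_matrix(mask: BlinkMask | np.ndarray, n_samples: int) -> np.ndarray:
    b = mask.mask if isinstance(mask, BlinkMask) else np.asarray(mask, dtype=np.float64)
    if b.ndim == 1:
        b = b[:, None]
    if b.shape[0] != n_samples:
        raise ValueError(f"mask length {b.shape[0]} does not match record length {n_samples}")
    return b


def fit_spatial_filter(
    rec: Recording,
    mask: BlinkMask | np.ndarray,
    retain: np.ndarray | None = None,
) -> SpatialModel:
    """Solve the backward regression and assemble the purge operator.

    Parameters
    ----------
    rec : Recording
        Training data, N x C.
    mask : BlinkMask or ndarray (N,) or (N, P)
        Regression target(s).  Must contain at least one 0 and one 1 per
        column among the retained samples.
    retain : boolean ndarray (N,), optional
        Rows to use for fitting (False rows -- rejected segments -- are
        excluded from the design matrix and from Sigma).

    Notes
    -----
    The least-squares problem is solved by SVD (``scipy.linalg.lstsq``)
    rather than the literal normal equations; on a rank-deficient design
    this degrades gracefully to the minimum-norm pseudo-inverse solution,
    with a warning.  Sigma is the population covariance of the
    mean-centered retained rows, which keeps A = Sigma.W and the
    idempotence of M_purge consistent with the unit-variance rescale.
    """
    B = _as_mask_matrix(mask, rec.n_samples)
    X = rec.data
    if retain is not None:
        keep = np.asarray(retain, dtype=bool)
        X = X[keep]
        B = B[keep]
    n, c = X.shape
    for p in range(B.shape[1]):
        col = B[:, p]
        if col.max() == col.min():
            raise DegenerateMaskError(
                f"mask column {p} is constant among retained samples"
            )
    if c >= n:
        raise TooShortError(f"need more samples ({n}) than channels ({c}) to fit")

    Xs = np.column_stack([X, np.ones(n)])
    W_star, _, rank, _ = spla.lstsq(Xs, B)
    if rank < c + 1:
        warnings.warn(
            f"rank-deficient design (rank {rank} < {c + 1}); "
            "minimum-norm pseudo-inverse solution used",
            stacklevel=2,
        )
    W = W_star[:c].copy()
    k = W_star[c].copy()

    # unit-variance rescale of each component on the training data
    Y = X @ W
    scale = Y.std(axis=0)  # population convention
    if np.any(scale == 0):
        raise DegenerateMaskError("spatially filtered training signal has zero variance")
    W /= scale
    k /= scale

    Sigma = np.cov(X, rowvar=False, ddof=0)
    Sigma = np.atleast_2d(Sigma)
    A = Sigma @ W
    M = np.eye(c) - W @ W.T @ Sigma
    return SpatialModel(
        W=W,
        A=A,
        Sigma=Sigma,
        intercept=np.atleast_1d(k),
        M_purge=M,
        training_fs=rec.fs,
        channel_labels=list(rec.channel_labels),
    )


def purge(rec: Recording, model: SpatialModel) -> PurgeResult:
    """Remove the blink subspace: X_purged = X.M_purge, B_c = X.W."""
    if rec.channel_labels != model.channel_labels:
        raise ChannelMismatchError(
            "recording channels do not match model channels (order-sensitive)"
        )
    purged = rec.copy_with(rec.data @ model.M_purge)
    bc = rec.data @ model.W
    return PurgeResult(purged=purged, blink_component=bc)


def apply_pretrained(chunk: Recording, model: SpatialModel) -> PurgeResult:
    """Apply a fitted model to new data, arbitrarily short chunks included.

    The purge is a per-sample linear map, so concatenating chunk-wise
    outputs is bit-identical to purging the concatenated record in one
    batch call.
    """
    return purge(chunk, model)


def fit_and_purge(
    rec: Recording,
    blink_channels: list[str],
    alpha0: float | str = "auto",
    alpha_step: float = 0.1,
    segment_len_s: float = 15.0,
    k_sigma: float = 5.0,
) -> tuple[SpatialModel, PurgeResult, BlinkMask]:
    """Full pipeline: reference, rejection, threshold, fit, purge.

    Steps: average blink channels into B_ref; enforce right skew; reject
    high-voltage segments (skipped when the record is shorter than one
    segment); robust quantile stats on retained samples; threshold either
    at the given ``alpha0`` or by the automatic band-power sweep; fit the
    spatial filter on retained rows; purge the *full* record.
    """
    from .autothreshold import MIN_BLINK_DELTA, select_alpha  # local import: avoid cycle

    ref = orient_right_skew(build_blink_reference(rec, blink_channels))
    retain: np.ndarray | None = None
    rejection: SegmentRejection | None = None
    if rec.n_samples >= int(round(segment_len_s * rec.fs)):
        rejection = reject_segments(ref, rec.fs, segment_len_s, k_sigma)
        if rejection.rejected:
            retain = rejection.retained_samples(rec.n_samples)
    stats = robust_stats(ref, retain=retain)
    if alpha0 == "auto":
        sweep = select_alpha(rec, ref, stats, step=alpha_step, retain=retain)
        finite = sweep.delta[np.isfinite(sweep.delta)]
        has_inf = bool(np.any(np.isinf(sweep.delta) & (sweep.delta > 0)))
        d_best = finite.max() if finite.size else 0.0
        if not has_inf and d_best < MIN_BLINK_DELTA:
            raise NoBlinkError(
                f"best band-energy ratio {d_best:.3g} < {MIN_BLINK_DELTA:g}: the "
                "extracted component is not low-band dominated; the recording "
                "appears to contain no blinks"
            )
        alpha_val, t0 = sweep.alpha_star, sweep.t0_star
    else:
        alpha_val = float(alpha0)
        t0 = compute_threshold(stats, alpha_val)
    bmask = make_mask(ref, t0, stats=stats, alpha0=alpha_val, retain=retain)
    kept = bmask.mask if retain is None else bmask.mask[retain]
    if kept.max() == kept.min():
        raise NoBlinkError(
            f"degenerate blink mask at alpha0={alpha_val:g} "
            f"(T0={t0:g}, nu={stats.nu:g}): no blink found"
        )
    model = fit_spatial_filter(rec, bmask, retain=retain)
    result = purge(rec, model)
    return model, result, bmask


def save_model(model: SpatialModel, path: str | Path) -> None:
    """Serialize a model to JSON text; matrices round-trip bit-exactly."""
    payload = {
        "format": "armbr-spatial-model",
        "version": 1,
        "channel_labels": model.channel_labels,
        "training_fs": model.training_fs,
        "W": model.W.tolist(),
        "A": model.A.tolist(),
        "Sigma": model.Sigma.tolist(),
        "intercept": model.intercept.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path: str | Path) -> SpatialModel:
    payload = json.loads(Path(path).read_text())
    W = np.asarray(payload["W"], dtype=np.float64)
    Sigma = np.asarray(payload["Sigma"], dtype=np.float64)
    return SpatialModel(
        W=W,
        A=np.asarray(payload["A"], dtype=np.float64),
        Sigma=Sigma,
        intercept=np.asarray(payload["intercept"], dtype=np.float64),
        M_purge=np.eye(W.shape[0]) - W @ W.T @ Sigma,
        training_fs=float(payload["training_fs"]),
        channel_labels=list(payload["channel_labels"]),
    )
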