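"""Reading and writing recordings, masks, models and reports.

Supported input formats: EDF, BDF, FIF (via MNE; amplitudes converted
from volts to microvolts on ingest) and delimited text with a
channel-label header row (one column per channel; the sampling rate must
then be supplied by the caller).  Output mirrors FIF and delimited text;
EDF/BDF outputs fall back to delimited text.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .detection import BlinkMask
from .exceptions import FormatError
from .signal_core import Recording

__all__ = [
    "read_recording",
    "write_recording",
    "write_mask",
    "write_intervals",
    "read_intervals",
]

_TEXT_SUFFIXES = {".txt", ".csv", ".tsv", ".dat"}


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt:
        return fmt.lower()
    suffix = path.suffix.lower()
    if suffix in {".edf", ".bdf", ".fif"}:
        return suffix[1:]
    if suffix in _TEXT_SUFFIXES:
        return "txt"
    raise FormatError(f"cannot infer format from {path.name!r}; pass an explicit format")


def read_recording(
    path: str | Path, fmt: str | None = None, fs: float | None = None
) -> Recording:
    """Load a multichannel recording; amplitudes in microvolts.

    For text input the first row holds channel labels and ``fs`` is
    required.  NaN/Inf anywhere in the data is rejected.
    """
    path = Path(path)
    kind = _infer_format(path, fmt)
    if kind == "txt":
        if fs is None:
            raise FormatError("sampling rate fs is required for delimited-text input")
        sep = "\t" if path.suffix.lower() == ".tsv" else None
        try:
            df = pd.read_csv(path, sep=sep, engine="python")
        except Exception as exc:
            raise FormatError(f"unreadable delimited file {path}: {exc}") from exc
        data = df.to_numpy(dtype=np.float64)
        if not np.isfinite(data).all():
            raise FormatError(f"{path} contains NaN or Inf values")
        return Recording(data, fs, [str(c) for c in df.columns])
    if kind in {"edf", "bdf", "fif"}:
        import mne

        readers = {
            "edf": mne.io.read_raw_edf,
            "bdf": mne.io.read_raw_bdf,
            "fif": mne.io.read_raw_fif,
        }
        try:
            raw = readers[kind](str(path), preload=True, verbose="error")
        except Exception as exc:
            raise FormatError(f"unreadable {kind} file {path}: {exc}") from exc
        data = raw.get_data().T * 1e6  # volts -> microvolts
        if not np.isfinite(data).all():
            raise FormatError(f"{path} contains NaN or Inf values")
        return Recording(data, float(raw.info["sfreq"]), list(raw.ch_names))
    raise FormatError(f"unsupported format {kind!r}")


def write_recording(rec: Recording, path: str | Path, fmt: str | None = None) -> Path:
    """Write a recording; returns the path actually written.

    FIF is written through MNE (converted back to volts).  EDF/BDF
    export is not supported and silently falls back to delimited text
    with a ``.csv`` suffix.
    """
    path = Path(path)
    kind = _infer_format(path, fmt)
    if kind == "fif":
        import mne

        info = mne.create_info(rec.channel_labels, rec.fs, ch_types="eeg")
        raw = mne.io.RawArray(rec.data.T * 1e-6, info, verbose="error")
        raw.save(str(path), overwrite=True, verbose="error")
        return path
    if kind in {"edf", "bdf"}:
        path = path.with_suffix(".csv")
        kind = "txt"
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    pd.DataFrame(rec.data, columns=rec.channel_labels).to_csv(path, sep=sep, index=False)
    return path


def write_mask(mask: BlinkMask, path: str | Path) -> None:
    """Two-column delimited export: sample_index, mask_value."""
    arr = np.column_stack([np.arange(mask.mask.size), mask.mask.astype(int)])
    pd.DataFrame(arr, columns=["sample_index", "mask_value"]).to_csv(path, index=False)


def write_intervals(intervals: list[tuple[float, float]], path: str | Path,
                    label: str = "blink") -> None:
    """Annotation-style export: onset_s, duration_s, label."""
    rows = [{"onset_s": a, "duration_s": b, "label": label} for a, b in intervals]
    pd.DataFrame(rows, columns=["onset_s", "duration_s", "label"]).to_csv(path, index=False)


def read_intervals(path: str | Path) -> list[tuple[float, float]]:
    df = pd.read_csv(path)
    return [(float(r["onset_s"]), float(r["duration_s"])) for _, r in df.iterrows()]
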