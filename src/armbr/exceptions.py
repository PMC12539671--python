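"""Exception hierarchy.

Every error raised by the library derives from :class:`ArmbrError` and
carries a short machine-parsable ``reason`` string used by the CLI for
one-line diagnostics.
"""


class ArmbrError(Exception):
    """Base class for all library errors."""

    reason = "error"


class InvalidBandError(ArmbrError):
    """Filter band edges invalid for the sampling rate."""

    reason = "invalid-band"


class TooShortError(ArmbrError):
    """Record too short for the requested operation."""

    reason = "too-short"


class MissingChannelError(ArmbrError):
    """A requested channel label is not present in the recording."""

    reason = "missing-channel"


class ChannelMismatchError(ArmbrError):
    """Recording channels do not match the fitted model's channels."""

    reason = "channel-mismatch"


class DegenerateMaskError(ArmbrError):
    """Blink mask is all-zero or all-one; regression target is degenerate."""

    reason = "degenerate-mask"


class NoBlinkError(ArmbrError):
    """No usable blink activity found at any candidate threshold."""

    reason = "no-blink"


class UndefinedEnergyError(ArmbrError):
    """Signal has zero total energy; band-energy ratio undefined."""

    reason = "undefined-energy"


class OverlapError(ArmbrError):
    """Requested blink rate cannot be realized without overlapping blinks."""

    reason = "overlap"


class ConstantSignalError(ArmbrError):
    """A metric requiring variability was given a constant signal."""

    reason = "constant-signal"


class ZeroPowerError(ArmbrError):
    """A PSD bin of the reference signal is zero; relative error undefined."""

    reason = "zero-power"


class FormatError(ArmbrError):
    """Unreadable or malformed input file."""

    reason = "format"
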