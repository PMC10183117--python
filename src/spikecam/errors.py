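"""Exception hierarchy.

Every error the toolkit raises deliberately derives from :class:`SpikecamError`
so that callers (and the CLI) can distinguish toolkit failures from bugs.
"""


class SpikecamError(Exception):
    """Base class for all toolkit errors."""


class ConfigurationError(SpikecamError):
    """Invalid user-supplied configuration (specs, thresholds, rates)."""


class InputError(SpikecamError):
    """Invalid data handed to an operation (shape, range, degenerate box)."""


class FormatError(SpikecamError):
    """Inconsistent or malformed on-disk data (e.g. mismatched array dumps)."""


class ParseError(FormatError):
    """Unparseable text row; carries the offending line number in its message."""


class ValidationError(FormatError):
    """Parsed but semantically invalid record (e.g. inverted box corners)."""


class LayerLookupError(SpikecamError, KeyError):
    """A referenced detection layer or (image, layer) mask does not exist."""

    def __str__(self) -> str:  # KeyError quotes its args; keep the message readable
        return Exception.__str__(self)


class StatisticsError(SpikecamError):
    """Statistic requested on an empty or inconsistent record set."""


class GenerationError(SpikecamError):
    """Synthetic-scene placement failed (overcrowded specification)."""
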