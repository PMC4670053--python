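"""Exception hierarchy shared across the package."""


class SongscanError(Exception):
    """Base class for all package-specific errors."""


class AudioFormatError(SongscanError, ValueError):
    """Unreadable, empty or unsupported audio input."""


class SchemaError(SongscanError, ValueError):
    """A table is missing required columns or a model schema does not match."""


class TableParseError(SongscanError, ValueError):
    """A selection table cell could not be parsed."""


class LabelError(SongscanError, ValueError):
    """An annotation class label is outside the allowed set."""


class ModelIOError(SongscanError, ValueError):
    """A serialized model file is truncated, corrupt or of the wrong version."""
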