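"""Exception hierarchy shared across the pipeline.

CLI exit-code mapping: ``InputError``/``ParameterError``/``FormatError`` ->
exit 2 (bad input), ``CapabilityError`` -> exit 3 (missing capability),
anything else -> exit 1.
"""


class SpeechSevError(Exception):
    """Base class for all package errors."""


class InputError(SpeechSevError):
    """Input data is missing, empty, or structurally invalid."""


class FormatError(InputError):
    """A file exists but is not in a readable format."""


class ParameterError(SpeechSevError):
    """A parameter value is outside its documented domain."""


class ConsistencyError(SpeechSevError):
    """Two objects that must share geometry or schema do not."""


class CapabilityError(SpeechSevError):
    """A required backend (e.g. a speech-to-text engine) is unavailable."""
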