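"""Exception hierarchy.

Configuration problems (bad parameters, impossible designs) are distinguished
from data problems (malformed containers, degenerate inputs) so that callers —
in particular the command-line interface — can map them to distinct exit codes.
"""


class AlphaRhythmError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(AlphaRhythmError, ValueError):
    """A parameter or design request is invalid or internally inconsistent."""


class DataError(AlphaRhythmError, ValueError):
    """Input data violate a precondition (shape, degeneracy, coverage)."""


class SchemaError(AlphaRhythmError, ValueError):
    """A dataset container does not match the documented schema/version."""
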