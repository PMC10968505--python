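"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: configuration/usage errors -> 1,
I/O errors -> 2, analysis errors -> 3.
"""


class ChromapupilError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(ChromapupilError, ValueError):
    """Invalid optical geometry (non-positive distances, negative offsets)."""


class ConfigurationError(ChromapupilError, ValueError):
    """Invalid configuration value or combination of values."""


class InputError(ChromapupilError, ValueError):
    """Malformed input data (e.g. duplicate frame indices in a detections table)."""


class AnalysisError(ChromapupilError, RuntimeError):
    """A trial cannot be analysed (no valid baseline samples, empty metric window)."""
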