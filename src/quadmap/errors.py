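"""Exception hierarchy shared across the package."""


class QuadmapError(Exception):
    """Base class for all package errors."""


class ConfigurationError(QuadmapError):
    """Invalid parameters, schedules, geometry presets, or run configs."""


class AnalysisError(QuadmapError):
    """A computation could not be carried out on the given data."""


class RegistrationError(AnalysisError):
    """Image registration failed (e.g. featureless or all-zero input)."""


class FormatError(QuadmapError):
    """A file could not be read or written in the expected format."""
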