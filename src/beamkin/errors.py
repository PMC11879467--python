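"""Package exception hierarchy."""


class BeamkinError(Exception):
    """Base class for all package-specific errors."""


class ParseError(BeamkinError, ValueError):
    """A file could not be parsed; the message names the offending line."""


class ConfigurationError(BeamkinError, ValueError):
    """Invalid or inconsistent run configuration."""


class FitError(BeamkinError, RuntimeError):
    """Threshold fit failed to converge; carries diagnostics."""


class DegenerateDataError(BeamkinError, ValueError):
    """Input data carry no usable signal (e.g. an all-zero cross section)."""
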