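"""Exception hierarchy.

User-facing errors derive from :class:`NirleafError`; the CLI maps them to
exit code 1 and internal faults to 2.
"""


class NirleafError(Exception):
    """Base class for all package errors."""


class GridDefinitionError(NirleafError):
    """Wavelength range is not an integer multiple of the step."""


class SpectraParseError(NirleafError):
    """Malformed spectra CSV (ragged row, bad label, non-uniform header)."""


class DegenerateSpectrumError(NirleafError):
    """A spectrum has no spread (constant row) where spread is required."""


class ParameterError(NirleafError):
    """Invalid operator, split or model parameter."""


class PipelineError(NirleafError):
    """A preprocessing step failed; carries the step index in the message."""


class ArchitectureError(NirleafError):
    """A layer specification produces a non-positive output length."""


class TrainingError(NirleafError):
    """Model training could not proceed (shape mismatch, divergence...)."""


class ConfigError(NirleafError):
    """Unknown or invalid key in a run configuration."""
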