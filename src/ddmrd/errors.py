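"""Exception hierarchy.

All package errors derive from :class:`DdmrdError` so callers (and the CLI)
can distinguish usage/configuration problems, malformed input files,
invariant violations, and invalid runs (failed plate controls).
"""


class DdmrdError(Exception):
    """Base class for all ddmrd errors."""


class ConfigurationError(DdmrdError):
    """Invalid configuration, rules or simulation parameters."""


class FormatError(DdmrdError):
    """A file could not be parsed: missing columns, unknown labels."""


class ValidationError(DdmrdError):
    """Data violates an invariant (e.g. more positive than accepted droplets)."""


class ControlInadequateError(DdmrdError):
    """The control gene failed QC or is unquantified; a ratio is undefined."""


class RunInvalidError(DdmrdError):
    """Plate controls failed (contaminated NTC, dead positive control)."""
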