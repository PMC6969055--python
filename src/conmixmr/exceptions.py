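"""Exception hierarchy.

``MRInputError`` marks problems with user-supplied data or configuration
(bad columns, zero exposure associations, invalid parameter ranges) and maps
to CLI exit code 2.  ``EstimationError`` marks failures inside a numerical
routine and maps to exit code 3.
"""


class ConmixError(Exception):
    """Base class for all package errors."""


class MRInputError(ConmixError, ValueError):
    """Invalid input data or configuration."""


class EstimationError(ConmixError, RuntimeError):
    """A numerical routine failed (non-finite likelihood, degenerate fit)."""
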