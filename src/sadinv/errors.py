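"""Exception hierarchy shared across the package.

Validation errors map to CLI exit code 2, numerical failures to exit code 3.
"""


class SadinvError(Exception):
    """Base class for package errors."""


class ValidationError(SadinvError):
    """Invalid user input: parameters, files, configuration."""


class NumericalError(SadinvError):
    """A numerical routine failed: divergent integral, non-convergence."""


class DivergentIntegralError(NumericalError):
    """Normalization integral diverges; message names the offending tail."""


class InfeasibleConstraintsError(NumericalError):
    """Maximum-entropy targets lie outside the attainable moment set."""
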