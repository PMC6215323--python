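"""Exception hierarchy shared across the package.

Validation problems (bad inputs, bad config) and numerical failures
(non-convergence) are distinguished so the command-line layer can map them
to distinct exit codes.
"""


class OxGradError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(OxGradError, ValueError):
    """Invalid user input: geometry, config, track file, image shapes."""


class NumericalError(OxGradError, RuntimeError):
    """A solver failed to converge or produced an unusable result."""
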