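"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: validation/format problems -> 1,
numerical problems -> 2, I/O problems -> 3.
"""


class PamfluxError(Exception):
    """Base class for all package errors."""


class ValidationError(PamfluxError):
    """Invalid parameters, designs, or controlled-vocabulary violations."""


class FormatError(ValidationError):
    """Malformed on-disk file; message carries file and line context."""


class ProtocolError(ValidationError):
    """A measurement protocol is inconsistent or incomplete."""


class ExtractionError(PamfluxError):
    """A landmark expected by the protocol could not be located in a trace."""


class DegenerateDataError(PamfluxError):
    """Data admit no meaningful statistic (e.g. zero residual variance, VJ=1)."""


class NumericalError(PamfluxError):
    """A numerical routine failed to converge or hit a division guard."""
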