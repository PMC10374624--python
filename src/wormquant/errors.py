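"""Exception hierarchy shared across the pipeline.

Validation errors (bad configs, malformed inputs, contract violations) are
kept distinct from numerical failures (non-convergence, degenerate fits) so
the command-line layer can map them to different exit codes.
"""


class WormquantError(Exception):
    """Base class for all package errors."""


class ValidationError(WormquantError):
    """Invalid configuration or input; names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class NumericalError(WormquantError):
    """A numerical procedure failed (non-convergence, degenerate system)."""
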