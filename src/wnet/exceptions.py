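"""Error types shared across the pipeline."""


class WnetError(Exception):
    """Base class for all wnet errors."""


class InvalidArgumentError(WnetError, ValueError):
    """An argument violates a precondition (bad band, threshold, shape...)."""


class DegenerateInputError(WnetError, ValueError):
    """Input is structurally valid but degenerate (all-zero matrix,
    fully disconnected graph, empty observation set)."""


class FormatError(WnetError, ValueError):
    """A file does not conform to the expected on-disk format."""


class FitFailureError(WnetError, RuntimeError):
    """Nonlinear fit failed to converge from every starting point."""
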