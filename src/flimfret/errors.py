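"""Exception types shared across the package."""


class InvalidInputError(ValueError):
    """Raised when an input violates a documented precondition."""


class FitDegenerateError(RuntimeError):
    """Raised when a fit problem carries no recoverable signal (e.g. a flat
    titration series with no protonation transition)."""


class UndefinedDistanceError(ValueError):
    """Raised when a donor-acceptor distance is requested at a transfer
    efficiency of exactly 0 or 1, where the inverse of the FRET law diverges."""
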