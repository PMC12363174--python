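"""Exception types shared across the package."""


class FormatError(ValueError):
    """Malformed input record (bad strand symbol, start > end, non-amino-acid
    characters, duplicate tip labels, ...). The message names the offender."""


class InsufficientDataError(ValueError):
    """Not enough complete observations to run the requested statistic."""


class UndefinedScoreError(ValueError):
    """A score whose denominator is empty (e.g. focal strain with no traits)."""


class CalibrationError(RuntimeError):
    """A standard curve that cannot be inverted (non-negative slope)."""


class NumericalFailure(RuntimeError):
    """Non-finite state encountered during simulation."""
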