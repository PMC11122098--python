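"""Exception hierarchy for frfit."""


class FrfitError(Exception):
    """Base class for all frfit errors."""


class SchemaError(FrfitError):
    """A tabular input is missing required columns or has a malformed header."""


class ValidationError(FrfitError):
    """A record violates the predation-trial invariants (e.g. more prey eaten
    than offered)."""


class NumericalError(FrfitError):
    """A numerical routine (implicit-equation solver) failed to converge."""


class FitError(FrfitError):
    """A model fit could not be carried out (invalid preconditions, not a
    failure to converge — non-convergence is reported in the result object)."""
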