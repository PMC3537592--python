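"""Exception hierarchy.

Validation problems (bad tables, bad arguments) and degenerate-data problems
(constant traits, too few samples) are kept distinct so the command-line layer
can map them onto different exit codes.
"""


class PGainError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(PGainError):
    """Malformed input: bad file schema, duplicate IDs, out-of-range argument."""


class NonPositiveConcentrationError(ValidationError):
    """Concentrations that cannot enter a log-ratio (zero, negative, NaN, inf).

    Carries the offending sample identifiers/indices in ``samples``.
    """

    def __init__(self, message, samples=None):
        super().__init__(message)
        self.samples = list(samples) if samples is not None else []


class DegenerateInputError(PGainError):
    """Data that makes a fit meaningless: constant trait, constant response."""


class InsufficientSamplesError(DegenerateInputError):
    """Fewer complete cases than the model has parameters (plus one)."""


class NotPositiveSemidefiniteError(ValidationError):
    """A requested correlation matrix is not PSD beyond tolerance.

    ``min_eigenvalue`` reports the offending eigenvalue.
    """

    def __init__(self, message, min_eigenvalue=None):
        super().__init__(message)
        self.min_eigenvalue = min_eigenvalue


class InsufficientReplicatesError(ValidationError):
    """Too few Monte Carlo replicates to resolve a requested tail quantile.

    ``required_reps`` states the minimum replicate count that would suffice.
    """

    def __init__(self, message, required_reps=None):
        super().__init__(message)
        self.required_reps = required_reps
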