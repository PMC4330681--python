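"""Exception hierarchy shared across the package."""


class TraitNicheError(Exception):
    """Base class for all package errors."""


class InvalidRecordError(TraitNicheError):
    """A measurement record violates its physical invariants."""


class UndefinedTraitError(TraitNicheError):
    """A trait value is mathematically undefined for this record."""


class ValidationError(TraitNicheError):
    """An input matrix, table or alignment fails a structural invariant."""


class UndefinedStatisticError(TraitNicheError):
    """A statistic cannot be computed (e.g. zero variance in a pair vector)."""


class SpeciesMismatchError(ValidationError):
    """Species identifiers differ between inputs that must align."""

    def __init__(self, message, offending=()):
        super().__init__(message)
        self.offending = sorted(offending)
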