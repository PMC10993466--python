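"""Small shared helpers: rounding and error types."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP


class PaleoPvError(Exception):
    """Base class for package errors."""


class SchemaError(PaleoPvError):
    """An input file is missing required columns or keys."""


class ValidationError(PaleoPvError):
    """A row or record violates a documented invariant."""


class ContractError(PaleoPvError):
    """A function was called outside its documented preconditions."""


class IntegrityError(PaleoPvError):
    """A packaged fixture failed its checksum or schema check."""


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (the convention used for all printed
    percentages), unlike Python's banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """100 * numerator / denominator rounded half away from zero."""
    if denominator == 0:
        raise ContractError("percentage with zero denominator")
    return round_half_away(100.0 * numerator / denominator, ndigits)
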