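"""Shared exceptions and small numeric helpers."""

from __future__ import annotations

import math


class NcycleError(Exception):
    """Base class for all package errors."""


class ParameterError(NcycleError, ValueError):
    """A numeric or structural parameter is outside its allowed range."""


class ConfigurationError(NcycleError, ValueError):
    """Inconsistent user-supplied configuration (sheets, primers, enzymes)."""


class InputError(NcycleError, ValueError):
    """Malformed or empty data input."""


class DegenerateCurveError(NcycleError, ValueError):
    """A standard curve that cannot be inverted (slope >= 0 or constant)."""


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero (unlike banker's rounding)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def percent_of(part: float, whole: float, ndigits: int = 1) -> float:
    """``100 * part / whole`` rounded to `ndigits`, ties away from zero."""
    if whole == 0:
        raise InputError("cannot take a percentage of a zero total")
    return round_half_away(100.0 * part / whole, ndigits)


def percent_reduction(a: float, b: float, ndigits: int = 1) -> float:
    """Relative reduction ``100 * (a - b) / a`` rounded to `ndigits`."""
    if a == 0:
        raise InputError("cannot compute a reduction relative to zero")
    return round_half_away(100.0 * (a - b) / a, ndigits)
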