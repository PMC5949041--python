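"""Q15 fixed-point arithmetic with exact 16/32-bit integer semantics.

The Q15 format stores a real number ``x`` in ``[-1, 1 - 2**-15]`` as the
16-bit signed integer ``round(x * 2**15)``.  Filter coefficients, Goertzel
tuning values and signal samples on the simulated micro-controller all live
in this format; sums of products are accumulated in a 32-bit signed
register, and quotients are cast back to 16 bits with round-half-to-even
("banker's") rounding, the convention that keeps IIR recursions from
drifting under systematic rounding bias.

Everything here is pure integer arithmetic on Python ints (which cannot
silently wrap), so overflow of the modelled 32-bit accumulator is *detected
and raised* rather than reproduced: the simulator's job is to expose
undefined hardware behaviour, not emulate it.  Vectorized helpers operating
on ``numpy`` int64 arrays implement the same rounding bit-exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

Q15_ONE = 1 << 15  #: scale factor: raw = value * 2**15
I16_MIN, I16_MAX = -(1 << 15), (1 << 15) - 1
I32_MIN, I32_MAX = -(1 << 31), (1 << 31) - 1

__all__ = [
    "Q15_ONE",
    "I16_MIN",
    "I16_MAX",
    "I32_MIN",
    "I32_MAX",
    "Q15Sample",
    "Accum32",
    "FixedPointOverflowError",
    "SaturationWarning",
    "to_q15",
    "from_q15",
    "rounded_div",
    "rounded_div_array",
]


class FixedPointOverflowError(ArithmeticError):
    """The modelled 32-bit accumulator (or filter state) overflowed."""


class SaturationWarning(UserWarning):
    """A result exceeded the 16-bit range and was clamped to the rail."""


def to_q15(x: float) -> int:
    """Convert a real number to its Q15 raw integer, nearest with saturation.

    Ties round half-to-even; values outside ``[-1, 1 - 2**-15]`` saturate to
    the 16-bit rails, so ``to_q15(1.0) == 32767`` and ``to_q15(-1.0) == -32768``.

    Raises
    ------
    ValueError
        If ``x`` is NaN or infinite.
    """
    if not math.isfinite(x):
        raise ValueError(f"cannot represent non-finite value {x!r} in Q15")
    raw = round(x * Q15_ONE)  # Python round = half-to-even
    return min(max(raw, I16_MIN), I16_MAX)


def from_q15(raw: int) -> float:
    """Real value represented by a Q15 raw integer (``raw / 2**15``)."""
    if not I16_MIN <= raw <= I16_MAX:
        raise ValueError(f"raw value {raw} outside 16-bit signed range")
    return raw / Q15_ONE


@dataclass(frozen=True)
class Q15Sample:
    """A 16-bit signed fixed-point sample, value ``raw / 2**15`` in [-1, 1)."""

    raw: int

    def __post_init__(self) -> None:
        if not I16_MIN <= self.raw <= I16_MAX:
            raise ValueError(f"raw value {self.raw} outside 16-bit signed range")

    @classmethod
    def from_float(cls, x: float) -> "Q15Sample":
        return cls(to_q15(x))

    @property
    def value(self) -> float:
        return from_q15(self.raw)


class Accum32:
    """32-bit signed accumulator that raises on overflow instead of wrapping.

    Mirrors the long-word register used to sum coefficient-sample products;
    the running sum is checked after every addition so that an intermediate
    overflow is reported even when the final total would fit.
    """

    __slots__ = ("value",)

    def __init__(self, value: int = 0) -> None:
        self.value = 0
        if value:
            self.add(value)

    def _check(self) -> None:
        if not I32_MIN <= self.value <= I32_MAX:
            raise FixedPointOverflowError(
                f"32-bit accumulator overflow: {self.value}"
            )

    def add(self, term: int) -> "Accum32":
        self.value += term
        self._check()
        return self

    def sub(self, term: int) -> "Accum32":
        self.value -= term
        self._check()
        return self


def rounded_div(numerator: int, denominator: int) -> int:
    """Integer division with round-half-to-even on the exact quotient.

    The rounding is applied to the exact rational value
    ``numerator / denominator`` (not truncate-then-adjust), for any sign
    combination.  Results outside the 16-bit signed range are clamped to the
    rail with a :class:`SaturationWarning`.

    Raises
    ------
    ZeroDivisionError
        If ``denominator`` is zero.
    """
    if denominator == 0:
        raise ZeroDivisionError("rounded_div by zero")
    if denominator < 0:
        numerator, denominator = -numerator, -denominator
    q, r = divmod(numerator, denominator)  # floor division: 0 <= r < d
    twice = 2 * r
    if twice > denominator or (twice == denominator and q % 2 != 0):
        q += 1
    if q > I16_MAX or q < I16_MIN:
        warnings.warn(
            f"rounded_div result {q} saturated to 16-bit range",
            SaturationWarning,
            stacklevel=2,
        )
        q = min(max(q, I16_MIN), I16_MAX)
    return q


def rounded_div_array(numerators: np.ndarray, denominator: int) -> np.ndarray:
    """Vectorized :func:`rounded_div` on an int64 array, bit-exact.

    Used by the block-processing filter paths; saturation is applied with a
    single warning if any element clips.
    """
    if denominator == 0:
        raise ZeroDivisionError("rounded_div by zero")
    num = np.asarray(numerators, dtype=np.int64)
    d = int(denominator)
    if d < 0:
        num, d = -num, -d
    q = num // d  # floor
    r = num - q * d
    twice = 2 * r
    bump = (twice > d) | ((twice == d) & (q % 2 != 0))
    q = q + bump
    if np.any(q > I16_MAX) or np.any(q < I16_MIN):
        warnings.warn(
            "rounded_div results saturated to 16-bit range",
            SaturationWarning,
            stacklevel=2,
        )
        q = np.clip(q, I16_MIN, I16_MAX)
    return q
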