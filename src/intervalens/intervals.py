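"""Closed subintervals of [0, 1] and orders on them.

The lattice of interest is ``L^I``, the set of all closed subintervals
``[lower, upper]`` of the unit interval.  The componentwise relation
(``x ⪯ y`` iff both bounds of ``x`` are below the corresponding bounds of
``y``) is only a partial order — e.g. [0.3, 0.5] and [0.1, 0.7] are
incomparable — so classification decisions additionally need one of the
admissible *linear* orders implemented here:

* ``XY`` (Xu–Yager): compare the sum of the bounds; on ties, the narrower
  interval precedes.
* ``LEX1``: compare lower bounds; on ties, upper bounds.
* ``LEX2``: compare upper bounds; on ties, lower bounds.

All three are total, antisymmetric and transitive, and refine ``⪯``.
Order keys are compared exactly, with no tolerance (a tolerance would break
antisymmetry), but the arithmetic behind the Xu–Yager keys is done in exact
rational arithmetic over the shortest-decimal reading of each bound: in
binary floating point ``0.2 + 0.4 > 0.1 + 0.5`` even though the decimal
sums are equal, which would silently misorder intervals whose bounds were
written as decimals.  The decimal reading is injective on floats and
preserves their order, so totality, antisymmetry and transitivity are
unaffected.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from decimal import Decimal
from fractions import Fraction
from typing import Iterator, Sequence


class InvalidIntervalError(ValueError):
    """Raised when bounds do not describe a subinterval of [0, 1]."""


@dataclass(frozen=True)
class Interval:
    """A closed subinterval ``[lower, upper]`` of the unit interval.

    Invariant (enforced at construction): ``0 <= lower <= upper <= 1``.
    Out-of-range bounds are an error, never clipped — normalisation of raw
    classifier scores into [0, 1] happens in the soft-label layer, not here.
    """

    lower: float
    upper: float

    def __post_init__(self) -> None:
        lo, up = float(self.lower), float(self.upper)
        if not (math.isfinite(lo) and math.isfinite(up)):
            raise InvalidIntervalError(f"non-finite bounds [{self.lower}, {self.upper}]")
        if not (0.0 <= lo <= up <= 1.0):
            raise InvalidIntervalError(
                f"[{self.lower}, {self.upper}] is not a valid subinterval of [0, 1]"
            )
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", up)

    @property
    def width(self) -> float:
        """Interval width ``upper - lower`` in [0, 1]."""
        return self.upper - self.lower

    @property
    def sum_key(self) -> float:
        """``lower + upper`` in [0, 2]; the Xu–Yager primary key."""
        return self.lower + self.upper

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lower + self.upper)

    def __iter__(self) -> Iterator[float]:
        yield self.lower
        yield self.upper

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Interval[{self.lower:g}, {self.upper:g}]"


#: The bottom and top elements of the lattice.
BOTTOM = Interval(0.0, 0.0)
TOP = Interval(1.0, 1.0)


def make_interval(lower: float, upper: float) -> Interval:
    """Construct an interval, raising :class:`InvalidIntervalError` if
    ``0 <= lower <= upper <= 1`` does not hold."""
    return Interval(lower, upper)


class TriState(enum.Enum):
    """Outcome of a partial-order comparison."""

    TRUE = "true"
    FALSE = "false"
    INCOMPARABLE = "incomparable"

    def __bool__(self) -> bool:
        return self is TriState.TRUE


class OrderSpec(enum.Enum):
    """One of the admissible linear orders on intervals."""

    XY = "xy"
    LEX1 = "lex1"
    LEX2 = "lex2"

    @classmethod
    def coerce(cls, order: "OrderSpec | str") -> "OrderSpec":
        if isinstance(order, OrderSpec):
            return order
        try:
            return cls(str(order).lower())
        except ValueError:
            valid = ", ".join(o.value for o in cls)
            raise ValueError(f"unknown interval order {order!r}; expected one of: {valid}")


def partial_leq(x: Interval, y: Interval) -> TriState:
    """Componentwise partial order ``x ⪯ y``.

    Returns ``TRUE`` iff ``x.lower <= y.lower`` and ``x.upper <= y.upper``,
    ``FALSE`` if the reverse holds strictly, and ``INCOMPARABLE`` when
    neither direction holds.
    """
    forward = x.lower <= y.lower and x.upper <= y.upper
    backward = y.lower <= x.lower and y.upper <= x.upper
    if forward:
        return TriState.TRUE
    if backward:
        return TriState.FALSE
    return TriState.INCOMPARABLE


def join(x: Interval, y: Interval) -> Interval:
    """Supremum under ⪯: componentwise maximum of the bounds."""
    return Interval(max(x.lower, y.lower), max(x.upper, y.upper))


def meet(x: Interval, y: Interval) -> Interval:
    """Infimum under ⪯: componentwise minimum of the bounds."""
    return Interval(min(x.lower, y.lower), min(x.upper, y.upper))


def _exact(v: float) -> Fraction:
    """The float read as the decimal number its shortest repr denotes."""
    return Fraction(Decimal(repr(v)))


def _keys(x: Interval, order: OrderSpec) -> tuple[Fraction, Fraction]:
    # (primary, secondary) keys; lexicographically smaller = earlier in the order
    lo, up = _exact(x.lower), _exact(x.upper)
    if order is OrderSpec.XY:
        return (lo + up, up - lo)
    if order is OrderSpec.LEX1:
        return (lo, up)
    return (up, lo)


def compare(x: Interval, y: Interval, order: OrderSpec | str = OrderSpec.XY) -> int:
    """Three-way comparison under a linear order.

    Returns -1 if ``x`` strictly precedes ``y``, 0 iff the bounds are
    identical, +1 if ``y`` strictly precedes ``x``.
    """
    order = OrderSpec.coerce(order)
    kx, ky = _keys(x, order), _keys(y, order)
    if kx < ky:
        return -1
    if kx > ky:
        return 1
    return 0


def argmax_interval(items: Sequence[Interval], order: OrderSpec | str = OrderSpec.XY) -> int:
    """Index of the greatest interval under the order.

    Ties (identical intervals) resolve to the smallest index, which keeps
    downstream class decisions deterministic.
    """
    order = OrderSpec.coerce(order)
    if len(items) == 0:
        raise ValueError("argmax_interval of an empty sequence")
    best = 0
    for i in range(1, len(items)):
        if compare(items[i], items[best], order) > 0:
            best = i
    return best
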