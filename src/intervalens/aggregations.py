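"""The ten interval-valued aggregation functions A1–A10.

Each aggregation maps n intervals ``[L_i, U_i]`` to a single interval whose
lower bound is a mean of the lower bounds and whose upper bound is a mean of
the upper bounds (with A2/A7 mixing one bound across sides).  Writing ``AM``
for the arithmetic mean, ``M_p`` for the power mean ``((1/n) Σ x^p)^(1/p)``,
``LM_p`` for the Lehmer-type ratio ``Σ x^p / Σ x^(p-1)`` and ``GM`` for the
geometric mean:

======  ============================  ==========================
name    lower bound                   upper bound
======  ============================  ==========================
A1      AM(L)                         AM(U)
A2      AM(L)                         max_i AM(U with U_i := L_i)
A3      AM(L)                         LM_2(U)
A4      AM(L)                         LM_3(U)
A5      M_2(L)                        M_3(U)
A6      M_3(L)                        M_4(U)
A7      min_i AM(L with L_i := U_i)   AM(U)
A8      GM(L)                         LM_2(U)
A9      M_2(L)                        LM_3(U)
A10     M_2(L)                        M_2(U)
======  ============================  ==========================

The Lehmer ratios use the 0/0 := 0 convention (A3, A4, A8, A9): a zero
denominator is only reachable when all relevant upper bounds are exactly 0,
and then the aggregated bound is 0.  No epsilon smoothing is applied.

Validity (lower <= upper) holds for every family: AM <= LM_2 <= LM_3 on
[0, 1] inputs, M_p is increasing in p, GM <= AM, and Cauchy–Schwarz gives
M_2 <= LM_2.  The result always lies inside the hull
``[min_i L_i, max_i U_i]``.

The array-level helpers (:func:`aggregate_bounds`) operate on stacked lower
and upper bound arrays along their last axis, which is what the ensemble's
prediction path uses; :func:`aggregate` is the scalar Interval wrapper.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .intervals import Interval

AGGREGATION_NAMES: tuple[str, ...] = tuple(f"A{i}" for i in range(1, 11))


def available_aggregations() -> list[str]:
    """The ten aggregation names, ``A1`` .. ``A10``, in order."""
    return list(AGGREGATION_NAMES)


def _am(x: np.ndarray) -> np.ndarray:
    return np.mean(x, axis=-1)


def _power_mean(x: np.ndarray, p: int) -> np.ndarray:
    return np.mean(x**p, axis=-1) ** (1.0 / p)


def _lehmer(x: np.ndarray, p: int) -> np.ndarray:
    """Σ x^p / Σ x^(p-1) with 0/0 := 0 (denominator 0 ⇒ all entries 0)."""
    num = np.sum(x**p, axis=-1)
    den = np.sum(x ** (p - 1), axis=-1)
    out = np.zeros_like(num)
    np.divide(num, den, out=out, where=den != 0)
    return out


def _gm(x: np.ndarray) -> np.ndarray:
    n = x.shape[-1]
    return np.prod(x, axis=-1) ** (1.0 / n)


def _a2_upper(lo: np.ndarray, up: np.ndarray) -> np.ndarray:
    # max over positions i of the mean of the uppers with the i-th entry
    # replaced by its lower bound; the max is attained where U_i - L_i is
    # smallest, so no explicit enumeration is needed.
    n = up.shape[-1]
    return (np.sum(up, axis=-1) - np.min(up - lo, axis=-1)) / n


def _a7_lower(lo: np.ndarray, up: np.ndarray) -> np.ndarray:
    # min over positions i of the mean of the lowers with the i-th entry
    # replaced by its upper bound; attained where U_i - L_i is smallest.
    n = lo.shape[-1]
    return (np.sum(lo, axis=-1) + np.min(up - lo, axis=-1)) / n


_LOWER_FNS = {
    "A1": lambda lo, up: _am(lo),
    "A2": lambda lo, up: _am(lo),
    "A3": lambda lo, up: _am(lo),
    "A4": lambda lo, up: _am(lo),
    "A5": lambda lo, up: _power_mean(lo, 2),
    "A6": lambda lo, up: _power_mean(lo, 3),
    "A7": _a7_lower,
    "A8": lambda lo, up: _gm(lo),
    "A9": lambda lo, up: _power_mean(lo, 2),
    "A10": lambda lo, up: _power_mean(lo, 2),
}

_UPPER_FNS = {
    "A1": lambda lo, up: _am(up),
    "A2": _a2_upper,
    "A3": lambda lo, up: _lehmer(up, 2),
    "A4": lambda lo, up: _lehmer(up, 3),
    "A5": lambda lo, up: _power_mean(up, 3),
    "A6": lambda lo, up: _power_mean(up, 4),
    "A7": lambda lo, up: _am(up),
    "A8": lambda lo, up: _lehmer(up, 2),
    "A9": lambda lo, up: _lehmer(up, 3),
    "A10": lambda lo, up: _power_mean(up, 2),
}


def coerce_aggregation(name: str) -> str:
    name = str(name).upper()
    if name not in _LOWER_FNS:
        valid = ", ".join(AGGREGATION_NAMES)
        raise ValueError(f"unknown aggregation {name!r}; expected one of: {valid}")
    return name


def aggregate_bounds(
    name: str, lowers: np.ndarray, uppers: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Apply aggregation ``name`` along the last axis of bound arrays.

    ``lowers`` and ``uppers`` must have identical shape ``(..., n)`` with
    ``n >= 1`` intervals to aggregate; returns ``(lower, upper)`` arrays of
    shape ``(...)``.  Round-off slightly outside [0, 1] is clamped; anything
    beyond round-off signals an internal error.
    """
    name = coerce_aggregation(name)
    lowers = np.asarray(lowers, dtype=float)
    uppers = np.asarray(uppers, dtype=float)
    if lowers.shape != uppers.shape:
        raise ValueError("lower/upper bound arrays must have identical shape")
    if lowers.shape[-1] == 0:
        raise ValueError("cannot aggregate an empty sequence of intervals")
    lo = _LOWER_FNS[name](lowers, uppers)
    up = _UPPER_FNS[name](lowers, uppers)
    tol = 1e-9
    if np.any(lo < -tol) or np.any(up > 1 + tol) or np.any(lo > up + tol):
        raise AssertionError(f"aggregation {name} produced an out-of-range interval")
    lo = np.clip(lo, 0.0, 1.0)
    up = np.clip(up, 0.0, 1.0)
    return lo, np.maximum(lo, up)


def aggregate(name: str, xs: Sequence[Interval]) -> Interval:
    """Aggregate a non-empty sequence of intervals into one interval."""
    if len(xs) == 0:
        raise ValueError("cannot aggregate an empty sequence of intervals")
    lowers = np.array([x.lower for x in xs])
    uppers = np.array([x.upper for x in xs])
    lo, up = aggregate_bounds(name, lowers, uppers)
    return Interval(float(lo), float(up))
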