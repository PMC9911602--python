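"""Balanced interval construction for doses of heterogeneous study quality.

A reported minimum effective dose from a large confirmatory study (tens of
thousands of insects, sub-effective doses tested) pins the species' true
required dose tightly; a dose from a 12-insect study barely constrains it.
To encode this, each reported dose D becomes an interval [L, U]:

* the lower bound L is the highest tested dose at which the treatment failed
  (<100% efficacy), floored at 25 Gy — the lowest effective dose on record;
* the upper bound is ``U = D + A * (1 - C)``, where C is the record's
  efficacy confidence and the spread factor ``A = u_l / (1 - u_c)`` is chosen
  from the dataset means ``u_l = mean(D - L)`` and ``u_c = mean(C)``.

This choice *balances* the censoring: the mean upper gap equals the mean
lower gap, ``mean(U - D) = A * (1 - u_c) = u_l = mean(D - L)``, exactly, so
the intervals widen individually with poor study quality but do not shift the
dataset as a whole.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

from .records import SpeciesDose

__all__ = [
    "MIN_LOWER_GY",
    "CensoredInterval",
    "CensoringSummary",
    "build_balanced_intervals",
    "intervals_from_raw",
]

#: floor for the lower interval bound: lowest effective dose in the literature
MIN_LOWER_GY = 25.0


@dataclass(frozen=True)
class CensoredInterval:
    """Per-species dose interval [lower_gy, upper_gy] around a reported dose."""

    species: str
    lower_gy: float
    reported_gy: float
    upper_gy: float
    confidence: float

    def __post_init__(self) -> None:
        if not (0 < self.lower_gy <= self.reported_gy <= self.upper_gy):
            raise ValueError(
                f"{self.species}: bounds must satisfy "
                f"0 < lower <= reported <= upper, got "
                f"({self.lower_gy}, {self.reported_gy}, {self.upper_gy})"
            )
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")


@dataclass(frozen=True)
class CensoringSummary:
    """Dataset-level quantities of the balanced construction."""

    u_l: float  # mean(D - L), Gy
    u_c: float  # mean confidence
    A: float  # u_l / (1 - u_c), Gy


def _balance(
    entries: Sequence[tuple[str, float, float | None, float]],
) -> tuple[list[CensoredInterval], CensoringSummary]:
    """Core construction from (species, D, highest_fail or None, C) tuples."""
    if len(entries) < 2:
        raise ValueError("at least 2 doses with confidences are required")
    lowers = []
    for species, dose, fail, conf in entries:
        if not 0.0 <= conf <= 1.0:
            raise ValueError(f"{species}: confidence must lie in [0, 1]")
        lo = MIN_LOWER_GY if fail is None else max(fail, MIN_LOWER_GY)
        lowers.append(min(lo, dose))  # a 25 Gy floor may not exceed the dose
    u_l = sum(d - lo for (_, d, _, _), lo in zip(entries, lowers)) / len(entries)
    u_c = sum(c for _, _, _, c in entries) / len(entries)
    if u_c >= 1.0:
        raise ValueError(
            "mean confidence is 1: the spread factor A is undefined; "
            "fit the exact doses instead of censoring"
        )
    if u_l == 0.0:
        warnings.warn(
            "all lower bounds equal the reported doses; intervals are degenerate",
            stacklevel=3,
        )
    A = u_l / (1.0 - u_c)
    intervals = [
        CensoredInterval(
            species=species,
            lower_gy=lo,
            reported_gy=dose,
            upper_gy=dose + A * (1.0 - conf),
            confidence=conf,
        )
        for (species, dose, _, conf), lo in zip(entries, lowers)
    ]
    return intervals, CensoringSummary(u_l=u_l, u_c=u_c, A=A)


def build_balanced_intervals(
    doses: Sequence[SpeciesDose],
    lower_bounds: Mapping[str, float] | None = None,
) -> tuple[list[CensoredInterval], CensoringSummary]:
    """Balanced censored intervals for combined species doses.

    ``lower_bounds`` optionally maps species name to the highest dose at
    which treatment failure was observed for that species; species without an
    entry fall back to the 25 Gy floor. Doses lacking a confidence (no
    specimen count anywhere in their source records) are excluded with a
    warning. Raises when the mean confidence is 1 (spread factor undefined).
    """
    lower_bounds = lower_bounds or {}
    entries = []
    for d in doses:
        if d.confidence is None:
            warnings.warn(
                f"{d.species}: no efficacy confidence (missing specimen "
                "count); excluded from the censored analysis",
                stacklevel=2,
            )
            continue
        entries.append((d.species, d.dose_gy, lower_bounds.get(d.species), d.confidence))
    return _balance(entries)


def intervals_from_raw(
    entries: Sequence[tuple[str, float, float | None, float]],
) -> tuple[list[CensoredInterval], CensoringSummary]:
    """Balanced intervals from raw (species, D, highest_fail or None, C) tuples."""
    return _balance(entries)
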