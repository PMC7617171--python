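"""Classical stratigraphic confidence intervals on origination and extinction.

Under the assumption of uniform fossil recovery within a clade's true
range, the range extension needed for confidence level C given H
fossiliferous horizons spanning a stratigraphic range R is

    alpha = R * ((1 - C)^(-1 / (H - 1)) - 1)

The number of horizons is taken as the number of unique fossil collections,
and R as the time between the oldest and youngest dated collections. The
origin interval runs from the oldest horizon back by alpha; the extinction
interval runs from the youngest horizon forward by alpha, floored at the
present. These intervals serve as the classical comparator to the
Brownian-bridge posterior intervals: with few horizons they can span
hundreds of Myr where the model-based intervals stay a few tens wide.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

__all__ = ["StratRecord", "ci_extension", "origin_ci", "extinction_ci", "strat_record_from_occurrences"]


@dataclass
class StratRecord:
    """Horizon-count summary of one family's fossil record."""

    H: int
    oldest: float
    youngest: float
    C: float = 0.95

    def __post_init__(self) -> None:
        if self.H < 1:
            raise ValueError("need at least one horizon")
        if self.oldest < self.youngest:
            raise ValueError("oldest must be >= youngest")
        if not 0.0 <= self.C < 1.0:
            raise ValueError("confidence level must be in [0, 1)")

    @property
    def R(self) -> float:
        return self.oldest - self.youngest


def ci_extension(R: float, H: int, C: float = 0.95) -> float:
    """Range extension alpha for confidence level C.

    Strictly decreasing in H, increasing in R and C; H < 2 carries no
    information about recovery density and is an error.
    """
    if H < 2:
        raise ValueError("insufficient horizons (H must be >= 2)")
    if R < 0:
        raise ValueError("stratigraphic range must be non-negative")
    if not 0.0 <= C < 1.0:
        raise ValueError("confidence level must be in [0, 1)")
    return R * ((1.0 - C) ** (-1.0 / (H - 1)) - 1.0)


def origin_ci(record: StratRecord) -> tuple[float, float]:
    """(lower, upper) for the origination age: oldest fossil to oldest + alpha."""
    alpha = ci_extension(record.R, record.H, record.C)
    return record.oldest, record.oldest + alpha


def extinction_ci(record: StratRecord) -> tuple[float, float]:
    """(lower, upper) for the extinction age, floored at the present."""
    alpha = ci_extension(record.R, record.H, record.C)
    return max(record.youngest - alpha, 0.0), record.youngest


def strat_record_from_occurrences(records: Sequence, C: float = 0.95) -> StratRecord:
    """Build a StratRecord from dated occurrence records of one family.

    Horizons are unique collections; their ages are the drawn collection
    ages (one age per collection by construction).
    """
    ages = {}
    for r in records:
        if r.age is None:
            raise ValueError("records must carry drawn ages")
        ages[r.collection_id] = r.age
    if not ages:
        raise ValueError("no records")
    vals = list(ages.values())
    return StratRecord(H=len(ages), oldest=max(vals), youngest=min(vals), C=C)
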