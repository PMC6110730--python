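"""Life tables from cross-sectional ages at death.

A cross-sectional sample of dead females carries survivorship
information in its standing age distribution, provided the counts
decrease monotonically with age.  Monotone cohorts are built with
variable-width bins constructed in reverse from the oldest individual:
the oldest bin holds the oldest female (all females sharing the maximum
age, if tied), and each successively younger bin is widened until it
holds strictly more females than the bin above it.  If the youngest bin
cannot, its count is smoothed up to match its neighbour.  Counts are
spread evenly across the whole years each bin covers.

Under stable population theory the standing count at age x relates to
survivorship by l(x) proportional to c(x) * exp(r x), where r is the
per-year exponential growth rate.  Survivorship is anchored at each
bin's youngest age by its growth-corrected count, with the survival
drop spread evenly (linearly) through the ages the bin covers; for
one-year bins this reduces to l(x) proportional to c_x * exp(r x)
age by age.  A growth rate is feasible only if the corrected anchor
counts remain non-increasing in age; the largest feasible rate, capped
at 0.1/yr, defines the "growing population" scenario.  A youngest bin
that was smoothed at build time is re-smoothed after the correction
(its anchor raised to its neighbour's) rather than constraining r.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import json
import numpy as np

#: relative slack when verifying that corrected counts are non-increasing
_MONOTONE_RTOL = 1e-9

GROWTH_CAP = 0.1


@dataclass
class CohortBin:
    """One age cohort: whole-year coverage [lower, upper] and its count."""

    lower: int
    upper: int
    count: float
    smoothed: bool = False

    @property
    def width(self) -> int:
        return self.upper - self.lower + 1


@dataclass
class CohortTable:
    """Monotone age cohorts (youngest first) and per-age standing counts."""

    bins: List[CohortBin]

    def __post_init__(self) -> None:
        if not self.bins:
            raise ValueError("cohort table needs at least one bin")
        for younger, older in zip(self.bins, self.bins[1:]):
            if younger.upper + 1 != older.lower:
                raise ValueError("bins must tile the age range without gaps")
        counts = [b.count for b in self.bins]
        # strictly decreasing with age, except the youngest may equal the second
        for i, (younger, older) in enumerate(zip(counts, counts[1:])):
            if i == 0:
                if younger < older:
                    raise ValueError("youngest bin count below its neighbour")
            elif younger <= older:
                raise ValueError("bin counts must strictly decrease with age")

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.bins[0].lower, self.bins[-1].upper + 1)

    @property
    def c_hat(self) -> np.ndarray:
        """Per-age standing counts: each bin's count spread evenly."""
        return np.concatenate([np.full(b.width, b.count / b.width) for b in self.bins])

    def anchor_ages(self) -> np.ndarray:
        """Each bin's youngest age: where its count anchors survivorship."""
        return np.array([b.lower for b in self.bins], dtype=float)

    def corrected_anchors(self, r: float) -> np.ndarray:
        """Growth-corrected anchor counts c_b * exp(r * x_b).

        A youngest bin smoothed at build time is re-smoothed here: its
        anchor is raised to its neighbour's if the correction pushed it
        below, instead of constraining the feasible growth rate.
        """
        a = np.array([b.count * np.exp(r * b.lower) for b in self.bins])
        if self.bins[0].smoothed and len(a) > 1:
            a[0] = max(a[0], a[1])
        return a

    def summary(self) -> str:
        lines = ["cohorts (youngest -> oldest):"]
        for b in self.bins:
            tag = " (smoothed)" if b.smoothed else ""
            lines.append(f"  ages {b.lower}-{b.upper}: count {b.count:g}{tag}")
        return "\n".join(lines)


@dataclass
class LifeTable:
    """Survivorship on a yearly age grid, l = 1 at the youngest age."""

    ages: np.ndarray
    lx: np.ndarray
    growth_rate: float

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.lx = np.asarray(self.lx, dtype=float)
        if self.ages.shape != self.lx.shape or self.ages.ndim != 1:
            raise ValueError("ages and lx must be matching 1-d arrays")
        if not np.isclose(self.lx[0], 1.0):
            raise ValueError("survivorship must be normalized to 1 at the youngest age")
        if np.any(self.lx < -1e-12):
            raise ValueError("survivorship must be non-negative")
        if np.any(np.diff(self.lx) > _MONOTONE_RTOL):
            raise ValueError("survivorship must be non-increasing")
        if not -GROWTH_CAP - 1e-12 <= self.growth_rate <= GROWTH_CAP + 1e-12:
            raise ValueError("growth rate must lie in [-0.1, 0.1]")

    @property
    def age_b(self) -> float:
        return float(self.ages[0])

    @property
    def omega(self) -> float:
        return float(self.ages[-1])

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("age,lx\n")
            for a, l in zip(self.ages, self.lx):
                fh.write(f"{a:g},{l!r}\n")

    def metadata(self) -> dict:
        return {"r": self.growth_rate, "B": self.age_b, "omega": self.omega}

    def write_metadata(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.metadata(), fh, sort_keys=True)


def build_cohorts(ages) -> CohortTable:
    """Reverse variable-width binning of floored ages at death.

    Scanning from the oldest age downward: the oldest bin holds every
    female at the maximum (floored) age; each new younger bin is
    extended over successive distinct ages until its count strictly
    exceeds the previously formed bin's; if the youngest bin runs out
    of ages first, its count is smoothed up to equal its neighbour's.
    """
    ages = np.asarray(ages, dtype=float)
    if len(ages) < 2:
        raise ValueError("need at least 2 records to build cohorts")
    floored = np.floor(ages).astype(int)
    distinct, counts = np.unique(floored, return_counts=True)
    if len(distinct) < 2:
        raise ValueError("need at least 2 distinct (whole-year) ages")

    order = np.argsort(distinct)[::-1]  # oldest first
    distinct, counts = distinct[order], counts[order]

    bins_old_to_young: List[CohortBin] = []
    i = 0
    prev_count = 0
    upper = int(distinct[0])
    while i < len(distinct):
        count = 0
        lower = int(distinct[i])
        while i < len(distinct):
            count += int(counts[i])
            lower = int(distinct[i])
            i += 1
            if bins_old_to_young and count > prev_count:
                break
            if not bins_old_to_young:
                break  # the oldest bin: only the (tied) maximum age
        smoothed = False
        if bins_old_to_young and count <= prev_count:
            if i < len(distinct):  # pragma: no cover - loop exits only when exceeded or exhausted
                raise AssertionError("bin closed early without exceeding its neighbour")
            count, smoothed = prev_count, True
        bins_old_to_young.append(CohortBin(lower, upper, float(count), smoothed))
        prev_count = count if not smoothed else prev_count
        upper = lower - 1
    return CohortTable(list(reversed(bins_old_to_young)))


def _is_non_increasing(values: np.ndarray) -> bool:
    scale = values.max(initial=0.0)
    return not np.any(np.diff(values) > _MONOTONE_RTOL * max(scale, 1.0))


def survival_from_cohorts(cohorts: CohortTable, r: float) -> LifeTable:
    """Survivorship from growth-corrected cohort counts.

    l is anchored at each bin's youngest age by c_b * exp(r * x_b),
    normalized to 1 at the youngest represented age, with the survival
    drop spread evenly (linear interpolation) through the ages each bin
    covers.  Raises if the correction makes the anchors increase with
    age (r infeasible for this age structure).
    """
    if not -GROWTH_CAP - 1e-12 <= r <= GROWTH_CAP + 1e-12:
        raise ValueError("growth rate must lie in [-0.1, 0.1]")
    a = cohorts.corrected_anchors(r)
    if not _is_non_increasing(a):
        raise ValueError(f"growth rate r={r:g} infeasible: corrected counts increase with age")
    grid = cohorts.ages.astype(float)
    lx = np.interp(grid, cohorts.anchor_ages(), a / a[0])
    lx = np.minimum.accumulate(lx)  # remove monotone-tolerance jitter
    return LifeTable(grid, lx, float(r))


def max_feasible_growth(cohorts: CohortTable, cap: float = GROWTH_CAP) -> float:
    """Largest r <= cap keeping corrected anchors non-increasing (floored at 0).

    Found by bisection on the feasibility predicate; for tables of
    one-year bins this equals min over adjacent ages of
    ln(c_x / c_{x+1}), capped and floored.  With a single bin the
    constraint is vacuous and the cap is returned.
    """

    def feasible(r: float) -> bool:
        return _is_non_increasing(cohorts.corrected_anchors(r))

    if feasible(cap):
        return float(cap)
    if not feasible(0.0):
        return 0.0
    lo, hi = 0.0, float(cap)
    for _ in range(80):
        mid = (lo + hi) / 2.0
        if feasible(mid):
            lo = mid
        else:
            hi = mid
    return 0.0 if lo < 1e-8 else lo
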