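"""Individual-based generator for cross-sectional corpora samples.

Emulates the data-generating process behind published corpora tables:
females ovulate at an age-dependent annual rate ``lambda(x)`` from
maturity, each ovulation leaving a permanent corpus; females die
according to a survival model; the sample consists of dead females, so
under exponential population growth at rate ``r`` the standing age
distribution of deaths is tilted by ``exp(-r * age)`` (younger deaths
over-represented in a growing population).  Cumulative corpora at death
are Poisson with mean equal to the integrated ovulation rate over the
adult lifespan — the minimal counting-process noise model for a
cumulative ovulation record.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .datasets import CorporaDataset


@dataclass
class PiecewiseRate:
    """Piecewise-linear annual ovulation rate ``lambda(x) >= 0``.

    Defined by (age, rate) knots; constant extrapolation outside the
    knot range.  ``integral`` is exact (trapezoid on a piecewise-linear
    function).
    """

    knots: Sequence[Tuple[float, float]]

    def __post_init__(self) -> None:
        knots = sorted((float(a), float(v)) for a, v in self.knots)
        if not knots:
            raise ValueError("at least one (age, rate) knot required")
        ages = [a for a, _ in knots]
        if len(set(ages)) != len(ages):
            raise ValueError("knot ages must be distinct")
        if any(v < 0 for _, v in knots):
            raise ValueError("ovulation rate must be non-negative everywhere")
        self.knots = knots
        self._x = np.array(ages)
        self._y = np.array([v for _, v in knots])

    def __call__(self, x):
        return np.interp(np.asarray(x, dtype=float), self._x, self._y)

    def integral(self, a, b):
        """Exact integral of the rate over [a, b] (vectorized in b)."""
        b = np.asarray(b, dtype=float)
        grid, y = self._x, self._y
        # cumulative integral at knots; between knots the rate is linear so
        # the cumulative is quadratic and must be evaluated exactly
        cum = np.concatenate([[0.0], np.cumsum(np.diff(grid) * (y[:-1] + y[1:]) / 2.0)])

        def cum_at(t):
            t = np.atleast_1d(np.asarray(t, dtype=float))
            out = np.empty_like(t)
            below = t <= grid[0]
            out[below] = (t[below] - grid[0]) * y[0]
            above = t >= grid[-1]
            out[above] = cum[-1] + (t[above] - grid[-1]) * y[-1]
            mid = ~(below | above)
            if mid.any():
                i = np.searchsorted(grid, t[mid], side="right") - 1
                dx = t[mid] - grid[i]
                width = grid[i + 1] - grid[i]
                slope = (y[i + 1] - y[i]) / width
                out[mid] = cum[i] + y[i] * dx + slope * dx**2 / 2.0
            return out

        return (cum_at(b) - cum_at(a)).reshape(np.shape(b)) if np.ndim(b) else float(cum_at(b)[0] - cum_at(a)[0])


@dataclass
class FixedAgeAtDeath:
    """Every female dies at exactly age ``omega``."""

    omega: float

    def __post_init__(self) -> None:
        if self.omega <= 0:
            raise ValueError("omega must be positive")

    def death_grid(self):
        """Return (year_start_ages, year_probs, terminal_age, terminal_prob)."""
        return np.empty(0), np.empty(0), float(self.omega), 1.0


@dataclass
class AnnualMortality:
    """Per-year death probabilities ``q_x`` from ``start_age``.

    ``q[i]`` is the probability of dying within year
    ``[start_age + i, start_age + i + 1)`` given survival to its start;
    deaths are uniform within the year.  Survivors of the whole
    schedule die at its end age exactly.
    """

    q: Sequence[float]
    start_age: float = 0.0

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        if q.ndim != 1 or len(q) == 0:
            raise ValueError("q must be a non-empty 1-d schedule")
        if np.any(q < 0) or np.any(q > 1):
            raise ValueError("death probabilities must lie in [0, 1]")
        self.q = q

    def death_grid(self):
        surv = np.concatenate([[1.0], np.cumprod(1.0 - self.q)])
        probs = surv[:-1] * self.q
        starts = self.start_age + np.arange(len(self.q), dtype=float)
        terminal_age = self.start_age + float(len(self.q))
        return starts, probs, terminal_age, float(surv[-1])


SurvivalModel = Union[FixedAgeAtDeath, AnnualMortality]


@dataclass
class SimConfig:
    """Study conditions for one simulated species sample.

    Parameters
    ----------
    n_individuals:
        Number of dead females in the cross-sectional sample.
    ovulation_rate:
        Piecewise-linear annual ovulation rate (events/year), or a
        sequence of (age, rate) knots.
    survival:
        Either :class:`FixedAgeAtDeath` or :class:`AnnualMortality`.
    maturity_age:
        Age (years) at which corpora begin accumulating.
    growth_rate_r:
        Per-year exponential population growth used to tilt the
        standing age distribution of deaths.
    age_error_sd:
        If > 0, Gaussian ageing error applied to the reported ages.
    pregnancy_rate_scale:
        If set, each record carries a 0/1 pregnancy flag drawn
        Bernoulli(scale * lambda(age), clipped to [0, 1]); pregnancy
        then ceases at the same age as ovulation.
    seed:
        Seed for the generator; all output is reproducible per seed.
    """

    n_individuals: int
    ovulation_rate: Union[PiecewiseRate, Sequence[Tuple[float, float]]]
    survival: SurvivalModel
    maturity_age: float = 0.0
    growth_rate_r: float = 0.0
    age_error_sd: float = 0.0
    pregnancy_rate_scale: Optional[float] = None
    seed: int = 0
    species_label: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if not isinstance(self.ovulation_rate, PiecewiseRate):
            self.ovulation_rate = PiecewiseRate(self.ovulation_rate)
        if self.age_error_sd < 0:
            raise ValueError("age_error_sd must be >= 0")
        if self.maturity_age < 0:
            raise ValueError("maturity_age must be >= 0")
        if not isinstance(self.survival, (FixedAgeAtDeath, AnnualMortality)):
            raise ValueError("survival must be FixedAgeAtDeath or AnnualMortality")


def _sample_death_ages(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    starts, probs, terminal_age, terminal_prob = config.survival.death_grid()
    r = config.growth_rate_r
    # growth tilt: weight each death-age class by exp(-r * age); within-year
    # classes use the mid-year age for the weight, the terminal atom its own age
    weights = np.concatenate([probs * np.exp(-r * (starts + 0.5)), [terminal_prob * np.exp(-r * terminal_age)]])
    total = weights.sum()
    if total <= 0:
        raise ValueError("survival model assigns no death mass")
    weights = weights / total
    idx = rng.choice(len(weights), size=config.n_individuals, p=weights)
    ages = np.empty(config.n_individuals, dtype=float)
    terminal = idx == len(weights) - 1
    ages[terminal] = terminal_age
    within = ~terminal
    ages[within] = starts[idx[within]] + rng.uniform(0.0, 1.0, size=within.sum())
    return ages


def simulate_species(config: SimConfig) -> CorporaDataset:
    """Simulate one cross-sectional sample of dead females.

    Each female's age at death is drawn from the survival model with
    standing-distribution weight ``exp(-r * age)``; her cumulative
    corpora count is Poisson with mean equal to the integrated
    ovulation rate over ``[maturity_age, age]``.
    """
    rng = np.random.default_rng(config.seed)
    ages = _sample_death_ages(config, rng)
    mean_corpora = np.maximum(
        config.ovulation_rate.integral(config.maturity_age, np.maximum(ages, config.maturity_age)),
        0.0,
    )
    corpora = rng.poisson(mean_corpora)
    frame = pd.DataFrame(
        {
            "id": np.arange(1, config.n_individuals + 1),
            "age": ages,
            "corpora": corpora,
        }
    )
    if config.pregnancy_rate_scale is not None:
        p = np.clip(config.pregnancy_rate_scale * config.ovulation_rate(ages), 0.0, 1.0)
        p = np.where(ages < config.maturity_age, 0.0, p)
        frame["pregnant"] = rng.binomial(1, p)
    dataset = CorporaDataset(config.species_label, frame)
    if config.age_error_sd > 0:
        dataset = apply_age_error(dataset, config.age_error_sd, seed=int(rng.integers(2**31)))
    return dataset


def apply_age_error(dataset: CorporaDataset, sd: float, seed: int = 0) -> CorporaDataset:
    """Perturb ages with zero-mean Gaussian noise of standard deviation ``sd``.

    Perturbed ages that fall below the dataset's minimum observed age
    are redrawn (truncated Gaussian); corpora counts are unchanged.
    Used to probe robustness of downstream results to ageing error.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if sd == 0:
        return CorporaDataset(dataset.species, dataset.data.copy())
    rng = np.random.default_rng(seed)
    ages = dataset.ages.copy()
    min_age = ages.min()
    new_ages = ages + rng.normal(0.0, sd, size=len(ages))
    bad = new_ages < min_age
    while bad.any():
        new_ages[bad] = ages[bad] + rng.normal(0.0, sd, size=int(bad.sum()))
        bad = new_ages < min_age
    frame = dataset.data.copy()
    frame["age"] = new_ages
    return CorporaDataset(dataset.species, frame)
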