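"""Preset study conditions: three synthetic species archetypes.

These configs define the reference conditions under which the pipeline
is exercised and validated:

``senescent``
    Ovulation rate declines linearly from 3/yr at first ovulation
    (age 5) to zero at age 17.5 — the midpoint of the adult span
    [5, 30] — with long post-cessation survival: a low adult hazard
    (0.05/yr) until age 20 and a senescent rise (0.08 -> 0.5/yr)
    thereafter, so roughly half of adult females outlive their ovaries.
    The life-history shape of a post-reproductive species.

``linear``
    Constant ovulation rate (0.5/yr) until death under the same
    mortality: corpora accumulate linearly with age, no reproductive
    senescence.

``uninformative``
    All ovulation packed into a single burst in the first adult year
    (20/yr between ages 5 and 6, none after): corpora counts are
    age-independent beyond age 6, so age explains essentially none of
    their variance and the corpora record is uninformative.
"""

from __future__ import annotations

import numpy as np

from .datasets import write_corpora_csv
from .synthetic import AnnualMortality, SimConfig, simulate_species

MATURITY_AGE = 5.0
MAX_AGE = 30.0
CESSATION_AGE = 17.5  # midpoint of the adult span [5, 30]

#: annual death probabilities for ages 5..29: low adult hazard, senescent rise
ADULT_HAZARD = np.concatenate([np.full(15, 0.05), np.linspace(0.08, 0.5, 10)])


def _survival() -> AnnualMortality:
    return AnnualMortality(ADULT_HAZARD, start_age=MATURITY_AGE)


def senescent_config(n: int = 1000, seed: int = 0, growth_rate_r: float = 0.0, **kwargs) -> SimConfig:
    """Reproductive senescence with a post-reproductive lifespan."""
    return SimConfig(
        n_individuals=n,
        ovulation_rate=[(MATURITY_AGE, 3.0), (CESSATION_AGE, 0.0)],
        survival=_survival(),
        maturity_age=MATURITY_AGE,
        growth_rate_r=growth_rate_r,
        seed=seed,
        species_label="senescent",
        **kwargs,
    )


def linear_config(n: int = 1000, seed: int = 0, **kwargs) -> SimConfig:
    """Constant ovulation until death: no reproductive senescence."""
    return SimConfig(
        n_individuals=n,
        ovulation_rate=[(MATURITY_AGE, 0.5)],
        survival=_survival(),
        maturity_age=MATURITY_AGE,
        seed=seed,
        species_label="linear",
        **kwargs,
    )


def uninformative_config(n: int = 1000, seed: int = 0, **kwargs) -> SimConfig:
    """Early ovulation burst: corpora carry no age signal."""
    return SimConfig(
        n_individuals=n,
        ovulation_rate=[(MATURITY_AGE, 20.0), (MATURITY_AGE + 1.0, 0.0)],
        survival=_survival(),
        maturity_age=MATURITY_AGE,
        seed=seed,
        species_label="uninformative",
        **kwargs,
    )


def true_life_table():
    """The senescent archetype's exact survivorship on the yearly grid 5..30."""
    ages = np.arange(MATURITY_AGE, MAX_AGE + 1.0)
    lx = np.concatenate([[1.0], np.cumprod(1.0 - ADULT_HAZARD)])
    return ages, lx


def true_activity(ages: np.ndarray) -> np.ndarray:
    """The senescent archetype's exact ovulation rate at given ages."""
    return np.maximum(np.interp(ages, [MATURITY_AGE, CESSATION_AGE], [3.0, 0.0], right=0.0), 0.0)


def write_demo_csv(path, n: int = 1000, seed: int = 0) -> None:
    """Write the three-species demonstration fixture to a corpora CSV."""
    datasets = [
        simulate_species(senescent_config(n, seed)),
        simulate_species(linear_config(n, seed + 1)),
        simulate_species(uninformative_config(n, seed + 2)),
    ]
    write_corpora_csv(datasets, path)
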