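"""Post-reproductive representation (PrR) and its significance test.

PrR = T(M) / T(B): the proportion of adult female-years in the
population lived after reproductive cessation.  B is the age of entry
into the adult population (the first age present in the truncated
corpora data), M the age by which 95% of population fecundity has been
completed, and T(x) the expected female-years lived above age x,
computed from survivorship with deaths spread uniformly within each
year (survivors of the final year die at the maximum age exactly).

Significance compares the observed PrR with PrR values from simulated
populations in which reproductive senescence equals somatic senescence
(null fecundity proportional to survivorship).  Each null population
resamples individual ages at death from the life table, rebuilds an
empirical life table through the same cohort-binning machinery, and
recomputes PrR; the reported p-value is two-tailed with an add-one
pseudocount.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from .datasets import CorporaDataset
from .demography import (
    GROWTH_CAP,
    CohortTable,
    LifeTable,
    build_cohorts,
    max_feasible_growth,
    survival_from_cohorts,
)
from .ovarian import (
    ActivitySchedule,
    OvarianFit,
    fit_corpora_models,
    ovarian_activity,
    relative_senescence_rate,
    truncate_to_first_ovulation,
)
from ._seeds import derive_seed

CONCLUSION_NONE = "Corpora are not a good measure of ovarian activity"
CONCLUSION_LINEAR = "No reproductive senescence"
CONCLUSION_SENESCENCE = "Reproductive senescence"
CONCLUSION_POST_REPRO = "Reproductive senescence and post-reproductive lifespans"

SCENARIOS = ("shrinking", "stable", "growing")


class PipelineStageError(RuntimeError):
    """Raised when a named stage of the per-species pipeline fails."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage '{stage}': {original}")
        self.stage = stage
        self.original = original


@dataclass
class PrRResult:
    age_B: float
    age_M: float
    prr: float
    growth_rate: float
    p_value: Optional[float] = None
    p_upper: Optional[float] = None
    n_pops: Optional[int] = None
    n_ind: Optional[int] = None
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "age_B": self.age_B,
            "age_M": self.age_M,
            "prr": self.prr,
            "growth_rate": self.growth_rate,
            "p_value": self.p_value,
            "p_upper": self.p_upper,
            "n_pops": self.n_pops,
            "n_ind": self.n_ind,
            "seed": self.seed,
        }


@dataclass
class SignificanceResult:
    """Two-tailed Monte-Carlo p-value with its upper-tail component."""

    p_value: float
    p_upper: float
    null_median: float
    n_pops: int
    n_ind: int
    seed: int

    def __float__(self) -> float:
        return self.p_value


@dataclass
class AnalysisSettings:
    """Settings for the per-species pipeline."""

    n_pops: int = 1000
    n_ind: int = 1000
    seed: int = 0
    alpha: float = 0.05
    shrink_rate: float = -0.1
    growth_cap: float = GROWTH_CAP
    rebuild_null: bool = True
    activity_grid_points: int = 513


@dataclass
class SpeciesResult:
    """One species' summary row: classification, rho, PrR per scenario."""

    species: str
    classification: str  # "none" | "linear" | "quadratic"
    fit: OvarianFit
    rho: Optional[float] = None
    r_max: Optional[float] = None
    scenarios: Optional[Dict[str, PrRResult]] = None
    conclusion: str = ""
    life_tables: Optional[Dict[str, LifeTable]] = field(default=None, repr=False)

    def to_dict(self) -> dict:
        out = {
            "species": self.species,
            "classification": self.classification,
            "fit": self.fit.to_dict(),
            "rho": self.rho,
            "r_max": self.r_max,
            "conclusion": self.conclusion,
            "scenarios": None,
        }
        if self.scenarios is not None:
            out["scenarios"] = {k: v.to_dict() for k, v in self.scenarios.items()}
        return out


def _invert_cumulative_step(m0: float, slope: float, need: float, h: float) -> float:
    """Smallest dx in [0, h] with m0*dx + slope*dx^2/2 = need (m linear in the step)."""
    if need <= 0:
        return 0.0
    if abs(slope) < 1e-300:
        return need / m0 if m0 > 0 else h
    disc = max(m0 * m0 + 2.0 * slope * need, 0.0)
    sq = math.sqrt(disc)
    roots = [(-m0 + sq) / slope, (-m0 - sq) / slope]
    valid = sorted(r for r in roots if -1e-9 <= r <= h * (1 + 1e-9))
    if not valid:
        return h
    return min(max(valid[0], 0.0), h)


def age_M(schedule: ActivitySchedule, quantile: float = 0.95) -> float:
    """Age by which ``quantile`` of cumulative fecundity is completed.

    The schedule is integrated trapezoidally (fecundity linear within
    steps) and the crossing age solved exactly within the bracketing
    step, so the result is independent of grid resolution for
    piecewise-linear fecundity.  M depends only on the fecundity
    schedule, never on survivorship, so it is shared across population
    growth scenarios.
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must lie in (0, 1)")
    x, m = schedule.ages, schedule.activity
    seg = np.diff(x) * (m[:-1] + m[1:]) / 2.0
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total <= 0:
        raise ValueError("fecundity schedule has zero total mass")
    target = quantile * total
    i = int(np.searchsorted(cum, target, side="left"))
    if i == 0:
        return float(x[0])
    i -= 1  # step [x_i, x_{i+1}] brackets the crossing
    h = x[i + 1] - x[i]
    slope = (m[i + 1] - m[i]) / h
    dx = _invert_cumulative_step(float(m[i]), float(slope), float(target - cum[i]), float(h))
    return float(x[i] + dx)


def _person_years_above(lt: LifeTable, x: float) -> float:
    """T(x): expected female-years lived above age x per female alive at B.

    Survivorship is piecewise linear between grid ages (deaths uniform
    within each year); survivors at the maximum age die there exactly,
    so nothing accrues beyond omega.
    """
    ages, lx = lt.ages, lt.lx
    if x >= ages[-1]:
        return 0.0
    x = max(x, float(ages[0]))
    grid = np.concatenate([[x], ages[ages > x]])
    lvals = np.interp(grid, ages, lx)
    return float(np.trapezoid(lvals, grid))


def compute_prr(lt: LifeTable, M: float, B: Optional[float] = None) -> float:
    """PrR = T(M) / T(B), clipped into [0, 1]; zero when M >= omega."""
    if B is None:
        B = lt.age_b
    if M < B - 1e-9:
        raise ValueError(f"age M ({M:g}) below age B ({B:g})")
    if M >= lt.omega:
        return 0.0
    t_b = _person_years_above(lt, B)
    if t_b <= 0:
        return 0.0
    t_m = _person_years_above(lt, max(M, B))
    return float(np.clip(t_m / t_b, 0.0, 1.0))


def _standing_death_sampler(lt: LifeTable):
    """Cross-sectional death-age distribution implied by l and r.

    Deaths in year [y, y+1) have mass l(y) - l(y+1) (uniform within the
    year) plus an atom l(omega) at the maximum age; under growth rate r
    the standing sample of deaths is tilted by exp(-r * age), which the
    stable-population correction later undoes in expectation.
    """
    ages, lx, r = lt.ages, lt.lx, lt.growth_rate
    year_starts = ages[:-1]
    d = lx[:-1] - lx[1:]
    weights = np.concatenate([d * np.exp(-r * (year_starts + 0.5)), [lx[-1] * np.exp(-r * ages[-1])]])
    total = weights.sum()
    if total <= 0:
        raise ValueError("degenerate life table: no death mass")
    p = weights / total

    def sample(rng: np.random.Generator, n: int) -> np.ndarray:
        idx = rng.choice(len(p), size=n, p=p)
        out = np.empty(n)
        terminal = idx == len(p) - 1
        out[terminal] = ages[-1]
        out[~terminal] = year_starts[idx[~terminal]] + rng.uniform(0.0, 1.0, size=int((~terminal).sum()))
        return out

    return sample


def _empirical_life_table(ages: np.ndarray, r: float) -> LifeTable:
    """Growth-weighted empirical survivor function on a yearly grid.

    Fallback null route that never needs monotone binning: l(x) is the
    exp(r * age)-weighted share of sampled deaths at age >= x.
    """
    floored = np.floor(ages).astype(int)
    lo, hi = int(floored.min()), int(floored.max())
    grid = np.arange(lo, hi + 1)
    w = np.exp(r * ages)
    lx = np.array([w[ages >= x].sum() for x in grid])
    lx = lx / lx[0]
    lx = np.minimum.accumulate(lx)
    return LifeTable(grid.astype(float), lx, r)


def _null_life_table(ages: np.ndarray, r: float, rebuild: bool) -> LifeTable:
    if not rebuild:
        return _empirical_life_table(ages, r)
    try:
        cohorts = build_cohorts(ages)
    except ValueError:
        return _empirical_life_table(ages, r)
    r_use = r
    if r > 0:
        r_use = min(r, max_feasible_growth(cohorts, cap=r))
    try:
        return survival_from_cohorts(cohorts, r_use)
    except ValueError:
        # resampled age structure infeasible even at the reduced rate
        return _empirical_life_table(ages, r)


def simulate_null_prrs(
    lt: LifeTable,
    n_pops: int,
    n_ind: int,
    rng: np.random.Generator,
    rebuild: bool = True,
) -> np.ndarray:
    """PrR values of populations whose fecundity tracks survivorship.

    The null sets fecundity proportional to l(x) (reproductive
    senescence equal to somatic senescence); each population resamples
    ``n_ind`` ages at death and rebuilds its own life table with the
    same growth rate.
    """
    m0 = ActivitySchedule(lt.ages, lt.lx)
    m_null = age_M(m0)
    sampler = _standing_death_sampler(lt)
    out = np.empty(n_pops)
    for i in range(n_pops):
        ages = sampler(rng, n_ind)
        lt_i = _null_life_table(ages, lt.growth_rate, rebuild)
        out[i] = compute_prr(lt_i, max(m_null, lt_i.age_b))
    return out


def prr_significance(
    lt: LifeTable,
    observed_prr: float,
    n_pops: int = 1000,
    n_ind: int = 1000,
    seed: int = 0,
    rebuild: bool = True,
) -> SignificanceResult:
    """Two-tailed Monte-Carlo test of the observed PrR against the null.

    One-tailed upper p+ = (1 + #{null >= observed}) / (n_pops + 1); the
    reported p doubles the smaller tail (with the add-one pseudocount
    in both), capped at 1.
    """
    if not 0 <= observed_prr <= 1:
        raise ValueError("observed PrR must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    nulls = simulate_null_prrs(lt, n_pops, n_ind, rng, rebuild=rebuild)
    n_ge = int(np.sum(nulls >= observed_prr))
    p_upper = (1 + n_ge) / (n_pops + 1)
    p_lower = 1 - p_upper + 1 / (n_pops + 1)
    p = min(1.0, 2.0 * min(p_upper, p_lower))
    return SignificanceResult(
        p_value=p,
        p_upper=p_upper,
        null_median=float(np.median(nulls)),
        n_pops=n_pops,
        n_ind=n_ind,
        seed=seed,
    )


def fecundity_from_pregnancy(dataset: CorporaDataset, bandwidth: float = 5.0) -> ActivitySchedule:
    """Smoothed age-specific pregnancy proportion as a fecundity schedule.

    A moving window of the stated bandwidth (full width, years) is
    averaged at each whole-year age; grid points whose window holds no
    records are dropped.  The result is usable wherever an ovarian
    activity schedule is (e.g. to compute age M from pregnancy rather
    than corpora).
    """
    if not dataset.has_pregnancy:
        raise ValueError("dataset carries no pregnancy flags")
    flags = dataset.data["pregnant"].to_numpy(dtype=float)
    ok = np.isfinite(flags)
    if not ok.any():
        raise ValueError("dataset carries no pregnancy flags")
    ages = dataset.ages[ok]
    flags = flags[ok]
    half = bandwidth / 2.0
    grid = np.arange(math.floor(ages.min()), math.ceil(ages.max()) + 1, dtype=float)
    xs, ps = [], []
    for x in grid:
        mask = np.abs(ages - x) <= half
        if mask.any():
            xs.append(x)
            ps.append(float(np.clip(flags[mask].mean(), 0.0, 1.0)))
    if len(xs) < 2:
        raise ValueError("too few ages with pregnancy data for a schedule")
    return ActivitySchedule(np.array(xs), np.array(ps))


def _scenario_rates(cohorts: CohortTable, settings: AnalysisSettings) -> Dict[str, float]:
    return {
        "shrinking": settings.shrink_rate,
        "stable": 0.0,
        "growing": max_feasible_growth(cohorts, cap=settings.growth_cap),
    }


def analyze_species(dataset: CorporaDataset, settings: Optional[AnalysisSettings] = None) -> SpeciesResult:
    """Full per-species pipeline: one summary result row.

    Truncation to first ovulation, AIC model choice, and — for species
    with a concave (senescent) quadratic — rho, growth-feasible
    cohorts, three life-table scenarios sharing one age M, PrR per
    scenario and its Monte-Carlo significance, and the conclusion
    label.
    """
    settings = settings or AnalysisSettings()

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError(name, exc) from exc

    truncated = stage("truncate", truncate_to_first_ovulation, dataset)
    fit = stage("fit", fit_corpora_models, truncated)

    if fit.model_kind == "none":
        return SpeciesResult(dataset.species, "none", fit, conclusion=CONCLUSION_NONE)
    concave = fit.model_kind == "quadratic" and fit.beta2 is not None and fit.beta2 < 0
    if not concave:
        # a convex "quadratic" carries no senescence signal: the linear null stands
        return SpeciesResult(dataset.species, "linear", fit, conclusion=CONCLUSION_LINEAR)

    rho = stage("rho", relative_senescence_rate, fit)
    schedule = stage("activity", ovarian_activity, fit)
    m_age = stage("age_M", age_M, schedule)
    cohorts = stage("cohorts", build_cohorts, truncated.ages)
    rates = stage("growth", _scenario_rates, cohorts, settings)

    scenarios: Dict[str, PrRResult] = {}
    tables: Dict[str, LifeTable] = {}
    for name in SCENARIOS:
        r = rates[name]
        lt = stage(f"lifetable[{name}]", survival_from_cohorts, cohorts, r)
        prr = stage(f"prr[{name}]", compute_prr, lt, max(m_age, lt.age_b))
        sub_seed = derive_seed(settings.seed, f"{dataset.species}:{name}")
        sig = stage(
            f"significance[{name}]",
            prr_significance,
            lt,
            prr,
            n_pops=settings.n_pops,
            n_ind=settings.n_ind,
            seed=sub_seed,
            rebuild=settings.rebuild_null,
        )
        tables[name] = lt
        scenarios[name] = PrRResult(
            age_B=lt.age_b,
            age_M=m_age,
            prr=prr,
            growth_rate=r,
            p_value=sig.p_value,
            p_upper=sig.p_upper,
            n_pops=sig.n_pops,
            n_ind=sig.n_ind,
            seed=sig.seed,
        )

    stable = scenarios["stable"]
    significant = stable.p_value < settings.alpha and stable.p_upper <= 0.5
    conclusion = CONCLUSION_POST_REPRO if significant else CONCLUSION_SENESCENCE
    return SpeciesResult(
        dataset.species,
        "quadratic",
        fit,
        rho=rho,
        r_max=rates["growing"],
        scenarios=scenarios,
        conclusion=conclusion,
        life_tables=tables,
    )
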