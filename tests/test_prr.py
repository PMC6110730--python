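"""Age M, post-reproductive representation, significance, and orchestration."""

import numpy as np
import pytest

from physprr import (
    ActivitySchedule,
    AnalysisSettings,
    LifeTable,
    age_M,
    analyze_species,
    compute_prr,
    fecundity_from_pregnancy,
    prr_significance,
    simulate_species,
)
from physprr import archetypes
from physprr.prr import (
    CONCLUSION_LINEAR,
    CONCLUSION_NONE,
    CONCLUSION_POST_REPRO,
    simulate_null_prrs,
)


def person_years_oracle(lt, a):
    """Brute-force T(a): sum expected years lived above a over the implied
    death distribution (uniform deaths within each year, survivors of the
    final year dying at the maximum age exactly)."""
    ages, lx = lt.ages, lt.lx
    total = 0.0
    for x, d in zip(ages[:-1], lx[:-1] - lx[1:]):
        if d <= 0:
            continue
        lo, hi = x, x + 1.0
        if a <= lo:
            total += d * (lo + 0.5 - a)
        elif a < hi:
            total += d * (hi - a) ** 2 / 2.0
    if lx[-1] > 0 and ages[-1] > a:
        total += lx[-1] * (ages[-1] - a)
    return total


class TestAgeM:
    def test_constant_fecundity(self):
        sched = ActivitySchedule(np.array([0.0, 10.0]), np.array([1.0, 1.0]))
        assert age_M(sched) == pytest.approx(9.5)

    def test_linear_decline_closed_form(self):
        sched = ActivitySchedule(np.array([0.0, 10.0]), np.array([1.0, 0.0]))
        assert age_M(sched) == pytest.approx(10 * (1 - np.sqrt(0.05)), abs=1e-9)

    def test_discrete_schedule_matches_fine_grid(self):
        coarse = ActivitySchedule(np.arange(10.0, 14.0), np.ones(4))
        fine_x = np.linspace(10.0, 13.0, 30001)
        fine = ActivitySchedule(fine_x, np.interp(fine_x, np.arange(10.0, 14.0), np.ones(4)))
        assert age_M(coarse) == pytest.approx(age_M(fine), abs=0.01)

    def test_independent_of_grid_refinement(self):
        # piecewise-linear decline: exact in-step inversion makes M grid-free
        x1 = np.array([5.0, 20.0])
        m1 = np.array([2.0, 0.0])
        x2 = np.linspace(5.0, 20.0, 301)
        sched1 = ActivitySchedule(x1, m1)
        sched2 = ActivitySchedule(x2, np.interp(x2, x1, m1))
        assert age_M(sched1) == pytest.approx(age_M(sched2), abs=1e-9)

    def test_all_zero_schedule_rejected(self):
        with pytest.raises(ValueError):
            age_M(ActivitySchedule(np.array([0.0, 1.0]), np.array([0.0, 0.0])))


class TestComputePrr:
    def test_uniform_death_closed_form(self):
        lt = LifeTable(np.arange(0.0, 11.0), np.ones(11), 0.0)
        assert compute_prr(lt, 5.0) == pytest.approx(0.5, abs=1e-12)

    def test_m_at_or_beyond_omega_is_zero(self):
        lt = LifeTable(np.arange(0.0, 11.0), np.ones(11), 0.0)
        assert compute_prr(lt, 10.0) == 0.0
        assert compute_prr(lt, 12.0) == 0.0

    def test_m_below_b_rejected(self):
        lt = LifeTable(np.arange(5.0, 11.0), np.linspace(1, 0.5, 6), 0.0)
        with pytest.raises(ValueError):
            compute_prr(lt, 3.0)

    def test_matches_person_years_oracle(self, random_life_table):
        rng = np.random.default_rng(31)
        for _ in range(200):
            lt = random_life_table(rng)
            m = float(rng.uniform(lt.age_b, lt.omega + 1.0))
            got = compute_prr(lt, m)
            t_b = person_years_oracle(lt, lt.age_b)
            t_m = person_years_oracle(lt, m)
            expected = 0.0 if m >= lt.omega else np.clip(t_m / t_b, 0, 1)
            assert got == pytest.approx(expected, abs=1e-10)

    def test_decreasing_in_m(self):
        lt = LifeTable(np.arange(0.0, 21.0), np.linspace(1, 0.02, 21), 0.0)
        prrs = [compute_prr(lt, m) for m in np.linspace(0.5, 19.5, 25)]
        assert all(a > b for a, b in zip(prrs, prrs[1:]))
        assert all(0 <= p <= 1 for p in prrs)


@pytest.fixture(scope="module")
def life_table():
    ds = simulate_species(archetypes.senescent_config(1000, seed=11))
    from physprr import build_cohorts, survival_from_cohorts, truncate_to_first_ovulation

    truncated = truncate_to_first_ovulation(ds)
    return survival_from_cohorts(build_cohorts(truncated.ages), 0.0)


class TestSignificance:
    def test_zero_observed_is_lower_tail(self, life_table):
        sig = prr_significance(life_table, 0.0, n_pops=100, n_ind=500, seed=1)
        assert sig.p_upper == pytest.approx(1.0)
        # the upper-tail question (is PrR unusually large?) is not significant
        assert sig.p_upper > 0.05

    def test_null_sample_median_is_not_significant(self, life_table):
        # the median of the very null sample the test draws has rank n/2,
        # so the two-tailed p is near 1 by construction
        for seed in (1, 2, 3):
            nulls = simulate_null_prrs(life_table, 200, 500, np.random.default_rng(seed))
            sig = prr_significance(
                life_table, float(np.median(nulls)), n_pops=200, n_ind=500, seed=seed
            )
            assert sig.p_value >= 0.9

    def test_deterministic_per_seed(self, life_table):
        a = prr_significance(life_table, 0.2, n_pops=50, n_ind=300, seed=5)
        b = prr_significance(life_table, 0.2, n_pops=50, n_ind=300, seed=5)
        assert a.p_value == b.p_value
        assert a.null_median == b.null_median


class TestPregnancyFecundity:
    def test_all_pregnant_is_unit_schedule(self, make_dataset):
        ds = make_dataset(np.linspace(5, 25, 40), np.ones(40), pregnant=np.ones(40))
        sched = fecundity_from_pregnancy(ds, bandwidth=4.0)
        assert np.all(sched.activity == 1.0)

    def test_support_ends_after_last_pregnancy(self, make_dataset):
        rng = np.random.default_rng(41)
        ages = rng.uniform(5, 30, size=400)
        pregnant = (ages < 15).astype(int)
        ds = make_dataset(ages, np.ones(400), pregnant=pregnant)
        sched = fecundity_from_pregnancy(ds, bandwidth=4.0)
        beyond = sched.ages > 15 + 4.0
        assert np.all(sched.activity[beyond] == 0.0)

    def test_no_pregnancy_data_rejected(self, make_dataset):
        with pytest.raises(ValueError):
            fecundity_from_pregnancy(make_dataset([1, 2], [0, 1]))

    def test_age_m_consistent_with_ovarian_route(self):
        # pregnancy and ovulation cease at the same age in the generator,
        # so M from the two fecundity measures should roughly agree
        from physprr import (
            AnnualMortality,
            SimConfig,
            fit_corpora_models,
            ovarian_activity,
            truncate_to_first_ovulation,
        )

        config = SimConfig(
            n_individuals=2000,
            ovulation_rate=[(5.0, 3.0), (17.5, 0.0)],
            survival=AnnualMortality([1.0 / (15 - i) for i in range(15)], start_age=5.0),
            maturity_age=5.0,
            pregnancy_rate_scale=0.25,
            seed=3,
        )
        ds = simulate_species(config)
        truncated = truncate_to_first_ovulation(ds)
        m_activity = age_M(ovarian_activity(fit_corpora_models(truncated)))
        m_pregnancy = age_M(fecundity_from_pregnancy(truncated, bandwidth=4.0))
        assert abs(m_pregnancy - m_activity) <= 2.0


class TestAnalyzeSpecies:
    settings = AnalysisSettings(n_pops=200, n_ind=500, seed=0)

    def test_senescent_species_detected(self):
        ds = simulate_species(archetypes.senescent_config(1000, seed=11))
        res = analyze_species(ds, self.settings)
        assert res.classification == "quadratic"
        assert res.rho > 1.0
        stable = res.scenarios["stable"]
        assert stable.p_value < 0.05
        assert res.conclusion == CONCLUSION_POST_REPRO
        # shrinking <= stable <= growing, the bracket ordering
        prrs = [res.scenarios[s].prr for s in ("shrinking", "stable", "growing")]
        assert prrs[0] <= prrs[1] <= prrs[2]
        # age M shared across scenarios
        assert len({res.scenarios[s].age_M for s in res.scenarios}) == 1

    def test_constant_ovulation_is_linear(self):
        ds = simulate_species(archetypes.linear_config(1000, seed=12))
        res = analyze_species(ds, self.settings)
        assert res.classification == "linear"
        assert res.scenarios is None
        assert res.conclusion == CONCLUSION_LINEAR

    def test_uninformative_corpora_is_none(self):
        ds = simulate_species(archetypes.uninformative_config(1000, seed=7))
        res = analyze_species(ds, self.settings)
        assert res.classification == "none"
        assert res.conclusion == CONCLUSION_NONE
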