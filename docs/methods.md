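# Methods

This note documents the models and procedures implemented in `physprr`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic-data checks do and do not establish.

## Ovarian activity from corpora counts

Each ovulation leaves a permanent corpus in the ovary, so a female's
corpora count is a cumulative record of her ovulation history. For a
cross-sectional sample of dead females with independent age estimates,
records are first truncated to the age of first ovulation — the youngest
age at which any female has a non-zero count (records of that exact age
with zero corpora are retained; they inform the intercept).

Two OLS models are fitted: `corpora ~ age` (the null — constant ovulation)
and `corpora ~ age + age²`. Selection is by AIC with a parsimony margin:
the quadratic is chosen only when it beats the line by more than 2 AIC
units *and* is concave (β₂ < 0). Two units is the conventional
"indistinguishable" band, and under the null it holds the false-selection
rate near 2% (a plain lower-AIC rule selects the quadratic ~16% of the
time on pure noise); convexity is excluded because accelerating ovulation
is not the senescence alternative. If the selected model's adjusted R² is
≤ 0.1 the species is classified `none`: corpora are not a usable measure
of ovarian activity there, and no demographic analysis follows.

Ovarian activity is the derivative of the fitted curve,
m(x) = max(0, β₁ + 2β₂x); the negative branch of a concave parabola is a
fitting artifact and is clipped to zero.

**Relative rate of reproductive senescence.** Activity is normalized to 1
at the age of first ovulation a_B and age to [0, 1] over the observed
adult span [a_B, a_max]:

ρ = 2|β₂|(a_max − a_B) / m(a_B).

ρ = 1 means activity reaches zero exactly at a_max (reproductive and
somatic senescence in step), ρ > 1 cessation before a_max, ρ < 1 activity
still positive at the oldest age. Normalizing by m(a_B) rather than by a
min–max range is deliberate: min–max would force ρ = 1 for every species
whose activity stays positive, destroying the ρ < 1 regime. An
`exclude_ids` argument refits without chosen records for outlier
sensitivity; no automated outlier rule is applied.

## Life tables from the standing age distribution

Treating the sample's age distribution as a standing age structure
requires counts that do not increase with age. Monotone cohorts are built
in reverse from the oldest individual: the oldest bin holds the oldest
female (all females sharing the maximum whole-year age, if tied — ages
cannot be split); each next-younger bin is extended over successive
distinct ages until it holds strictly more females than the bin above; if
the youngest bin runs out of ages first, its count is smoothed up to its
neighbour's. Ages are floored to whole years; published corpora tables
report ages at yearly resolution, and PrR, being a ratio of person-years,
is insensitive to proportional age rescaling.

Survivorship is anchored at each bin's youngest age by its
growth-corrected count, a_b = c_b·e^{r·x_b} (the stable-population
identity l(x) ∝ c(x)·e^{rx}), normalized to 1 at the first age, with the
survival drop spread evenly — linear interpolation of l — through the
ages each bin covers. On one-year bins this reduces to l(x) ∝ c_x·e^{rx}
exactly. Anchoring at bin level rather than spreading counts as a per-age
density is deliberate: a density reading makes survivorship increase
whenever a younger bin is wider than its older neighbour, which occurs in
most realistic samples and would leave every growth rate infeasible.

A growth rate is *feasible* when the corrected anchors are non-increasing
with age; infeasible rates raise an error. A youngest bin smoothed at
build time is re-smoothed after correction instead of constraining the
rate (its equality with its neighbour is an artifact of the monotonicity
patch, not information about age structure). Three scenarios are
computed: shrinking (r = −0.1/yr), stable (r = 0), and growing, the
largest feasible rate up to 0.1/yr found by bisection. The bounds span
the growth rates observed in hunted-to-recovering cetacean populations.

## Post-reproductive representation

Age **B** is the first age present in the truncated data. Age **M** is
the age by which 95% of population fecundity is complete, computed from
the activity schedule alone (fecundity is a property of the ovary, not of
population growth, so M is shared across scenarios). The cumulative
integral is trapezoidal with the crossing age solved exactly inside the
bracketing step, so M is independent of grid resolution for
piecewise-linear schedules.

PrR = T(M)/T(B), where T(x) is expected female-years lived above age x
per female alive at B: survivorship is piecewise linear between yearly
ages (deaths uniform within a year) and survivors of the final year die
at the maximum age exactly, so nothing accrues beyond ω. PrR is clipped
to [0, 1] and is zero when M ≥ ω.

**Significance.** The null sets fecundity proportional to survivorship —
with m₀ ∝ l, the cumulative-fecundity age M₀ is exactly the age above
which 5% of person-years remain, so a null population's PrR is ≈ 0.05 by
construction plus estimation noise. Each of n_pops = 1000 null
populations draws n_ind = 1000 ages at death from the cross-sectional
death distribution implied by l and r (deaths tilted by e^{−r·age}, so
that the later correction undoes the tilt in expectation), rebuilds its
own life table through the same cohort-binning machinery — putting the
binning's sampling noise inside the null — and recomputes PrR with the
fixed M₀. If a resampled age structure cannot support the scenario's
growth rate, the rate is reduced to that population's feasible maximum;
if binning itself is impossible the growth-weighted empirical survivor
function is used instead (`rebuild=False` selects this resampling-only
null throughout). One-tailed p⁺ = (1 + #{null ≥ observed})/(n_pops + 1);
the reported p doubles the smaller tail, with the add-one pseudocount
preventing p = 0 from finite simulation. A species is concluded to have a
post-reproductive lifespan when the quadratic model is selected and the
stable-scenario test is significant at α = 0.05 in the upper tail.

An independent fecundity route smooths per-individual pregnancy flags
with a moving window (default bandwidth 4 years, full width) into an
age-specific pregnancy rate usable wherever an activity schedule is —
e.g. to compare M from pregnancy against M from ovarian activity.

## Ancestral-state reconstruction

Presence/absence of post-reproductive lifespans evolves as a two-state
continuous-time Markov chain with a single rate q in both directions:
P(stay over branch t) = (1 + e^{−2qt})/2. The tree likelihood is computed
by post-order pruning with per-node scaling; the root prior is uniform —
the stationary distribution of the symmetric chain. q is fitted by
bounded scalar ML on [10⁻⁸, 100/tree height]; with all tips in one state
the likelihood is monotone in q and the lower bound is returned with a
boundary flag. Marginal probabilities at internal nodes combine downward
conditional likelihoods with the outside likelihood of the rest of the
tree (equivalent to re-rooting at each node). Polytomies are handled
natively by the pruning product. Consensus-tree construction from a
posterior sample is out of scope; the module consumes one rooted newick
tree with branch lengths.

## Synthetic data: what it emulates

The generator mirrors how corpora datasets arise: females die according
to a survival model (a fixed age at death, or per-year death
probabilities with deaths uniform within the year and survivors of the
schedule dying at its end age); the sampled deaths are tilted by
e^{−r·age} so a growing population over-represents young deaths; corpora
at death are Poisson with mean equal to the exactly integrated
piecewise-linear ovulation rate over [maturity, age] — the minimal
counting-process noise for a cumulative record. Optional Gaussian ageing
error redraws perturbations that fall below the minimum observed age.
Poly-ovulation and corpora regression are deliberately not modelled:
there is no evidence of age-related change in either, which is what would
bias an age-dependence analysis. The exact error magnitudes of published
age estimates are unknown, so the ageing-error s.d. is an exposed
parameter, not a reproduction of any particular study.

Three packaged archetypes define the reference conditions (first
ovulation at 5 y, maximum age 30 y, low adult hazard 0.05/yr with a
senescent rise to 0.5/yr after age 20): `senescent` (ovulation 3/yr
declining to zero at 17.5 y — the midpoint of the adult span — with
roughly half of females outliving their ovaries), `linear` (constant
0.5/yr), and `uninformative` (a single early ovulation burst, leaving
corpora age-independent). Simulation sizes follow the standard design:
n = 1000 individuals per species, 1000 null populations of 1000
individuals; recovery checks use 50 replicates at n = 500 (ρ) and 25 at
n = 2000 (PrR); calibration uses 200–400 replicates with 200 null
populations each. These sizes keep the full suite in the minutes range.

What passing tests show: the demographic arithmetic (binning,
survivorship, person-years, p-values) is exact against brute-force
oracles; detection works end to end (a senescent population is classified
quadratic with a significant stable-scenario PrR; constant ovulation
stays linear; age-independent corpora are set aside). What they do not
show: that ρ and PrR are unbiased point estimates (see limitations), or
anything about digitized real datasets, which differ in ageing error,
sampling bias (hunted populations under-sample old females) and corpora
count fidelity.

## Numerical choices

- AIC margin 2.0; adjusted-R² floor 0.1; significance α = 0.05.
- Monotonicity of survivorship verified to a 10⁻⁹ relative slack;
  feasibility bisection runs 80 halvings and snaps rates below 10⁻⁸ to 0.
- Rate optimization uses bounded Brent with xatol = 10⁻¹⁰; the pruning
  pass rescales partial likelihoods per node to avoid underflow.
- Degenerate inputs raise: all-zero corpora (no first ovulation), fewer
  than 3 distinct ages (quadratic unidentifiable), a single distinct
  whole-year age (no cohorts), all-zero fecundity (no M), M < B,
  infeasible growth rates, missing tip states, malformed newick.
- One run seed drives every stochastic stage through stage-name-keyed
  31-bit sub-seeds, so stages can be rerun independently and whole run
  bundles are byte-reproducible.

## Known limitations

- **Late-vertex bias.** When corpora plateau after cessation, the global
  quadratic places its zero-activity vertex past the true cessation age
  (plateau records are high-leverage), so fitted ρ underestimates the
  true relative rate (≈1.5 recovered where the generating value is 2.0
  under the senescent archetype) and M is placed late, making Phys-PrR
  conservative (≈0.31 recovered against a generator truth of 0.39).
  Detection — is there a significant post-reproductive lifespan? — is
  unaffected in the regimes tested; point estimates inherit the bias.
  This is a property of the estimator itself, not of its implementation.
- Ovarian activity equates fecundity with the physiological capacity to
  ovulate; populations may stop breeding before ovulation ceases, so the
  physiological route is conservative about post-reproductive lifespans.
- Cross-sectional life tables assume a stable age distribution; the three
  growth scenarios bracket, but cannot remove, that assumption.
- The reverse-binning construction tends to under-estimate late-life
  survival (rare old ages are under-sampled), further depressing PrR.
- The equal-rates model has a single parameter by design; asymmetric or
  hidden-rate transition models are out of scope.
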