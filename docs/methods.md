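# Methods

## Model structure

`stepce` implements a state-transition (Markov) cohort model with seven
mutually exclusive health states: Healthy, ischaemic heart disease,
stroke, diabetes mellitus, colorectal cancer, breast cancer, and Death.
The cycle length is one year and the default horizon five cycles. The
cohort is closed and stratified over the cross-product of province
{BC, NL} × sex × age band {13–19, 20–34, 35–49, 50–64, 65+} × app
engagement level {Limited, Occasional, Regular, Committed}; each of the
80 strata is modelled independently and results are person-count
weighted on aggregation. All members start Healthy. Transitions allowed
per cycle: Healthy→{self, any disease, Death}; disease→{self, Death};
Death absorbing. There are no backward transitions, no comorbidity
states, and no tunnel states.

### Competing risks within a cycle

The sources for transition inputs are an annual incidence table
(Healthy→disease) and a mortality table (per occupied state), which do
not by themselves define a joint annual transition law. We resolve death
first and apply incidence to survivors:

    P(H→Death)   = m_h
    P(H→disease) = (1 − m_h) · p_d · r_d
    P(H→H)       = remainder (≥ 0 enforced; a negative remainder is an error)

This ordering yields a valid row for any `m_h`, `p_d` in [0, 1] with
moderate sums and is a standard convention; the alternative
(multiplicative combination of independent hazards) gives differences of
order `m_h · p_d`, negligible at the rates involved.

### Ageing across cycles

The model is age-dependent, so strata advance one year of age per
cycle: the band used for incidence, mortality, and RR lookups in cycle
*t* is the band containing (baseline band midpoint + *t* − 1), with
midpoints 16, 27, 42, 57, 70 and 65+ absorbing at the top. Bands are
wide relative to the 5-year horizon, so only the 13–19 band (midpoint
16) actually crosses into 20–34 within the default horizon. Utilities
and medical costs are looked up at the baseline band: the QALY and cost
accrual formulas are deliberately not cycle-indexed on band, keeping the
accounting transparent and hand-checkable; at these band widths the
difference is second-order.

### Effect mapping

Engagement drives effectiveness through sustained daily step-count
improvements: 448.8 steps/day (Regular) and 884.6 steps/day (Committed);
Limited and Occasional users have no measured improvement and therefore
RR = 1 in both arms. Step increases convert to a standardized
energy-expenditure unit through a single linear coefficient (default 1),
and a literature RR quoted at a reference dose is rescaled linearly in
dose ratio:

    r(dose) = max(1 − (1 − r_lit) · dose/dose_ref, floor)

The floor (default 0.01) guards against linear extrapolation driving a
transition probability to zero or below. Because the adjustment works in
dose-*ratio* space, results are invariant to the energy coefficient
whenever literature and user doses are expressed in the same unit; the
coefficient exists so users can supply literature doses in energy units.
The linear dose–response is an explicit modelling assumption; true
dose–response curves for physical activity are concave, so linearity is
conservative at low baseline activity.

## Economic accounting

Perspective: public healthcare payer; currency 2015 CAD with no
inflation adjustment. Costs and QALYs are discounted identically at
1.5%/year (configurable) with the end-of-cycle convention
`(1 + r)^(−t)`, t = 1..H; the 5-year utility-1 annuity is therefore
Σ 1.015^(−t) = 4.7826449, an upper bound on any per-person discounted
QALY total. An optional half-cycle correction (off by default) averages
adjacent occupancy rows before accrual.

Medical costs attach to occupied disease states only — Healthy and Death
are cost-free. Incentive costs accrue in the intervention arm to the
alive fraction (1 − Death occupancy) each cycle, including members in
disease states, since participation (and hence rewarding) is assumed to
continue: registration ($0.60) once in cycle 1, then $0.04 per goal-met
day and $0.40 per completed biweekly challenge at each stratum's annual
utilization, every cycle.

Incremental results are classified as: *dominant* (ΔC < 0, ΔE > 0),
*dominated* (ΔC > 0, ΔE < 0), `cost_only` sentinel when ΔE = 0 (no
ratio is formed — important under PSA where draws can land on the
boundary), otherwise ICER = ΔC/ΔE. Subgroup reporting aggregates
per-person outcomes with person-count weights before forming the
ratio, so recombining any partition of the cohort (e.g. the two
provinces) reproduces the base case exactly — an identity the tests
assert to floating-point tolerance.

## Sensitivity analyses

**One-way DSA.** Each parameter listed in `dsa_bounds` (slash-delimited
paths such as `rr/Committed/female/50-64/Diabetes`) is set to its low
and high bound with everything else at point estimates, and the full
cohort model is rerun. Entries are ranked by the width of the resulting
ICER range. Where a bound flips the verdict to dominant, the signed
ratio ΔC/ΔE (negative for dominant) is used so widths stay finite; a
bound with ΔE = 0 yields an undefined ratio and a NaN width, sorted
last. Verdicts at both bounds are reported alongside the ratios.

**PSA.** All uncertain parameters vary concurrently, each from the
distribution conventional for its type:

- transition probabilities (incidence *and* mortality): beta, fitted by
  method of moments from (mean, SE); parameters with SE = 0 or mean at
  the boundary stay fixed; an SE too large for a valid beta is an error,
  not a silent clamp;
- relative risks: log-normal with `mu = ln(point)` and
  `sigma = (ln ci_high − ln ci_low)/(2·1.96)`; the stored CI is widened
  if needed to contain the draw so sampled sets still validate;
- incentive unit costs: gamma by method of moments.

Medical costs and utilities are held fixed by default, matching the
three named families; the parameter-path mechanism makes extending this
straightforward. Each of the n simulations gets an independent child
stream spawned from the master seed (`numpy.random.SeedSequence`), so
output is bit-reproducible and independent of execution order. Draws
failing validation are redrawn up to 10 times, then error.

Derived summaries: CE-plane quadrant shares (boundary draws assigned to
the positive side), P(more effective) and P(costlier), a bivariate-
normal confidence ellipse from the sample mean and covariance at the
chi-square(2) quantile (5.991 at 95%), and the CEAC — the fraction of
draws with positive net monetary benefit `λ·ΔE − ΔC` over a WTP grid
(default $0–100,000 in $250 steps), with the 50% crossing linearly
interpolated between grid points.

## Synthetic data

The generator emulates the *structure* of real input tables: incidence
and mortality rise multiplicatively with age band (factors 1.9 and 2.6
per band) and differ by sex and province; male breast-cancer incidence
is zero; disease mortality is a per-disease multiple of healthy
mortality; costs rise with age; utilities are highest when Healthy,
decremented per disease, zero at Death; protective RRs in (0.60, 0.95)
exist for Regular/Committed only; cohort counts are multinomial over the
80 cells from mixes that skew toward BC, females, young adults, and low
engagement (45% Limited, 25% Occasional, 20% Regular, 10% Committed),
with the default cohort size 38,452. Youngest-band incidences (0.7–6 per
10,000) were set so that 5-year per-person medical costs land at a
realistic scale for a young-adult-weighted cohort. All synthetic SEs use
a 20% coefficient of variation, and DSA bounds are derived from the RR
and incidence CIs. Magnitudes are plausible but not calibrated to any
surveillance database: passing tests demonstrate the correctness of the
machinery, not conclusions about any real programme — those require real
tables mapped into the file schema.

The worked fixture is a two-person, single-disease model (diabetes
incidence 0.05, healthy/diabetes mortality 0.01/0.03, annual cost $200,
utilities 0.9/0.7, Committed RR 0.8 applying exactly at the reference
dose) whose discounted costs, QALYs, and ICER were computed
independently with an explicit scalar recurrence and frozen as expected
values; the pipeline must reproduce them to 1e−6 relative tolerance.
Because the parameter-set contract requires the full 80-cell
cross-product, the fixture carries the remaining 78 strata with zero
counts and zero rates. A second fixture variant (65+, incidence 0.20,
cost $5,000, RR 0.60) is constructed so averted medical costs exceed the
incentive outlay, making the intervention dominant deterministically and
in ≥95% of PSA draws.

## Numerical choices and problem sizes

Row-stochasticity is enforced at 1e−12 on construction and 1e−10 on
trace propagation. The microsimulation cross-check uses 50,000
individuals (binomial error ≲ 0.005 per occupancy), compared against
the matrix trace at a 0.01 ceiling. Distribution-recovery checks use
10,000 draws against 3 Monte Carlo standard errors; fixture-level PSA
checks use 200–2,000 draws, chosen so each check completes in seconds
while leaving wide margins to its threshold.

## Known limitations

- No societal perspective, productivity losses, or programme
  development/overhead costs.
- No comorbidity, no recovery, no time-in-state-dependent mortality.
- Engagement-specific step improvements are assumed sustained over the
  whole horizon and fixed per engagement group.
- The energy-expenditure conversion is a single linear coefficient; any
  nonlinear steps→energy relationship must be absorbed into the
  reference dose.
- Correlations between sampled parameters are not modelled (families
  are sampled independently), and EVPI is out of scope.
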