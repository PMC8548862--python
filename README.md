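# stepce

Markov cohort cost-effectiveness analysis of incentive-based
physical-activity programmes.

Public-health payers increasingly consider funding smartphone apps that
pay users small financial rewards (cents per day) for meeting step-count
goals. Whether the health gains justify the incentive outlay is a
health-economics question: averted chronic disease accrues slowly and
unevenly across ages, sexes, regions, and — critically — levels of app
engagement, while the incentive cost is paid to everyone who
participates, engaged or not. `stepce` implements the standard
decision-analytic machinery for that question as a tested, reusable
Python library.

## The model

A closed cohort, stratified by province (BC, NL), sex, age band
(13–19 … 65+), and engagement level (Limited, Occasional, Regular,
Committed), moves through seven health states — Healthy, ischaemic heart
disease, stroke, diabetes, colorectal cancer, breast cancer, Death — in
annual cycles over a 5-year horizon. Everyone starts Healthy; diseased
members cannot recover or acquire a second condition; Death is
absorbing. Within a cycle death is resolved first, so the
Healthy→disease transition probability is

```
P(H → d) = (1 − m_h) · p_d · r_d
```

with `m_h` the healthy-state mortality, `p_d` the annual incidence, and
`r_d` a dose-adjusted relative risk. Sustained step-count improvements
(448.8/day for Regular, 884.6/day for Committed users; nothing for the
rest) scale literature RRs linearly in dose:
`r = 1 − (1 − r_lit) · dose/dose_ref`, floored at 0.01. Costs (2015 CAD,
direct medical costs per disease state plus micro-costed incentives:
$0.60 registration, $0.04 per goal-met day, $0.40 per completed
challenge) and QALYs (EQ-5D utilities) are both discounted at 1.5%/year,
and the comparison against a no-intervention arm is summarised as
`ICER = ΔC/ΔE` or a dominance verdict. One-way deterministic sensitivity
analysis produces a tornado ranking; probabilistic sensitivity analysis
samples transition probabilities (beta), relative risks (log-normal),
and incentive unit costs (gamma) concurrently, yielding CE-plane
summaries, a 95% confidence ellipse, and the cost-effectiveness
acceptability curve.

## Worked example

`examples/02_base_case.py` runs the hand-checkable fixture: one
Committed and one Limited 50–64 female in BC, a single active disease
(diabetes, incidence 0.05, annual cost $200), Committed RR 0.8:

```
per person over 5 years (discounted at 1.5%):
  control:      cost $  124.84   QALYs 4.0378
  intervention: cost $  164.51   QALYs 4.0512
  increments:   cost $   39.67   QALYs 0.013327
  verdict: 2,976.94/QALY  (hand-computed expectation: 2976.94)
```

The intervention costs $39.67 more per person (incentives minus averted
diabetes care) and buys 0.0133 QALYs, i.e. about $2,977 per QALY — far
below a $50,000/QALY willingness-to-pay. The Limited user pays
incentives with no health return (`cost_only`), while the Committed user
alone comes in at $2,608/QALY; engagement is what separates cost from
value. The other example scripts cover parameter generation
(`01`), the tornado (`03`), and the PSA/CEAC (`04`). The same pipeline
is scriptable from a shell via the `stepce` CLI
(`generate` / `base-case` / `dsa` / `psa`).

Real analyses supply their own tables (surveillance incidence and
mortality, literature RRs and utilities, costed incentives) in the
documented CSV/JSON schema; `stepce.synthetic` generates structurally
faithful synthetic stand-ins so the whole pipeline runs without any
external data.

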