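"""Base-case cost-effectiveness on the hand-checkable worked fixture.

Two people in one BC female 50-64 cell: one Committed app user (step
increase 884.6/day, diabetes relative risk 0.8) and one Limited user (no
effect, incentive costs only).  Prints per-arm discounted outcomes, the
increments, and the ICER, which match an independent hand computation.
"""

from stepce import (
    ModelConfig,
    aggregate_cohort,
    evaluate_cohort,
    generate_worked_fixture,
    subgroup_table,
)

ps, expected = generate_worked_fixture()
cfg = ModelConfig()  # 5 annual cycles, 1.5% discounting

results = evaluate_cohort(ps, cfg)
agg = aggregate_cohort(results, ps.strata)

print("per person over 5 years (discounted at 1.5%):")
print(f"  control:      cost ${agg.control.discounted_cost:8.2f}   QALYs {agg.control.discounted_qalys:.4f}")
print(f"  intervention: cost ${agg.intervention.discounted_cost:8.2f}   QALYs {agg.intervention.discounted_qalys:.4f}")
print(f"  increments:   cost ${agg.delta_cost:8.2f}   QALYs {agg.delta_qalys:.6f}")
print(f"  verdict: {agg.verdict}  (hand-computed expectation: {expected['aggregate']['icer']:.2f})")
print()
print("subgroups with members (engagement splits the benefit from the cost):")
table = subgroup_table(ps, cfg)
cols = ["family", "level", "delta_cost", "delta_qalys", "verdict", "icer"]
print(table[cols].to_string(index=False, float_format=lambda v: f"{v:.4f}"))
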