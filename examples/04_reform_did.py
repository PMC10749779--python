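"""The school-leaving-age natural experiment with trend adjustment.

Compares the first affected 12-month school cohort with the last unaffected
one and subtracts the average year-on-year cohort difference over the ten
years on either side, then scales the jump by the jump in staying past 15
to get a per-school-year effect.
"""

from edumr import SimulationConfig, did_reform_effect, reform_iv_per_year, simulate_cohort, simulate_gwas_weights

cfg = SimulationConfig(n_families=50_000, seed=4)
gwas = simulate_gwas_weights(cfg)
cohort, _ = simulate_cohort(cfg, gwas)

stay = did_reform_effect(cohort, "stayed_past_15")
print(f"reform first stage: {100 * stay.delta:.1f} pp more likely to stay past 15 "
      f"(SE {100 * stay.delta_se:.1f})")

ref, est = reform_iv_per_year(cohort, "sbp")
print(f"trend-adjusted jump in sbp: {ref.delta:.3f} (secular trend {ref.trend:.3f}/cohort-year)")
print(f"per additional school year: {est.beta:.2f} (95% CI {est.ci_low:.2f} to {est.ci_high:.2f})")
print("the generating truth is -0.32 mmHg per year; the reform shifts few people,")
print("so its confidence interval is much wider than the allele score's")
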