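"""Generate a synthetic education cohort with known causal structure.

The generator draws parental genotypes at 74 independent loci, transmits
alleles Mendelianly, builds years of schooling from a weighted allele score
plus confounding and noise, and applies the 1972-style school-leaving-age
reform to cohorts born from September 1957.
"""

from edumr import SimulationConfig, simulate_cohort, simulate_gwas_weights

cfg = SimulationConfig(n_families=5000, seed=7)
gwas = simulate_gwas_weights(cfg)
cohort, panel = simulate_cohort(cfg, gwas)

print(f"cohort: {len(cohort)} participants from {cfg.n_families} families")
print(f"panel:  {panel.n_participants} x {panel.n_snps} dosages")
print(f"mean years of education: {cohort['education_years'].mean():.2f}")
pre = cohort[cohort["month_of_birth"] < 0]
post = cohort[cohort["month_of_birth"] >= 0]
print(
    "stayed past 15: {:.1%} (born before cutoff) vs {:.1%} (born after)".format(
        pre["stayed_past_15"].mean(), post["stayed_past_15"].mean()
    )
)
print("the difference is the reform's first stage: compliance x early-leaver share")
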