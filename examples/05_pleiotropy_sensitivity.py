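"""Pleiotropy-robust sensitivity suite on per-SNP summary statistics.

Generates a cohort where 40% of SNPs have directional direct effects on the
outcome (violating the exclusion restriction), then shows how the estimators
respond: IVW absorbs the bias, MR-Egger's intercept detects it and its slope
corrects it, and the weighted median resists it while a majority of weight
is valid.
"""

import pandas as pd

from edumr import OutcomeSpec, SimulationConfig, ivw, leave_one_out, mr_egger, per_snp_ratios, simulate_cohort, simulate_gwas_weights, weighted_median
from edumr.pleiotropy import snp_associations

cfg = SimulationConfig(
    n_families=40_000,
    seed=5,
    snp_beta_scale=0.3,
    palindromic_fraction=0.0,
    panel_recode_fraction=0.0,
    confounder_effect_on_education=0.0,
    confounder_effect_on_outcome=0.0,
    pleiotropy_fraction=0.4,
    pleiotropy_mean=0.08,  # directional: inflates every affected ratio upward
    pleiotropy_sd=0.02,
    outcomes={"y": OutcomeSpec(scale="continuous", true_effect=0.1, noise_sd=1.0)},
)
gwas = simulate_gwas_weights(cfg)
cohort, panel = simulate_cohort(cfg, gwas)
dosages = pd.DataFrame(panel.dosages, columns=panel.snp_ids)
summary = snp_associations(dosages, cohort, "education_years", "y")
snps, n_excluded = per_snp_ratios(summary)

est, q = ivw(snps)
slope, intercept = mr_egger(snps)
med = weighted_median(snps, seed=5)
loo = leave_one_out(snps)

print(f"{len(snps)} SNP instruments ({n_excluded} excluded); true effect 0.1/year")
print(f"IVW:             {est.beta:.3f} (Cochran Q = {q:.0f}, df = {len(snps) - 1})")
print(f"MR-Egger slope:  {slope.beta:.3f}")
print(f"Egger intercept: {intercept.beta:.4f} (p = {intercept.pvalue:.2g}) "
      "<- nonzero signals directional pleiotropy")
print(f"weighted median: {med.beta:.3f}")
print(f"leave-one-out flags: {int(loo['flagged'].sum())} of {len(loo)} SNPs")
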