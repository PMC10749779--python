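"""Collider bias from education-dependent sampling, fixed by IPW.

Samples participants with probabilities depending on staying in school and
on the (binary) outcome — the kind of volunteer selection that biobanks
exhibit — then removes the induced collider bias with inverse-probability
weights computed from the source-population stratum shares.  The study's
published leaving-age weights are shipped as a constant for reference.
"""

from edumr import (
    PUBLISHED_LEAVING_AGE_WEIGHTS,
    EstimationRequest,
    OutcomeSpec,
    SimulationConfig,
    attach_ipw,
    mva_adjusted,
    simulate_cohort,
    simulate_gwas_weights,
)

truth = -0.014
cfg = SimulationConfig(
    n_families=40_000,
    seed=9,
    outcomes={
        "d": OutcomeSpec(scale="binary", true_effect=truth, baseline_risk=0.15,
                         confounder_effect=0.0, trend_slope=0.002)
    },
    selection_model={"intercept": 0.5, "stayed_past_15": 1.5, "d": -1.5},
)
gwas = simulate_gwas_weights(cfg)
cohort, _ = simulate_cohort(cfg, gwas)
cohort["stratum"] = cohort["stayed_past_15"].astype(str) + "_" + cohort["d"].astype(str)
population_shares = cohort["stratum"].value_counts(normalize=True).to_dict()

selected = cohort[cohort["selected"] == 1].copy()
req = EstimationRequest(outcome="d", scale="binary")
naive = mva_adjusted(selected, req)
selected = attach_ipw(selected, "stratum", population_shares, weight_col="ipw")
corrected = mva_adjusted(selected, req.with_(weight_col="ipw"))

print(f"selected {len(selected)} of {len(cohort)} ({len(selected) / len(cohort):.0%})")
print(f"true risk difference per year: {100 * truth:.2f} pp")
print(f"unweighted estimate:           {100 * naive.beta:.2f} pp  <- collider-biased")
print(f"IPW-weighted estimate:         {100 * corrected.beta:.2f} pp")
print(f"(published leaving-age weights for reference: {PUBLISHED_LEAVING_AGE_WEIGHTS})")
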