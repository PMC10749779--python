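"""Triangulate the effect of a year of education across three designs.

Runs the whole pipeline — simulate, harmonize, score, estimate — and prints
the triangulation table: multivariable-adjusted regression (MVA),
allele-score Mendelian randomization (2SLS / additive SMM) and the
school-leaving-age reform (ROSLA), each reporting the effect of one
additional year of schooling.  Binary outcomes are risk differences x100.
"""

from edumr import RunConfig, SimulationConfig, run_pipeline

cfg = RunConfig(
    simulation=SimulationConfig(n_families=20_000, seed=1),
    out_dir="",  # set a path to also write CSV artifacts
    run_sensitivity=False,
)
result = run_pipeline(cfg)

cols = ["method", "outcome", "beta_display", "ci_low_display", "ci_high_display", "n", "annotation"]
print(result.triangulation[cols].round(3).to_string(index=False))
print()
print(f"first-stage partial F: score {result.partial_f['allele_score']:.0f}, "
      f"reform {result.partial_f['reform']:.0f} (both well above the weak-instrument rule of thumb of 10)")
print("generating truths: sbp -0.32 per year; died -1.4 percentage points per year")
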