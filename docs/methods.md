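# Methods

## The estimand and the three designs

Throughout, the target is the effect of one additional year of education,
assumed constant across individuals (the homogeneous-effect reading; under
monotonicity the IV estimates instead identify local average treatment
effects among those the instrument moves — a documentation point, not a
computation). Continuous outcomes are mean differences per year; binary
outcomes are risk differences per year, displayed ×100.

**MVA.** Weighted least squares of outcome on exposure and covariates
(default: sex, age, month of birth), a linear probability model for binary
outcomes so all methods share the risk-difference scale. Standard errors
are heteroskedasticity-robust, clustered on month of birth, with the usual
small-sample factor `G/(G−1) · (n−1)/(n−k)` (switchable off).

**Allele-score MR.** 2SLS with covariates in both stages; the first-stage
partial F for the instrument block is attached to every estimate. For
binary outcomes, the additive structural mean model is estimated from the
moment conditions `E[Z̃(Y − ψX − C'γ)] = 0`, where `Z̃` stacks the
covariate-residualized instruments with the covariates. Just-identified
systems solve exactly and coincide numerically with 2SLS (the tests assert
this to 1e−10); over-identified systems use two-step GMM with identity
first-step weighting and a clustered sandwich. `linearmodels`-style IV
machinery is implemented in-package (numpy); `statsmodels`' sandbox IV2SLS
serves as an independent cross-check in the test suite only.

**ROSLA.** School-year cohorts run September–August so the reform cutoff
(September 1957 births) splits cohorts cleanly. The estimator is

    δ = (mean, first affected 12-month cohort) − (mean, last unaffected)
        − trend,   trend = average year-on-year cohort difference over the
                   ±10-year window, excluding the pair straddling the cutoff.

Because the trend is an equal-weight average of consecutive differences it
telescopes to four cohort means, and δ is a linear functional of individual
outcomes: `δ = Σ a_i y_i`. Standard errors are exact delta-method sums
`Σ a_i² r_i²` over within-cohort residuals, and the per-year estimate
`ψ = δ(outcome)/δ(stayed past 15)` uses the joint covariance of the two
functionals (they share individuals). Any outcome affine in cohort is
removed exactly (machine-precision tests); curvature is not — the quadratic
oracle test documents this known limitation of linear trend adjustment.
A first stage with |t| < 2 attaches a weak-instrument warning rather than
failing. No local-polynomial or optimal-bandwidth machinery is attempted.

## Diagnostics

*Partial F* uses the restricted/unrestricted RSS form and reduces to
`r²(n−2)/(1−r²)` in the single-instrument case (asserted to 1e−8).
*Balance ratios* divide the instrument→covariate association by the
instrument→exposure association; both are just-identified moment conditions
estimated jointly, so the delta-method SE includes their covariance. Ratios
are invariant to affine rescaling of the instrument; a near-null exposure
association (|t| < 2) flags the ratio undefined instead of reporting an
explosive number. *IPW*: `w(s) = scale · population share(s) / sample
share(s)`; after weighting, weighted sample shares equal population shares
exactly. The published leaving-age pair (34.29 for leaving at 15, 12.37 for
staying on) ships as a constant; its derivation from census and invitation
figures is upstream of this package and treated as given.

## Pleiotropy suite

Per-SNP associations with exposure and outcome are computed in-sample
(one-sample design, matching the study; a summary-table entry point covers
two-sample inputs). The per-SNP ratio SE used for weighting is the
first-order `se_out/|β_exp|`: the second-order delta term `β_out²·se_exp²/
β_exp⁴` would make weights functions of the realized outcome beta and
biases the pooled IVW downward — measurably so in simulation — while the
first-order form is the conventional choice. The full delta SE is exposed
separately for reporting. IVW applies multiplicative random-effects
inflation `sqrt(Q/df)` when Cochran's Q exceeds its degrees of freedom.
MR-Egger orients SNPs to positive exposure betas, uses weights `1/se_out²`
and a multiplicative overdispersion factor never below 1. The weighted
median interpolates the inverse-variance-weighted cumulative distribution
at 0.5; its SE is a seeded parametric bootstrap over the summary
statistics. Leave-one-out flags a SNP when omitting it moves IVW by more
than one full-sample SE (configurable).

## The synthetic cohort generator

The generator emulates the statistical structure of a mid-20th-century
British cohort study:

- **Genetics.** 74 independent loci (no LD, no X chromosome, no imputation
  noise), EAF uniform on (0.1, 0.9), a configurable palindromic fraction,
  per-allele weights N(0, 0.05) years of education — sized so the score
  explains ~1% of education variance and the first-stage F is in the
  hundreds at n = 20 000 and the thousands at biobank scale. Parental
  genotypes are Hardy–Weinberg; assortative mating is induced by rank-
  matching spouses on a noisy copy of the score; transmission is exact
  Mendelian segregation. A configurable fraction of families (default 0.2)
  contributes sibling pairs for the within-family estimator.
- **Education.** Latent years = 12 + score + 0.5·confounder + N(0, 2.5),
  snapped to the ISCED grid (7, 10, 13, 15, 19, 20). Grid values ≤ 10 mark
  would-be early leavers (~45% of these birth cohorts). Births are uniform
  over ±120 months around September 1957; affected early leavers comply
  with probability 0.23 and compliers gain exactly one year of schooling
  (added after grid snapping — snapping afterwards would erase the extra
  year and undefine the per-year estimand). The population first stage is
  therefore compliance × early-leaver share (~10 pp), and the reform's
  per-year estimate is noisier than the score's at equal n, as in real
  data. Compliance is homogeneous (no sex/region heterogeneity).
- **Outcomes.** Continuous: secular trend (0.05 units per birth-year)
  + true effect × education + 0.5·confounder + optional dynastic and
  pleiotropy terms + Gaussian noise. Binary: a linear-in-risk threshold
  mechanism (uniform draw against the linear risk), so the configured risk
  difference is exactly the additive-SMM estimand; binary defaults use
  order-of-magnitude smaller confounding/trend so risks stay inside (0, 1)
  (clipping is applied but rare by construction). Ages derive from a
  recruitment window spread uniformly over four years — a fixed assessment
  date would make age an exact affine function of month of birth and the
  covariate set collinear.
- **Violations.** Pleiotropy gives a random SNP subset direct outcome
  effects on the *education-increasing* allele orientation (directional
  when the mean is nonzero; on the raw coded allele the signed weights
  would cancel and directional pleiotropy would be invisible). Dynastic
  effects add `effect × standardized mid-parent score` to outcomes, and the
  mid-parent score is emitted so balance diagnostics can detect the
  induced score–family association. Selection draws from a logistic model
  on education/outcome columns; `apply_selection` attaches the true inverse
  probabilities as oracle weights.
- **What it does not emulate.** Linkage disequilibrium, genotyping error,
  population stratification, age-varying effects, non-linear cohort
  effects, measurement error in self-reported education, and real UK
  census margins. Passing tests show the estimators are correct under the
  stated model, not that real-data assumptions hold.

## Monte-Carlo validation sizes

The validation suite uses: 200 replicates at n = 20 000 for allele-score
recovery (mean within 0.01 of the truth, CI coverage in [92, 98]%) and for
reform recovery; 100 replicates per generator for the triangulation
null/confounded contrast; 150 for the collider/IPW contrast; 200/100 for
directional/balanced pleiotropy; 80 sibling-pair replicates (families of
two, n = 12 000) for the dynastic contrast. Pleiotropy scenarios use
per-allele weights of 0.3 years so each variant is individually a strong
instrument and the check isolates pleiotropy from weak-instrument dilution;
the directional scenario (40% of SNPs, mean direct effect 0.08 outcome
units per education-increasing allele, SD 0.02) was sized by power analysis
to give the Egger intercept ~85–90% detection power. Monte-Carlo tolerances
are 3 Monte-Carlo standard errors of the replicate mean throughout.

## Numerical and design notes

- Determinism: every stochastic step flows from one integer seed through
  `numpy` `SeedSequence`; identical configs give byte-identical artifacts.
- Palindromic SNPs: a literal minor-allele-frequency cutoff at 0.5 or
  above can never trigger (MAF ≤ 0.5 by definition); the implemented rule excludes
  palindromic SNPs with MAF within a half-width (default 0.08) of 0.5, and
  orients the remaining ones by allele-frequency concordance, the standard
  harmonization practice.
- Missing dosages contribute the SNP's expected dosage 2×EAF (mean
  imputation) by default, with a complete-case switch; an all-missing
  participant gets NaN, never zero.
- Rank deficiency raises with the offending columns named (QR diagonal);
  degenerate instruments (constant, or constant within families) raise
  dedicated errors rather than returning huge estimates.
- The trend in the reform design weights year-pairs equally; alternative
  weightings are a constructor argument away but not defaulted.
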