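"""Synthetic cohorts with known causal structure.

The generator mirrors the design of a one-sample education study: an external
GWAS supplies per-SNP weights for an education allele score; parental
genotypes are drawn in Hardy-Weinberg proportions and transmitted Mendelianly
(each parent passes each allele with probability 1/2); years of education are
a weighted allele score plus confounding, noise, and a school-leaving-age
reform at a birth-month cutoff; outcomes carry secular cohort trends, the
causal effect of education, and optional exclusion-restriction violations
(pleiotropy, dynastic effects, assortative mating) plus education-dependent
sample selection.  Because every bias is switched on explicitly, downstream
estimators can be validated by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .config import SimulationConfig
from .exceptions import ConfigurationError, DegenerateSampleError

_BASES = np.array(list("ACGT"))
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class GwasSummaryRecord:
    """One SNP's reported effect on years of education (discovery GWAS)."""

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float  # years of education per effect allele
    se: float
    pval: float
    eaf: float  # effect-allele frequency

    @property
    def is_palindromic(self) -> bool:
        return self.other_allele == _COMPLEMENT[self.effect_allele]


@dataclass
class GenotypePanel:
    """Per-participant dosages of the panel-coded allele, one column per SNP."""

    participant_id: np.ndarray  # (n,)
    snp_ids: List[str]
    coded_allele: List[str]
    other_allele: List[str]
    dosages: np.ndarray  # (n, m) in [0, 2]; NaN = missing

    @property
    def n_participants(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def coded_frequency(self) -> np.ndarray:
        """Empirical coded-allele frequency per SNP (missing dosages ignored)."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.dosages, columns=self.snp_ids)
        df.insert(0, "participant_id", self.participant_id)
        return df


def simulate_gwas_weights(config: SimulationConfig) -> List[GwasSummaryRecord]:
    """Draw a set of genome-wide-significant education SNPs.

    Alleles come from {A,C,G,T} with a configurable palindromic (A/T, C/G)
    fraction; effect-allele frequencies are uniform on ``eaf_range``; betas are
    N(0, snp_beta_scale) so the sample SD of betas matches the configured
    scale; z-scores are drawn large enough that every SNP clears genome-wide
    significance.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.eaf_range
    records: List[GwasSummaryRecord] = []
    for j in range(config.n_snps):
        palindromic = rng.uniform() < config.palindromic_fraction
        if palindromic:
            ea = rng.choice(_BASES)
            oa = _COMPLEMENT[ea]
        else:
            while True:
                ea, oa = rng.choice(_BASES, size=2, replace=False)
                if _COMPLEMENT[ea] != oa:
                    break
        eaf = rng.uniform(lo, hi)
        beta = rng.normal(0.0, config.snp_beta_scale)
        z = rng.uniform(5.6, 12.0)  # all discovery SNPs pass p < 5e-8
        se = abs(beta) / z if beta != 0 else config.snp_beta_scale / z
        pval = float(2 * norm.sf(z))
        records.append(
            GwasSummaryRecord(
                snp_id=f"rs{j + 1:06d}",
                effect_allele=str(ea),
                other_allele=str(oa),
                beta=float(beta),
                se=float(se),
                pval=pval,
                eaf=float(eaf),
            )
        )
    return records


def _transmit(parent_dosage: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One transmitted allele per locus: 0/1 with the Mendelian probabilities."""
    het = parent_dosage == 1
    out = (parent_dosage == 2).astype(np.int8)
    out[het] = rng.integers(0, 2, size=int(het.sum()), dtype=np.int8)
    return out


def _pair_parents(
    mother_score: np.ndarray, father_score: np.ndarray, r: float, rng: np.random.Generator
) -> np.ndarray:
    """Return an index permuting fathers so spousal scores correlate ~ r.

    Rank-matching on a noisy copy of the mother's score; exact for rank
    correlation in the Gaussian limit, close enough for the property tests.
    """
    n = len(mother_score)
    if r == 0.0:
        return rng.permutation(n)
    zm = (mother_score - mother_score.mean()) / (mother_score.std() + 1e-12)
    target = r * zm + np.sqrt(max(0.0, 1 - r * r)) * rng.normal(size=n)
    fathers_sorted = np.argsort(father_score, kind="stable")
    perm = np.empty(n, dtype=int)
    perm[np.argsort(target, kind="stable")] = fathers_sorted
    return perm


def _snap_to_grid(x: np.ndarray, grid: Sequence[float]) -> np.ndarray:
    g = np.asarray(grid, dtype=float)
    idx = np.argmin(np.abs(x[:, None] - g[None, :]), axis=1)
    return g[idx]


def simulate_cohort(
    config: SimulationConfig, gwas: Sequence[GwasSummaryRecord]
) -> Tuple[pd.DataFrame, GenotypePanel]:
    """Generate a cohort and its genotype panel from GWAS records.

    Returns ``(cohort, panel)``: the cohort carries ids, family ids, birth
    timing, education, the reform exposure, outcomes, the latent confounder
    (emitted for testing only — estimators must not use it) and selection
    columns; the panel carries dosages with a realistic mixture of allele
    codings (a configurable fraction of SNPs is coded on the other allele, so
    harmonization has real work to do).
    """
    config.validate()
    if len(gwas) != config.n_snps:
        raise ConfigurationError(f"gwas has {len(gwas)} records, config.n_snps = {config.n_snps}")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed & 0x7FFFFFFF, 0xC0F0]))

    m = config.n_snps
    eaf = np.array([g.eaf for g in gwas])
    beta = np.array([g.beta for g in gwas])

    # families and offspring counts
    nf = config.n_families
    two_kids = rng.uniform(size=nf) < config.sibling_prob
    n_children = np.where(two_kids, 2, 1)
    n = int(n_children.sum())
    fam_of_child = np.repeat(np.arange(nf), n_children)

    # parental genotypes under HWE, with optional assortative mating on score
    g_mother = rng.binomial(2, eaf[None, :], size=(nf, m)).astype(np.int8)
    g_father = rng.binomial(2, eaf[None, :], size=(nf, m)).astype(np.int8)
    score_m = g_mother @ beta
    score_f = g_father @ beta
    perm = _pair_parents(score_m, score_f, config.mating_correlation, rng)
    g_father = g_father[perm]
    score_f = score_f[perm]

    # Mendelian transmission, one draw per child
    gm_child = g_mother[fam_of_child]
    gf_child = g_father[fam_of_child]
    dosage = (_transmit(gm_child.ravel(), rng) + _transmit(gf_child.ravel(), rng)).reshape(n, m)

    score = dosage @ beta
    parent_mid_score = (score_m + score_f)[fam_of_child] / 2.0
    sd_par = parent_mid_score.std()
    z_parental = (parent_mid_score - parent_mid_score.mean()) / (sd_par if sd_par > 0 else 1.0)

    # birth timing: uniform over +/- birth_window_months around the cutoff
    cutoff_y, cutoff_m = config.reform_cutoff
    month_offset = rng.integers(-config.birth_window_months, config.birth_window_months, size=n)
    month_abs = (cutoff_y * 12 + (cutoff_m - 1)) + month_offset
    birth_year = month_abs // 12
    birth_month = month_abs % 12 + 1
    birth_decimal = birth_year + (birth_month - 0.5) / 12.0
    post_reform = month_offset >= 0

    confounder = rng.normal(size=n)
    sex = rng.integers(0, 2, size=n)

    # education: latent -> ISCED grid -> reform adds one extra year for compliers
    latent = (
        config.education_base
        + score
        + config.confounder_effect_on_education * confounder
        + rng.normal(0.0, config.education_noise_sd, size=n)
    )
    edu0 = _snap_to_grid(latent, config.isced_grid)
    would_leave_early = edu0 <= config.leave_at_15_years
    complier = would_leave_early & post_reform & (rng.uniform(size=n) < config.reform_compliance)
    education = edu0 + complier.astype(float)  # the extra forced school year
    stayed_past_15 = (~would_leave_early | complier).astype(int)

    # pleiotropy: a fixed subset of SNPs acts on outcomes directly; directional
    # effects are defined relative to the education-increasing allele, so the
    # dosage is oriented by the sign of the SNP's education weight
    n_pleio = int(round(config.pleiotropy_fraction * m))
    if n_pleio:
        pleio_snps = rng.choice(m, size=n_pleio, replace=False)
        pleio_alpha = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, size=n_pleio)
        x_incr = np.where(beta[pleio_snps] >= 0, dosage[:, pleio_snps], 2 - dosage[:, pleio_snps])
        pleio_term = x_incr @ pleio_alpha
    else:
        pleio_term = np.zeros(n)

    half_w = config.assessment_window_years / 2.0
    assessment_date = config.assessment_year + rng.uniform(-half_w, half_w, size=n)
    cohort = pd.DataFrame(
        {
            "participant_id": np.arange(n),
            "family_id": fam_of_child,
            "sex": sex,
            "birth_year": birth_year,
            "birth_month": birth_month,
            # months relative to the reform cutoff; also the clustering variable
            "month_of_birth": month_offset,
            "age": assessment_date - birth_decimal,
            "education_years": education,
            "stayed_past_15": stayed_past_15,
            "would_leave_early": would_leave_early.astype(int),
            "confounder": confounder,  # latent; test-only, not an analysis covariate
            "allele_score_true": score,
            "parental_score": z_parental,  # standardized mid-parent score
        }
    )

    years_since_cutoff = birth_decimal - (cutoff_y + (cutoff_m - 0.5) / 12.0)
    for name, spec in config.outcomes.items():
        conf_eff = (
            spec.confounder_effect
            if spec.confounder_effect is not None
            else config.confounder_effect_on_outcome
        )
        trend = spec.trend_slope if spec.trend_slope is not None else config.trend_slope
        signal = (
            trend * years_since_cutoff
            + spec.true_effect * (education - config.education_reference)
            + conf_eff * confounder
            + config.dynastic_effect * z_parental
            + pleio_term
            + spec.sex_effect * sex
        )
        if spec.scale == "continuous":
            cohort[name] = signal + rng.normal(0.0, spec.noise_sd, size=n)
        else:
            risk = np.clip(spec.baseline_risk + signal, 0.0, 1.0)
            cohort[name] = (rng.uniform(size=n) < risk).astype(int)

    # selection: logistic on the configured columns; everyone kept if None
    if config.selection_model is None:
        prob = np.ones(n)
    else:
        lin = np.full(n, config.selection_model.get("intercept", 0.0))
        for col, coef in config.selection_model.items():
            if col == "intercept":
                continue
            lin = lin + coef * cohort[col].to_numpy(dtype=float)
        prob = expit(lin)
    cohort["selection_prob"] = prob
    cohort["selected"] = (rng.uniform(size=n) < prob).astype(int)
    cohort["sampling_weight"] = 1.0  # replaced by apply_selection / compute_ipw

    panel = _build_panel(cohort["participant_id"].to_numpy(), gwas, dosage, rng, config)
    return cohort, panel


def _build_panel(
    pid: np.ndarray,
    gwas: Sequence[GwasSummaryRecord],
    dosage: np.ndarray,
    rng: np.random.Generator,
    config: SimulationConfig,
) -> GenotypePanel:
    """Recode a fraction of SNPs on the other allele, as a real panel would."""
    m = dosage.shape[1]
    flip = rng.uniform(size=m) < config.panel_recode_fraction
    dosages = dosage.astype(float)
    coded, other = [], []
    for j, g in enumerate(gwas):
        if flip[j]:
            dosages[:, j] = 2.0 - dosages[:, j]
            coded.append(g.other_allele)
            other.append(g.effect_allele)
        else:
            coded.append(g.effect_allele)
            other.append(g.other_allele)
    return GenotypePanel(
        participant_id=pid,
        snp_ids=[g.snp_id for g in gwas],
        coded_allele=coded,
        other_allele=other,
        dosages=dosages,
    )


def apply_selection(cohort: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Keep selected rows, attaching true inverse-probability sampling weights.

    The weights come from the generating selection model, so weighted analyses
    of the selected sample are unbiased for the full-cohort estimand — the
    oracle against which estimated weights can be compared.
    """
    if "selection_prob" not in cohort.columns:
        raise DegenerateSampleError("cohort has no selection_prob column; run simulate_cohort first")
    out = cohort.loc[cohort["selected"] == 1].copy()
    if len(out) == 0:
        raise DegenerateSampleError("selection removed every row")
    out["sampling_weight"] = 1.0 / out["selection_prob"].to_numpy()
    return out
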