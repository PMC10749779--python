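"""Generator properties: Mendelian transmission, determinism, known structure."""

import numpy as np
import pandas as pd
import pytest

from edumr import OutcomeSpec, SimulationConfig, apply_selection, simulate_cohort, simulate_gwas_weights
from edumr.exceptions import ConfigurationError, DegenerateSampleError
from edumr.simulate import _transmit

from conftest import small_config


class TestGwasWeights:
    def test_seed_determinism(self):
        cfg = small_config(n_snps=74, seed=1)
        a = simulate_gwas_weights(cfg)
        b = simulate_gwas_weights(cfg)
        assert len(a) == 74
        assert a == b  # dataclass equality: byte-identical records

    def test_no_palindromic_when_fraction_zero(self):
        recs = simulate_gwas_weights(small_config(palindromic_fraction=0.0, seed=2))
        assert all(not r.is_palindromic for r in recs)
        assert all(r.effect_allele != r.other_allele for r in recs)

    def test_beta_scale_law_of_large_numbers(self):
        s = 0.04
        recs = simulate_gwas_weights(small_config(n_snps=1000, snp_beta_scale=s, seed=3))
        sd = np.std([r.beta for r in recs])
        assert abs(sd - s) / s < 0.10

    def test_eaf_within_range_and_significant(self):
        recs = simulate_gwas_weights(small_config(eaf_range=(0.2, 0.6), seed=4))
        assert all(0.2 <= r.eaf <= 0.6 for r in recs)
        assert all(r.pval < 5e-8 for r in recs)

    def test_invalid_eaf_range_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_gwas_weights(small_config(eaf_range=(0.9, 0.1)))


class TestTransmission:
    def test_het_by_het_segregation(self):
        """Two heterozygous parents: offspring dosage ~ (1/4, 1/2, 1/4)."""
        rng = np.random.default_rng(0)
        n = 40_000
        het = np.ones(n, dtype=np.int8)
        child = _transmit(het, rng) + _transmit(het, rng)
        freq = np.bincount(child, minlength=3) / n
        assert np.allclose(freq, [0.25, 0.5, 0.25], atol=0.01)

    def test_expected_dosage_is_parental_mean(self):
        rng = np.random.default_rng(1)
        gm = rng.integers(0, 3, size=100_000).astype(np.int8)
        gf = rng.integers(0, 3, size=100_000).astype(np.int8)
        child = _transmit(gm, rng) + _transmit(gf, rng)
        resid = child - (gm + gf) / 2.0
        assert abs(resid.mean()) < 3 * resid.std() / np.sqrt(len(resid))


class TestCohort:
    def test_seed_determinism(self):
        cfg = small_config(n_families=500, seed=5)
        gwas = simulate_gwas_weights(cfg)
        c1, p1 = simulate_cohort(cfg, gwas)
        c2, p2 = simulate_cohort(cfg, gwas)
        pd.testing.assert_frame_equal(c1, c2)
        assert np.array_equal(p1.dosages, p2.dosages)

    def test_panel_frequencies_converge_to_eaf(self, base_run):
        cohort, panel, gwas, weights, _ = base_run
        n = panel.n_participants
        for w in weights:
            p = gwas[[g.snp_id for g in gwas].index(w.snp_id)].eaf
            eff_freq = w.panel_eaf
            tol = 3 * np.sqrt(p * (1 - p) / (2 * n))
            assert abs(eff_freq - p) < tol

    def test_dosages_independent_of_confounder(self, base_run):
        cohort, panel, *_ = base_run
        n = len(cohort)
        conf = cohort["confounder"].to_numpy()
        r = np.array(
            [np.corrcoef(panel.dosages[:, j], conf)[0, 1] for j in range(0, panel.n_snps, 7)]
        )
        assert np.all(np.abs(r) < 4 / np.sqrt(n))

    def test_binary_outcomes_are_01_and_weights_positive(self, base_cohort):
        assert set(base_cohort["d"].unique()) <= {0, 1}
        assert (base_cohort["sampling_weight"] > 0).all()

    def test_stayed_consistent_with_education(self, base_cohort):
        post16 = base_cohort["education_years"] > 11
        assert (base_cohort.loc[post16, "stayed_past_15"] == 1).all()

    def test_family_sizes(self):
        cfg = small_config(n_families=2000, sibling_prob=0.3, seed=6)
        cohort, _ = simulate_cohort(cfg, simulate_gwas_weights(cfg))
        sizes = cohort.groupby("family_id").size()
        assert set(sizes.unique()) <= {1, 2}
        assert abs((sizes == 2).mean() - 0.3) < 0.04

    def test_unknown_outcome_in_selection_model_rejected(self):
        with pytest.raises(ConfigurationError):
            cfg = small_config(selection_model={"intercept": 0.0, "nonexistent": 1.0})
            simulate_gwas_weights(cfg)

    def test_assortative_mating_raises_sibling_score_covariance(self):
        def sib_cov(r):
            cfg = small_config(
                n_families=6000, sibling_prob=1.0, mating_correlation=r, seed=17
            )
            cohort, _ = simulate_cohort(cfg, simulate_gwas_weights(cfg))
            wide = cohort.groupby("family_id")["allele_score_true"].agg(["first", "last"])
            return wide["first"].cov(wide["last"])

        assert sib_cov(0.8) > 1.5 * sib_cov(0.0)

    def test_spousal_score_correlation_near_zero_under_random_mating(self):
        cfg = small_config(n_families=4000, mating_correlation=0.0, seed=19)
        gwas = simulate_gwas_weights(cfg)
        beta = np.array([g.beta for g in gwas])
        eaf = np.array([g.eaf for g in gwas])
        rng = np.random.default_rng(0)
        gm = rng.binomial(2, eaf[None, :], size=(4000, len(beta)))
        gf = rng.binomial(2, eaf[None, :], size=(4000, len(beta)))
        from edumr.simulate import _pair_parents

        perm = _pair_parents(gm @ beta, gf @ beta, 0.0, rng)
        r = np.corrcoef(gm @ beta, (gf @ beta)[perm])[0, 1]
        assert abs(r) < 4 / np.sqrt(4000)


class TestSelection:
    def test_no_selection_is_identity(self):
        cfg = small_config(selection_model={"intercept": 50.0}, seed=7)
        cohort, _ = simulate_cohort(cfg, simulate_gwas_weights(cfg))
        out = apply_selection(cohort, cfg)
        assert len(out) == len(cohort)
        assert np.allclose(out["sampling_weight"], 1.0)

    def test_mcar_half_selection_gives_weight_two(self):
        cfg = small_config(n_families=4000, selection_model={"intercept": 0.0}, seed=8)
        cohort, _ = simulate_cohort(cfg, simulate_gwas_weights(cfg))
        out = apply_selection(cohort, cfg)
        assert np.allclose(out["sampling_weight"], 2.0)
        assert abs(len(out) / len(cohort) - 0.5) < 0.03
        # MCAR: unweighted education-outcome association unbiased
        full = np.polyfit(cohort["education_years"], cohort["y"], 1)[0]
        sel = np.polyfit(out["education_years"], out["y"], 1)[0]
        assert abs(full - sel) < 0.02

    def test_selection_removing_all_rows_errors(self):
        cfg = small_config(n_families=200, selection_model={"intercept": -60.0}, seed=9)
        cohort, _ = simulate_cohort(cfg, simulate_gwas_weights(cfg))
        with pytest.raises(DegenerateSampleError):
            apply_selection(cohort, cfg)
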