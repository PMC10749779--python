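"""Harmonization and allele-score construction."""

import numpy as np
import pytest

from edumr import (
    GenotypePanel,
    GwasSummaryRecord,
    build_allele_score,
    frequency_concordance,
    harmonize,
)
from edumr.exceptions import UndefinedStatisticError

from conftest import scored_cohort, small_config


def rec(snp="rs1", ea="A", oa="G", beta=0.02, eaf=0.3):
    return GwasSummaryRecord(snp_id=snp, effect_allele=ea, other_allele=oa,
                             beta=beta, se=0.004, pval=1e-9, eaf=eaf)


def panel_of(snp_ids, coded, other, dosages):
    dosages = np.asarray(dosages, dtype=float)
    return GenotypePanel(
        participant_id=np.arange(dosages.shape[0]),
        snp_ids=list(snp_ids),
        coded_allele=list(coded),
        other_allele=list(other),
        dosages=dosages,
    )


class TestHarmonize:
    def test_panel_codes_other_allele_reorients_dosage(self):
        # panel codes G; score must count allele A via 2 - x
        p = panel_of(["rs1"], ["G"], ["A"], [[0.0], [1.0], [2.0]])
        weights, rep = harmonize([rec()], p)
        assert rep.n_flipped == 1 and weights[0].flipped
        s = build_allele_score(p, weights)
        assert np.allclose(s.score, 0.02 * (2 - np.array([0.0, 1.0, 2.0])))

    def test_already_aligned_not_flipped(self):
        p = panel_of(["rs1"], ["A"], ["G"], [[1.0], [2.0]])
        weights, rep = harmonize([rec()], p)
        assert rep.n_flipped == 0 and not weights[0].flipped

    def test_palindromic_at_half_frequency_excluded(self):
        p = panel_of(["rs1"], ["A"], ["T"], [[1.0], [1.0], [0.0], [2.0]])
        weights, rep = harmonize([rec(ea="A", oa="T", eaf=0.50)], p)
        assert weights == []
        assert rep.n_excluded_palindromic == 1

    def test_palindromic_far_from_half_kept_and_freq_oriented(self):
        # eaf 0.1: panel coded-allele frequency 0.9 means the panel counts T
        dos = np.array([[2.0]] * 9 + [[0.0]])
        p = panel_of(["rs1"], ["A"], ["T"], dos)
        weights, rep = harmonize([rec(ea="A", oa="T", eaf=0.1)], p)
        assert rep.n_excluded_palindromic == 0
        assert weights[0].flipped  # frequency concordance resolves the strand

    def test_missing_snp_counted_and_proxy_substitution(self):
        p = panel_of(["rs9"], ["A"], ["G"], [[1.0], [2.0]])
        _, rep = harmonize([rec(snp="rs1")], p)
        assert rep.n_missing_in_panel == 1
        weights, rep2 = harmonize([rec(snp="rs1")], p, proxy_table={"rs1": "rs9"})
        assert rep2.n_substituted_proxies == 1 and weights[0].panel_index == 0

    def test_allele_mismatch_recorded_not_fatal(self):
        p = panel_of(["rs1", "rs2"], ["C", "A"], ["A", "G"], [[1.0, 1.0], [2.0, 0.0]])
        weights, rep = harmonize([rec(snp="rs1", ea="A", oa="G"), rec(snp="rs2")], p)
        assert rep.n_allele_mismatch == 1
        assert len(rep.errors) == 1 and "rs1" in rep.errors[0]
        assert [w.snp_id for w in weights] == ["rs2"]

    def test_strand_complement_recognized(self):
        # GWAS reports A/G; panel genotyped the other strand as T/C
        p = panel_of(["rs1"], ["T"], ["C"], [[0.0], [2.0]])
        weights, rep = harmonize([rec(ea="A", oa="G")], p)
        assert len(weights) == 1 and not weights[0].flipped
        assert rep.n_flipped == 0


class TestFrequencyConcordance:
    def test_identity(self):
        rho, mx = frequency_concordance([0.2, 0.5, 0.8], [0.2, 0.5, 0.8])
        assert rho == pytest.approx(1.0) and mx == 0.0

    def test_affine_shift_exact(self):
        rho, mx = frequency_concordance([0.2, 0.5, 0.8], [0.25, 0.55, 0.85])
        assert rho == pytest.approx(1.0, abs=1e-12)
        assert mx == pytest.approx(0.05)

    def test_anticorrelation_flags_orientation_fault(self):
        rho, _ = frequency_concordance([0.2, 0.8], [0.8, 0.2])
        assert rho == pytest.approx(-1.0)

    def test_single_snp_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            frequency_concordance([0.2], [0.2])

    def test_simulated_panel_emulates_reported_concordance(self, base_run):
        *_, report = base_run
        assert report.freq_correlation > 0.99
        assert report.max_freq_diff < 0.05


class TestAlleleScore:
    def test_weighted_sum_arithmetic(self):
        p = panel_of(["rs1", "rs2"], ["A", "C"], ["G", "T"], [[2.0, 1.0], [0.0, 0.0]])
        w, _ = harmonize([rec("rs1", "A", "G", 0.5), rec("rs2", "C", "T", 0.2)], p)
        s = build_allele_score(p, w)
        assert s.score[0] == pytest.approx(1.2)
        assert s.score[1] == 0.0  # all-zero dosages -> zero score

    def test_reoriented_full_dosage_contributes_zero(self):
        p = panel_of(["rs1"], ["G"], ["A"], [[2.0]])
        w, _ = harmonize([rec()], p)
        s = build_allele_score(p, w)
        assert s.score[0] == pytest.approx(0.0)

    def test_zero_beta_snp_leaves_scores_unchanged(self):
        p = panel_of(["rs1", "rs2"], ["A", "C"], ["G", "T"], [[2.0, 1.0], [1.0, 2.0]])
        w1, _ = harmonize([rec("rs1", "A", "G", 0.5)], p)
        w2, _ = harmonize([rec("rs1", "A", "G", 0.5), rec("rs2", "C", "T", 0.0)], p)
        assert np.allclose(build_allele_score(p, w1).score, build_allele_score(p, w2).score)

    def test_missing_dosage_mean_imputed_and_all_missing_nan(self):
        dos = [[np.nan, 1.0], [np.nan, np.nan], [2.0, 0.0]]
        p = panel_of(["rs1", "rs2"], ["A", "C"], ["G", "T"], dos)
        w, _ = harmonize([rec("rs1", "A", "G", 0.5), rec("rs2", "C", "T", 0.2)], p)
        s = build_allele_score(p, w)
        exp_dosage = 2.0 * p.coded_frequency()[0]  # = 2.0 from the one observed value
        assert s.score[0] == pytest.approx(0.5 * exp_dosage + 0.2 * 1.0)
        assert np.isnan(s.score[1])
        sc = build_allele_score(p, w, missing="complete")
        assert np.isnan(sc.score[0]) and np.isnan(sc.score[1])
        assert sc.score[2] == pytest.approx(0.5 * 2.0)

    def test_orientation_invariance_under_full_panel_recode(self):
        cfg = small_config(n_families=300, seed=23, panel_recode_fraction=0.0)
        cohort, panel, gwas, w, _ = scored_cohort(cfg)
        flipped_panel = GenotypePanel(
            participant_id=panel.participant_id,
            snp_ids=panel.snp_ids,
            coded_allele=list(panel.other_allele),
            other_allele=list(panel.coded_allele),
            dosages=2.0 - panel.dosages,
        )
        w2, _ = harmonize(gwas, flipped_panel)
        s1 = build_allele_score(panel, w)
        s2 = build_allele_score(flipped_panel, w2)
        assert np.allclose(s1.score, s2.score)

    def test_snp_order_invariance(self):
        cfg = small_config(n_families=200, seed=29)
        _, panel, gwas, w, _ = scored_cohort(cfg)
        s1 = build_allele_score(panel, w)
        w_rev, _ = harmonize(list(reversed(gwas)), panel)
        s2 = build_allele_score(panel, w_rev)
        assert np.allclose(s1.score, s2.score)
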