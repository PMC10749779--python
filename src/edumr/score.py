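"""Harmonize GWAS summary statistics to a genotype panel and build the score.

Harmonization orients every SNP so that the counted allele is the GWAS effect
allele: if the panel codes the other allele the dosage is reoriented
(x -> 2 - x); if the panel alleles are the strand complement of the GWAS pair
the comparison is made on the complemented strand; palindromic SNPs (A/T,
C/G) whose minor-allele frequency is within a window of 0.5 are excluded
because their strand cannot be resolved.  The report carries the counts and
the GWAS-vs-panel allele-frequency concordance used as a sanity check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .exceptions import UndefinedStatisticError
from .simulate import GenotypePanel, GwasSummaryRecord, _COMPLEMENT


@dataclass
class AlignedWeight:
    """One SNP after harmonization: which panel column, flipped or not, beta."""

    snp_id: str
    panel_index: int
    beta: float
    flipped: bool  # True when counted dosage is 2 - panel dosage
    gwas_eaf: float
    panel_eaf: float  # effect-allele frequency in the panel after orientation


@dataclass
class HarmonizationReport:
    n_input: int = 0
    n_aligned: int = 0
    n_flipped: int = 0
    n_excluded_palindromic: int = 0
    n_missing_in_panel: int = 0
    n_substituted_proxies: int = 0
    n_allele_mismatch: int = 0
    freq_correlation: float = float("nan")
    max_freq_diff: float = float("nan")
    errors: List[str] = field(default_factory=list)

    def to_dict(self) -> Dict[str, object]:
        return {
            "n_input": self.n_input,
            "n_aligned": self.n_aligned,
            "n_flipped": self.n_flipped,
            "n_excluded_palindromic": self.n_excluded_palindromic,
            "n_missing_in_panel": self.n_missing_in_panel,
            "n_substituted_proxies": self.n_substituted_proxies,
            "n_allele_mismatch": self.n_allele_mismatch,
            "freq_correlation": self.freq_correlation,
            "max_freq_diff": self.max_freq_diff,
            "errors": list(self.errors),
        }


@dataclass
class AlleleScore:
    """Weighted count of education-increasing alleles per participant."""

    participant_id: np.ndarray
    score: np.ndarray
    snp_ids: List[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"participant_id": self.participant_id, "allele_score": self.score})


def _is_palindromic_pair(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


def harmonize(
    gwas: Sequence[GwasSummaryRecord],
    panel: GenotypePanel,
    proxy_table: Optional[Dict[str, str]] = None,
    palindrome_window: float = 0.08,
) -> Tuple[List[AlignedWeight], HarmonizationReport]:
    """Align GWAS effect alleles with the panel coding.

    ``proxy_table`` maps a GWAS SNP id absent from the panel to a substitute
    panel SNP id assumed to be in perfect linkage disequilibrium (same alleles
    and orientation conventions apply to the proxy).  Palindromic SNPs with
    MAF within ``palindrome_window`` of 0.5 are excluded.  SNPs whose alleles
    match the panel on neither strand are recorded as errors, not fatal.
    """
    report = HarmonizationReport(n_input=len(gwas))
    panel_idx = {sid: j for j, sid in enumerate(panel.snp_ids)}
    panel_freq = panel.coded_frequency()
    aligned: List[AlignedWeight] = []

    for rec in gwas:
        sid = rec.snp_id
        j = panel_idx.get(sid)
        proxied = False
        if j is None and proxy_table and sid in proxy_table:
            j = panel_idx.get(proxy_table[sid])
            proxied = j is not None
        if j is None:
            report.n_missing_in_panel += 1
            continue

        p_panel = panel_freq[j]
        coded, other = panel.coded_allele[j], panel.other_allele[j]
        ea, oa = rec.effect_allele, rec.other_allele
        cea, coa = _COMPLEMENT[ea], _COMPLEMENT[oa]
        if rec.is_palindromic:
            maf = min(rec.eaf, 1.0 - rec.eaf)
            if maf >= 0.5 - palindrome_window:
                report.n_excluded_palindromic += 1
                continue
            if {coded, other} != {ea, oa}:
                report.n_allele_mismatch += 1
                report.errors.append(
                    f"{sid}: palindromic GWAS alleles {ea}/{oa} do not match panel {coded}/{other}"
                )
                continue
            # allele labels cannot resolve strand for A/T and C/G pairs:
            # orient by allele-frequency concordance (safe away from MAF 0.5)
            flipped = abs((1.0 - p_panel) - rec.eaf) < abs(p_panel - rec.eaf)
        elif (coded, other) == (ea, oa) or (coded, other) == (cea, coa):
            flipped = False
        elif (coded, other) == (oa, ea) or (coded, other) == (coa, cea):
            flipped = True
        else:
            report.n_allele_mismatch += 1
            report.errors.append(
                f"{sid}: GWAS alleles {ea}/{oa} match panel {coded}/{other} on neither strand"
            )
            continue

        eff_freq = 1.0 - p_panel if flipped else p_panel
        if proxied:
            report.n_substituted_proxies += 1
        if flipped:
            report.n_flipped += 1
        aligned.append(
            AlignedWeight(
                snp_id=sid,
                panel_index=j,
                beta=rec.beta,
                flipped=flipped,
                gwas_eaf=rec.eaf,
                panel_eaf=float(eff_freq),
            )
        )

    report.n_aligned = len(aligned)
    if len(aligned) >= 2:
        g = np.array([w.gwas_eaf for w in aligned])
        p = np.array([w.panel_eaf for w in aligned])
        report.freq_correlation, report.max_freq_diff = frequency_concordance(g, p)
    return aligned, report


def frequency_concordance(
    gwas_eaf: np.ndarray, panel_eaf: np.ndarray
) -> Tuple[float, float]:
    """Pearson correlation and max |difference| of aligned allele frequencies.

    A strongly negative correlation signals a strand/orientation fault.
    """
    gwas_eaf = np.asarray(gwas_eaf, dtype=float)
    panel_eaf = np.asarray(panel_eaf, dtype=float)
    if len(gwas_eaf) < 2 or len(gwas_eaf) != len(panel_eaf):
        raise UndefinedStatisticError("need >= 2 aligned SNPs for frequency concordance")
    if np.ptp(gwas_eaf) == 0 or np.ptp(panel_eaf) == 0:
        rho = float("nan")  # correlation undefined for a constant frequency vector
    else:
        rho = float(np.corrcoef(gwas_eaf, panel_eaf)[0, 1])
    return rho, float(np.max(np.abs(gwas_eaf - panel_eaf)))


def build_allele_score(
    panel: GenotypePanel,
    weights: Sequence[AlignedWeight],
    missing: str = "mean",
) -> AlleleScore:
    """score_i = sum_j beta_j x_ij over harmonized effect-allele dosages.

    Missing dosages contribute the SNP's expected dosage 2 x EAF
    (``missing="mean"``) or invalidate the participant's score
    (``missing="complete"``).  A participant missing every dosage gets NaN in
    either mode — never a silent zero.
    """
    if missing not in ("mean", "complete"):
        raise ValueError("missing must be 'mean' or 'complete'")
    n = panel.n_participants
    if weights:
        idx = [w.panel_index for w in weights]
        beta = np.array([w.beta for w in weights])
        flip = np.array([w.flipped for w in weights])
        eaf = np.array([w.panel_eaf for w in weights])
        X = panel.dosages[:, idx].copy()
        X[:, flip] = 2.0 - X[:, flip]
        miss = np.isnan(X)
        X = np.where(miss, 2.0 * eaf[None, :], X)
        score = X @ beta
        score[miss.all(axis=1)] = np.nan
        if missing == "complete":
            score[miss.any(axis=1)] = np.nan
    else:
        score = np.zeros(n)
    return AlleleScore(
        participant_id=np.asarray(panel.participant_id),
        score=score,
        snp_ids=[w.snp_id for w in weights],
    )
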