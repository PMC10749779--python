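"""End-to-end orchestration: simulate -> harmonize -> score -> estimate -> diagnose.

A run produces a triangulation table — one row per (outcome, method) for
multivariable adjustment (MVA), allele-score Mendelian randomization (2SLS
for continuous outcomes, additive SMM for binary ones) and the
school-leaving-age reform — plus a diagnostics bundle (first-stage partial F,
covariate balance, harmonization report) and the per-SNP sensitivity suite.
Runs are deterministic given (config, seed) and log row counts at every
stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import io as _io
from .config import RunConfig
from .diagnostics import balance_ratios, partial_f
from .exceptions import ConfigurationError, DataError
from .iv import EffectEstimate, EstimationRequest, additive_smm, mva_adjusted, tsls
from .pleiotropy import ivw, leave_one_out, mr_egger, per_snp_ratios, snp_associations, weighted_median
from .reform import assign_reform_exposure, reform_iv_per_year
from .score import build_allele_score, harmonize
from .simulate import apply_selection, simulate_cohort, simulate_gwas_weights

logger = logging.getLogger("edumr")


def map_qualifications_to_years(labels: Sequence[str], mapping: Mapping[str, float]) -> pd.Series:
    """ISCED recode: qualification label -> years of education.

    Every label must be present in the mapping; unmapped labels raise with
    the offending labels listed.
    """
    ser = pd.Series(list(labels), dtype="object")
    unmapped = sorted(set(ser.dropna()) - set(mapping))
    if unmapped:
        raise ConfigurationError(f"unmapped qualification labels: {unmapped}")
    return ser.map(mapping).astype(float)


@dataclass
class PipelineResult:
    """Everything a run computes, ready to write or inspect."""

    triangulation: pd.DataFrame
    estimates: List[EffectEstimate]
    reform_estimates: Dict[str, object]
    harmonization: object
    balance: pd.DataFrame
    sensitivity: pd.DataFrame
    leave_one_out: Dict[str, pd.DataFrame]
    partial_f: Dict[str, float]
    cohort: pd.DataFrame
    log: List[str] = field(default_factory=list)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute all toggled stages in order; see module docstring."""
    config.validate()
    log: List[str] = []

    def note(msg: str) -> None:
        logger.info(msg)
        log.append(msg)

    sim = config.simulation
    if config.cohort_path and config.genotype_path and config.gwas_path:
        cohort = _io.read_cohort(config.cohort_path)
        panel = _io.read_dosages(config.genotype_path)
        gwas = _io.read_gwas(config.gwas_path)
        note(f"loaded cohort n={len(cohort)}, panel {panel.n_participants}x{panel.n_snps}")
    else:
        gwas = simulate_gwas_weights(sim)
        cohort, panel = simulate_cohort(sim, gwas)
        note(f"simulated cohort n={len(cohort)}, {panel.n_snps} SNPs")

    if sim.selection_model is not None:
        before = len(cohort)
        cohort = apply_selection(cohort, sim)
        panel_keep = np.isin(panel.participant_id, cohort["participant_id"].to_numpy())
        panel.dosages = panel.dosages[panel_keep]
        panel.participant_id = panel.participant_id[panel_keep]
        note(f"selection kept {len(cohort)}/{before} rows; true IPW weights attached")

    weights, report = harmonize(gwas, panel)
    note(
        f"harmonized {report.n_aligned}/{report.n_input} SNPs "
        f"(flipped {report.n_flipped}, palindromic excluded {report.n_excluded_palindromic}); "
        f"freq rho={report.freq_correlation:.4f}, max diff={report.max_freq_diff:.3f}"
    )
    score = build_allele_score(panel, weights)
    cohort = cohort.merge(score.to_frame(), on="participant_id", how="left")

    weight_col = "sampling_weight" if config.use_weights else None
    covs = tuple(config.covariates)
    estimates: List[EffectEstimate] = []
    reform_estimates: Dict[str, object] = {}
    fstats: Dict[str, float] = {}

    fstats["allele_score"] = partial_f(
        cohort, "education_years", "allele_score", covs, weight_col=weight_col
    )
    cohort["reform"] = assign_reform_exposure(
        cohort["birth_year"], cohort["birth_month"], sim.reform_cutoff
    )
    fstats["reform"] = partial_f(
        cohort, "stayed_past_15", "reform", ("sex",), weight_col=weight_col
    )
    note(f"first-stage partial F: score {fstats['allele_score']:.1f}, reform {fstats['reform']:.1f}")

    for name, spec in sim.outcomes.items():
        req = EstimationRequest(
            outcome=name,
            exposure="education_years",
            instruments=("allele_score",),
            covariates=covs,
            scale=spec.scale,
            weight_col=weight_col,
            cluster_col=config.cluster_col,
        )
        if config.run_mva:
            estimates.append(mva_adjusted(cohort, req))
        if config.run_mr:
            if spec.scale == "binary":
                estimates.append(additive_smm(cohort, req))
            else:
                estimates.append(tsls(cohort, req))
        if config.run_rosla:
            ref, est = reform_iv_per_year(
                cohort, name, weight_col=weight_col, scale=spec.scale,
                cutoff=sim.reform_cutoff,
            )
            reform_estimates[name] = ref
            estimates.append(est)
        note(f"estimated outcome {name!r} ({spec.scale})")

    balance_df = pd.DataFrame()
    if config.run_diagnostics:
        bal_covs = [c for c in ("sex", "age", "confounder") if c in cohort.columns]
        stats_ = balance_ratios(
            cohort, "allele_score", "education_years", bal_covs,
            weight_col=weight_col, instrument_label="allele_score",
        )
        stats_ += balance_ratios(
            cohort, "reform", "education_years", bal_covs,
            weight_col=weight_col, instrument_label="reform",
        )
        balance_df = pd.DataFrame([s.to_dict() for s in stats_])
        note(f"balance ratios computed for {len(bal_covs)} covariates x 2 instruments")

    sens_rows: List[dict] = []
    loo: Dict[str, pd.DataFrame] = {}
    if config.run_sensitivity:
        dos = pd.DataFrame(panel.dosages, columns=panel.snp_ids)
        # orient dosages to effect alleles using the harmonized weights
        oriented = {}
        for w in weights:
            x = panel.dosages[:, w.panel_index]
            oriented[w.snp_id] = 2.0 - x if w.flipped else x
        dos = pd.DataFrame(oriented)
        for name, spec in sim.outcomes.items():
            summ = snp_associations(
                dos, cohort.reset_index(drop=True), "education_years", name,
                covariates=covs, weight_col=weight_col,
            )
            snps, n_excl = per_snp_ratios(summ)
            est_ivw, q = ivw(snps)
            egger_slope, egger_int = mr_egger(snps)
            wmed = weighted_median(snps, seed=config.seed)
            loo[name] = leave_one_out(snps)
            for est in (est_ivw, egger_slope, egger_int, wmed):
                row = est.to_dict()
                row["outcome"] = name
                row["scale"] = spec.scale
                if est.method == "IVW":
                    row["cochran_q"] = q
                sens_rows.append(row)
            note(f"sensitivity suite for {name!r}: {len(snps)} SNPs ({n_excl} excluded), Q={q:.1f}")

    tri = pd.DataFrame([e.to_dict() for e in estimates])
    if not tri.empty:
        binary = tri["scale"] == "binary"
        tri["annotation"] = np.where(binary, "risk difference x100", "outcome units per year")
        tri["ci_low_display"] = np.where(binary, tri["ci_low"] * 100, tri["ci_low"])
        tri["ci_high_display"] = np.where(binary, tri["ci_high"] * 100, tri["ci_high"])
    result = PipelineResult(
        triangulation=tri,
        estimates=estimates,
        reform_estimates=reform_estimates,
        harmonization=report,
        balance=balance_df,
        sensitivity=pd.DataFrame(sens_rows),
        leave_one_out=loo,
        partial_f=fstats,
        cohort=cohort,
        log=log,
    )
    if config.out_dir:
        _write_artifacts(result, config)
    return result


def _write_artifacts(result: PipelineResult, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.triangulation.to_csv(out / "triangulation.csv", index=False)
    if not result.balance.empty:
        result.balance.to_csv(out / "balance.csv", index=False)
    if not result.sensitivity.empty:
        result.sensitivity.to_csv(out / "sensitivity.csv", index=False)
    with open(out / "harmonization.json", "w") as fh:
        json.dump(result.harmonization.to_dict(), fh, indent=2)
    with open(out / "run.log", "w") as fh:
        fh.write("\n".join(result.log) + "\n")
    config.to_yaml(out / "config_used.yaml")


def export_figure_data(
    result: PipelineResult, n_quantiles: int = 5
) -> Dict[str, pd.DataFrame]:
    """Plot-ready tables: leaving-age distributions and forest-plot rows.

    Returns (a) the distribution of education years by reform status and by
    allele-score quintile (each distribution sums to 1) and (b) the
    triangulation rows keyed for a forest plot.
    """
    cohort = result.cohort
    tabs: Dict[str, pd.DataFrame] = {}

    by_reform = (
        cohort.groupby(["reform", "education_years"]).size().rename("n").reset_index()
    )
    by_reform["fraction"] = by_reform["n"] / by_reform.groupby("reform")["n"].transform("sum")
    tabs["education_by_reform"] = by_reform

    stay = cohort.groupby(["reform", "stayed_past_15"]).size().rename("n").reset_index()
    stay["fraction"] = stay["n"] / stay.groupby("reform")["n"].transform("sum")
    tabs["stay_by_reform"] = stay

    score_ok = cohort.dropna(subset=["allele_score"]).copy()
    score_ok["score_quintile"] = pd.qcut(score_ok["allele_score"], n_quantiles, labels=False) + 1
    by_q = (
        score_ok.groupby(["score_quintile", "education_years"]).size().rename("n").reset_index()
    )
    by_q["fraction"] = by_q["n"] / by_q.groupby("score_quintile")["n"].transform("sum")
    tabs["education_by_score_quintile"] = by_q

    tabs["forest_rows"] = result.triangulation.copy()
    return tabs
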