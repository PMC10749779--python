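import numpy as np
import pandas as pd
import pytest

from edumr import (
    EstimationRequest,
    OutcomeSpec,
    SimulationConfig,
    assign_reform_exposure,
    build_allele_score,
    harmonize,
    simulate_cohort,
    simulate_gwas_weights,
)


def small_config(**kw) -> SimulationConfig:
    """A fast default scenario: one continuous and one binary outcome."""
    defaults = dict(
        n_families=3000,
        sibling_prob=0.0,
        seed=11,
        outcomes={
            "y": OutcomeSpec(scale="continuous", true_effect=0.1, noise_sd=1.0),
            "d": OutcomeSpec(
                scale="binary",
                true_effect=-0.014,
                baseline_risk=0.15,
                confounder_effect=0.02,
                trend_slope=0.002,
            ),
        },
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


def scored_cohort(cfg: SimulationConfig):
    """simulate -> harmonize -> score -> attach reform indicator."""
    gwas = simulate_gwas_weights(cfg)
    cohort, panel = simulate_cohort(cfg, gwas)
    weights, report = harmonize(gwas, panel)
    score = build_allele_score(panel, weights)
    cohort = cohort.merge(score.to_frame(), on="participant_id")
    cohort["reform"] = assign_reform_exposure(
        cohort["birth_year"], cohort["birth_month"], cfg.reform_cutoff
    )
    return cohort, panel, gwas, weights, report


@pytest.fixture(scope="session")
def base_config():
    return small_config()


@pytest.fixture(scope="session")
def base_run(base_config):
    return scored_cohort(base_config)


@pytest.fixture(scope="session")
def base_cohort(base_run):
    return base_run[0]


def cohort_grid(per_month=5, months=240):
    """Deterministic birth-month grid: +/-10 school years around Sep 1957."""
    offs = np.repeat(np.arange(-months // 2, months // 2), per_month)
    month_abs = (1957 * 12 + 8) + offs
    return pd.DataFrame(
        {
            "birth_year": month_abs // 12,
            "birth_month": month_abs % 12 + 1,
            "k": np.floor(offs / 12.0),  # school-cohort index
            "t": offs / 12.0,  # continuous cohort time
        }
    )


def wald_oracle(df: pd.DataFrame, y: str, x: str, z: str) -> float:
    """Independent Wald-ratio oracle: group-mean differences by a binary instrument."""
    g1, g0 = df[df[z] == 1], df[df[z] == 0]
    return (g1[y].mean() - g0[y].mean()) / (g1[x].mean() - g0[x].mean())
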