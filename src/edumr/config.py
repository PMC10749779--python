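"""Configuration objects for the synthetic cohort generator and the pipeline.

Everything the generator does is driven by :class:`SimulationConfig`, so a run
is fully reproducible from (config, seed).  Configs round-trip through YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, Optional, Sequence, Tuple

import yaml

from .exceptions import ConfigurationError

#: years of schooling attached to ISCED qualification levels, UK coding
#: (none -> 7, CSE/O-level -> 10, A-level -> 13, NVQ -> 15, professional -> 19,
#: degree -> 20).  Overridable everywhere it is used.
DEFAULT_ISCED_MAP: Dict[str, float] = {
    "none": 7,
    "cse": 10,
    "o_level": 10,
    "a_level": 13,
    "nvq": 15,
    "professional": 19,
    "degree": 20,
}

#: the discrete years-of-education grid implied by the ISCED recode
DEFAULT_ISCED_GRID: Tuple[float, ...] = (7.0, 10.0, 13.0, 15.0, 19.0, 20.0)


@dataclass
class OutcomeSpec:
    """Generating model for one outcome.

    ``true_effect`` is the causal effect of one additional year of education:
    outcome units for continuous outcomes, a risk difference for binary ones.
    """

    scale: str = "continuous"  # 'continuous' | 'binary'
    true_effect: float = 0.0
    noise_sd: float = 1.0  # continuous only
    baseline_risk: float = 0.10  # binary only
    confounder_effect: Optional[float] = None  # falls back to the config-wide value
    trend_slope: Optional[float] = None  # outcome units per birth-year
    sex_effect: float = 0.0

    def validate(self, name: str) -> None:
        if self.scale not in ("continuous", "binary"):
            raise ConfigurationError(f"outcome {name!r}: scale must be continuous|binary")
        if self.scale == "binary" and not (0.0 < self.baseline_risk < 1.0):
            raise ConfigurationError(f"outcome {name!r}: baseline_risk must be in (0,1)")
        if self.noise_sd < 0:
            raise ConfigurationError(f"outcome {name!r}: noise_sd must be >= 0")


def _default_outcomes() -> Dict[str, OutcomeSpec]:
    # a continuous blood-pressure-like outcome and a binary mortality-like one
    # binary effects live on the risk-difference scale, so confounding and
    # trends must be an order of magnitude smaller than for continuous outcomes
    return {
        "sbp": OutcomeSpec(scale="continuous", true_effect=-0.32, noise_sd=8.0),
        "died": OutcomeSpec(
            scale="binary",
            true_effect=-0.014,
            baseline_risk=0.15,
            confounder_effect=0.02,
            trend_slope=0.002,
        ),
    }


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort with known causal structure.

    The generator draws parental genotypes in Hardy-Weinberg proportions,
    transmits alleles Mendelianly, builds years of education from a weighted
    allele score plus confounding and noise, applies a school-leaving-age
    reform at ``reform_cutoff`` with per-early-leaver compliance, and produces
    outcomes with configurable causal effects, secular trends, pleiotropy,
    dynastic effects and selection.
    """

    # genetics
    n_families: int = 10_000
    sibling_prob: float = 0.2  # probability a family contributes 2 offspring
    n_snps: int = 74
    eaf_range: Tuple[float, float] = (0.1, 0.9)
    palindromic_fraction: float = 0.1
    snp_beta_scale: float = 0.05  # years of education per allele (SD of betas)
    mating_correlation: float = 0.0

    # education model
    education_base: float = 12.0  # years, population latent mean
    education_noise_sd: float = 2.5
    confounder_effect_on_education: float = 0.5  # years per confounder SD
    isced_grid: Tuple[float, ...] = DEFAULT_ISCED_GRID
    leave_at_15_years: float = 10.0  # grid value meaning "left school at 15"

    # reform (ROSLA)
    reform_cutoff: Tuple[int, int] = (1957, 9)  # (year, month): first affected birth month
    reform_compliance: float = 0.23  # P(a would-be early leaver stays past 15)
    birth_window_months: int = 120  # births uniform within +/- this many months of cutoff

    # outcomes
    outcomes: Dict[str, OutcomeSpec] = field(default_factory=_default_outcomes)
    confounder_effect_on_outcome: float = 0.5  # outcome units per confounder SD
    trend_slope: float = 0.05  # outcome units per birth-year (default for all outcomes)
    education_reference: float = 12.0  # centering for binary risk models

    # exclusion-restriction violations
    pleiotropy_fraction: float = 0.0  # fraction of SNPs with direct outcome effects
    pleiotropy_mean: float = 0.0  # directional when != 0
    pleiotropy_sd: float = 0.0
    dynastic_effect: float = 0.0  # outcome units per parental-score SD

    # selection (None -> everyone selected, weight 1)
    selection_model: Optional[Dict[str, float]] = None

    # bookkeeping
    panel_recode_fraction: float = 0.5  # panel SNPs coded on the other allele
    assessment_year: float = 2008.5  # centre of the recruitment period -> age covariate
    assessment_window_years: float = 4.0  # recruitment spread (uniform)
    seed: int = 0

    # ------------------------------------------------------------------
    def true_effects(self) -> Dict[str, float]:
        return {name: spec.true_effect for name, spec in self.outcomes.items()}

    def validate(self) -> None:
        lo, hi = self.eaf_range
        if not (0.0 < lo < hi < 1.0):
            raise ConfigurationError(f"eaf_range must satisfy 0 < lo < hi < 1, got {self.eaf_range}")
        if self.n_snps < 1:
            raise ConfigurationError("n_snps must be >= 1")
        if self.n_families < 1:
            raise ConfigurationError("n_families must be >= 1")
        for name, p in [
            ("sibling_prob", self.sibling_prob),
            ("palindromic_fraction", self.palindromic_fraction),
            ("reform_compliance", self.reform_compliance),
            ("pleiotropy_fraction", self.pleiotropy_fraction),
        ]:
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"{name} must be in [0,1], got {p}")
        if not (-1.0 <= self.mating_correlation <= 1.0):
            raise ConfigurationError("mating_correlation must be in [-1,1]")
        if len(self.isced_grid) < 2 or list(self.isced_grid) != sorted(self.isced_grid):
            raise ConfigurationError("isced_grid must be a sorted grid of >= 2 values")
        for name, spec in self.outcomes.items():
            spec.validate(name)
        if self.selection_model is not None:
            known = {"intercept", "education_years", "stayed_past_15"} | set(self.outcomes)
            unknown = set(self.selection_model) - known
            if unknown:
                raise ConfigurationError(f"selection_model refers to unknown columns: {sorted(unknown)}")

    # YAML round-trip -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["outcomes"] = {k: asdict(v) for k, v in self.outcomes.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        raw = d.pop("outcomes", None)
        cfg = cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})
        for tup in ("eaf_range", "reform_cutoff", "isced_grid"):
            setattr(cfg, tup, tuple(getattr(cfg, tup)))
        if raw is not None:
            cfg.outcomes = {k: OutcomeSpec(**v) for k, v in raw.items()}
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class RunConfig:
    """One pipeline run: a simulation (or user-supplied files) plus toggles."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    # paths override simulation when all three are given
    cohort_path: Optional[str] = None
    genotype_path: Optional[str] = None
    gwas_path: Optional[str] = None

    covariates: Sequence[str] = ("sex", "age", "month_of_birth")
    cluster_col: str = "month_of_birth"
    use_weights: bool = True
    run_mva: bool = True
    run_mr: bool = True
    run_rosla: bool = True
    run_diagnostics: bool = True
    run_sensitivity: bool = True
    out_dir: str = "edumr_run"
    seed: int = 0
    isced_map: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ISCED_MAP))

    def validate(self) -> None:
        self.simulation.validate()
        if not self.simulation.outcomes:
            raise ConfigurationError("outcome list must be non-empty")
        bad = {k: v for k, v in self.isced_map.items() if not (7 <= v <= 20)}
        if bad:
            raise ConfigurationError(f"ISCED years outside plausible range [7, 20]: {bad}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulation"] = self.simulation.to_dict()
        d["covariates"] = list(self.covariates)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("simulation", None)
        cfg = cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})
        if sim is not None:
            cfg.simulation = SimulationConfig.from_dict(sim)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
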