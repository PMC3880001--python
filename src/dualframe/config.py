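"""Configuration types for the population generator and the sample design.

Defaults reproduce the study conditions of the continuous NZ Health Survey
design: 21 District Health Board strata spanning roughly 30,000-460,000
residents, meshblocks of ~40 households (CV ~70%) grouped into area units of
~20 meshblocks, overlapping total-response ethnicity for Maori / Pacific /
Asian, an electoral-roll list frame flagging Maori-descent addresses, and the
published targeting-factor coefficients 0.31 / 0.37 / 0.09 / 0.20 / 0.03.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Tuple

import yaml

ETHNICITIES = ("maori", "pacific", "asian")

#: Published targeting-factor coefficients (pacific MB, pacific AU, asian MB,
#: asian AU, constant).  They sum to 1.00.
DEFAULT_TARGETING_COEFFICIENTS = (0.31, 0.37, 0.09, 0.20, 0.03)


@dataclass
class EthnicityProfile:
    """Marginal prevalence and spatial behaviour of one ethnic group.

    prevalence
        population share holding this (total-response) ethnicity flag.
    clustering_sd
        standard deviation of the area-unit level latent logit field; larger
        values concentrate the group in fewer areas.
    mean_household_size
        mean size of households carrying this flag; groups living in larger
        households are undersampled by one-person-per-household selection.
    """

    prevalence: float
    clustering_sd: float = 1.0
    mean_household_size: float = 2.6


@dataclass
class OutcomeSpec:
    """A binary health indicator: overall prevalence, within-meshblock
    intra-class correlation, and optional additive per-ethnicity shifts."""

    name: str
    prevalence: float
    icc: float = 0.0
    ethnicity_shifts: Dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError(f"outcome {self.name}: prevalence must be in (0,1)")
        if not 0.0 <= self.icc < 1.0:
            raise ValueError(f"outcome {self.name}: ICC must be in [0,1)")


@dataclass
class PopulationConfig:
    """Parameters of the synthetic population generator."""

    n_strata: int = 21
    stratum_person_range: Tuple[float, float] = (30_000.0, 460_000.0)
    mean_households_per_mb: float = 40.0
    mb_size_cv: float = 0.70
    mbs_per_au: int = 20
    ethnic_profile: Dict[str, EthnicityProfile] = field(
        default_factory=lambda: {
            "maori": EthnicityProfile(0.15, clustering_sd=1.0, mean_household_size=2.6),
            "pacific": EthnicityProfile(0.07, clustering_sd=1.6, mean_household_size=4.2),
            "asian": EthnicityProfile(0.11, clustering_sd=1.3, mean_household_size=3.4),
        }
    )
    #: target pairwise correlations of MB-level ethnic densities
    target_density_correlations: Dict[Tuple[str, str], float] = field(
        default_factory=lambda: {
            ("asian", "pacific"): 0.14,
            ("asian", "maori"): -0.15,
            ("maori", "pacific"): 0.30,
        }
    )
    base_household_size: float = 2.6
    child_member_prob: float = 0.33
    mb_density_concentration: float = 60.0
    roll_coverage: float = 0.80
    outcome_specs: List[OutcomeSpec] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.stratum_person_range
        if lo > hi or lo <= 0:
            raise ValueError("stratum_person_range must satisfy 0 < min <= max")
        if self.n_strata < 1 or self.mbs_per_au < 1:
            raise ValueError("counts must be positive")
        if self.mean_households_per_mb <= 0 or self.mb_size_cv < 0:
            raise ValueError("meshblock size parameters must be positive")
        if not 0.0 <= self.roll_coverage <= 1.0:
            raise ValueError("roll_coverage must be in [0,1]")
        for name, prof in self.ethnic_profile.items():
            if not 0.0 <= prof.prevalence <= 1.0:
                raise ValueError(f"{name}: prevalence must be in [0,1]")
            if prof.mean_household_size < 1.0:
                raise ValueError(f"{name}: mean household size must be >= 1")
        for spec in self.outcome_specs:
            spec.validate()


@dataclass
class DesignConfig:
    """Tunable parameters of the dual-frame sample design."""

    total_households_per_year: int = 12_500
    within_mb_target: int = 20  # c: target household take per area meshblock
    power_exponent: float = 0.5
    targeting_coefficients: Tuple[float, float, float, float, float] = (
        DEFAULT_TARGETING_COEFFICIENTS
    )
    roll_share: float = 0.15
    roll_addresses_per_mb: int = 10
    quarters: int = 4
    response_prob: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.within_mb_target <= 0:
            raise ValueError("within_mb_target c must be positive")
        if not 0.0 < self.power_exponent <= 1.0:
            raise ValueError("power_exponent must be in (0,1]")
        if any(b < 0 for b in self.targeting_coefficients):
            raise ValueError("targeting coefficients must be nonnegative")
        if not 0.0 <= self.roll_share < 1.0:
            raise ValueError("roll_share must be in [0,1)")
        if self.roll_addresses_per_mb <= 0 or self.quarters < 1:
            raise ValueError("counts must be positive")
        if not 0.0 < self.response_prob <= 1.0:
            raise ValueError("response_prob must be in (0,1]")


@dataclass
class ExperimentConfig:
    """A reproducible simulation experiment: population + design + replicates."""

    population: PopulationConfig = field(default_factory=PopulationConfig)
    design: DesignConfig = field(default_factory=DesignConfig)
    n_replicates: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        self.population.validate()
        self.design.validate()


def nz_like_population_config(
    total_persons: Optional[float] = None, seed: int = 0, **overrides
) -> PopulationConfig:
    """An NZ-like population, optionally rescaled to ``total_persons``.

    Rescaling shrinks every stratum proportionally while preserving the
    stratum-size skew and the meshblock size distribution.  Area-unit size is
    shrunk with the square root of the scale: a scaled population keeps a
    reasonable *number* of area units, otherwise every spatial statistic
    (notably the cross-ethnicity density correlations) would be dominated by
    having only a handful of independent latent draws.
    """
    cfg = PopulationConfig(seed=seed, **overrides)
    if total_persons is not None:
        import numpy as np

        lo, hi = cfg.stratum_person_range
        base = np.geomspace(lo, hi, cfg.n_strata).sum()
        scale = float(total_persons) / float(base)
        cfg.stratum_person_range = (lo * scale, hi * scale)
        if "mbs_per_au" not in overrides and scale < 1.0:
            cfg.mbs_per_au = max(2, int(round(cfg.mbs_per_au * np.sqrt(scale))))
    return cfg


# ---------------------------------------------------------------------------
# YAML round-trip helpers (CLI surface)
# ---------------------------------------------------------------------------


def _pop_from_dict(d: dict) -> PopulationConfig:
    d = dict(d)
    if "ethnic_profile" in d:
        d["ethnic_profile"] = {
            k: EthnicityProfile(**v) if isinstance(v, dict) else v
            for k, v in d["ethnic_profile"].items()
        }
    if "target_density_correlations" in d:
        d["target_density_correlations"] = {
            tuple(k.split("/")) if isinstance(k, str) else tuple(k): float(v)
            for k, v in d["target_density_correlations"].items()
        }
    if "outcome_specs" in d:
        d["outcome_specs"] = [
            OutcomeSpec(**o) if isinstance(o, dict) else o for o in d["outcome_specs"]
        ]
    if "stratum_person_range" in d:
        d["stratum_person_range"] = tuple(d["stratum_person_range"])
    return PopulationConfig(**d)


def _pop_to_dict(cfg: PopulationConfig) -> dict:
    d = asdict(cfg)
    d["target_density_correlations"] = {
        "/".join(k): v for k, v in cfg.target_density_correlations.items()
    }
    d["stratum_person_range"] = list(cfg.stratum_person_range)
    return d


def load_experiment_config(path: str) -> ExperimentConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    pop = _pop_from_dict(raw.get("population", {}))
    des = raw.get("design", {})
    if "targeting_coefficients" in des:
        des["targeting_coefficients"] = tuple(des["targeting_coefficients"])
    design = DesignConfig(**des)
    cfg = ExperimentConfig(
        population=pop,
        design=design,
        n_replicates=int(raw.get("n_replicates", 1)),
        seed=int(raw.get("seed", 0)),
    )
    cfg.validate()
    return cfg


def dump_experiment_config(cfg: ExperimentConfig, path: str) -> None:
    raw = {
        "population": _pop_to_dict(cfg.population),
        "design": asdict(cfg.design),
        "n_replicates": cfg.n_replicates,
        "seed": cfg.seed,
    }
    raw["design"]["targeting_coefficients"] = list(cfg.design.targeting_coefficients)
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
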