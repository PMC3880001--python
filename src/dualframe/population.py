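"""Synthetic population generator.

Builds hierarchical populations (stratum > area unit > meshblock > household >
person) carrying the structural features a targeted dual-frame design
exploits:

* stratum person counts spanning a configured range with geometric skew
  (mimicking District Health Boards from ~30k to ~460k residents);
* lognormal meshblock household counts (mean ~40, CV ~70%);
* spatially clustered, mutually correlated ethnic densities: an area-unit
  level logit-normal latent field with a calibrated cross-ethnicity
  correlation, plus beta-distributed meshblock jitter around the area-unit
  value;
* ethnicity-dependent household sizes (groups in larger households are
  undersampled by one-person-per-household selection);
* electoral-roll flags on a configurable fraction of households containing a
  Maori-descent adult;
* binary outcomes with controlled prevalence and within-meshblock
  intra-class correlation via beta-binomial meshblock random effects.

The latent-field calibration is deliberate: the target quantities (marginal
prevalence, MB-level density correlations) are moments of a *transformed*
Gaussian, so the generator solves for the latent mean and latent correlation
by Gauss-Hermite quadrature instead of asking the user to reason on the logit
scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from ._rng import substream
from .config import ETHNICITIES, OutcomeSpec, PopulationConfig

__all__ = [
    "Population",
    "InfeasibleCorrelationError",
    "generate_population",
    "attach_outcomes",
    "census_snapshot",
    "write_population",
    "read_population",
]

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(48)


class InfeasibleCorrelationError(ValueError):
    """Raised when the requested density correlations cannot be attained;
    carries the closest achievable values."""

    def __init__(self, message: str, achievable: Dict[Tuple[str, str], float]):
        super().__init__(message)
        self.achievable = achievable


@dataclass
class Population:
    """A generated population: four tables plus provenance."""

    strata: pd.DataFrame
    meshblocks: pd.DataFrame
    households: pd.DataFrame
    persons: pd.DataFrame
    config: PopulationConfig
    achieved_density_correlations: Dict[Tuple[str, str], float] = field(
        default_factory=dict
    )
    outcome_names: List[str] = field(default_factory=list)

    @property
    def n_persons(self) -> int:
        return len(self.persons)


# ---------------------------------------------------------------------------
# Logit-normal calibration
# ---------------------------------------------------------------------------


def _ln_moments(mu: float, sd: float) -> Tuple[float, float, float]:
    """(mean, variance, E[p(1-p)]) of p = expit(mu + sd*Z), Z ~ N(0,1)."""
    p = expit(mu + sd * np.sqrt(2.0) * _GH_NODES)
    w = _GH_WEIGHTS / np.sqrt(np.pi)
    m = float(np.sum(w * p))
    m2 = float(np.sum(w * p * p))
    return m, m2 - m * m, m - m2


def _calibrate_mu(prevalence: float, sd: float) -> float:
    """Latent mean giving E[expit(mu + sd Z)] = prevalence."""
    f = lambda mu: _ln_moments(mu, sd)[0] - prevalence
    return brentq(f, -40.0, 40.0, xtol=1e-12)


def _cross_moment(mu1, sd1, mu2, sd2, rho) -> float:
    """E[p1 p2] for correlated logit-normals via 2-D Gauss-Hermite."""
    x = np.sqrt(2.0) * _GH_NODES
    w = _GH_WEIGHTS / np.sqrt(np.pi)
    p1 = expit(mu1 + sd1 * x)  # (n,)
    z2 = rho * x[:, None] + np.sqrt(max(0.0, 1.0 - rho * rho)) * x[None, :]
    p2 = expit(mu2 + sd2 * z2)  # (n, n)
    return float(w @ (p2 @ w * p1))


def _latent_rho(target_corr: float, par1, par2) -> float:
    """Latent Gaussian correlation reproducing a density-scale correlation."""
    (mu1, sd1, m1, v1), (mu2, sd2, m2, v2) = par1, par2
    sds = np.sqrt(v1 * v2)

    def g(rho: float) -> float:
        return (_cross_moment(mu1, sd1, mu2, sd2, rho) - m1 * m2) / sds - target_corr

    lo, hi = g(-0.999), g(0.999)
    if not (lo <= 0.0 <= hi):
        raise ValueError("unreachable")
    return brentq(g, -0.999, 0.999, xtol=1e-10)


def _build_latent_model(config: PopulationConfig):
    """Calibrate latent means and the latent correlation matrix.

    Accounts for the attenuation of AU-level correlations at MB level caused
    by the beta jitter: corr_MB = corr_AU * sqrt(r1 r2) with
    r_e = var_AU / (var_AU + E[p(1-p)]/(kappa+1)).
    """
    kappa = config.mb_density_concentration
    names = [e for e in ETHNICITIES if config.ethnic_profile.get(e, None) is not None]
    active = [e for e in names if config.ethnic_profile[e].prevalence > 0.0]
    pars: Dict[str, tuple] = {}
    atten: Dict[str, float] = {}
    for e in active:
        prof = config.ethnic_profile[e]
        mu = _calibrate_mu(prof.prevalence, prof.clustering_sd)
        m, v_au, epq = _ln_moments(mu, prof.clustering_sd)
        v_mb = v_au + epq / (kappa + 1.0)
        pars[e] = (mu, prof.clustering_sd, m, v_au)
        atten[e] = np.sqrt(v_au / v_mb)

    k = len(active)
    R = np.eye(k)
    achievable: Dict[Tuple[str, str], float] = {}
    problems = []
    for (a, b), target in config.target_density_correlations.items():
        if a not in active or b not in active:
            continue
        ia, ib = active.index(a), active.index(b)
        corr_au_needed = target / (atten[a] * atten[b])
        try:
            if abs(corr_au_needed) >= 1.0:
                raise ValueError("unreachable")
            rho = _latent_rho(corr_au_needed, pars[a], pars[b])
        except ValueError:
            max_au = _cross_moment(*pars[a][:2], *pars[b][:2], 0.999)
            max_corr = (
                (max_au - pars[a][2] * pars[b][2])
                / np.sqrt(pars[a][3] * pars[b][3])
                * atten[a]
                * atten[b]
            )
            achievable[(a, b)] = float(np.sign(target) * abs(max_corr))
            problems.append(f"{a}/{b}: target {target:+.3f}")
            rho = np.sign(target) * 0.999
        R[ia, ib] = R[ib, ia] = rho
    eigvals = np.linalg.eigvalsh(R)
    if eigvals.min() < -1e-10:
        problems.append(f"latent correlation matrix not PSD (min eig {eigvals.min():.3g})")
    if problems:
        raise InfeasibleCorrelationError(
            "density correlations not attainable: " + "; ".join(problems),
            achievable,
        )
    # guard tiny negative eigenvalues from numerics
    L = np.linalg.cholesky(R + 1e-12 * np.eye(k))
    return active, pars, L


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _stratum_person_targets(config: PopulationConfig) -> np.ndarray:
    lo, hi = config.stratum_person_range
    if config.n_strata == 1:
        return np.array([0.5 * (lo + hi)])
    return np.geomspace(lo, hi, config.n_strata)


def _expected_household_size(config: PopulationConfig) -> float:
    # crude first moment: affiliated households are rarer but larger
    size = config.base_household_size
    for e, prof in config.ethnic_profile.items():
        size += prof.prevalence * max(0.0, prof.mean_household_size - config.base_household_size)
    return size


def generate_population(config: PopulationConfig) -> Population:
    """Generate a population; fully reproducible from ``config.seed``."""
    config.validate()
    active, pars, L = _build_latent_model(config) if any(
        p.prevalence > 0 for p in config.ethnic_profile.values()
    ) else ([], {}, np.zeros((0, 0)))

    kappa = config.mb_density_concentration
    person_targets = _stratum_person_targets(config)
    mean_size = _expected_household_size(config)

    sd_l = np.sqrt(np.log1p(config.mb_size_cv**2))
    mu_l = np.log(config.mean_households_per_mb) - 0.5 * sd_l**2

    mb_rows, hh_chunks, person_chunks, strata_rows = [], [], [], []
    mb_id = au_id = hh_id = person_id = 0

    for h, target in enumerate(person_targets):
        rng = substream(config.seed, "population", f"stratum{h}")
        n_mb = max(1, int(round(target / (config.mean_households_per_mb * mean_size))))
        hh_counts = np.maximum(
            1, np.round(rng.lognormal(mu_l, sd_l, size=n_mb)).astype(int)
        )
        n_au = int(np.ceil(n_mb / config.mbs_per_au))
        au_of_mb = np.minimum(np.arange(n_mb) // config.mbs_per_au, n_au - 1)

        # area-unit latent field -> AU densities -> beta jitter -> MB densities
        d_au = np.zeros((n_au, len(ETHNICITIES)))
        d_mb = np.zeros((n_mb, len(ETHNICITIES)))
        if active:
            z = rng.standard_normal((n_au, len(active))) @ L.T
            for j, e in enumerate(active):
                mu_e, sd_e, _, _ = pars[e]
                col = ETHNICITIES.index(e)
                dau = expit(mu_e + sd_e * z[:, j])
                d_au[:, col] = dau
                a = kappa * dau[au_of_mb]
                b = kappa * (1.0 - dau[au_of_mb])
                d_mb[:, col] = rng.beta(np.maximum(a, 1e-9), np.maximum(b, 1e-9))

        # households: flags, sizes, composition
        n_hh = int(hh_counts.sum())
        mb_of_hh = np.repeat(np.arange(n_mb), hh_counts)
        flags = np.zeros((n_hh, len(ETHNICITIES)), dtype=bool)
        for col, e in enumerate(ETHNICITIES):
            prof = config.ethnic_profile.get(e)
            if prof is None or prof.prevalence == 0.0:
                continue
            # size-bias correction keeps the person-level share near the
            # density even though affiliated households are larger
            q = np.clip(
                d_mb[mb_of_hh, col]
                * (config.base_household_size / prof.mean_household_size),
                0.0,
                1.0,
            )
            flags[:, col] = rng.random(n_hh) < q

        mean_hh = np.full(n_hh, config.base_household_size)
        for col, e in enumerate(ETHNICITIES):
            prof = config.ethnic_profile.get(e)
            if prof is None:
                continue
            mean_hh = np.where(
                flags[:, col], np.maximum(mean_hh, prof.mean_household_size), mean_hh
            )
        sizes = 1 + rng.poisson(np.maximum(mean_hh - 1.0, 0.0))

        # persons: member 0 is an adult; later members are children with
        # probability child_member_prob
        n_p = int(sizes.sum())
        hh_of_p = np.repeat(np.arange(n_hh), sizes)
        first = np.zeros(n_p, dtype=bool)
        first[np.concatenate(([0], np.cumsum(sizes)[:-1]))] = True
        is_adult = first | (rng.random(n_p) >= config.child_member_prob)
        p_flags = flags[hh_of_p]

        n_adults = np.bincount(hh_of_p, weights=is_adult, minlength=n_hh).astype(int)
        n_children = sizes - n_adults

        # electoral roll: households containing a Maori adult are on the roll
        # with probability roll_coverage
        maori_col = ETHNICITIES.index("maori")
        has_maori_adult = (
            np.bincount(
                hh_of_p, weights=is_adult & p_flags[:, maori_col], minlength=n_hh
            )
            > 0
        )
        on_roll = has_maori_adult & (rng.random(n_hh) < config.roll_coverage)

        roll_per_mb = np.bincount(mb_of_hh, weights=on_roll, minlength=n_mb).astype(int)
        persons_per_mb = np.bincount(mb_of_hh, weights=sizes, minlength=n_mb).astype(int)

        strata_rows.append(
            dict(
                stratum_id=h,
                census_persons=int(n_p),
                census_dwellings=int(n_hh),
                n_meshblocks=n_mb,
            )
        )
        mb_rows.append(
            pd.DataFrame(
                dict(
                    mb_id=np.arange(mb_id, mb_id + n_mb),
                    au_id=au_id + au_of_mb,
                    stratum_id=h,
                    census_persons=persons_per_mb,
                    census_dwellings=hh_counts,
                    current_dwellings=hh_counts,
                    maori_mb=d_mb[:, 0],
                    pacific_mb=d_mb[:, 1],
                    asian_mb=d_mb[:, 2],
                    maori_au=d_au[au_of_mb, 0],
                    pacific_au=d_au[au_of_mb, 1],
                    asian_au=d_au[au_of_mb, 2],
                    roll_addresses=roll_per_mb,
                )
            )
        )
        hh_chunks.append(
            pd.DataFrame(
                dict(
                    household_id=np.arange(hh_id, hh_id + n_hh),
                    mb_id=mb_id + mb_of_hh,
                    stratum_id=h,
                    size=sizes,
                    n_adults=n_adults,
                    n_children=n_children,
                    maori=flags[:, 0],
                    pacific=flags[:, 1],
                    asian=flags[:, 2],
                    on_roll=on_roll,
                )
            )
        )
        person_chunks.append(
            pd.DataFrame(
                dict(
                    person_id=np.arange(person_id, person_id + n_p),
                    household_id=hh_id + hh_of_p,
                    mb_id=mb_id + mb_of_hh[hh_of_p],
                    stratum_id=h,
                    is_adult=is_adult,
                    maori=p_flags[:, 0],
                    pacific=p_flags[:, 1],
                    asian=p_flags[:, 2],
                    on_roll_maori_descent=is_adult
                    & p_flags[:, maori_col]
                    & on_roll[hh_of_p],
                )
            )
        )
        mb_id += n_mb
        au_id += n_au
        hh_id += n_hh
        person_id += n_p

    meshblocks = pd.concat(mb_rows, ignore_index=True)
    households = pd.concat(hh_chunks, ignore_index=True)
    persons = pd.concat(person_chunks, ignore_index=True)

    achieved: Dict[Tuple[str, str], float] = {}
    for (a, b), _ in config.target_density_correlations.items():
        ca, cb = f"{a}_mb", f"{b}_mb"
        if meshblocks[ca].std() > 0 and meshblocks[cb].std() > 0:
            achieved[(a, b)] = float(meshblocks[ca].corr(meshblocks[cb]))

    pop = Population(
        strata=pd.DataFrame(strata_rows),
        meshblocks=meshblocks,
        households=households,
        persons=persons,
        config=config,
        achieved_density_correlations=achieved,
    )
    if config.outcome_specs:
        attach_outcomes(pop, config.outcome_specs)
    return pop


def attach_outcomes(
    population: Population,
    outcome_specs: List[OutcomeSpec],
    seed: Optional[int] = None,
) -> Population:
    """Attach binary outcomes with meshblock-level random effects (in place).

    For ICC rho > 0 the meshblock prevalence is Beta with mean p and
    a + b = (1 - rho)/rho, which makes the within-MB intra-class correlation
    of the binary outcome exactly rho; rho = 0 pins every meshblock at p.
    """
    seed = population.config.seed if seed is None else seed
    persons = population.persons
    mb_codes = pd.factorize(persons["mb_id"])[0]
    n_mb = mb_codes.max() + 1
    for spec in outcome_specs:
        spec.validate()
        rng = substream(seed, "outcomes", spec.name)
        p, rho = spec.prevalence, spec.icc
        if rho == 0.0:
            p_mb = np.full(n_mb, p)
        else:
            s = (1.0 - rho) / rho
            p_mb = rng.beta(p * s, (1.0 - p) * s, size=n_mb)
        prob = p_mb[mb_codes]
        if spec.ethnicity_shifts:
            shift = np.zeros(len(persons))
            for e, delta in spec.ethnicity_shifts.items():
                shift += delta * persons[e].to_numpy()
            prob = np.clip(prob + shift, 1e-6, 1.0 - 1e-6)
        persons[spec.name] = rng.random(len(persons)) < prob
        if spec.name not in population.outcome_names:
            population.outcome_names.append(spec.name)
    return population


def census_snapshot(
    population: Population, drift: float = 0.0, seed: Optional[int] = None
) -> pd.DataFrame:
    """Sampling frame as of enumeration time.

    Census quantities (N*_i, dwellings, densities, roll counts) keep their
    generation-time values; the *current* dwelling count H_i is perturbed by
    a multiplicative drift with mean relative change ``drift`` (sign random),
    emulating an outdated census frame.  drift = 0 returns the truth.
    """
    if drift < 0:
        raise ValueError("drift must be >= 0")
    frame = population.meshblocks.copy()
    if drift > 0:
        rng = substream(population.config.seed if seed is None else seed, "drift")
        n = len(frame)
        sign = np.where(rng.random(n) < 0.5, -1.0, 1.0)
        factor = 1.0 + drift * sign * rng.uniform(0.5, 1.5, size=n)
        frame["current_dwellings"] = np.maximum(
            0, np.round(frame["census_dwellings"] * factor)
        ).astype(int)
    return frame


# ---------------------------------------------------------------------------
# Columnar text serialization
# ---------------------------------------------------------------------------

_TABLES = ("strata", "meshblocks", "households", "persons")


def write_population(population: Population, directory: str) -> None:
    """Write the four tables as TSV files under ``directory``."""
    import os

    os.makedirs(directory, exist_ok=True)
    for name in _TABLES:
        getattr(population, name).to_csv(
            os.path.join(directory, f"{name}.tsv"), sep="\t", index=False
        )


def read_population(directory: str, config: Optional[PopulationConfig] = None) -> Population:
    """Read tables written by :func:`write_population`."""
    import os

    tables = {
        name: pd.read_csv(os.path.join(directory, f"{name}.tsv"), sep="\t")
        for name in _TABLES
    }
    cfg = config or PopulationConfig()
    core = {
        "person_id", "household_id", "mb_id", "stratum_id", "is_adult",
        "maori", "pacific", "asian", "on_roll_maori_descent",
    }
    outcomes = [c for c in tables["persons"].columns if c not in core]
    return Population(config=cfg, outcome_names=outcomes, **tables)
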