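"""Deterministic design quantities.

Covers the four building blocks of the targeted area design:

* power allocation of the meshblock sample across strata
  (m_h proportional to stratum population ** q, default q = 1/2);
* the targeting factor f_i — a nonnegative combination of square-rooted
  Pacific/Asian densities at meshblock and area-unit level plus a constant
  (published coefficients 0.31, 0.37, 0.09, 0.20, 0.03);
* per-stratum PPS inclusion probabilities
  pi_i = m_h * N*_i f_i / sum_j N*_j f_j with iterative certainty treatment;
* the within-meshblock household take H_i * c / N*_i realized by stochastic
  rounding, so the household selection probability given the meshblock is
  exactly c / N*_i and household probabilities stay proportional to f_i
  within each stratum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import DesignConfig

__all__ = [
    "Allocation",
    "DesignPlan",
    "power_allocation",
    "largest_remainder_round",
    "targeting_factor",
    "mb_selection_probabilities",
    "within_mb_sample_size",
    "design_plan",
]


@dataclass
class Allocation:
    """Per-stratum meshblock sample sizes and expected household takes."""

    m_h: np.ndarray  # meshblocks per stratum
    expected_households: np.ndarray

    @property
    def total_meshblocks(self) -> int:
        return int(self.m_h.sum())


def largest_remainder_round(shares: np.ndarray, total: int, minimum: int = 0) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``shares``.

    Largest-remainder (Hamilton) rounding; every entry receives at least
    ``minimum``.
    """
    shares = np.asarray(shares, dtype=float)
    k = len(shares)
    if total < k * minimum:
        raise ValueError(f"total {total} cannot give every stratum >= {minimum}")
    if shares.sum() <= 0:
        raise ValueError("shares must have a positive sum")
    quota = shares / shares.sum() * total
    base = np.maximum(np.floor(quota).astype(int), minimum)
    # iterate: clamping to the minimum changes the distributable remainder
    for _ in range(k + 1):
        short = total - base.sum()
        if short == 0:
            return base
        if short < 0:
            # took too much via minimums; shave from largest over-minimum entries
            order = np.argsort(quota - base)
            for i in order:
                if short == 0:
                    break
                if base[i] > minimum:
                    base[i] -= 1
                    short += 1
            return base
        remainders = quota - base
        order = np.argsort(-remainders)
        base[order[:short]] += 1
    return base


def power_allocation(
    stratum_populations: Sequence[float],
    total_mb_sample: int,
    exponent: float = 0.5,
) -> Allocation:
    """Allocate a meshblock sample across strata by power allocation.

    m_h is proportional to population ** exponent (exponent 1 gives
    proportional allocation, 0.5 the square-root compromise between national
    and small-stratum precision); largest-remainder rounding, at least one
    meshblock per nonempty stratum.
    """
    pops = np.asarray(stratum_populations, dtype=float)
    if np.any(pops <= 0):
        raise ValueError("stratum populations must be positive")
    if total_mb_sample < len(pops):
        raise ValueError("total sample smaller than the number of strata")
    m_h = largest_remainder_round(pops**exponent, total_mb_sample, minimum=1)
    return Allocation(m_h=m_h, expected_households=m_h.astype(float))


def targeting_factor(
    pac_mb, pac_au, asi_mb, asi_au, coefficients: Optional[Sequence[float]] = None
):
    """Targeting factor f_i from meshblock/area-unit Pacific and Asian densities.

    f = b1*sqrt(pac_mb) + b2*sqrt(pac_au) + b3*sqrt(asi_mb) + b4*sqrt(asi_au)
        + b_const.

    Square roots temper the targeting: probabilities rise where the target
    groups live, but sub-linearly, limiting the weight-variation penalty.
    Monotone nondecreasing in every density and strictly positive whenever
    b_const > 0.
    """
    if coefficients is None:
        coefficients = DesignConfig().targeting_coefficients
    b1, b2, b3, b4, b0 = coefficients
    dens = [np.asarray(d, dtype=float) for d in (pac_mb, pac_au, asi_mb, asi_au)]
    for d in dens:
        if np.any(d < 0) or np.any(d > 1):
            raise ValueError("densities must lie in [0, 1]")
    return (
        b1 * np.sqrt(dens[0])
        + b2 * np.sqrt(dens[1])
        + b3 * np.sqrt(dens[2])
        + b4 * np.sqrt(dens[3])
        + b0
    )


def mb_selection_probabilities(size_measure: Sequence[float], m_h: int) -> np.ndarray:
    """PPS inclusion probabilities for one stratum with certainty treatment.

    pi_i = m_h * s_i / sum(s), where s_i is the size measure (N*_i f_i for the
    area frame, roll address counts for the list frame).  Any pi_i >= 1 is
    pinned to exactly 1 and the remaining probabilities are rescaled so the
    sum stays m_h; repeated until no unit exceeds 1.
    """
    s = np.asarray(size_measure, dtype=float)
    if np.any(s < 0):
        raise ValueError("size measure must be nonnegative")
    if s.sum() <= 0:
        raise ValueError("all size measures are zero")
    n_pos = int((s > 0).sum())
    if m_h > n_pos:
        raise ValueError(f"m_h={m_h} exceeds the {n_pos} units with positive size")
    pi = np.zeros_like(s)
    certain = np.zeros(len(s), dtype=bool)
    remaining = m_h
    for _ in range(len(s) + 1):
        idx = (~certain) & (s > 0)
        if remaining <= 0 or not idx.any():
            break
        pi[idx] = remaining * s[idx] / s[idx].sum()
        over = idx & (pi >= 1.0)
        if not over.any():
            break
        pi[over] = 1.0
        certain |= over
        remaining = m_h - int(certain.sum())
    pi[certain] = 1.0
    return pi


def within_mb_sample_size(
    H_i: int, N_star_i: float, c: int, rng: Optional[np.random.Generator] = None
) -> int:
    """Number of dwellings to select in a meshblock.

    The expected take H_i * c / N*_i is realized by stochastic rounding
    (floor plus a Bernoulli on the fractional part) and capped at H_i, so the
    per-household selection probability given the meshblock is exactly
    min(c / N*_i, 1) regardless of how the meshblock has grown or shrunk
    since the census.
    """
    if N_star_i <= 0:
        raise ValueError("census size N*_i must be positive")
    if H_i <= 0:
        return 0
    expected = H_i * c / N_star_i
    base = int(np.floor(expected))
    frac = expected - base
    if frac > 0.0:
        u = np.random.random() if rng is None else rng.random()
        base += int(u < frac)
    return min(base, int(H_i))


@dataclass
class DesignPlan:
    """Resolved annual plan: per-stratum area and roll meshblock takes.

    The roll meshblock count r_h is calibrated against the frame using the
    exact PPS expectation of the roll household take,
    T(r) = sum_i pi^R_i(r) * min(roll_addresses_per_mb, R_i), and capped so
    that no roll meshblock becomes a certainty selection — a certainty roll
    meshblock would remove its non-roll households from the covered
    population, since the area frame excludes roll-selected meshblocks.
    """

    strata: pd.DataFrame  # stratum_id, persons, m_h (area MBs), r_h (roll MBs),
    # expected area/roll households
    config: DesignConfig

    @property
    def m_h(self) -> np.ndarray:
        return self.strata["m_h"].to_numpy()

    @property
    def r_h(self) -> np.ndarray:
        return self.strata["r_h"].to_numpy()

    @property
    def expected_roll_share(self) -> float:
        roll = self.strata["expected_roll_households"].sum()
        area = self.strata["expected_area_households"].sum()
        return float(roll / (roll + area)) if roll + area > 0 else 0.0


def _expected_roll_take(R: np.ndarray, r: int, per_mb: int) -> float:
    """Exact expected roll households for a take of r meshblocks."""
    if r <= 0:
        return 0.0
    pi = mb_selection_probabilities(R, r)
    return float(pi @ np.minimum(per_mb, R))


def design_plan(frame: pd.DataFrame, config: DesignConfig) -> DesignPlan:
    """Resolve a design config against a meshblock frame.

    ``frame`` needs columns stratum_id, census_persons, census_dwellings,
    current_dwellings and roll_addresses.  Area meshblock counts come from
    power allocation of the area household target (total * (1 - roll_share))
    at c households per meshblock; roll meshblock counts are searched so the
    exact expected roll household take best matches the stratum's roll
    household target, subject to the no-certainty cap.
    """
    config.validate()
    if "current_dwellings" not in frame.columns:
        frame = frame.assign(current_dwellings=frame["census_dwellings"])
    g = frame.groupby("stratum_id", sort=True)
    persons = g["census_persons"].sum()
    strata = pd.DataFrame(
        {"stratum_id": persons.index.to_numpy(), "persons": persons.to_numpy()}
    )
    hh_target = largest_remainder_round(
        strata["persons"].to_numpy() ** config.power_exponent,
        config.total_households_per_year,
        minimum=1,
    ).astype(float)

    c = config.within_mb_target
    area_target = (1.0 - config.roll_share) * hh_target
    n_mbs = g.size().to_numpy()
    m_h = np.minimum(
        np.maximum(1, np.round(area_target / c).astype(int)), n_mbs
    )

    r_h = np.zeros(len(strata), dtype=int)
    exp_roll_hh = np.zeros(len(strata))
    exp_area_hh = np.zeros(len(strata))
    per_mb = config.roll_addresses_per_mb
    for k, (_, sub) in enumerate(g):
        size = sub["census_dwellings"].to_numpy(dtype=float)
        H = sub["current_dwellings"].to_numpy(dtype=float)
        # expected household take per selected area meshblock (full frame,
        # pre-exclusion approximation)
        pi_a = mb_selection_probabilities(size, int(m_h[k]))
        exp_area_hh[k] = float(pi_a @ np.minimum(c * H / size, H))

        R = sub["roll_addresses"].to_numpy(dtype=float)
        if config.roll_share <= 0 or R.sum() <= 0:
            continue
        # no-certainty cap: r * max(R)/sum(R) must stay below 1
        r_cap = int((R > 0).sum())
        while r_cap > 0 and r_cap * R.max() / R.sum() >= 1.0 - 1e-12:
            r_cap -= 1
        # leave at least m_h meshblocks for the area frame
        r_cap = min(r_cap, int(len(R) - m_h[k]))
        if r_cap <= 0:
            continue
        want = config.roll_share / (1.0 - config.roll_share) * exp_area_hh[k]
        best_r, best_err, best_take = 0, abs(want), 0.0
        for r in range(1, r_cap + 1):
            take = _expected_roll_take(R, r, per_mb)
            if abs(take - want) < best_err:
                best_r, best_err, best_take = r, abs(take - want), take
        r_h[k] = best_r
        exp_roll_hh[k] = best_take

    strata["m_h"] = m_h
    strata["r_h"] = r_h
    strata["expected_area_households"] = exp_area_hh
    strata["expected_roll_households"] = exp_roll_hh
    return DesignPlan(strata=strata, config=config)
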