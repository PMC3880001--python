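"""Weighting and estimation.

Pooled inclusion probabilities combine the two selection paths:

    pi(person) = pi_roll(MB) * take/R * p(person)   [roll-flagged household]
               + E_S[ 1{MB not in S} * pi_area(MB | S) ] * min(c/N*, 1) * p(person)

where S is the (random) set of roll-selected meshblocks in the person's
stratum.  Because the area probabilities are renormalized on the reduced
frame, the expectation over S is taken explicitly: exactly, by enumerating
the randomized-order systematic PPS outcome distribution when the stratum is
small (or the roll take is 0 or 1 meshblock, where the outcome law is just
the marginal pi); otherwise by Monte-Carlo conditioning over simulated roll
outcomes.

Estimators: Hajek (ratio) weighted prevalences, delete-a-group jackknife
replicate weights and variances, design effects against the binomial SRS
benchmark, the one-way ANOVA intra-class correlation, and the RR3 response
rate with an estimated eligibility rate for unknown-eligibility cases.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._rng import substream
from .config import DesignConfig
from .design import DesignPlan, design_plan, mb_selection_probabilities
from .frames import FrameIndex
from .population import Population
from .sampler import SampleDraw, systematic_pps

__all__ = [
    "PooledProbabilities",
    "WeightedSample",
    "IndicatorEstimate",
    "Dispositions",
    "exact_systematic_set_distribution",
    "compute_inclusion_probabilities",
    "inclusion_probability",
    "build_weighted_sample",
    "estimate_prevalence",
    "jackknife_replicates",
    "jackknife_variance",
    "design_effect",
    "icc_anova",
    "response_rate_rr3",
    "indicator_table",
]


# ---------------------------------------------------------------------------
# Roll-outcome distribution and pooled probabilities
# ---------------------------------------------------------------------------


def exact_systematic_set_distribution(
    pi: np.ndarray,
) -> List[Tuple[Tuple[int, ...], float]]:
    """Exact sample-set distribution of randomized-order systematic PPS.

    Enumerates all orderings of the non-certainty units; for each ordering the
    selected set is piecewise constant in the random start u, so the interval
    lengths between breakpoints give exact probabilities.  Exponential in the
    number of units — intended for small strata.
    """
    pi = np.asarray(pi, dtype=float)
    m = int(round(pi.sum()))
    certain = np.flatnonzero(pi >= 1.0 - 1e-12)
    rest = np.flatnonzero((pi > 1e-15) & (pi < 1.0 - 1e-12))
    r = m - len(certain)
    if r == 0:
        return [(tuple(certain.tolist()), 1.0)]
    if r == 1:
        # exactly one non-certain unit selected: P({i}) = pi_i
        return [
            (tuple(sorted(certain.tolist() + [int(i)])), float(pi[i])) for i in rest
        ]
    dist: Dict[Tuple[int, ...], float] = {}
    n_perm = 0
    for perm in itertools.permutations(rest.tolist()):
        n_perm += 1
        c = np.cumsum(pi[list(perm)])
        c[-1] = r  # exact integer total
        breaks = np.unique(np.concatenate(([0.0, 1.0], np.mod(c, 1.0))))
        lo_c = np.concatenate(([0.0], c[:-1]))
        for a, b in zip(breaks[:-1], breaks[1:]):
            u = 0.5 * (a + b)
            sel = np.floor(c - u) > np.floor(lo_c - u)
            key = tuple(sorted(certain.tolist() + [perm[j] for j in np.flatnonzero(sel)]))
            dist[key] = dist.get(key, 0.0) + (b - a)
    return [(k, v / n_perm) for k, v in dist.items()]


@dataclass
class PooledProbabilities:
    """Per-meshblock path probabilities and per-person pooled probabilities,
    aligned to the FrameIndex sorted person order."""

    mb_roll_pi: np.ndarray  # marginal roll-selection probability per MB
    mb_area_pi_pooled: np.ndarray  # E_S[1{mb not in S} pi_area(mb|S)]
    hh_pi: np.ndarray  # pooled household probability (frame order)
    person_pi: np.ndarray  # pooled person probability (sorted person order)
    person_pi_roll: np.ndarray
    person_pi_area: np.ndarray
    method: str = "exact"


def _roll_outcome_distribution(
    frame: FrameIndex,
    plan: DesignPlan,
    s: int,
    exact_max: int,
    n_mc: int,
    rng: np.random.Generator,
) -> Tuple[List[Tuple[Tuple[int, ...], float]], bool]:
    """Distribution of the roll meshblock set in stratum ``s`` (local frame
    positions translated to global MB positions).  Second element flags
    Monte-Carlo conditioning."""
    mbs = frame.mb_by_stratum[s]
    r = int(plan.r_h[s])
    counts = frame.roll_count[mbs]
    if r <= 0 or counts.sum() == 0:
        return [((), 1.0)], False
    pi = mb_selection_probabilities(counts, r)
    eligible = np.flatnonzero(pi > 0)
    if r <= 1 or len(eligible) <= exact_max:
        dist = exact_systematic_set_distribution(pi)
        return [(tuple(int(mbs[j]) for j in key), p) for key, p in dist], False
    # Monte-Carlo conditioning
    tally: Dict[Tuple[int, ...], int] = {}
    for _ in range(n_mc):
        key = tuple(sorted(int(mbs[j]) for j in systematic_pps(pi, rng)))
        tally[key] = tally.get(key, 0) + 1
    return [(k, v / n_mc) for k, v in tally.items()], True


def compute_inclusion_probabilities(
    frame: FrameIndex,
    config: DesignConfig,
    plan: Optional[DesignPlan] = None,
    exact_max: int = 8,
    n_mc: int = 2000,
    seed: Optional[int] = None,
) -> PooledProbabilities:
    """Pooled dual-frame inclusion probabilities for every person on the frame."""
    if plan is None:
        frame_table = pd.DataFrame(
            dict(
                stratum_id=frame.stratum_ids[frame.stratum_code],
                census_persons=frame.census_persons,
                census_dwellings=frame.N_star,
                current_dwellings=frame.H_cur,
                roll_addresses=frame.roll_count,
            )
        )
        plan = design_plan(frame_table, config)
    rng = substream(config.seed if seed is None else seed, "inclusion")

    n_mb = frame.n_mb
    mb_roll_pi = np.zeros(n_mb)
    mb_area_pooled = np.zeros(n_mb)
    method = "exact"
    area_size = frame.N_star * frame.f

    for s in range(frame.n_strata):
        mbs = frame.mb_by_stratum[s]
        r = int(plan.r_h[s])
        if r > 0 and frame.roll_count[mbs].sum() > 0:
            mb_roll_pi[mbs] = mb_selection_probabilities(frame.roll_count[mbs], r)
        outcomes, used_mc = _roll_outcome_distribution(frame, plan, s, exact_max, n_mc, rng)
        if used_mc:
            method = "monte-carlo"
        cache: Dict[Tuple[int, ...], np.ndarray] = {}
        m = int(plan.m_h[s])
        for key, p_out in outcomes:
            if key not in cache:
                keep = mbs[~np.isin(mbs, np.array(key, dtype=int))] if key else mbs
                pi_a = np.zeros(n_mb)
                pi_a[keep] = mb_selection_probabilities(area_size[keep], m)
                cache[key] = pi_a[mbs]
            mb_area_pooled[mbs] += p_out * cache[key]

    # household-level path probabilities
    c = config.within_mb_target
    hh_area = mb_area_pooled[frame.hh_mb] * np.minimum(
        c / frame.N_star[frame.hh_mb], 1.0
    )
    take = np.minimum(config.roll_addresses_per_mb, frame.hh_roll_count)
    with np.errstate(divide="ignore", invalid="ignore"):
        roll_frac = np.where(
            frame.hh_roll_count > 0, take / np.maximum(frame.hh_roll_count, 1), 0.0
        )
    hh_roll = np.where(
        frame.hh_on_roll, mb_roll_pi[frame.hh_mb] * roll_frac[frame.hh_mb], 0.0
    )
    hh_pi = hh_area + hh_roll

    # person level: adults 1/n_adults, children 1/n_children
    hh_of_p = frame.person_hh
    n_a = frame.hh_n_adults[hh_of_p]
    n_c = frame.hh_n_children[hh_of_p]
    with np.errstate(divide="ignore"):
        p_person = np.where(
            frame.person_is_adult,
            1.0 / np.maximum(n_a, 1),
            1.0 / np.maximum(n_c, 1),
        )
    resp = config.response_prob
    person_roll = hh_roll[hh_of_p] * p_person * resp
    person_area = hh_area[hh_of_p] * p_person * resp
    return PooledProbabilities(
        mb_roll_pi=mb_roll_pi,
        mb_area_pi_pooled=mb_area_pooled,
        hh_pi=hh_pi,
        person_pi=person_roll + person_area,
        person_pi_roll=person_roll,
        person_pi_area=person_area,
        method=method,
    )


def inclusion_probability(
    probs: PooledProbabilities, person_sorted_pos: np.ndarray
) -> np.ndarray:
    """Pooled selection probability for given persons (sorted positions)."""
    pi = probs.person_pi[np.asarray(person_sorted_pos, dtype=int)]
    if np.any(pi <= 0):
        raise ValueError("zero pooled inclusion probability encountered")
    return pi


# ---------------------------------------------------------------------------
# Weighted samples and estimators
# ---------------------------------------------------------------------------


@dataclass
class WeightedSample:
    """Respondents with base weights and optional replicate weights."""

    data: pd.DataFrame  # one row per respondent
    replicate_weights: Optional[np.ndarray] = None  # (n, G)
    strata_of_replicates: Optional[np.ndarray] = None

    @property
    def n(self) -> int:
        return len(self.data)

    def subset(self, mask: np.ndarray) -> "WeightedSample":
        rw = self.replicate_weights[mask] if self.replicate_weights is not None else None
        return WeightedSample(self.data.loc[mask].reset_index(drop=True), rw)


@dataclass
class IndicatorEstimate:
    prevalence: float
    se: float
    design_effect: float
    icc: float
    subpopulation: str
    n: int


def build_weighted_sample(
    draw: SampleDraw,
    frame: FrameIndex,
    probs: PooledProbabilities,
    population: Population,
    adults_only: bool = False,
) -> WeightedSample:
    """Assemble the respondent file: ids, flags, outcomes, design weights
    (inverse pooled inclusion probabilities)."""
    resp = draw.responded
    parts = []
    for role, pos in (("adult", draw.adult_pos), ("child", draw.child_pos)):
        if adults_only and role == "child":
            continue
        ok = (pos >= 0) & resp
        spos = pos[ok]
        pi = inclusion_probability(probs, spos)
        rows = frame.person_row[spos]
        pdf = population.persons.iloc[rows].reset_index(drop=True)
        part = pd.DataFrame(
            dict(
                person_sorted_pos=spos,
                person_id=pdf["person_id"].to_numpy(),
                stratum=draw.stratum[ok],
                mb_id=frame.mb_id[draw.mb_idx[ok]],
                frame_of_selection=draw.frame_of_selection[ok],
                quarter=draw.quarter[ok],
                role=role,
                is_adult=pdf["is_adult"].to_numpy(),
                weight=1.0 / pi,
                n_adults_hh=frame.hh_n_adults[draw.hh_idx[ok]],
                n_children_hh=frame.hh_n_children[draw.hh_idx[ok]],
                pi_pooled=pi,
            )
        )
        for colname in ("maori", "pacific", "asian"):
            part[colname] = pdf[colname].to_numpy()
        for out in population.outcome_names:
            part[out] = pdf[out].to_numpy().astype(float)
        parts.append(part)
    data = pd.concat(parts, ignore_index=True)
    data["all"] = True
    return WeightedSample(data=data)


def _subpop_mask(data: pd.DataFrame, subpop: Optional[str]) -> np.ndarray:
    if subpop in (None, "all"):
        return np.ones(len(data), dtype=bool)
    return data[subpop].to_numpy().astype(bool)


def hajek_mean(weights: np.ndarray, y: np.ndarray) -> float:
    """Ratio (Hajek) estimator: weighted mean with estimated denominator."""
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise ValueError("empty or zero-weight sample")
    return float(np.dot(w, y) / w.sum())


def estimate_prevalence(
    ws: WeightedSample,
    outcome: str,
    subpop: Optional[str] = None,
    adults_only: bool = True,
) -> IndicatorEstimate:
    """Hajek prevalence for a subpopulation, with jackknife SE/deff when
    replicate weights are attached and the ANOVA ICC of the sample."""
    data = ws.data
    mask = _subpop_mask(data, subpop)
    if adults_only:
        mask &= data["is_adult"].to_numpy().astype(bool)
    if not mask.any():
        raise ValueError(f"empty subpopulation {subpop!r}")
    y = data.loc[mask, outcome].to_numpy(dtype=float)
    w = data.loc[mask, "weight"].to_numpy(dtype=float)
    p = hajek_mean(w, y)
    se = float("nan")
    deff = float("nan")
    if ws.replicate_weights is not None:
        var = jackknife_variance(ws, outcome, subpop=subpop, adults_only=adults_only)
        se = float(np.sqrt(var))
        if 0.0 < p < 1.0:
            deff = design_effect(p, var, int(mask.sum()))
    mbs = data.loc[mask, "mb_id"].to_numpy()
    icc = icc_anova(y, mbs) if len(np.unique(mbs)) >= 2 else float("nan")
    return IndicatorEstimate(
        prevalence=p,
        se=se,
        design_effect=deff,
        icc=icc,
        subpopulation=subpop or "all",
        n=int(mask.sum()),
    )


def jackknife_replicates(
    ws: WeightedSample, G: int = 100, seed: int = 0
) -> WeightedSample:
    """Attach delete-a-group jackknife replicate weights.

    PSUs (meshblocks) are randomly assigned to G groups within strata;
    replicate g zeroes group-g PSUs and rescales the remaining weights within
    each stratum to the full-sample stratum weight total, so every replicate
    column reproduces the (variance-)stratum totals exactly.  Design strata
    holding a single sampled PSU cannot be rescaled, so consecutive strata
    are collapsed until every variance stratum holds at least two PSUs — the
    standard collapsed-stratum device.
    """
    data = ws.data
    psu_key = data["stratum"].to_numpy() * 10**9 + pd.factorize(data["mb_id"])[0]
    psus, psu_of_row = np.unique(psu_key, return_inverse=True)
    if G > len(psus):
        raise ValueError(f"G={G} exceeds the {len(psus)} PSUs in the sample")
    if len(psus) < 2:
        raise ValueError("need at least 2 PSUs for jackknife variance")
    rng = substream(seed, "jackknife")
    strat_of_psu = (psus // 10**9).astype(int)

    # collapse design strata until each variance stratum has >= 2 PSUs
    design_strata = np.unique(strat_of_psu)
    counts = {s: int((strat_of_psu == s).sum()) for s in design_strata}
    vstrat_of_stratum: Dict[int, int] = {}
    v, acc = 0, 0
    for s in design_strata:
        vstrat_of_stratum[s] = v
        acc += counts[s]
        if acc >= 2:
            v, acc = v + 1, 0
    if acc > 0:  # tail stratum too small: merge into the previous group
        last = max(0, v - 1)
        for s in design_strata:
            if vstrat_of_stratum[s] == v:
                vstrat_of_stratum[s] = last
    vstrat_of_psu = np.array([vstrat_of_stratum[s] for s in strat_of_psu])

    group_of_psu = np.empty(len(psus), dtype=int)
    for s in np.unique(vstrat_of_psu):
        idx = np.flatnonzero(vstrat_of_psu == s)
        # balanced random grouping within the variance stratum
        group_of_psu[idx] = rng.permutation(np.arange(len(idx)) % G)
    group_of_row = group_of_psu[psu_of_row]
    strat_of_row = vstrat_of_psu[psu_of_row]
    w = data["weight"].to_numpy(dtype=float)

    strata = np.unique(strat_of_row)
    strat_idx = np.searchsorted(strata, strat_of_row)
    totals = np.bincount(strat_idx, weights=w, minlength=len(strata))
    rw = np.repeat(w[:, None], G, axis=1)
    for g in range(G):
        dropped = group_of_row == g
        kept_tot = np.bincount(
            strat_idx, weights=w * (~dropped), minlength=len(strata)
        )
        scale = np.where(kept_tot > 0, totals / np.maximum(kept_tot, 1e-300), 1.0)
        col = w * scale[strat_idx]
        col[dropped] = 0.0
        rw[:, g] = col
    return WeightedSample(
        data=data, replicate_weights=rw, strata_of_replicates=strat_of_row
    )


def jackknife_variance(
    ws: WeightedSample,
    outcome: str,
    subpop: Optional[str] = None,
    adults_only: bool = True,
    statistic: Optional[Callable[[np.ndarray, pd.DataFrame], float]] = None,
) -> float:
    """Delete-a-group jackknife variance: (G-1)/G * sum_g (theta_g - theta)^2."""
    if ws.replicate_weights is None:
        raise ValueError("attach replicate weights first")
    data = ws.data
    mask = _subpop_mask(data, subpop)
    if adults_only:
        mask &= data["is_adult"].to_numpy().astype(bool)
    sub = data.loc[mask]
    rw = ws.replicate_weights[mask]
    if statistic is None:
        y = sub[outcome].to_numpy(dtype=float)
        theta = hajek_mean(sub["weight"].to_numpy(dtype=float), y)
        tot = rw.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            thetas = (y @ rw) / tot
        thetas = np.where(tot > 0, thetas, theta)
    else:
        theta = statistic(sub["weight"].to_numpy(dtype=float), sub)
        thetas = np.array([statistic(rw[:, g], sub) for g in range(rw.shape[1])])
    G = rw.shape[1]
    return float((G - 1) / G * np.sum((thetas - theta) ** 2))


def design_effect(p: float, variance: float, n_sub: int) -> float:
    """Variance under the complex design over the binomial SRS benchmark
    p(1-p)/n at the same subpopulation sample size."""
    if not 0.0 < p < 1.0:
        raise ValueError("prevalence must be strictly inside (0,1)")
    return float(variance / (p * (1.0 - p) / n_sub))


def icc_anova(values: np.ndarray, groups: np.ndarray) -> float:
    """One-way ANOVA intra-class correlation with the unequal-group-size
    adjustment k0; clipped at 0."""
    y = np.asarray(values, dtype=float)
    codes, counts = np.unique(groups, return_counts=True)
    idx = np.searchsorted(codes, groups)
    N, I = len(y), len(codes)
    if I < 2 or N - I < 1:
        raise ValueError("need at least 2 groups and one within-group df")
    sums = np.bincount(idx, weights=y, minlength=I)
    means = sums / counts
    grand = y.mean()
    ssb = float(np.sum(counts * (means - grand) ** 2))
    ssw = float(np.sum((y - means[idx]) ** 2))
    msb = ssb / (I - 1)
    msw = ssw / (N - I)
    k0 = (N - np.sum(counts**2) / N) / (I - 1)
    denom = msb + (k0 - 1.0) * msw
    if denom <= 0:
        return 0.0
    return float(np.clip((msb - msw) / denom, 0.0, 1.0))


@dataclass
class Dispositions:
    """Final case dispositions for a response-rate calculation."""

    interviews: int
    refusals: int = 0
    other_eligible_noninterview: int = 0
    ineligible: int = 0
    unknown_eligibility: int = 0


def response_rate_rr3(d: Dispositions, e: Optional[float] = None) -> float:
    """RR3 response rate: interviews over eligible cases plus an estimated
    eligible share e of unknown-eligibility cases.

    By default e is the eligibility rate among resolved cases,
    eligible / (eligible + ineligible).
    """
    eligible = d.interviews + d.refusals + d.other_eligible_noninterview
    if e is None:
        resolved = eligible + d.ineligible
        e = eligible / resolved if resolved > 0 else 1.0
    if not 0.0 <= e <= 1.0:
        raise ValueError("eligibility rate e must be in [0,1]")
    denom = eligible + e * d.unknown_eligibility
    if denom <= 0:
        raise ValueError("empty denominator")
    return d.interviews / denom


def indicator_table(
    ws: WeightedSample,
    outcomes: Sequence[str],
    subpops: Sequence[str] = ("all", "maori", "pacific"),
) -> pd.DataFrame:
    """Key-indicator table: prevalence %, SE %, ICC and design effect by
    subpopulation (adults 15+)."""
    rows = []
    for out in outcomes:
        row: Dict[str, object] = {"indicator": out}
        for sp in subpops:
            try:
                est = estimate_prevalence(ws, out, subpop=sp)
            except ValueError:
                row.update(
                    {
                        f"{sp}_prevalence_pct": np.nan,
                        f"{sp}_se_pct": np.nan,
                        f"{sp}_icc": np.nan,
                        f"{sp}_deff": np.nan,
                    }
                )
                continue
            row[f"{sp}_prevalence_pct"] = 100 * est.prevalence
            row[f"{sp}_se_pct"] = 100 * est.se
            row[f"{sp}_icc"] = est.icc
            row[f"{sp}_deff"] = est.design_effect
        rows.append(row)
    return pd.DataFrame(rows)
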