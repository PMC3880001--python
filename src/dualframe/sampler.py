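"""Stochastic execution of the dual-frame annual draw.

Stage order: the list (electoral-roll) meshblock sample is drawn first by
randomized-order systematic PPS on roll address counts; the roll meshblocks
are then excluded from the area frame and the area meshblock sample is drawn
by systematic PPS on the renormalized Eq-1 probabilities, keeping the two
meshblock sets disjoint.  Households follow (10 roll addresses per roll
meshblock or all if fewer; an equal-probability sample of c/N* of the
households of each area meshblock), then one random adult and one random
child per household, then random allocation of meshblocks to quarters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from ._rng import substream
from .config import DesignConfig
from .design import DesignPlan, design_plan, mb_selection_probabilities, within_mb_sample_size
from .frames import FrameIndex

__all__ = [
    "SampleDraw",
    "systematic_pps",
    "select_roll_sample",
    "select_area_sample",
    "select_persons",
    "assign_quarters",
    "run_annual_sample",
]

AREA, ROLL = 0, 1


def systematic_pps(pi: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Randomized-order systematic PPS draw.

    ``pi`` are inclusion probabilities in (0, 1] summing to an integer m.
    Units are placed in random order on a line of cumulative lengths pi; the
    points u, u+1, ..., u+m-1 (u uniform) pick the sample.  Marginal
    inclusion probabilities equal pi exactly.
    """
    pi = np.asarray(pi, dtype=float)
    m = int(round(pi.sum()))
    if m == 0:
        return np.empty(0, dtype=int)
    perm = rng.permutation(len(pi))
    c = np.cumsum(pi[perm])
    c *= m / c[-1]  # guard float drift on the integer total
    u = rng.random()
    lo = np.floor(np.concatenate(([0.0], c[:-1])) - u)
    hi = np.floor(c - u)
    return perm[hi > lo]


@dataclass
class SampleDraw:
    """One annual draw: one row per selected household with stage metadata."""

    hh_idx: np.ndarray  # positions in FrameIndex household order
    mb_idx: np.ndarray  # meshblock position per selected household
    stratum: np.ndarray
    frame_of_selection: np.ndarray  # AREA (0) or ROLL (1)
    quarter: np.ndarray
    mb_pi: np.ndarray  # conditional stage probability used in the draw
    hh_prob: np.ndarray
    adult_pos: np.ndarray  # sorted-person position, -1 if no adult
    adult_prob: np.ndarray
    child_pos: np.ndarray  # -1 if no child
    child_prob: np.ndarray
    responded: np.ndarray
    roll_mbs: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    area_mbs: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    log: List[str] = field(default_factory=list)

    @property
    def n_households(self) -> int:
        return len(self.hh_idx)

    def persons_dataframe(self, frame: FrameIndex) -> pd.DataFrame:
        """Long view: one row per selected person with stage probabilities."""
        rows = []
        for role, pos, prob in (
            ("adult", self.adult_pos, self.adult_prob),
            ("child", self.child_pos, self.child_prob),
        ):
            ok = pos >= 0
            rows.append(
                pd.DataFrame(
                    dict(
                        person_sorted_pos=pos[ok],
                        person_row=frame.person_row[pos[ok]],
                        household_id=frame.hh_id[self.hh_idx[ok]],
                        mb_id=frame.mb_id[self.mb_idx[ok]],
                        stratum_id=frame.stratum_ids[self.stratum[ok]],
                        role=role,
                        frame_of_selection=np.where(
                            self.frame_of_selection[ok] == ROLL, "roll", "area"
                        ),
                        quarter=self.quarter[ok],
                        mb_pi=self.mb_pi[ok],
                        hh_prob=self.hh_prob[ok],
                        person_prob=prob[ok],
                        responded=self.responded[ok],
                    )
                )
            )
        return pd.concat(rows, ignore_index=True)


def select_roll_sample(
    frame: FrameIndex, plan: DesignPlan, rng: np.random.Generator
) -> Dict[str, np.ndarray]:
    """Roll meshblocks (PPS on roll address counts) and their addresses
    (simple random sample of min(per_mb, available) on-roll households)."""
    per_mb = plan.config.roll_addresses_per_mb
    mb_sel, mb_pi_sel, hh_sel, hh_mb, hh_prob, log = [], [], [], [], [], []
    for s, r in enumerate(plan.r_h):
        mbs = frame.mb_by_stratum[s]
        counts = frame.roll_count[mbs]
        if r <= 0 or counts.sum() == 0:
            if r > 0:
                log.append(f"stratum {frame.stratum_ids[s]}: no roll addresses")
            continue
        pi = mb_selection_probabilities(counts, int(r))
        chosen = mbs[systematic_pps(pi, rng)]
        pi_by_mb = dict(zip(mbs, pi))
        for mb in chosen:
            avail = frame.hh_roll_count[mb]
            take = min(per_mb, avail)
            if take == 0:
                continue
            start = frame.hh_start[mb]
            picked = start + rng.choice(avail, size=take, replace=False)
            hh_sel.append(picked)
            hh_mb.append(np.full(take, mb))
            hh_prob.append(np.full(take, take / avail))
            mb_sel.append(mb)
            mb_pi_sel.append(pi_by_mb[mb])
    empty = np.empty(0)
    return dict(
        mbs=np.array(mb_sel, dtype=int),
        mb_pi=np.array(mb_pi_sel, dtype=float),
        hh=np.concatenate(hh_sel) if hh_sel else empty.astype(int),
        hh_mb=np.concatenate(hh_mb) if hh_mb else empty.astype(int),
        hh_prob=np.concatenate(hh_prob) if hh_prob else empty,
        log=log,
    )


def select_area_sample(
    frame: FrameIndex,
    plan: DesignPlan,
    excluded_mbs: np.ndarray,
    rng: np.random.Generator,
) -> Dict[str, np.ndarray]:
    """Area meshblocks by systematic PPS on N* f over the non-excluded frame,
    then an equal-probability household sample of expected size H c / N*."""
    c = plan.config.within_mb_target
    excl = set(excluded_mbs.tolist())
    size = frame.N_star * frame.f
    mb_sel, mb_pi_sel, hh_sel, hh_mb, hh_prob, log = [], [], [], [], [], []
    for s, m in enumerate(plan.m_h):
        mbs = frame.mb_by_stratum[s]
        if excl:
            mbs = mbs[~np.isin(mbs, excluded_mbs)]
        if m > len(mbs):
            raise ValueError(
                f"stratum {frame.stratum_ids[s]}: m_h={m} exceeds the "
                f"{len(mbs)} meshblocks left after roll exclusion"
            )
        pi = mb_selection_probabilities(size[mbs], int(m))
        chosen = mbs[systematic_pps(pi, rng)]
        pi_by_mb = dict(zip(mbs, pi))
        for mb in chosen:
            avail = frame.hh_count[mb]
            take = within_mb_sample_size(frame.H_cur[mb], frame.N_star[mb], c, rng)
            if take > avail:
                log.append(
                    f"mb {frame.mb_id[mb]}: take {take} capped at {avail} households"
                )
                take = avail
            mb_sel.append(mb)
            mb_pi_sel.append(pi_by_mb[mb])
            if take == 0:
                continue
            picked = frame.hh_start[mb] + rng.choice(avail, size=take, replace=False)
            hh_sel.append(picked)
            hh_mb.append(np.full(take, mb))
            hh_prob.append(np.full(take, min(c / frame.N_star[mb], 1.0)))
    empty = np.empty(0)
    return dict(
        mbs=np.array(mb_sel, dtype=int),
        mb_pi=np.array(mb_pi_sel, dtype=float),
        hh=np.concatenate(hh_sel) if hh_sel else empty.astype(int),
        hh_mb=np.concatenate(hh_mb) if hh_mb else empty.astype(int),
        hh_prob=np.concatenate(hh_prob) if hh_prob else empty,
        log=log,
    )


def select_persons(frame: FrameIndex, hh_idx: np.ndarray, rng: np.random.Generator):
    """One adult uniformly at random per household (if any) and one child
    uniformly at random (if any).  Ethnicity plays no role, so selection
    probabilities stay computable for every respondent."""
    n_a = frame.hh_n_adults[hh_idx]
    n_c = frame.hh_n_children[hh_idx]
    start = frame.p_start[hh_idx]
    adult_pos = np.where(
        n_a > 0, start + (rng.random(len(hh_idx)) * np.maximum(n_a, 1)).astype(int), -1
    )
    child_pos = np.where(
        n_c > 0,
        start + n_a + (rng.random(len(hh_idx)) * np.maximum(n_c, 1)).astype(int),
        -1,
    )
    with np.errstate(divide="ignore"):
        adult_prob = np.where(n_a > 0, 1.0 / np.maximum(n_a, 1), 0.0)
        child_prob = np.where(n_c > 0, 1.0 / np.maximum(n_c, 1), 0.0)
    return adult_pos, adult_prob, child_pos, child_prob


def assign_quarters(
    mb_list: np.ndarray, stratum_of_mb: np.ndarray, Q: int, rng: np.random.Generator
) -> Dict[int, int]:
    """Randomize meshblocks (both frames pooled) to quarters within strata,
    balanced up to remainder, so each quarter is itself a probability sample."""
    if Q < 1:
        raise ValueError("Q must be >= 1")
    quarter: Dict[int, int] = {}
    for s in np.unique(stratum_of_mb):
        mbs = mb_list[stratum_of_mb == s]
        perm = rng.permutation(len(mbs))
        for k, j in enumerate(perm):
            quarter[int(mbs[j])] = k % Q + 1
    return quarter


def run_annual_sample(
    frame: FrameIndex,
    config: DesignConfig,
    plan: Optional[DesignPlan] = None,
    rng: Optional[np.random.Generator] = None,
    frame_table: Optional[pd.DataFrame] = None,
) -> SampleDraw:
    """Orchestrate one annual draw: roll -> area -> households -> persons ->
    quarters -> household response filter."""
    if plan is None:
        if frame_table is None:
            frame_table = pd.DataFrame(
                dict(
                    stratum_id=frame.stratum_ids[frame.stratum_code],
                    census_persons=frame.census_persons,
                    census_dwellings=frame.N_star,
                    roll_addresses=frame.roll_count,
                )
            )
        plan = design_plan(frame_table, config)
    rng = substream(config.seed, "draw") if rng is None else rng

    roll = (
        select_roll_sample(frame, plan, rng)
        if config.roll_share > 0
        else dict(
            mbs=np.empty(0, dtype=int),
            mb_pi=np.empty(0),
            hh=np.empty(0, dtype=int),
            hh_mb=np.empty(0, dtype=int),
            hh_prob=np.empty(0),
            log=[],
        )
    )
    area = select_area_sample(frame, plan, roll["mbs"], rng)

    hh_idx = np.concatenate([roll["hh"].astype(int), area["hh"].astype(int)])
    hh_mb = np.concatenate([roll["hh_mb"].astype(int), area["hh_mb"].astype(int)])
    frame_flag = np.concatenate(
        [np.full(len(roll["hh"]), ROLL), np.full(len(area["hh"]), AREA)]
    )
    hh_prob = np.concatenate([roll["hh_prob"], area["hh_prob"]])

    mb_pi_lookup = dict(zip(roll["mbs"].tolist(), roll["mb_pi"].tolist()))
    mb_pi_lookup.update(zip(area["mbs"].tolist(), area["mb_pi"].tolist()))
    mb_pi = np.array([mb_pi_lookup[m] for m in hh_mb.tolist()])

    adult_pos, adult_prob, child_pos, child_prob = select_persons(frame, hh_idx, rng)

    all_mbs = np.concatenate([roll["mbs"], area["mbs"]]).astype(int)
    quarters = assign_quarters(
        all_mbs, frame.stratum_code[all_mbs], config.quarters, rng
    )
    quarter = np.array([quarters.get(int(m), 1) for m in hh_mb])

    responded = (
        rng.random(len(hh_idx)) < config.response_prob
        if config.response_prob < 1.0
        else np.ones(len(hh_idx), dtype=bool)
    )

    return SampleDraw(
        hh_idx=hh_idx,
        mb_idx=hh_mb,
        stratum=frame.stratum_code[hh_mb],
        frame_of_selection=frame_flag,
        quarter=quarter,
        mb_pi=mb_pi,
        hh_prob=hh_prob,
        adult_pos=adult_pos,
        adult_prob=adult_prob,
        child_pos=child_pos,
        child_prob=child_prob,
        responded=responded,
        roll_mbs=roll["mbs"],
        area_mbs=area["mbs"],
        log=list(roll["log"]) + list(area["log"]),
    )
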