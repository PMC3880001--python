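"""Compiled sampling-frame view.

The sampler is exercised tens of thousands of times in probability-
correctness checks, so the population tables are compiled once into flat
numpy arrays with CSR-style offsets (stratum -> meshblock -> household ->
person).  Households within a meshblock are sorted roll-flagged-first so the
roll sub-frame of a meshblock is a contiguous slice; persons within a
household are sorted adults-first so uniform adult/child selection is a
single integer draw.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import pandas as pd

from .config import DesignConfig
from .design import targeting_factor
from .population import Population

__all__ = ["FrameIndex", "build_frame_index"]


@dataclass
class FrameIndex:
    # --- meshblock level (index: 0..n_mb-1, frame order) ---
    mb_id: np.ndarray
    stratum_code: np.ndarray  # 0..n_strata-1
    stratum_ids: np.ndarray  # code -> original stratum_id
    N_star: np.ndarray  # PPS size measure (census dwellings)
    census_persons: np.ndarray
    H_cur: np.ndarray  # current dwellings per frame
    f: np.ndarray  # targeting factor
    roll_count: np.ndarray  # roll addresses per MB (frame value)
    mb_by_stratum: List[np.ndarray]
    # --- household level (sorted: mb, roll-first) ---
    hh_id: np.ndarray
    hh_mb: np.ndarray
    hh_start: np.ndarray  # per MB
    hh_count: np.ndarray  # per MB (actual households present)
    hh_roll_count: np.ndarray  # per MB, count of on-roll households
    hh_n_adults: np.ndarray
    hh_n_children: np.ndarray
    hh_on_roll: np.ndarray
    # --- person level (sorted: household, adults first) ---
    person_row: np.ndarray  # sorted position -> row in population.persons
    p_start: np.ndarray  # per household
    person_hh: np.ndarray
    person_is_adult: np.ndarray

    @property
    def n_mb(self) -> int:
        return len(self.mb_id)

    @property
    def n_strata(self) -> int:
        return len(self.stratum_ids)

    @property
    def n_households(self) -> int:
        return len(self.hh_id)

    @property
    def n_persons(self) -> int:
        return len(self.person_row)

    def adult_slice(self, hh: int) -> slice:
        s = self.p_start[hh]
        return slice(s, s + self.hh_n_adults[hh])

    def hh_prob_area(self, c: int) -> np.ndarray:
        """Household selection probability given area selection of its MB."""
        return np.minimum(c / self.N_star, 1.0)

    def hh_prob_roll(self, per_mb: int) -> np.ndarray:
        """Roll-address selection probability given roll selection of the MB."""
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.minimum(per_mb / self.roll_count, 1.0)
        return np.where(self.roll_count > 0, p, 0.0)


def build_frame_index(
    population: Population,
    design: Optional[DesignConfig] = None,
    frame: Optional[pd.DataFrame] = None,
) -> FrameIndex:
    """Compile a population (and optionally a drifted census snapshot) into a
    :class:`FrameIndex` under a design's targeting coefficients."""
    design = design or DesignConfig()
    mbs = (frame if frame is not None else population.meshblocks).reset_index(drop=True)
    coeffs = design.targeting_coefficients
    f = np.asarray(
        targeting_factor(
            mbs["pacific_mb"], mbs["pacific_au"], mbs["asian_mb"], mbs["asian_au"], coeffs
        ),
        dtype=float,
    )

    stratum_ids, stratum_code = np.unique(mbs["stratum_id"].to_numpy(), return_inverse=True)
    mb_by_stratum = [np.flatnonzero(stratum_code == s) for s in range(len(stratum_ids))]

    mb_pos = pd.Series(np.arange(len(mbs)), index=mbs["mb_id"].to_numpy())

    hh = population.households
    hh_mb_pos = mb_pos.loc[hh["mb_id"].to_numpy()].to_numpy()
    order = np.lexsort((hh["household_id"].to_numpy(), ~hh["on_roll"].to_numpy(), hh_mb_pos))
    hh_mb = hh_mb_pos[order]
    hh_id = hh["household_id"].to_numpy()[order]
    hh_on_roll = hh["on_roll"].to_numpy()[order]
    hh_n_adults = hh["n_adults"].to_numpy()[order]
    hh_n_children = hh["n_children"].to_numpy()[order]
    hh_size = hh["size"].to_numpy()[order]

    n_mb = len(mbs)
    hh_count = np.bincount(hh_mb, minlength=n_mb)
    hh_start = np.concatenate(([0], np.cumsum(hh_count)[:-1]))
    hh_roll_count = np.bincount(hh_mb, weights=hh_on_roll, minlength=n_mb).astype(int)

    # persons sorted by (household sorted position, adults first)
    persons = population.persons
    hh_sorted_pos = pd.Series(np.arange(len(hh_id)), index=hh_id)
    p_hh = hh_sorted_pos.loc[persons["household_id"].to_numpy()].to_numpy()
    is_adult = persons["is_adult"].to_numpy()
    p_order = np.lexsort((persons["person_id"].to_numpy(), ~is_adult, p_hh))
    person_hh = p_hh[p_order]
    person_is_adult = is_adult[p_order]
    p_start = np.concatenate(([0], np.cumsum(hh_size)[:-1]))

    return FrameIndex(
        mb_id=mbs["mb_id"].to_numpy(),
        stratum_code=stratum_code,
        stratum_ids=stratum_ids,
        N_star=mbs["census_dwellings"].to_numpy(dtype=float),
        census_persons=mbs["census_persons"].to_numpy(dtype=float),
        H_cur=mbs["current_dwellings"].to_numpy(dtype=int),
        f=f,
        roll_count=mbs["roll_addresses"].to_numpy(dtype=int),
        mb_by_stratum=mb_by_stratum,
        hh_id=hh_id,
        hh_mb=hh_mb,
        hh_start=hh_start,
        hh_count=hh_count,
        hh_roll_count=hh_roll_count,
        hh_n_adults=hh_n_adults,
        hh_n_children=hh_n_children,
        hh_on_roll=hh_on_roll,
        person_row=p_order,
        p_start=p_start,
        person_hh=person_hh,
        person_is_adult=person_is_adult,
    )
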