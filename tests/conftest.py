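"""Shared fixtures.

``micro_pop`` is a hand-crafted two-stratum population (24 households, 6
meshblocks) small enough that dual-frame inclusion probabilities are
computable by exact enumeration — the oracle for the probability-correctness
checks.  ``nz_pop`` is the NZ-like synthetic population (~50k persons)
shared by the statistical acceptance checks; generating it once per session
keeps the suite fast.
"""

from __future__ import annotations

import pandas as pd
import pytest

import dualframe as df
from dualframe.config import PopulationConfig
from dualframe.design import design_plan
from dualframe.population import Population

# --- micro population ------------------------------------------------------

# per meshblock: (pac_mb, pac_au, asi_mb, asi_au), and 4 households each
_MICRO_DENS = [
    (0.20, 0.15, 0.10, 0.10),
    (0.00, 0.05, 0.30, 0.20),
    (0.50, 0.40, 0.00, 0.05),
    (0.10, 0.10, 0.10, 0.10),
    (0.00, 0.00, 0.00, 0.00),
    (0.30, 0.20, 0.20, 0.30),
]

# per household: (n_adults, n_children, maori, on_roll); 4 households per MB.
# Roll addresses per MB: stratum 0 -> (2, 1, 1), stratum 1 -> (2, 2, 1).
_MICRO_HH = {
    0: [(1, 0, True, True), (2, 1, True, True), (2, 0, False, False), (1, 2, False, False)],
    1: [(3, 1, True, True), (1, 0, False, False), (2, 2, False, False), (1, 1, False, False)],
    2: [(2, 0, True, True), (1, 1, True, False), (2, 1, False, False), (1, 0, False, False)],
    3: [(1, 1, True, True), (2, 0, True, True), (3, 0, False, False), (1, 2, False, False)],
    4: [(2, 2, True, True), (1, 0, True, True), (2, 1, False, False), (2, 0, False, False)],
    5: [(1, 0, True, True), (2, 1, False, False), (1, 1, False, False), (3, 0, False, False)],
}


def make_micro_population() -> Population:
    mb_rows, hh_rows, p_rows = [], [], []
    hh_id = p_id = 0
    for mb in range(6):
        stratum = mb // 3
        roll_ct = 0
        for n_a, n_c, maori, on_roll in _MICRO_HH[mb]:
            roll_ct += on_roll
            hh_rows.append(
                dict(household_id=hh_id, mb_id=mb, stratum_id=stratum,
                     size=n_a + n_c, n_adults=n_a, n_children=n_c,
                     maori=maori, pacific=False, asian=False, on_roll=on_roll)
            )
            for k in range(n_a + n_c):
                p_rows.append(
                    dict(person_id=p_id, household_id=hh_id, mb_id=mb,
                         stratum_id=stratum, is_adult=k < n_a,
                         maori=maori, pacific=False, asian=False,
                         on_roll_maori_descent=(k < n_a) and on_roll and maori)
                )
                p_id += 1
            hh_id += 1
        pac_mb, pac_au, asi_mb, asi_au = _MICRO_DENS[mb]
        mb_rows.append(
            dict(mb_id=mb, au_id=mb // 3, stratum_id=stratum,
                 census_persons=0, census_dwellings=4, current_dwellings=4,
                 maori_mb=0.3, pacific_mb=pac_mb, asian_mb=asi_mb,
                 maori_au=0.3, pacific_au=pac_au, asian_au=asi_au,
                 roll_addresses=roll_ct)
        )
    mbs = pd.DataFrame(mb_rows)
    persons = pd.DataFrame(p_rows)
    mbs["census_persons"] = mbs["mb_id"].map(persons.groupby("mb_id").size()).astype(int)
    strata = pd.DataFrame(
        dict(stratum_id=[0, 1],
             census_persons=persons.groupby("stratum_id").size().to_numpy())
    )
    return Population(
        strata=strata, meshblocks=mbs, households=pd.DataFrame(hh_rows),
        persons=persons, config=PopulationConfig(seed=0),
    )


@pytest.fixture(scope="session")
def micro_pop() -> Population:
    return make_micro_population()


@pytest.fixture(scope="session")
def micro_design() -> df.DesignConfig:
    # c = 2 of 4 households per area MB; 2 roll addresses per roll MB
    return df.DesignConfig(
        total_households_per_year=6, within_mb_target=2, roll_share=0.35,
        roll_addresses_per_mb=2, quarters=2, seed=9,
    )


@pytest.fixture(scope="session")
def micro_setup(micro_pop, micro_design):
    frame_table = df.census_snapshot(micro_pop, drift=0.0)
    frame = df.build_frame_index(micro_pop, micro_design, frame_table)
    plan = design_plan(frame_table, micro_design)
    probs = df.compute_inclusion_probabilities(frame, micro_design, plan=plan)
    return dict(pop=micro_pop, design=micro_design, frame_table=frame_table,
                frame=frame, plan=plan, probs=probs)


# --- NZ-like population ----------------------------------------------------

NZ_SEED = 11
NZ_OUTCOMES = [
    df.OutcomeSpec("flat", 0.5, 0.0),
    df.OutcomeSpec("vege", 0.442, 0.06),
    df.OutcomeSpec("active", 0.544, 0.21),
]


@pytest.fixture(scope="session")
def nz_pop() -> Population:
    cfg = df.nz_like_population_config(total_persons=50_000, seed=NZ_SEED)
    cfg.outcome_specs = list(NZ_OUTCOMES)
    return df.generate_population(cfg)


@pytest.fixture(scope="session")
def nz_setup(nz_pop):
    """Design scaled to 1/10 of the full annual household take."""
    design = df.DesignConfig(total_households_per_year=1250, seed=5)
    frame_table = df.census_snapshot(nz_pop, drift=0.0)
    frame = df.build_frame_index(nz_pop, design, frame_table)
    plan = design_plan(frame_table, design)
    probs = df.compute_inclusion_probabilities(
        frame, design, plan=plan, n_mc=4000, seed=7
    )
    return dict(pop=nz_pop, design=design, frame_table=frame_table,
                frame=frame, plan=plan, probs=probs)
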