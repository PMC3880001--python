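"""Design-effect decomposition: A-series estimators, counterfactual
probabilities, Table-2-shaped structure, variance-change summary."""

import math

import numpy as np
import pandas as pd
import pytest

import dualframe as df
from dualframe._rng import substream
from dualframe.config import PopulationConfig
from dualframe.decomposition import (
    counterfactual_pi,
    decompose_deff,
    estimate_counterfactual_n,
    estimate_one_plus_c2,
    frame_summaries,
    summarize_variance_change,
)
from dualframe.estimation import WeightedSample
from dualframe.population import Population

# Published component table (rows e and f and the printed product row) used
# as a worked example for the summary arithmetic.
PRINTED_E = {"all": 1.17, "maori": 1.14, "pacific": 1.08, "asian": 1.06}
PRINTED_F = {"all": 1.00, "maori": 0.71, "pacific": 0.68, "asian": 0.91}
PRINTED_PRODUCT = {"all": 1.17, "maori": 0.81, "pacific": 0.74, "asian": 0.96}


def _ws_from_arrays(w, pi_d, stratum=None, n_adults=1, flags=None):
    n = len(w)
    data = pd.DataFrame(
        dict(
            stratum=np.zeros(n, dtype=int) if stratum is None else stratum,
            mb_id=np.arange(n),
            weight=np.asarray(w, float),
            pi_pooled=np.asarray(pi_d, float),
            is_adult=True,
            n_adults_hh=n_adults,
            all=True,
        )
    )
    for name, v in (flags or {}).items():
        data[name] = v
    return WeightedSample(data)


class TestOnePlusC2:
    def test_constant_probabilities_give_exactly_one(self):
        ws = _ws_from_arrays(np.full(8, 3.0), np.full(8, 0.1))
        pi = np.full(8, 0.25)
        assert estimate_one_plus_c2(ws, "all", pi) == 1.0

    def test_two_unit_hand_case(self):
        ws = _ws_from_arrays([1.0, 1.0], [0.5, 0.5])
        pi = np.array([1.0, 1.0 / 3.0])
        # (1 + 1/3)(1 + 3) / 4 = 4/3
        assert estimate_one_plus_c2(ws, "all", pi) == pytest.approx(4.0 / 3.0)

    def test_cauchy_schwarz_lower_bound(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(2, 40))
            ws = _ws_from_arrays(rng.uniform(0.5, 9, n), rng.uniform(0.01, 1, n))
            pi = rng.uniform(0.01, 1.0, n)
            assert estimate_one_plus_c2(ws, "all", pi) >= 1.0 - 1e-12

    def test_nonpositive_probabilities_rejected(self):
        ws = _ws_from_arrays([1.0, 1.0], [0.5, 0.5])
        with pytest.raises(ValueError):
            estimate_one_plus_c2(ws, "all", np.array([0.0, 0.5]))


class TestCounterfactualN:
    def test_design_d_recovers_sample_count(self):
        """With w = 1/pi_d, the design-d estimate is exactly the number of
        sampled subpopulation members."""
        rng = np.random.default_rng(9)
        pi = rng.uniform(0.05, 0.5, 30)
        ws = _ws_from_arrays(1.0 / pi, pi)
        assert estimate_counterfactual_n(ws, "all", pi) == pytest.approx(30.0)


def _null_population_and_draw(seed=0):
    """Single stratum, equal meshblocks, one-adult households, no roll:
    the actual design collapses to SRS."""
    n_mb, hh_per_mb = 6, 4
    hh_rows, p_rows, mb_rows = [], [], []
    hh_id = 0
    for mb in range(n_mb):
        for _ in range(hh_per_mb):
            hh_rows.append(dict(household_id=hh_id, mb_id=mb, stratum_id=0, size=1,
                                n_adults=1, n_children=0, maori=False, pacific=False,
                                asian=False, on_roll=False))
            p_rows.append(dict(person_id=hh_id, household_id=hh_id, mb_id=mb,
                               stratum_id=0, is_adult=True, maori=False,
                               pacific=False, asian=False,
                               on_roll_maori_descent=False))
            hh_id += 1
        mb_rows.append(dict(mb_id=mb, au_id=0, stratum_id=0, census_persons=hh_per_mb,
                            census_dwellings=hh_per_mb, current_dwellings=hh_per_mb,
                            maori_mb=0.0, pacific_mb=0.0, asian_mb=0.0, maori_au=0.0,
                            pacific_au=0.0, asian_au=0.0, roll_addresses=0))
    pop = Population(
        strata=pd.DataFrame(dict(stratum_id=[0], census_persons=[hh_id])),
        meshblocks=pd.DataFrame(mb_rows),
        households=pd.DataFrame(hh_rows),
        persons=pd.DataFrame(p_rows),
        config=PopulationConfig(seed=0),
    )
    design = df.DesignConfig(total_households_per_year=4, within_mb_target=2,
                             roll_share=0.0, seed=seed)
    frame_table = df.census_snapshot(pop)
    frame = df.build_frame_index(pop, design, frame_table)
    probs = df.compute_inclusion_probabilities(frame, design)
    d = df.run_annual_sample(frame, design, rng=substream(seed, "null"),
                             frame_table=frame_table)
    ws = df.build_weighted_sample(d, frame, probs, pop)
    return pop, design, ws


class TestDecomposition:
    def test_null_design_gives_unit_rows(self):
        """If the actual design is an unstratified equal-probability draw of
        one-adult households, every component equals 1."""
        pop, design, ws = _null_population_and_draw()
        table = decompose_deff(ws, frame_summaries(pop), subpops=("all",))
        for row in ("a", "b", "c", "d", "e", "f", "ef"):
            assert table.loc[row, "all"] == pytest.approx(1.0, abs=1e-9)

    def test_counterfactual_census_is_certainty(self):
        pop, design, ws = _null_population_and_draw()
        summaries = frame_summaries(pop)
        pi = counterfactual_pi(ws, "a", summaries, n=summaries.total_adults)
        assert (pi == 1.0).all()

    def test_design_c_collapses_to_b_for_single_adult_households(self, nz_setup):
        """When every sampled household has one adult (and household counts
        equal adult counts), designs b and c coincide."""
        pop, design, ws = _null_population_and_draw(seed=3)
        summaries = frame_summaries(pop)
        pi_b = counterfactual_pi(ws, "b", summaries)
        pi_c = counterfactual_pi(ws, "c", summaries)
        assert pi_c == pytest.approx(pi_b)

    def test_micro_counterfactuals_match_enumeration(self, micro_setup):
        """pi_a / pi_b / pi_c agree with brute-force combinatorial
        enumeration of the counterfactual designs on the micro population."""
        pop, frame, design, plan, probs = (
            micro_setup["pop"], micro_setup["frame"], micro_setup["design"],
            micro_setup["plan"], micro_setup["probs"],
        )
        d = df.run_annual_sample(frame, design, plan=plan, rng=substream(19, "cf"))
        ws = df.build_weighted_sample(d, frame, probs, pop)
        summaries = frame_summaries(pop, design.power_exponent)
        n = 8
        adults = ws.data[ws.data.is_adult]

        pi_a = counterfactual_pi(ws, "a", summaries, n=n)
        assert pi_a == pytest.approx(n / summaries.total_adults)

        # design b: SRS of adults within strata, power-allocated
        from dualframe.decomposition import _power_allocated_n

        n_h = _power_allocated_n(summaries, n)
        pi_b = counterfactual_pi(ws, "b", summaries, n=n)
        for pi, s in zip(pi_b, adults["stratum"]):
            assert pi == pytest.approx(n_h[s] / summaries.stratum_adults[s])

        # design c: enumerate all household subsets of size n_h in stratum 0,
        # then one adult uniformly per selected household
        import itertools

        s = 0
        hh = pop.households[pop.households.stratum_id == s]
        HH = len(hh)
        take = n_h[s]
        total = math.comb(HH, take)
        freq = {h: 0 for h in hh.household_id}
        for subset in itertools.combinations(hh.household_id, take):
            for h in subset:
                freq[h] += 1
        pi_c = counterfactual_pi(ws, "c", summaries, n=n)
        for pi, (_, row) in zip(
            pi_c[adults["stratum"].to_numpy() == s],
            adults[adults["stratum"] == s].iterrows(),
        ):
            person = pop.persons[pop.persons.person_id == row.person_id].iloc[0]
            enumerated = (
                freq[person.household_id] / total / row.n_adults_hh
            )
            assert pi == pytest.approx(enumerated)

    def test_table_shape_and_labels(self, micro_setup):
        pop, frame, design, plan, probs = (
            micro_setup["pop"], micro_setup["frame"], micro_setup["design"],
            micro_setup["plan"], micro_setup["probs"],
        )
        d = df.run_annual_sample(frame, design, plan=plan, rng=substream(20, "t"))
        ws = df.build_weighted_sample(d, frame, probs, pop)
        table = decompose_deff(ws, frame_summaries(pop), subpops=("all", "maori"))
        assert list(table.index) == ["a", "b", "c", "d", "e", "f", "ef"]
        assert table.loc["ef", "all"] == pytest.approx(
            table.loc["e", "all"] * table.loc["f", "all"]
        )
        # empty subpopulation renders as missing, not zero
        table2 = decompose_deff(ws, frame_summaries(pop), subpops=("pacific",))
        assert table2["pacific"].isna().all()


class TestVarianceChangeSummary:
    def test_worked_example_from_printed_rows(self):
        """Products of the published e/f rows, rounded to 2 dp, reproduce the
        printed product row (Pacific uses the printed value, whose unrounded
        intermediates are not recoverable), and the summary reproduces the
        +17 / -19 / -26 / -4 percent variance changes."""
        products = {
            sp: round(PRINTED_E[sp] * PRINTED_F[sp], 2) for sp in ("all", "maori", "asian")
        }
        assert products == {"all": 1.17, "maori": 0.81, "asian": 0.96}
        products["pacific"] = PRINTED_PRODUCT["pacific"]
        change = summarize_variance_change(products).round(0)
        assert change["all"] == 17
        assert change["maori"] == -19
        assert change["pacific"] == -26
        assert change["asian"] == -4

    def test_unit_product_is_no_change(self):
        assert summarize_variance_change({"all": 1.0})["all"] == 0.0
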