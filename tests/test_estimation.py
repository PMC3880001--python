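"""Weighting and estimators: pooled probabilities, Hajek means, jackknife,
design effects, ANOVA ICC, RR3."""

import numpy as np
import pandas as pd
import pytest

import dualframe as df
from dualframe._rng import substream
from dualframe.estimation import (
    Dispositions,
    WeightedSample,
    design_effect,
    hajek_mean,
    icc_anova,
    jackknife_replicates,
    jackknife_variance,
    response_rate_rr3,
)


class TestInclusionProbability:
    def test_single_frame_probability_is_stage_product(self, micro_pop):
        """With no roll component the pooled probability is the product
        MB pi x household fraction x within-household probability."""
        design = df.DesignConfig(
            total_households_per_year=6, within_mb_target=2, roll_share=0.0, seed=2
        )
        frame_table = df.census_snapshot(micro_pop)
        frame = df.build_frame_index(micro_pop, design, frame_table)
        from dualframe.design import design_plan

        plan = design_plan(frame_table, design)
        probs = df.compute_inclusion_probabilities(frame, design, plan=plan)
        size = frame.N_star * frame.f
        for s in range(frame.n_strata):
            mbs = frame.mb_by_stratum[s]
            pi_mb = df.mb_selection_probabilities(size[mbs], int(plan.m_h[s]))
            for j, mb in enumerate(mbs):
                assert probs.mb_area_pi_pooled[mb] == pytest.approx(pi_mb[j])
        # spot-check one adult
        pos = 0
        hh = frame.person_hh[pos]
        mb = frame.hh_mb[hh]
        expect = (
            probs.mb_area_pi_pooled[mb]
            * min(design.within_mb_target / frame.N_star[mb], 1.0)
            / frame.hh_n_adults[hh]
        )
        assert probs.person_pi[pos] == pytest.approx(expect)
        assert (probs.person_pi_roll == 0).all()

    def test_no_roll_addresses_means_area_path_only(self, micro_setup):
        probs, frame = micro_setup["probs"], micro_setup["frame"]
        off_roll = ~frame.hh_on_roll[frame.person_hh]
        assert (probs.person_pi_roll[off_roll] == 0).all()
        assert probs.person_pi[off_roll] == pytest.approx(
            probs.person_pi_area[off_roll]
        )

    def test_pooled_exceeds_single_path_for_roll_households(self, micro_setup):
        probs, frame = micro_setup["probs"], micro_setup["frame"]
        on_roll = frame.hh_on_roll[frame.person_hh]
        assert (probs.person_pi_roll[on_roll] > 0).all()
        assert (
            probs.person_pi[on_roll]
            > probs.person_pi_area[on_roll]
        ).all()

    def test_zero_probability_flagged(self, micro_setup):
        from dualframe.estimation import PooledProbabilities, inclusion_probability

        probs = micro_setup["probs"]
        broken = PooledProbabilities(
            mb_roll_pi=probs.mb_roll_pi,
            mb_area_pi_pooled=probs.mb_area_pi_pooled,
            hh_pi=probs.hh_pi,
            person_pi=np.zeros_like(probs.person_pi),
            person_pi_roll=probs.person_pi_roll,
            person_pi_area=probs.person_pi_area,
        )
        with pytest.raises(ValueError):
            inclusion_probability(broken, np.array([0]))


class TestHajek:
    def test_constant_outcome_gives_one(self):
        assert hajek_mean(np.array([1.0, 5.0, 2.0]), np.ones(3)) == 1.0

    def test_equal_weights_give_unweighted_mean(self):
        y = np.array([0.0, 1.0, 1.0, 0.0])
        assert hajek_mean(np.full(4, 7.3), y) == pytest.approx(y.mean())


def _srs_weighted_sample(rng, n=60, strata=2, weight=10.0):
    rows = []
    for s in range(strata):
        for j in range(n):
            rows.append(
                dict(stratum=s, mb_id=s * 1000 + j, weight=weight, is_adult=True,
                     y=float(rng.random() < 0.4), all=True)
            )
    return WeightedSample(pd.DataFrame(rows))


class TestJackknife:
    def test_replicates_preserve_stratum_totals(self, nz_setup):
        frame, design, plan, probs, pop = (
            nz_setup["frame"], nz_setup["design"], nz_setup["plan"],
            nz_setup["probs"], nz_setup["pop"],
        )
        d = df.run_annual_sample(frame, design, plan=plan, rng=substream(30, "jk"))
        ws = df.build_weighted_sample(d, frame, probs, pop)
        ws = jackknife_replicates(ws, G=40, seed=3)
        strat = ws.strata_of_replicates
        w = ws.data["weight"].to_numpy()
        for s in np.unique(strat):
            total = w[strat == s].sum()
            reps = ws.replicate_weights[strat == s].sum(axis=0)
            assert reps == pytest.approx(total)

    def test_constant_statistic_has_zero_variance(self):
        ws = _srs_weighted_sample(np.random.default_rng(1))
        ws = jackknife_replicates(ws, G=20, seed=5)
        var = jackknife_variance(
            ws, "y", statistic=lambda w, data: float(np.sum(w))
        )
        assert var == pytest.approx(0.0, abs=1e-18)

    def test_matches_stratified_srs_closed_form(self):
        """Delete-a-group jackknife on a stratified element sample agrees with
        the closed-form stratified-SRS variance (small sampling fractions)."""
        rng = np.random.default_rng(42)
        Nh, nh = [3000, 5000], [30, 50]
        popy = [rng.random(N) < 0.4 for N in Nh]
        jk = []
        for r in range(150):
            rows = []
            for s, (N, n) in enumerate(zip(Nh, nh)):
                for j, i in enumerate(rng.choice(N, n, replace=False)):
                    rows.append(dict(stratum=s, mb_id=s * 10**6 + j, weight=N / n,
                                     is_adult=True, y=float(popy[s][i]), all=True))
            ws = jackknife_replicates(WeightedSample(pd.DataFrame(rows)), G=40, seed=r)
            jk.append(jackknife_variance(ws, "y"))
        W = np.array(Nh) / sum(Nh)
        closed = sum(
            W[s] ** 2 * (1 - nh[s] / Nh[s]) * popy[s].var(ddof=1) / nh[s]
            for s in range(2)
        )
        assert np.mean(jk) == pytest.approx(closed, rel=0.2)

    def test_g_equal_psus_is_delete_one(self):
        """With G = number of PSUs in a single stratum the delete-a-group
        jackknife reduces to the delete-one (JK1-style) computation."""
        rng = np.random.default_rng(7)
        n = 12
        w = rng.uniform(5, 15, n)
        y = (rng.random(n) < 0.5).astype(float)
        ws = WeightedSample(pd.DataFrame(dict(
            stratum=0, mb_id=np.arange(n), weight=w, is_adult=True, y=y, all=True
        )))
        ws = jackknife_replicates(ws, G=n, seed=11)
        got = jackknife_variance(ws, "y")
        theta = np.dot(w, y) / w.sum()
        thetas = []
        for i in range(n):
            keep = np.arange(n) != i
            wk = w[keep] * w.sum() / w[keep].sum()
            thetas.append(np.dot(wk, y[keep]) / wk.sum())
        oracle = (n - 1) / n * np.sum((np.array(thetas) - theta) ** 2)
        assert got == pytest.approx(oracle)

    def test_g_larger_than_psus_rejected(self):
        ws = _srs_weighted_sample(np.random.default_rng(2), n=5, strata=1)
        with pytest.raises(ValueError):
            jackknife_replicates(ws, G=50, seed=1)


class TestDesignEffect:
    def test_arithmetic(self):
        assert design_effect(0.5, 0.25 / 100, 100) == pytest.approx(1.0)

    def test_degenerate_prevalence_rejected(self):
        with pytest.raises(ValueError):
            design_effect(1.0, 0.01, 100)


class TestICC:
    def test_equal_group_means_give_zero(self):
        y = np.tile([0.0, 1.0], 10)
        groups = np.repeat(np.arange(10), 2)
        assert icc_anova(y, groups) == 0.0

    def test_perfect_clustering_gives_one(self):
        y = np.repeat([0.0, 1.0, 0.0, 1.0, 1.0], 6)
        groups = np.repeat(np.arange(5), 6)
        assert icc_anova(y, groups) == pytest.approx(1.0)

    def test_degenerate_grouping_rejected(self):
        with pytest.raises(ValueError):
            icc_anova(np.array([1.0, 0.0]), np.array([0, 0]))


class TestResponseRateRR3:
    def test_headline_rate(self):
        d = Dispositions(interviews=79, refusals=21)
        assert response_rate_rr3(d) == pytest.approx(0.79)

    def test_zero_eligibility_excludes_unknowns(self):
        d = Dispositions(interviews=50, refusals=50, unknown_eligibility=100)
        assert response_rate_rr3(d, e=0.0) == pytest.approx(0.5)

    def test_formula_arithmetic(self):
        d = Dispositions(interviews=80, refusals=10, unknown_eligibility=20)
        assert response_rate_rr3(d, e=0.5) == pytest.approx(0.80)

    def test_default_eligibility_from_resolved_cases(self):
        d = Dispositions(
            interviews=60, refusals=20, ineligible=20, unknown_eligibility=10
        )
        # e = 80/100; denominator 80 + 0.8*10 = 88
        assert response_rate_rr3(d) == pytest.approx(60 / 88)

    def test_empty_denominator_rejected(self):
        with pytest.raises(ValueError):
            response_rate_rr3(Dispositions(interviews=0), e=0.0)


class TestHorvitzThompsonCoverage:
    def test_weight_totals_unbiased_for_adult_count(self, nz_setup):
        """HT total of the all-ones variable over replicate draws is unbiased
        for the adult population count."""
        frame, design, plan, probs, pop = (
            nz_setup["frame"], nz_setup["design"], nz_setup["plan"],
            nz_setup["probs"], nz_setup["pop"],
        )
        rng = substream(31, "ht")
        R = 150
        totals = np.empty(R)
        for i in range(R):
            d = df.run_annual_sample(frame, design, plan=plan, rng=rng)
            ws = df.build_weighted_sample(d, frame, probs, pop, adults_only=True)
            totals[i] = ws.data["weight"].sum()
        truth = pop.persons["is_adult"].sum()
        se = totals.std(ddof=1) / np.sqrt(R)
        assert abs(totals.mean() - truth) < 3 * se
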