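"""Design-effect decomposition across counterfactual designs.

Under Kish's rule (no clustering) the variance of a subpopulation mean under
a complex design is approximately (1 + C_sub^2) / n_sub * S_sub^2, where
C_sub is the coefficient of variation of the weights among subpopulation
respondents and n_sub the subpopulation sample size.  Comparing the actual
design (d) with a ladder of counterfactuals sharing the same total person
sample size n —

    (a) simple random sampling of people,
    (b) stratified SRS of people with power allocation,
    (c) stratified SRS of households with one adult selected per household,
    (d) the actual dual-frame targeted design —

factorizes the deff into a weight-variation ratio (1+C^2_next)/(1+C^2_prev)
and a sample-size ratio n_prev/n_next for each rung.  Both are estimable
from the realized design-d sample alone: with survey weight w_i and the
counterfactual inclusion probability pi_xi of respondent i,

    n_hat_sub(x)      = sum_sub w_i pi_xi
    1 + C_hat^2_sub(x) = sum_sub(w pi_x) * sum_sub(w / pi_x) / (sum_sub w)^2.

The product of the final two rows (weight variation x over/undersampling due
to within-stratum unequal probabilities) is the net variance impact of
targeting plus the dual frame, reported as a percentage change.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .design import largest_remainder_round
from .estimation import WeightedSample
from .population import Population

__all__ = [
    "FrameSummaries",
    "frame_summaries",
    "counterfactual_pi",
    "estimate_counterfactual_n",
    "estimate_one_plus_c2",
    "decompose_deff",
    "summarize_variance_change",
    "COMPONENT_LABELS",
]

DESIGNS = ("a", "b", "c", "d")

COMPONENT_LABELS = {
    "a": "Varying weights due to disproportionate allocation to strata",
    "b": "Over- or undersampling due to disproportionate allocation to strata",
    "c": "Varying weights due to 1/household sampling",
    "d": "Over- or undersampling due to 1/household sampling",
    "e": "Varying weights due to unequal probabilities of selection of households within strata",
    "f": "Over- or undersampling due to unequal probabilities of selection of households within strata",
    "ef": "Unequal probability of selection of households within strata (product of e and f)",
}


@dataclass
class FrameSummaries:
    """Population quantities the counterfactual probabilities need."""

    total_adults: int
    stratum_adults: Dict[int, int]
    stratum_households: Dict[int, int]
    stratum_persons: Dict[int, int]
    power_exponent: float = 0.5


def frame_summaries(
    population: Population, power_exponent: float = 0.5
) -> FrameSummaries:
    persons = population.persons
    adults = persons[persons["is_adult"]]
    return FrameSummaries(
        total_adults=int(len(adults)),
        stratum_adults=adults.groupby("stratum_id").size().to_dict(),
        stratum_households=population.households.groupby("stratum_id").size().to_dict(),
        stratum_persons=persons.groupby("stratum_id").size().to_dict(),
        power_exponent=power_exponent,
    )


def _power_allocated_n(summaries: FrameSummaries, n: int) -> Dict[int, int]:
    """Allocate the person sample n to strata by power allocation on census
    person counts (the stratification rule of designs b-d)."""
    ids = sorted(summaries.stratum_persons)
    shares = np.array([summaries.stratum_persons[i] for i in ids], dtype=float)
    alloc = largest_remainder_round(
        shares**summaries.power_exponent, int(n), minimum=1
    )
    return dict(zip(ids, alloc))


def counterfactual_pi(
    ws: WeightedSample,
    design_label: str,
    summaries: FrameSummaries,
    n: Optional[int] = None,
) -> np.ndarray:
    """Inclusion probability each adult respondent would have had under a
    counterfactual design, all designs normalized to person sample size n
    (default: the realized adult sample size)."""
    if design_label not in DESIGNS:
        raise ValueError(f"unknown design {design_label!r}")
    data = ws.data
    adults = data["is_adult"].to_numpy().astype(bool)
    sub = data.loc[adults]
    if n is None:
        n = int(adults.sum())
    stratum_ids = sub["stratum"].to_numpy()

    if design_label == "a":
        return np.full(len(sub), min(n / summaries.total_adults, 1.0))

    n_h = _power_allocated_n(summaries, n)
    if design_label == "b":
        return np.array(
            [min(n_h[s] / summaries.stratum_adults[s], 1.0) for s in stratum_ids]
        )
    if design_label == "c":
        # n_h households SRS per stratum, one adult per household
        hh_frac = np.array(
            [min(n_h[s] / summaries.stratum_households[s], 1.0) for s in stratum_ids]
        )
        return hh_frac / sub["n_adults_hh"].to_numpy()
    return sub["pi_pooled"].to_numpy()


def _adult_subpop(ws: WeightedSample, subpop: Optional[str]) -> np.ndarray:
    data = ws.data
    mask = data["is_adult"].to_numpy().astype(bool)
    sub_of_adults = (
        np.ones(int(mask.sum()), dtype=bool)
        if subpop in (None, "all")
        else data.loc[mask, subpop].to_numpy().astype(bool)
    )
    return sub_of_adults


def estimate_counterfactual_n(
    ws: WeightedSample,
    subpop: Optional[str],
    pi_x: np.ndarray,
) -> float:
    """Expected subpopulation sample size under design x: sum_sub w_i pi_xi."""
    data = ws.data
    adults = data["is_adult"].to_numpy().astype(bool)
    w = data.loc[adults, "weight"].to_numpy(dtype=float)
    m = _adult_subpop(ws, subpop)
    return float(np.dot(w[m], pi_x[m]))


def estimate_one_plus_c2(
    ws: WeightedSample,
    subpop: Optional[str],
    pi_x: np.ndarray,
) -> float:
    """1 + C^2 of the design-x weights on the subpopulation:
    sum(w pi) * sum(w / pi) / (sum w)^2, restricted to subpop respondents.
    Always >= 1 (Cauchy-Schwarz), equal to 1 iff pi_x is constant there."""
    data = ws.data
    adults = data["is_adult"].to_numpy().astype(bool)
    w = data.loc[adults, "weight"].to_numpy(dtype=float)
    m = _adult_subpop(ws, subpop)
    w, pi = w[m], pi_x[m]
    if np.any(pi <= 0):
        raise ValueError("counterfactual probabilities must be positive")
    sw = w.sum()
    if sw <= 0:
        raise ValueError("empty subpopulation")
    return float(np.dot(w, pi) * np.dot(w, 1.0 / pi) / sw**2)


def decompose_deff(
    ws: WeightedSample,
    summaries: FrameSummaries,
    subpops: Sequence[str] = ("all", "maori", "pacific", "asian"),
    n: Optional[int] = None,
) -> pd.DataFrame:
    """Six-component decomposition (plus the e*f product row) by subpopulation.

    Rows a/c/e are weight-variation ratios (1+C^2) across the design ladder
    a->b, b->c, c->d; rows b/d/f are the matching sample-size ratios
    n(prev)/n(next).  Full precision is kept internally; round only for
    presentation.
    """
    pis = {x: counterfactual_pi(ws, x, summaries, n=n) for x in DESIGNS}
    rows = {label: {} for label in COMPONENT_LABELS}
    for sp in subpops:
        try:
            c2 = {x: estimate_one_plus_c2(ws, sp, pis[x]) for x in DESIGNS}
            nn = {x: estimate_counterfactual_n(ws, sp, pis[x]) for x in DESIGNS}
        except ValueError:
            for label in COMPONENT_LABELS:
                rows[label][sp] = np.nan
            continue
        rows["a"][sp] = c2["b"] / c2["a"]
        rows["b"][sp] = nn["a"] / nn["b"]
        rows["c"][sp] = c2["c"] / c2["b"]
        rows["d"][sp] = nn["b"] / nn["c"]
        rows["e"][sp] = c2["d"] / c2["c"]
        rows["f"][sp] = nn["c"] / nn["d"]
        rows["ef"][sp] = rows["e"][sp] * rows["f"][sp]
    table = pd.DataFrame(rows).T
    table.insert(0, "component", [COMPONENT_LABELS[i] for i in table.index])
    table.index.name = "row"
    return table


def summarize_variance_change(products: Dict[str, float] | pd.Series) -> pd.Series:
    """Percent variance change implied by the e*f product per subpopulation:
    (product - 1) * 100; positive = variance increase."""
    s = pd.Series(products, dtype=float)
    return (s - 1.0) * 100.0
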