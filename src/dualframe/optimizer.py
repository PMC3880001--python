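"""Numerical choice of targeting-factor coefficients.

The five coefficients (Pacific MB, Pacific AU, Asian MB, Asian AU, constant)
live on the unit simplex — the published set sums to 1.00.  Candidate
coefficient vectors are scored with an anticipated-variance model built from
Kish's rule: for each subpopulation, selection probabilities implied by the
candidate targeting factor on an evaluation frame give an expected
subpopulation sample size n_sub and a weight-variation factor 1 + C_sub^2,
and the proxy variance is (1 + C_sub^2) / n_sub * p(1-p).  The objective is
an importance-weighted sum of subpopulation proxies; clustering penalties are
excluded from the default proxy (an optional multiplier hook is provided).

The search is derivative-free Nelder-Mead on a softmax parameterization of
the simplex, multi-started and fully seeded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from ._rng import substream
from .config import DEFAULT_TARGETING_COEFFICIENTS
from .design import largest_remainder_round, targeting_factor

__all__ = ["ObjectiveSpec", "anticipated_variance", "optimize_coefficients"]


@dataclass
class ObjectiveSpec:
    """What the optimizer minimizes and on which frame."""

    frame: pd.DataFrame  # meshblock table with densities + census_persons
    importance: Dict[str, float] = field(
        default_factory=lambda: {"all": 1.0, "maori": 1.0, "pacific": 1.0, "asian": 1.0}
    )
    prevalences: Dict[str, float] = field(default_factory=dict)
    total_person_sample: int = 12_500
    power_exponent: float = 0.5
    cluster_multiplier: Optional[Dict[str, float]] = None

    def validate(self) -> None:
        if any(v < 0 for v in self.importance.values()):
            raise ValueError("importance weights must be nonnegative")
        if not any(v > 0 for v in self.importance.values()):
            raise ValueError("importance weights must not all be zero")


def _person_probabilities(frame: pd.DataFrame, coeffs, n: int, q: float):
    """Person-level inclusion probabilities per meshblock implied by the
    targeting factor: within stratum h, pi = n_h f_i / sum_j N_j f_j."""
    f = np.asarray(
        targeting_factor(
            frame["pacific_mb"], frame["pacific_au"], frame["asian_mb"],
            frame["asian_au"], coeffs,
        ),
        dtype=float,
    )
    N = frame["census_persons"].to_numpy(dtype=float)
    strata = frame["stratum_id"].to_numpy()
    ids, inv = np.unique(strata, return_inverse=True)
    pops = np.bincount(inv, weights=N)
    n_h = largest_remainder_round(pops**q, int(n), minimum=1).astype(float)
    denom = np.bincount(inv, weights=N * f)
    if np.any(denom <= 0):
        raise ValueError(
            "zero selection probability in some stratum (constant coefficient is 0 "
            "and densities vanish)"
        )
    pi = n_h[inv] * f / denom[inv]
    if np.any(pi <= 0):
        raise ValueError("zero selection probability for some meshblock")
    return pi, N


def anticipated_variance(
    coefficients: Sequence[float], spec: ObjectiveSpec
) -> Dict[str, float]:
    """Kish anticipated-variance proxy per subpopulation for one candidate
    coefficient vector (on the simplex)."""
    spec.validate()
    b = np.asarray(coefficients, dtype=float)
    if np.any(b < 0):
        raise ValueError("coefficients must be nonnegative")
    pi, N = _person_probabilities(
        spec.frame, tuple(b), spec.total_person_sample, spec.power_exponent
    )
    out: Dict[str, float] = {}
    for sp in spec.importance:
        dens = (
            np.ones(len(spec.frame))
            if sp == "all"
            else spec.frame[f"{sp}_mb"].to_numpy(dtype=float)
        )
        N_sub = float(np.dot(dens, N))
        if N_sub <= 0:
            out[sp] = np.nan
            continue
        n_sub = float(np.dot(dens * N, pi))
        inv = float(np.dot(dens * N, 1.0 / pi))
        one_plus_c2 = n_sub * inv / N_sub**2
        p = spec.prevalences.get(sp, 0.5)
        v = one_plus_c2 / n_sub * p * (1.0 - p)
        if spec.cluster_multiplier:
            v *= spec.cluster_multiplier.get(sp, 1.0)
        out[sp] = v
    return out


def _objective(coeffs: np.ndarray, spec: ObjectiveSpec) -> float:
    proxies = anticipated_variance(coeffs, spec)
    tot_imp = sum(spec.importance.values())
    return sum(
        w / tot_imp * proxies[sp] for sp, w in spec.importance.items() if w > 0
    )


def _softmax(theta: np.ndarray) -> np.ndarray:
    z = np.exp(theta - theta.max())
    return z / z.sum()


@dataclass
class OptimizationResult:
    coefficients: np.ndarray
    objective: float
    per_subpop_variance: Dict[str, float]
    trace: pd.DataFrame
    converged: bool


def optimize_coefficients(
    spec: ObjectiveSpec,
    n_starts: int = 6,
    seed: int = 0,
    maxiter: int = 400,
) -> OptimizationResult:
    """Minimize the anticipated-variance objective over the coefficient
    simplex: multi-start Nelder-Mead on softmax-parameterized coefficients.
    Deterministic given the seed; non-convergence is reported, not raised."""
    spec.validate()
    rng = substream(seed, "optimizer")
    starts = [np.log(np.asarray(DEFAULT_TARGETING_COEFFICIENTS))]
    starts.append(np.zeros(5))  # uniform coefficients
    for _ in range(max(0, n_starts - len(starts))):
        starts.append(rng.normal(0.0, 1.5, size=5))

    records = []
    best = None
    converged = False
    for k, theta0 in enumerate(starts):
        res = minimize(
            lambda th: _objective(_softmax(th), spec),
            theta0,
            method="Nelder-Mead",
            options={"maxiter": maxiter, "xatol": 1e-6, "fatol": 1e-12},
        )
        b = _softmax(res.x)
        records.append(
            dict(start=k, objective=float(res.fun), converged=bool(res.success),
                 **{f"b{i}": float(v) for i, v in enumerate(b)})
        )
        if best is None or res.fun < best[0]:
            best = (float(res.fun), b)
            converged = bool(res.success)
    obj, coeffs = best
    return OptimizationResult(
        coefficients=coeffs,
        objective=obj,
        per_subpop_variance=anticipated_variance(coeffs, spec),
        trace=pd.DataFrame(records),
        converged=converged,
    )
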