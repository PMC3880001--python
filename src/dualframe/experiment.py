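"""Reproducible experiment runner.

Generates a population, repeats draw -> weight -> estimate over replicate
draws, and aggregates Monte-Carlo bias and variance of the estimators, a
key-indicator table (prevalence / SE / ICC / deff by subpopulation), the
design-effect component table, and the variance-change summary.  Every output
is regenerable from the embedded config and master seed; per-replicate
substreams keep replicates independent and individually re-runnable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from typing import Dict

import numpy as np
import pandas as pd

from ._rng import spawn_seed, substream
from .config import ExperimentConfig, _pop_to_dict
from .decomposition import decompose_deff, frame_summaries, summarize_variance_change
from .estimation import (
    build_weighted_sample,
    compute_inclusion_probabilities,
    estimate_prevalence,
    indicator_table,
    jackknife_replicates,
)
from .frames import build_frame_index
from .population import census_snapshot, generate_population
from .sampler import run_annual_sample

__all__ = ["run_experiment", "render_tables"]

SUBPOPS = ("all", "maori", "pacific", "asian")


def _config_hash(cfg: ExperimentConfig) -> str:
    payload = json.dumps(
        {
            "population": _pop_to_dict(cfg.population),
            "design": dataclasses.asdict(cfg.design),
            "n_replicates": cfg.n_replicates,
            "seed": cfg.seed,
        },
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_experiment(cfg: ExperimentConfig, jackknife_groups: int = 50) -> Dict:
    """Run the full pipeline; returns a report bundle (plain dict)."""
    cfg.validate()
    pop = generate_population(cfg.population)
    frame_table = census_snapshot(pop, drift=0.0)
    frame = build_frame_index(pop, cfg.design, frame_table)
    probs = compute_inclusion_probabilities(frame, cfg.design, seed=cfg.seed)
    summaries = frame_summaries(pop, cfg.design.power_exponent)
    outcomes = pop.outcome_names

    truth = {}
    adults = pop.persons[pop.persons["is_adult"]]
    for out in outcomes:
        for sp in SUBPOPS:
            sub = adults if sp == "all" else adults[adults[sp]]
            if len(sub):
                truth[(out, sp)] = float(sub[out].mean())

    errors = []
    est_rows = []
    decomp_tables = []
    first_ws = None
    for r in range(cfg.n_replicates):
        rng = substream(cfg.seed, "replicate", str(r))
        try:
            draw = run_annual_sample(frame, cfg.design, rng=rng, frame_table=frame_table)
            ws = build_weighted_sample(draw, frame, probs, pop)
        except Exception as exc:  # aggregate stage failures, keep going
            errors.append(f"replicate {r}: {exc}")
            continue
        if first_ws is None:
            n_psu = ws.data["mb_id"].nunique()
            first_ws = jackknife_replicates(
                ws, G=min(jackknife_groups, n_psu), seed=spawn_seed(cfg.seed, "jk")
            )
        for out in outcomes:
            for sp in SUBPOPS:
                try:
                    est = estimate_prevalence(ws, out, subpop=sp)
                except ValueError:
                    continue
                est_rows.append(
                    dict(replicate=r, outcome=out, subpop=sp,
                         prevalence=est.prevalence, n=est.n)
                )
        decomp_tables.append(
            decompose_deff(ws, summaries, subpops=SUBPOPS).drop(columns="component")
        )

    estimates = pd.DataFrame(est_rows)
    mc_summary = None
    if len(estimates) and cfg.n_replicates > 1:
        g = estimates.groupby(["outcome", "subpop"])["prevalence"]
        mc_summary = g.agg(["mean", "var", "count"]).reset_index()
        mc_summary["truth"] = [
            truth.get((o, s), np.nan)
            for o, s in zip(mc_summary["outcome"], mc_summary["subpop"])
        ]
        mc_summary["bias"] = mc_summary["mean"] - mc_summary["truth"]

    table1 = (
        indicator_table(first_ws, outcomes, subpops=SUBPOPS)
        if (first_ws is not None and outcomes)
        else None
    )
    table2 = None
    variance_change = None
    if decomp_tables:
        table2 = sum(decomp_tables) / len(decomp_tables)
        table2.insert(0, "component", decompose_deff(
            first_ws, summaries, subpops=SUBPOPS)["component"] if first_ws is not None else "")
        variance_change = summarize_variance_change(table2.loc["ef", list(SUBPOPS)])

    return dict(
        provenance=dict(
            config_hash=_config_hash(cfg),
            seed=cfg.seed,
            n_replicates=cfg.n_replicates,
            version=_package_version(),
        ),
        truth=truth,
        estimates=estimates,
        mc_summary=mc_summary,
        table1=table1,
        table2=table2,
        variance_change=variance_change,
        errors=errors,
        inclusion_method=probs.method,
    )


def _package_version() -> str:
    try:
        from importlib.metadata import version

        return version("dualframe")
    except Exception:
        return "unknown"


def render_tables(bundle: Dict, outdir: str, fmt: str = "tsv") -> Dict[str, str]:
    """Write the bundle's tables; returns {name: path}.  TSV round-trips."""
    if fmt not in ("tsv", "csv"):
        raise ValueError(f"unknown format {fmt!r}")
    sep = "\t" if fmt == "tsv" else ","
    os.makedirs(outdir, exist_ok=True)
    written: Dict[str, str] = {}
    for name in ("estimates", "mc_summary", "table1", "table2"):
        obj = bundle.get(name)
        if obj is None or (hasattr(obj, "__len__") and len(obj) == 0):
            continue
        path = os.path.join(outdir, f"{name}.{fmt}")
        obj.to_csv(path, sep=sep, index=(name == "table2"))
        written[name] = path
    if bundle.get("variance_change") is not None:
        path = os.path.join(outdir, f"variance_change.{fmt}")
        bundle["variance_change"].rename("pct_variance_change").to_csv(
            path, sep=sep, header=True
        )
        written["variance_change"] = path
    meta = dict(bundle["provenance"], errors=bundle.get("errors", []),
                inclusion_method=bundle.get("inclusion_method"))
    meta_path = os.path.join(outdir, "report.json")
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=2)
    written["report"] = meta_path
    return written
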