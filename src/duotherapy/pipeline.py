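"""Pipeline orchestration: simulate → cohort → exposure → match → analyze.

``run_all`` executes the base analysis plus each requested subgroup,
mode and sensitivity variant, writing stage outputs and a run manifest
(config hash, per-stage row counts, wall times, seed plan). Sensitivity
variants are pure parameter overrides resolved at config load — the
base and variant analyses share every code path. All randomness flows
from a single root seed expanded per stage with ``SeedSequence``.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import build_cohort
from .config import RunConfig
from .episodes import build_exposure
from .io import write_streams, write_table
from .simulate import generate_population
from .survival import run_comparison

logger = logging.getLogger(__name__)

#: Covariates entering the propensity model (all baseline families the
#: record streams carry).
PS_COVARIATES = (
    "age", "male", "bmi", "smoking", "deprivation_index", "ethnicity",
    "baseline_sbp", "baseline_dbp", "hypertension_grade", "has_ht_dx",
    "ht_months",
    "hist_mi_ever", "hist_mi_1y", "hist_stroke_ever", "hist_stroke_1y",
    "hist_tia_ever", "hist_angina_ever", "hist_angina_1y", "hist_af_ever",
    "hist_diabetes_ever", "hist_pad_ever", "hist_ckd_ever",
    "prior_antihtn", "prior_antihtn_months_since", "prior_antihtn_n_classes",
    "comed_lipid_lowering", "comed_antiplatelet", "comed_antidiabetic",
    "gp_visits_1y", "hosp_days_1y", "prior_followup_days",
)


def run_stages(config: RunConfig, streams: dict | None = None) -> dict:
    """Run one configuration end to end; return all intermediate objects."""
    seeds = np.random.SeedSequence(config.seed).generate_state(4)
    timings, counts = {}, {}

    t0 = time.perf_counter()
    if streams is None:
        gen = dataclasses.replace(config.generator, seed=int(seeds[0] % 2**31))
        streams = generate_population(gen)
    timings["simulate"] = time.perf_counter() - t0
    counts["prescriptions"] = len(streams["prescriptions"])

    t0 = time.perf_counter()
    cohort, attrition = build_cohort(streams, config.eligibility)
    timings["cohort"] = time.perf_counter() - t0
    counts["cohort"] = len(cohort)

    t0 = time.perf_counter()
    exposure = build_exposure(
        cohort, streams["prescriptions"], streams["patients"], config.episode,
        hard_end=config.eligibility.followup_hard_end, mode=config.mode)
    timings["exposure"] = time.perf_counter() - t0
    counts["episodes"] = len(exposure["episodes"])

    t0 = time.perf_counter()
    match_spec = dataclasses.replace(config.match, seed=int(seeds[1] % 2**31))
    results = {}
    for subgroup in config.subgroups:
        results[subgroup] = run_comparison(
            cohort, streams, exposure, PS_COVARIATES, match_spec,
            subgroup=subgroup)
    timings["analyze"] = time.perf_counter() - t0

    return {"streams": streams, "cohort": cohort, "attrition": attrition,
            "exposure": exposure, "results": results,
            "timings": timings, "counts": counts}


def _results_table(results: dict, label: str) -> pd.DataFrame:
    """Flatten the per-subgroup result bundles into one results table."""
    rows = []
    for subgroup, res in results.items():
        if not res.get("estimable", False):
            rows.append({"analysis": label, "subgroup": subgroup,
                         "estimable": False})
            continue
        for endpoint, ir_key, hr_key in (("bp_control", "ir_bp_control",
                                          "hr_bp_control"),
                                         ("mace", "ir_mace", "hr_mace")):
            hr = res[hr_key]
            for arm, ir in res[ir_key].items():
                rows.append({
                    "analysis": label, "subgroup": subgroup, "estimable": True,
                    "endpoint": endpoint,
                    "arm": "two_drug" if arm else "monotherapy",
                    "n": res["n_treated"] if arm else res["n_control"],
                    "events": ir.events,
                    "person_time": round(ir.person_time, 1),
                    "ir_unit": f"per {ir.denominator:g} {ir.unit}",
                    "ir": round(ir.rate, 2),
                    "ir_lo": round(ir.ci_lower, 2),
                    "ir_hi": round(ir.ci_upper, 2),
                    "hr": round(hr.hr, 3) if arm else None,
                    "hr_lo": round(hr.ci_lower, 3) if arm else None,
                    "hr_hi": round(hr.ci_upper, 3) if arm else None,
                })
    return pd.DataFrame(rows)


def run_all(config: RunConfig, outdir=None) -> dict:
    """Execute the base case plus every requested sensitivity variant.

    Writes record streams, cohort, attrition, exposure tables, matches,
    results tables and ``manifest.json`` under ``outdir`` and returns
    {'manifest': ..., 'base': ..., variants...}.
    """
    outdir = Path(outdir if outdir is not None else config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()

    bundle = {}
    t_start = time.perf_counter()
    base = run_stages(config)
    bundle["base"] = base
    tables = {"base": _results_table(base["results"], "base")}

    for variant in config.variants:
        vcfg = config.with_variant(variant)
        logger.info("running sensitivity variant %s", variant)
        # Variants re-use the simulated streams: overrides change analysis
        # parameters only, never the data.
        vres = run_stages(vcfg, streams=base["streams"])
        bundle[variant] = vres
        tables[variant] = _results_table(vres["results"], variant)

    write_streams(base["streams"], outdir / "streams",
                  extra_manifest={"config_hash": cfg_hash})
    cohort_out = base["cohort"].copy()
    cohort_out["initial_classes"] = cohort_out["initial_classes"].map(
        lambda t: "+".join(t))
    write_table(cohort_out, outdir / "cohort.csv")
    write_table(base["attrition"], outdir / "attrition.csv")
    write_table(base["exposure"]["episodes"], outdir / "episodes.csv")
    spells = base["exposure"]["spells"].copy()
    spells["classes"] = spells["classes"].map(lambda t: "+".join(t))
    write_table(spells, outdir / "spells.csv")
    write_table(base["exposure"]["changes"], outdir / "changes.csv")
    write_table(base["exposure"]["followup"], outdir / "followup.csv")
    results_table = pd.concat(tables.values(), ignore_index=True)
    write_table(results_table, outdir / "results.csv")

    manifest = {
        "config_hash": cfg_hash, "seed": config.seed,
        "software_version": __version__,
        "config": config.to_jsonable(),
        "row_counts": {k: v["counts"] for k, v in bundle.items()},
        "wall_time_s": {k: {s: round(t, 3) for s, t in v["timings"].items()}
                        for k, v in bundle.items()},
        "total_wall_time_s": round(time.perf_counter() - t_start, 3),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    bundle["manifest"] = manifest
    bundle["results_table"] = results_table
    return bundle
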