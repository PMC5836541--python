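"""End-to-end orchestration: simulate|demux -> process -> fitness -> glm -> select.

A run is driven by a single config (YAML on disk or a dict) holding stage
parameters — all quality thresholds, g, FDR levels, permutation and bootstrap
counts, and per-stage seeds — and writes every stage artifact plus a JSON
manifest sufficient to reproduce the run.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import glm as glm_mod
from . import processing as proc
from . import selection as sel
from . import synthetic as syn
from .fitness import estimate_fitness, fitness_matrix

PAPER_DEFAULTS = {
    "min_total": 300_000,
    "min_replicate_correlation": 0.5,
    "min_mutant_counts": 2_000,
    "g": 24,
    "fdr_inhomogeneity": 1e-4,
    "n_bootstrap": 1000,
    "n_perm": 1000,
    "mahalanobis_cutoff": 2.0,
    "min_transgressive_support": 3,
    "gate_fraction": 0.40,
    "min_events": 2_000,
    "min_gated_events": 4_000,
}


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        cfg = dict(path_or_dict)
    else:
        with open(path_or_dict) as fh:
            cfg = yaml.safe_load(fh) or {}
    merged = dict(PAPER_DEFAULTS)
    merged.update(cfg)
    return merged


def run_pipeline(config, out_dir) -> dict:
    """Run the stage sequence on simulated (or supplied) counts.

    Returns the manifest (also written to ``out_dir/manifest.json``).
    Deterministic given the config seeds; stages never mutate their inputs.
    """
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "seeds": {}, "config": _jsonable(cfg)}

    sim = cfg.get("simulate", {})
    if "counts" in cfg:
        counts = syn.read_counts_tsv(cfg["counts"])
        sheet = syn.read_sample_sheet_tsv(cfg["samplesheet"])
        neutral = cfg.get("neutral_ids", [])
    else:
        seed = int(sim.get("seed", cfg.get("seed", 0)))
        simcfg = syn.SimConfig(
            n_mutants=int(sim.get("n_mutants", 200)),
            periods=tuple(sim.get("periods", (6,))),
            depth_per_sample=float(sim.get("depth_per_sample", 1e6)),
            nb_dispersion=float(sim.get("nb_dispersion", 0.01)),
            seed=seed,
        )
        truth = syn.TrueParams.random(
            simcfg.n_mutants,
            sd_w=float(sim.get("sd_w", 0.02)),
            frac_inhomogeneous=float(sim.get("frac_inhomogeneous", 0.0)),
            beta3_effect=float(sim.get("beta3_effect", 0.05)),
            seed=seed + 1,
        )
        counts, sheet = syn.simulate_experiment(simcfg, truth)
        neutral = truth.neutral_ids
        syn.write_counts_tsv(counts, out / "counts.tsv")
        syn.write_sample_sheet_tsv(sheet, out / "sample_sheet.tsv")
        manifest["seeds"]["simulate"] = seed
        manifest["stages"]["simulate"] = {
            "n_mutants": simcfg.n_mutants, "n_samples": counts.shape[1]}

    kept, discarded = proc.filter_samples(
        counts, sheet, cfg["min_total"], cfg["min_replicate_correlation"])
    kept = proc.filter_mutants(kept, cfg["min_mutant_counts"])
    norm = proc.normalize(kept, sheet)
    norm.values.to_csv(out / "norm.tsv", sep="\t", index_label="mutant_id")
    manifest["stages"]["process"] = {
        "discarded_samples": discarded,
        "n_mutants": kept.shape[0], "n_samples": kept.shape[1],
        "normalization": norm.method,
    }

    fit_long = estimate_fitness(norm, sheet, neutral, g=cfg["g"])
    fit_long.to_csv(out / "fitness.tsv", sep="\t", index=False)
    manifest["stages"]["fitness"] = {"n_rows": len(fit_long)}

    periods = sorted(
        int(p) for p in sheet.loc[sheet["period_h"] > 0, "period_h"].unique())
    glm_results = {}
    for p in periods:
        res = glm_mod.fit_all_mutants(norm.scaled, sheet, p)
        res.to_csv(out / f"glm_NS{p}.tsv", sep="\t")
        called = glm_mod.call_inhomogeneous(res, cfg["fdr_inhomogeneity"])
        glm_results[p] = {"n_converged": int(res["converged"].sum()),
                          "n_called": len(called)}
    manifest["stages"]["glm"] = glm_results
    manifest["seeds"]["selection"] = int(cfg.get("selection_seed", 7))

    sel_report = _selection_stage(fit_long, periods, cfg,
                                  manifest["seeds"]["selection"], out)
    manifest["stages"]["select"] = sel_report

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _selection_stage(fit_long, periods, cfg, seed, out: Path) -> dict:
    wN = fitness_matrix(fit_long, "N")
    wS = fitness_matrix(fit_long, "S")
    common = wN.index.intersection(wS.index)
    pairs = {
        m: sel.pair_replicates(wN.loc[m].dropna().values,
                               wS.loc[m].dropna().values,
                               seed=seed + i)
        for i, m in enumerate(common)
        if wN.loc[m].notna().sum() >= 2 and wS.loc[m].notna().sum() >= 2
    }
    report: dict = {}
    if len(pairs) >= 3:
        ap = sel.call_AP_table(pairs)
        ap.to_csv(out / "ap_calls.tsv", sep="\t")
        exp_ap, _ = sel.permutation_null_AP(pairs, cfg["n_perm"], seed)
        report["ap"] = {"n_called": int(ap["is_AP"].sum()),
                        "null_expectation": exp_ap}
    if periods:
        p0 = periods[0]
        wNS = fitness_matrix(fit_long, f"NS{p0}")
        common2 = wNS.index.intersection(common)
        d_ns = {m: wNS.loc[m].dropna().values for m in common2}
        d_n = {m: wN.loc[m].dropna().values for m in common2}
        d_s = {m: wS.loc[m].dropna().values for m in common2}
        tg = sel.call_transgressive_table(d_ns, d_n, d_s)
        tg.to_csv(out / "transgressive_calls.tsv", sep="\t")
        exp_tg, _ = sel.permutation_null_transgressivity(
            d_ns, d_n, d_s, cfg["n_perm"], seed)
        report["transgressive"] = {
            "n_called": int((tg["direction"] != "none").sum()),
            "null_expectation": exp_tg,
        }
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
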