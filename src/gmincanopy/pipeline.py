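"""End-to-end pipeline: simulate -> estimate -> fit -> correlate -> integrate.

``run_pipeline`` drives the stages from a YAML/dict config and writes tidy
CSV tables plus run metadata into a run directory.  Stages never mutate each
other's outputs and every numeric table is deterministic for a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import reference
from .canopy import CanopySpec, scenario_sweep, sweep_to_frame
from .drydown import aggregate_gmin, conductance_curve, estimate_gmin
from .report import conductance_report, emin_report, group_summary
from .simulate import (
    ClimateSimParams,
    DrydownSimParams,
    TraitSimParams,
    climate_from_extremes,
    simulate_diurnal_climate,
    simulate_drydown,
    simulate_trait_table,
)
from .temperature import fit_exponential, fit_segmented
from .traits import correlate_traits

__all__ = ["run_pipeline", "default_config", "PipelineError"]

log = logging.getLogger("gmincanopy")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def default_config(seed: int = 0) -> dict:
    """All-synthetic demo configuration exercising every stage."""
    return {
        "seed": seed,
        "stages": ["drydown", "temperature", "traits", "canopy"],
        "drydown": {
            "n_species": 3,
            "n_trees": 3,
            "n_leaves": 4,
            "gmin_range": [1.0, 5.0],
            "rwc_window": [0.50, 0.80],
            "pressure_kPa": 98.0,
        },
        "temperature": {
            "a": 0.5,
            "b": 0.06,
            "temperatures": [25, 30, 35, 37, 43, 45, 48, 50],
            "n_rep": 3,
            "noise_cv": 0.10,
            "bootstrap": 0,
        },
        "traits": {"n_species": 9, "noise_scale": 0.15},
        "canopy": {
            "t_max": reference.HOT_DAY_T_MAX_C,
            "rh_min": reference.HOT_DAY_RH_MIN_PCT,
            "t_min": 17.0,
            "pressure_kPa": 94.9,
            "sweep_step": 0.1,
            "t_cap": 50.0,
            "use_reference_species": True,
        },
    }


def _stage_drydown(cfg: dict, seed: int, outdir: Path) -> pd.DataFrame:
    c = cfg["drydown"]
    rng = np.random.default_rng(seed)
    lo, hi = c["gmin_range"]
    rows = []
    for si in range(c["n_species"]):
        species = f"species{si+1}"
        true_g = float(rng.uniform(lo, hi))
        for ti in range(c["n_trees"]):
            for li in range(c["n_leaves"]):
                leaf_seed = int(rng.integers(0, 2**31 - 1))
                rec = simulate_drydown(
                    replace(DrydownSimParams(true_gmin=true_g), seed=leaf_seed),
                    sample_id=f"{species}-t{ti+1}-l{li+1}",
                    species=species,
                    tree_id=f"{species}-t{ti+1}",
                )
                est = estimate_gmin(
                    conductance_curve(rec, pressure=c["pressure_kPa"]),
                    window=tuple(c["rwc_window"]),
                    species=species,
                    tree_id=rec.tree_id,
                )
                rows.append(
                    {
                        "sample_id": est.sample_id,
                        "species": species,
                        "tree_id": est.tree_id,
                        "true_gmin": true_g,
                        "gmin": est.gmin,
                        "n_intervals": est.n_intervals_used,
                        "plateau_slope": est.plateau_slope,
                    }
                )
    est_table = pd.DataFrame(rows)
    est_table.to_csv(outdir / "gmin_estimates.csv", index=False)
    agg = aggregate_gmin(est_table)
    agg["tree"].to_csv(outdir / "gmin_by_tree.csv", index=False)
    agg["species"].to_csv(outdir / "gmin_by_species.csv", index=False)
    return est_table


def _stage_temperature(cfg: dict, seed: int, outdir: Path) -> pd.DataFrame:
    c = cfg["temperature"]
    rng = np.random.default_rng(seed + 1)
    temps = np.repeat(np.asarray(c["temperatures"], dtype=float), c["n_rep"])
    truth = c["a"] * np.exp(c["b"] * temps)
    g = truth * rng.lognormal(0.0, c["noise_cv"], temps.size)
    fit = fit_exponential(temps, g)
    seg = fit_segmented(temps, g, n_boot=c.get("bootstrap", 0), seed=seed + 2)
    out = pd.DataFrame(
        [
            {
                "model": "exponential",
                "a": fit.a,
                "b": fit.b,
                "n": fit.n,
                "rss": fit.rss,
            },
            {
                "model": "segmented",
                "t_break": seg.t_break,
                "slope_low": seg.slope_low,
                "slope_high": seg.slope_high,
                "p_value": seg.p_value,
                "n": seg.n,
            },
        ]
    )
    out.to_csv(outdir / "temperature_fits.csv", index=False)
    return out


def _stage_traits(cfg: dict, seed: int, outdir: Path) -> pd.DataFrame:
    c = cfg["traits"]
    table = simulate_trait_table(
        TraitSimParams(n_species=c["n_species"], noise_scale=c["noise_scale"], seed=seed + 3)
    )
    table.to_csv(outdir / "trait_table.csv", index=False)
    corr = correlate_traits(
        table,
        trait_cols=["stomatal_density", "stomatal_size", "g_max", "ct_total", "sla"],
    )
    corr.to_csv(outdir / "trait_correlations.csv", index=False)
    return corr


def _stage_canopy(cfg: dict, seed: int, outdir: Path) -> pd.DataFrame:
    c = cfg["canopy"]
    climate = climate_from_extremes(
        t_max=c["t_max"], rh_min=c["rh_min"], t_min=c["t_min"], pressure=c["pressure_kPa"]
    )
    climate.to_frame().to_csv(outdir / "climate_base_day.csv", index=False)
    if c.get("use_reference_species", True):
        species = reference.species_conductance_table().merge(
            reference.canopy_scaling_table(), on="species"
        )
        models = {r["species"]: float(r["gmin"]) for _, r in species.iterrows()}
        r_ratios = {r["species"]: float(r["r_ratio"]) for _, r in species.iterrows()}
    else:
        models = dict(c["species_gmin"])
        r_ratios = dict(c["species_r"])
    frames = []
    for sp, g in models.items():
        results = scenario_sweep(
            g,
            climate,
            CanopySpec(species=sp, r_ratio=r_ratios[sp]),
            step=c["sweep_step"],
            t_cap=c["t_cap"],
        )
        frames.append(sweep_to_frame(results))
    sweep = pd.concat(frames, ignore_index=True)
    sweep.to_csv(outdir / "emin_sweep.csv", index=False)
    emin_report(sweep).to_csv(outdir / "emin_report.csv", index=False)
    return sweep


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> Path:
    """Run the configured stages; returns the run directory.

    ``config`` may be a dict or a path to a YAML file.  Outputs: one tidy CSV
    per stage product, a formatted conductance report when the drydown stage
    runs, and ``run_metadata.json`` with the seed, config hash and stage
    timings.  A stage failure aborts with :class:`PipelineError` naming the
    stage; earlier outputs are retained.
    """
    if isinstance(config, (str, Path)):
        path = Path(config)
        if not path.exists():
            raise PipelineError(f"config file not found: {path}")
        config = yaml.safe_load(path.read_text())
    cfg = default_config()
    for key, val in config.items():
        if isinstance(val, dict) and key in cfg:
            cfg[key] = {**cfg[key], **val}
        else:
            cfg[key] = val

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]

    stage_fns = {
        "drydown": _stage_drydown,
        "temperature": _stage_temperature,
        "traits": _stage_traits,
        "canopy": _stage_canopy,
    }
    timings = {}
    products: dict[str, pd.DataFrame] = {}
    for stage in cfg["stages"]:
        if stage not in stage_fns:
            raise PipelineError(f"unknown stage '{stage}'")
        t0 = time.perf_counter()
        log.info("stage %s starting", stage)
        try:
            products[stage] = stage_fns[stage](cfg, seed, outdir)
        except Exception as err:
            raise PipelineError(f"stage '{stage}' failed: {err}") from err
        timings[stage] = round(time.perf_counter() - t0, 3)
        log.info("stage %s done in %.2fs", stage, timings[stage])

    if "drydown" in products:
        est = products["drydown"]
        species_means = (
            est.groupby("species", as_index=False)
            .agg(gmin=("gmin", "mean"))
            .assign(gmax=np.nan, group="synthetic")
        )
        conductance_report(species_means).to_csv(
            outdir / "conductance_report.csv", index=False
        )

    (outdir / "run_metadata.json").write_text(
        json.dumps(
            {
                "seed": seed,
                "config_sha256": cfg_hash,
                "stages": list(cfg["stages"]),
                "timings_s": timings,
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            indent=2,
        )
    )
    return outdir
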