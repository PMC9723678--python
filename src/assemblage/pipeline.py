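"""Pipeline orchestration: simulate -> normalise -> diversity -> similarity
-> fit -> classify -> report, driven by a single YAML-able configuration
with seeded reproducibility and provenance headers on every artifact."""

from __future__ import annotations

import copy
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._utils import ValidationError, config_hash, logger
from .beta import (read_similarity_records, replicate_similarity_series,
                   write_similarity_records)
from .classify import format_report, make_assembly_calls
from .counts import (filter_samples, hill_profile, read_count_table,
                     read_metadata, rarefy_mean, write_count_table,
                     write_metadata)
from .model import (MCMCConfig, ModelSpec, derive_group_slopes,
                    fit_distributional_model, group_slopes_from_dataframe,
                    prepare_model_data)
from .simulate import (DEFAULT_REGIMES, DEFAULT_SAMPLING_DAYS, DesignSpec,
                       ReadDepthModel, default_schedules, neutral_community,
                       scenario_bloom_rate, selection_community,
                       simulate_experiment)

STAGES = ("simulate", "normalize", "diversity", "similarity", "fit",
          "classify", "report")

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "outdir": "assemblage_run",
    "simulation": {
        "scenario": "neutral",          # neutral | selection
        "n_taxa": 400,
        "total_abundance": 1e6,
        "growth_rate": 2.5,             # day^-1
        "growth_rate_cv": 0.2,          # selection scenario only
        "fitness_abundance_corr": 0.95, # selection scenario only
        "sad_sigma": 2.0,
        "regimes": list(DEFAULT_REGIMES),
        "replicates_per_regime": 3,
        "sampling_days": list(DEFAULT_SAMPLING_DAYS),
        "inoculum_samples": 2,
        "k_low": 1e6,
        "k_high": 5e6,
        "continuous_dilution_rate": 1.0,
        "pulse_fraction": 0.02,
        "pulse_interval": 2.0,
        "crossover_day": 28.0,
        "total_days": 50.0,
        "step": 0.05,
        "env_noise_sd": 0.02,
        "env_noise_tau": 14.0,
        "overdispersion_sd": 0.6,
        "bloom_rate": None,   # per-scenario default: 0.01 neutral, 0 selection
        "bloom_sd": 1.0,
        "depth_mean": 63460.0,
        "depth_sd": 31411.0,
        "depth_min": 10000,
    },
    "normalisation": {"depth": 10000, "n_rep": 1000},
    "filtering": {"exclude_first_day": True, "exclude_rule": None},
    "similarity": {"indices": ["bray_curtis", "sorensen"]},
    "model": {
        "chains": 4,
        "iterations_per_chain": 4000,
        "warmup": 2000,
        "target_acceptance": 0.99,
        "periods": [1, 2],
        "rhat_action": "raise",
        "sigma_link": "log",
    },
    "classification": {},
}


def _merge(defaults: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, val in (override or {}).items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ValidationError(f"unknown configuration key: {here}")
        if isinstance(defaults[key], dict) and not isinstance(val, dict):
            raise ValidationError(f"configuration key {here} must be a mapping")
        out[key] = _merge(defaults[key], val, here) if isinstance(defaults[key], dict) else val
    return out


def default_config() -> dict:
    return copy.deepcopy(DEFAULT_CONFIG)


def load_config(path: str | Path | None) -> dict:
    """Merge a YAML config file over the defaults (validating key paths)."""
    if path is None:
        return default_config()
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return _merge(DEFAULT_CONFIG, user)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _provenance(cfg: dict) -> str:
    return (f"assemblage v{__version__} config_hash={config_hash(cfg)} "
            f"seed={cfg['seed']}")


def _need(ctx: dict, key: str, loader, stage_hint: str):
    if key in ctx:
        return ctx[key]
    try:
        value = loader()
    except FileNotFoundError as exc:
        raise ValidationError(
            f"missing upstream artifact {exc.filename}; run stage {stage_hint!r} first"
        ) from exc
    ctx[key] = value
    return value


def _stage_simulate(cfg, outdir, ctx, prov):
    sim = cfg["simulation"]
    seed = int(cfg["seed"])
    kwargs = dict(n_taxa=int(sim["n_taxa"]), total_abundance=float(sim["total_abundance"]),
                  growth_rate=float(sim["growth_rate"]), sad_sigma=float(sim["sad_sigma"]),
                  seed=seed)
    if sim["scenario"] == "selection":
        taxa = selection_community(
            growth_rate_cv=float(sim["growth_rate_cv"]),
            fitness_abundance_corr=float(sim["fitness_abundance_corr"]), **kwargs)
    elif sim["scenario"] == "neutral":
        taxa = neutral_community(**kwargs)
    else:
        raise ValidationError(f"unknown scenario {sim['scenario']!r}")
    sched_kwargs = dict(
        continuous_dilution_rate=float(sim["continuous_dilution_rate"]),
        pulse_fraction=float(sim["pulse_fraction"]),
        pulse_interval=float(sim["pulse_interval"]),
        crossover_day=float(sim["crossover_day"]),
        total_days=float(sim["total_days"]),
    )
    schedules = default_schedules(tuple(sim["regimes"]), k_low=float(sim["k_low"]),
                                  k_high=float(sim["k_high"]), **sched_kwargs)
    spec = DesignSpec(
        regimes=tuple(sim["regimes"]),
        replicates_per_regime=int(sim["replicates_per_regime"]),
        sampling_days=tuple(sim["sampling_days"]),
        inoculum_samples=int(sim["inoculum_samples"]),
        crossover_day=float(sim["crossover_day"]),
        reads_per_sample=ReadDepthModel(float(sim["depth_mean"]),
                                        float(sim["depth_sd"]),
                                        int(sim["depth_min"])),
    )
    bloom_rate = sim["bloom_rate"]
    if bloom_rate is None:
        bloom_rate = scenario_bloom_rate(sim["scenario"])
    table, metadata = simulate_experiment(
        spec, taxa, schedules, seed=seed, step=float(sim["step"]),
        env_noise_sd=float(sim["env_noise_sd"]),
        env_noise_tau=float(sim["env_noise_tau"]),
        bloom_rate=float(bloom_rate), bloom_sd=float(sim["bloom_sd"]),
        overdispersion_sd=float(sim["overdispersion_sd"]))
    write_count_table(table, outdir / "counts.tsv", prov)
    write_metadata(metadata, outdir / "metadata.csv", prov)
    ctx["counts"], ctx["metadata"] = table, metadata
    logger.info("simulate: wrote %d taxa x %d samples", *table.shape)


def _stage_normalize(cfg, outdir, ctx, prov):
    table = _need(ctx, "counts", lambda: read_count_table(outdir / "counts.tsv"), "simulate")
    norm = cfg["normalisation"]
    normalized = rarefy_mean(table, depth=int(norm["depth"]), n_rep=int(norm["n_rep"]),
                             seed=int(cfg["seed"]) + 1)
    write_count_table(normalized, outdir / "normalized.tsv", prov)
    ctx["normalized"] = normalized


def _filtered(cfg, outdir, ctx):
    normalized = _need(ctx, "normalized",
                       lambda: read_count_table(outdir / "normalized.tsv"), "normalize")
    metadata = _need(ctx, "metadata",
                     lambda: read_metadata(outdir / "metadata.csv"), "simulate")
    metadata = metadata[metadata["sample_id"].isin(normalized.samples)].reset_index(drop=True)
    rule = cfg["filtering"].get("exclude_rule")
    if rule is None and cfg["filtering"].get("exclude_first_day"):
        days = metadata.loc[metadata["regime_code"] != "inoculum", "day"]
        rule = f"day == {days.min()} and regime_code != 'inoculum'"
    if rule:
        normalized, metadata = filter_samples(normalized, metadata, rule)
    return normalized, metadata


def _stage_diversity(cfg, outdir, ctx, prov):
    normalized = _need(ctx, "normalized",
                       lambda: read_count_table(outdir / "normalized.tsv"), "normalize")
    profile = hill_profile(normalized)
    with open(outdir / "diversity.csv", "w") as fh:
        fh.write(f"# {prov}\n")
        profile.to_csv(fh)
    ctx["diversity"] = profile


def _stage_similarity(cfg, outdir, ctx, prov):
    normalized, metadata = _filtered(cfg, outdir, ctx)
    frames = [replicate_similarity_series(normalized, metadata, index)
              for index in cfg["similarity"]["indices"]]
    records = pd.concat(frames, ignore_index=True)
    write_similarity_records(records, outdir / "similarity.csv", prov)
    ctx["similarity"] = records


def _stage_fit(cfg, outdir, ctx, prov):
    records = _need(ctx, "similarity",
                    lambda: read_similarity_records(outdir / "similarity.csv"),
                    "similarity")
    m = cfg["model"]
    spec = ModelSpec(sigma_link=m["sigma_link"])
    config = MCMCConfig(chains=int(m["chains"]),
                        iterations_per_chain=int(m["iterations_per_chain"]),
                        warmup=int(m["warmup"]),
                        target_acceptance=float(m["target_acceptance"]),
                        seed=int(cfg["seed"]) + 2)
    slopes_all = {}
    for index in cfg["similarity"]["indices"]:
        sub = records[records["index"] == index]
        for period in m["periods"]:
            data = prepare_model_data(sub, period=int(period), spec=spec)
            fit = fit_distributional_model(data, spec, config,
                                           rhat_action=m["rhat_action"])
            tag = f"{index}_period{period}"
            with open(outdir / f"posterior_{tag}.csv", "w") as fh:
                fh.write(f"# {prov}\n")
                fit.to_dataframe().to_csv(fh, index=False)
            with open(outdir / f"diagnostics_{tag}.json", "w") as fh:
                json.dump({
                    "provenance": prov,
                    "max_rhat": float(fit.diagnostics["rhat"].max()),
                    "min_ess_bulk": float(fit.diagnostics["ess_bulk"].min()),
                    "n_divergences": fit.n_divergences,
                    "retained_draws": fit.n_retained,
                }, fh, indent=2)
            slopes = derive_group_slopes(fit)
            with open(outdir / f"slopes_{tag}.csv", "w") as fh:
                fh.write(f"# {prov}\n")
                slopes.summary().to_csv(fh, index=False)
            slopes_all[tag] = slopes
    ctx["slopes"] = slopes_all


def _load_slopes_from_disk(cfg, outdir):
    slopes_all = {}
    m = cfg["model"]
    for index in cfg["similarity"]["indices"]:
        for period in m["periods"]:
            tag = f"{index}_period{period}"
            path = outdir / f"posterior_{tag}.csv"
            if not path.exists():
                raise ValidationError(
                    f"missing upstream artifact {path}; run stage 'fit' first")
            df = pd.read_csv(path, comment="#")
            slopes_all[tag] = group_slopes_from_dataframe(
                df, period=int(period), index=index, sigma_link=m["sigma_link"])
    return slopes_all


def _stage_classify(cfg, outdir, ctx, prov):
    slopes_all = ctx.get("slopes") or _load_slopes_from_disk(cfg, outdir)
    ctx["slopes"] = slopes_all
    calls = pd.concat([make_assembly_calls(s) for s in slopes_all.values()],
                      ignore_index=True)
    with open(outdir / "calls.csv", "w") as fh:
        fh.write(f"# {prov}\n")
        calls.to_csv(fh, index=False)
    ctx["calls"] = calls


def _stage_report(cfg, outdir, ctx, prov):
    calls = _need(ctx, "calls",
                  lambda: pd.read_csv(outdir / "calls.csv", comment="#"), "classify")
    text = f"# {prov}\n\n" + format_report(calls)
    (outdir / "report.txt").write_text(text)
    ctx["report"] = text


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "normalize": _stage_normalize,
    "diversity": _stage_diversity,
    "similarity": _stage_similarity,
    "fit": _stage_fit,
    "classify": _stage_classify,
    "report": _stage_report,
}


def run_pipeline(config: dict | None = None, stages=("all",),
                 outdir: str | Path | None = None) -> dict:
    """Execute the requested stages in canonical order; returns the context
    with all in-memory artifacts plus the output directory."""
    cfg = _merge(DEFAULT_CONFIG, config or {})
    out = Path(outdir or cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)

    if "all" in stages:
        selected = list(STAGES)
    else:
        unknown = [s for s in stages if s not in STAGES]
        if unknown:
            raise ValidationError(f"unknown stage(s): {unknown}; choose from {STAGES}")
        selected = [s for s in STAGES if s in stages]

    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    prov = _provenance(cfg)
    ctx: dict = {"outdir": out, "config": cfg}
    try:
        logger.info("run: %s | stages=%s", prov, selected)
        for stage in selected:
            logger.info("stage %s: start", stage)
            _STAGE_FUNCS[stage](cfg, out, ctx, prov)
            logger.info("stage %s: done", stage)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return ctx


def run_scenario_benchmark(scenario: str, seed: int, n_rep: int = 250,
                           chains: int = 2, iterations_per_chain: int = 1200,
                           warmup: int = 400,
                           index: str = "bray_curtis") -> pd.DataFrame:
    """One seeded end-to-end run of a study scenario, returning the
    assembly-call table for cultivation period 1.

    Simulates the full 2 x 2 factorial design under the named scenario
    ('neutral' or 'selection'), rarefaction-averages to 10,000 reads,
    removes the first sampling day, builds the replicate-similarity series,
    fits the distributional model for period 1 at reduced MCMC settings and
    classifies every disturbance x capacity group.
    """
    from .beta import replicate_similarity_series
    from .classify import make_assembly_calls
    from .counts import filter_samples, rarefy_mean
    from .model import (MCMCConfig, derive_group_slopes,
                        fit_distributional_model, prepare_model_data)

    if scenario == "neutral":
        taxa = neutral_community(seed=seed)
    elif scenario == "selection":
        taxa = selection_community(seed=seed)
    else:
        raise ValidationError(f"unknown scenario {scenario!r}")
    table, md = simulate_experiment(
        DesignSpec(), taxa, default_schedules(), seed=seed,
        bloom_rate=scenario_bloom_rate(scenario))
    norm = rarefy_mean(table, depth=10_000, n_rep=n_rep, seed=seed)
    md = md[md["sample_id"].isin(norm.samples)].reset_index(drop=True)
    norm, md = filter_samples(norm, md,
                              "day == 2 and regime_code != 'inoculum'")
    records = replicate_similarity_series(norm, md, index)
    data = prepare_model_data(records, period=1)
    fit = fit_distributional_model(
        data, config=MCMCConfig(chains=chains,
                                iterations_per_chain=iterations_per_chain,
                                warmup=warmup, seed=seed),
        rhat_action="ignore")
    return make_assembly_calls(derive_group_slopes(fit))


__all__ = ["STAGES", "DEFAULT_CONFIG", "default_config", "load_config",
           "run_pipeline", "run_scenario_benchmark"]
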