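"""End-to-end orchestration: simulate → classify → flow → quantify → profile → model.

A run is described by one YAML/dict configuration with per-stage parameter
blocks and a single global seed, which expands deterministically into
per-stage seeds so that one number reproduces a whole study.  Each stage
writes its artifacts into the output directory and records its status in a
JSON manifest keyed by the configuration hash; identical configurations
produce identical outputs.  A failing stage is recorded with its error and
all downstream stages are skipped.
"""

from __future__ import annotations

import hashlib
import json
import traceback
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .biomass import (
    biomass_timeseries,
    colony_mass_pdf,
    detect_clusters_stack,
    preprocess_stack,
    retention_curve,
)
from .flow import FlowConfig, shear_rate, solve_stokes
from .geometry import discretize, pore_stats
from .io import (
    read_mask,
    write_dep_records,
    write_json,
    write_label_map,
    write_mask,
    write_stack,
    write_velocity,
)
from .qsmodel import (
    ModelParams,
    extract_zeta_sim,
    predict_zeta_scaling,
    solve_coupled_model,
)
from .reporter import dep_depth_profile, extract_front, normalize_activity
from .synthetic import (
    GeometryParams,
    generate_biomass_stack,
    generate_geometry,
    generate_reporter_stack,
)

__all__ = ["ConfigError", "STAGES", "expand_seeds", "run_pipeline"]

STAGES = ("simulate", "classify", "flow", "quantify", "profile", "model", "report")


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def expand_seeds(seed: int) -> dict[str, int]:
    """Expand one global seed into per-stage seeds (all below 2³¹)."""
    state = np.random.SeedSequence(seed).generate_state(4)
    names = ("geometry", "biomass", "reporter", "tracer")
    return {k: int(s & 0x7FFFFFFF) for k, s in zip(names, state)}


def _validate(config: dict) -> None:
    if "mask" not in config and "geometry" not in config:
        raise ConfigError(
            "configuration needs a 'geometry' block (synthetic scene) or a "
            "'mask' block (measured mask image); both are missing"
        )


def run_pipeline(
    config: dict,
    outdir: str | Path,
    stages: tuple[str, ...] | None = None,
    dry_run: bool = False,
) -> dict:
    """Execute the requested stages in dependency order and write a manifest."""
    _validate(config)
    stages = tuple(stages or STAGES)
    for s in stages:
        if s not in STAGES:
            raise ConfigError(f"unknown stage '{s}'; valid stages: {STAGES}")
    outdir = Path(outdir)
    seed = int(config.get("seed", 0))
    seeds = expand_seeds(seed)
    manifest: dict = {
        "scenario": config.get("scenario", "unnamed"),
        "version": __version__,
        "config_hash": config_hash(config),
        "seed": seed,
        "stage_seeds": seeds,
        "stages": {},
        "outputs": [],
    }
    if dry_run:
        manifest["dry_run"] = True
        return manifest
    outdir.mkdir(parents=True, exist_ok=True)

    ctx: dict = {}
    failed = False
    for stage in STAGES:
        if stage not in stages:
            continue
        if failed:
            manifest["stages"][stage] = {"status": "skipped"}
            continue
        try:
            outputs = _run_stage(stage, config, seeds, ctx, outdir)
            manifest["stages"][stage] = {"status": "ok"}
            manifest["outputs"].extend(outputs)
        except Exception as exc:  # noqa: BLE001 - recorded in the manifest
            manifest["stages"][stage] = {
                "status": "failed",
                "error": f"{type(exc).__name__}: {exc}",
                "traceback": traceback.format_exc(limit=5),
            }
            failed = True
    write_json(outdir / "manifest.json", manifest)
    return manifest


def _get_mask(config: dict, seeds: dict, ctx: dict, outdir: Path):
    if "mask_obj" in ctx:
        return ctx["mask_obj"], ctx.get("truth")
    if "mask" in config:
        m = read_mask(config["mask"]["path"], config["mask"]["pixel_size"])
        ctx["mask_obj"] = m
        return m, None
    geo = dict(config.get("geometry", {}))
    geo.setdefault("seed", seeds["geometry"])
    if "domain_size_px" in geo:
        geo["domain_size_px"] = tuple(geo["domain_size_px"])
    params = GeometryParams(**geo)
    mask, truth = generate_geometry(params)
    ctx["mask_obj"], ctx["truth"] = mask, truth
    return mask, truth


def _run_stage(stage, config, seeds, ctx, outdir: Path) -> list[str]:
    out: list[str] = []

    if stage == "simulate":
        mask, truth = _get_mask(config, seeds, ctx, outdir)
        write_mask(outdir / "mask.png", mask)
        out.append("mask.png")
        if truth is not None:
            write_label_map(outdir / "label_map_truth.png", truth.true_label_map)
            out.append("label_map_truth.png")
        bio = dict(config.get("biomass", {}))
        times = np.asarray(bio.get("times", np.arange(13) * 600.0), dtype=float)
        ratio = bio.get("ratio_curve")
        if ratio is None:
            ratio = np.concatenate([[0.0], np.linspace(1.0, 2.5, len(times) - 1)])
        lmap = truth.true_label_map if truth is not None else None
        if lmap is None:
            raise ConfigError("simulate stage needs a synthetic geometry block")
        stack, btruth = generate_biomass_stack(
            lmap,
            times,
            ratio,
            tp_mean=bio.get("tp_mean", 3000.0),
            mode=bio.get("mode", "uniform"),
            n_spots_per_dep=bio.get("n_spots_per_dep", 0),
            noise_sigma=bio.get("noise_sigma", 0.0),
            seed=seeds["biomass"],
        )
        ctx["biomass_stack"], ctx["biomass_truth"] = stack, btruth
        write_stack(outdir / "brightfield.tif", stack)
        out += ["brightfield.tif", "brightfield.times.csv"]
        rep = dict(config.get("reporter", {}))
        if rep and truth is not None:
            gfp, rtruth = generate_reporter_stack(
                lmap,
                stack,
                btruth,
                truth.cavities,
                front_depth_mm=rep.get("front_depth_mm", 0.1),
                steepness_um=rep.get("steepness_um", 5.0),
                noise_sigma=rep.get("noise_sigma", 0.0),
                seed=seeds["reporter"],
            )
            ctx["reporter_stack"], ctx["reporter_truth"] = gfp, rtruth
            write_stack(outdir / "gfp.tif", gfp)
            out += ["gfp.tif", "gfp.times.csv"]
        return out

    if stage == "classify":
        mask, _ = _get_mask(config, seeds, ctx, outdir)
        lmap, skel, disks, grains = discretize(mask)
        ctx.update(lmap=lmap, skel=skel, disks=disks, grains=grains)
        write_label_map(outdir / "mapped_mask.png", lmap)
        write_dep_records(outdir / "dep_records.csv", lmap)
        stats = pore_stats(lmap, skel, disks)
        pd.DataFrame(
            [
                {
                    "porosity": stats.porosity,
                    "lambda_m_um": stats.lambda_m,
                    "dep_volume_fraction": stats.dep_volume_fraction,
                    "n_deps": len(stats.dep_depths_mm),
                    "mean_dep_depth_mm": float(stats.dep_depths_mm.mean())
                    if len(stats.dep_depths_mm)
                    else np.nan,
                }
            ]
        ).to_csv(outdir / "pore_stats.csv", index=False)
        return ["mapped_mask.png", "dep_records.csv", "pore_stats.csv"]

    if stage == "flow":
        mask, _ = _get_mask(config, seeds, ctx, outdir)
        fl = dict(config.get("flow", {}))
        cfg = FlowConfig(Q=fl.get("Q", 0.1), h=fl.get("h", 0.05))
        field = solve_stokes(mask, cfg, target_u_m=fl.get("target_u_m"))
        ctx["velocity"] = field
        write_velocity(outdir / "velocity.tif", field, shear=shear_rate(field, cfg))
        return ["velocity.tif", "velocity.summary.csv"]

    if stage == "quantify":
        if "biomass_stack" not in ctx:
            raise ConfigError("quantify requires the simulate stage (no stack in context)")
        lmap = ctx.get("lmap") or ctx["truth"].true_label_map
        corrected = preprocess_stack(ctx["biomass_stack"], lmap)
        ctx["corrected"] = corrected
        rc = retention_curve(corrected, lmap)
        rc.to_csv(outdir / "retention_curve.csv", index=False)
        ts = biomass_timeseries(corrected, lmap)
        ts.to_csv(outdir / "biomass_series.csv", index=False)
        clusters = detect_clusters_stack(corrected, lmap)
        clusters.to_csv(outdir / "clusters.csv", index=False)
        outs = ["retention_curve.csv", "biomass_series.csv", "clusters.csv"]
        if not clusters.empty:
            colony_mass_pdf(clusters).to_csv(outdir / "colony_mass_pdf.csv", index=False)
            outs.append("colony_mass_pdf.csv")
        return outs

    if stage == "profile":
        if "reporter_stack" not in ctx:
            return []  # nothing to profile in this scenario
        lmap = ctx.get("lmap") or ctx["truth"].true_label_map
        if "skel" not in ctx:
            raise ConfigError("profile requires the classify stage")
        corrected = ctx.get("corrected")
        if corrected is None:
            corrected = preprocess_stack(ctx["biomass_stack"], lmap)
        rep_corr = preprocess_stack(ctx["reporter_stack"], lmap)
        floor = config.get("reporter", {}).get("biomass_floor", 10.0)
        rows, fronts = [], []
        for fi in range(1, corrected.n_frames):
            amap = normalize_activity(rep_corr.frames[fi], corrected.frames[fi], floor)
            profs = dep_depth_profile(
                amap,
                ctx["lmap"],
                ctx["skel"],
                ctx["disks"],
                biomass_frame=corrected.frames[fi],
                time_s=corrected.times[fi],
            )
            for p in profs:
                for s, a, b in zip(p.s_um, p.activity, p.biomass):
                    rows.append(
                        {
                            "time_s": p.time_s,
                            "dep_id": p.dep_id,
                            "s_um": s,
                            "activity": a,
                            "biomass": b,
                        }
                    )
                fp = extract_front(p)
                fronts.append(
                    {
                        "dep_id": fp.dep_id,
                        "time_s": fp.time_s,
                        "zeta_mm": fp.zeta_mm,
                        "defined": fp.defined,
                    }
                )
        pd.DataFrame(rows).to_csv(outdir / "profiles.csv", index=False)
        pd.DataFrame(fronts).to_csv(outdir / "fronts.csv", index=False)
        return ["profiles.csv", "fronts.csv"]

    if stage == "model":
        mp = dict(config.get("model", {}))
        c_B = mp.pop("c_B", 0.03)
        t_end = mp.pop("t_end", 600.0)
        params = ModelParams(**mp)
        save = np.linspace(t_end / 5, t_end, 5)
        sol = solve_coupled_model(params, c_B, t_end=t_end, save_times=save)
        rows = []
        for ti, t in enumerate(sol.times):
            for xi, xv in enumerate(sol.x):
                rows.append(
                    {
                        "t_s": t,
                        "x_mm": xv,
                        "c_G_mM": sol.c_G[ti, xi],
                        "c_AI2": sol.c_AI2[ti, xi],
                        "lsrR": sol.lsrR[ti, xi],
                    }
                )
        pd.DataFrame(rows).to_csv(outdir / "model_solution.csv", index=False)
        dl = predict_zeta_scaling(params, c_B)
        zrows = [
            {
                "t_s": t,
                "zeta_sim_mm": extract_zeta_sim(sol, t),
                "zeta_scaling_mm": dl.zeta_scaling,
                "tau_U_s": dl.tau_U,
            }
            for t in sol.times
        ]
        pd.DataFrame(zrows).to_csv(outdir / "zeta.csv", index=False)
        return ["model_solution.csv", "zeta.csv"]

    if stage == "report":
        written = sorted(p.name for p in outdir.iterdir() if p.is_file())
        write_json(outdir / "report.json", {"files": written})
        return ["report.json"]

    raise ConfigError(f"unknown stage {stage}")
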