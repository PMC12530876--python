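"""End-to-end workflow: sample -> evaluate -> preprocess -> train -> optimize -> verify.

Ties the stages together from a single YAML-style configuration, writes every
intermediate artifact as delimited text, and records a manifest (stage,
outputs, content hashes, seeds, wall time) so a run can be replayed exactly.
Two shipped presets: ``paper`` (full-scale sample sizes, 19 ratios, 50 seeds)
and ``desk`` (reduced scale for interactive use).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import harness, surrogates
from .conformers import make_conformer_fixture
from .data import DensityDataset, preprocess, read_dataset, write_dataset
from .errors import ConfigError, StageError
from .oracle import OracleConfig, evaluate_samples
from .optimizer import (
    OptimizationTargets,
    OptimizerConfig,
    optimize,
    verify,
)
from .space import (
    LJ_PARAM_NAMES,
    GridSpec,
    LJParamSet,
    ParameterSpace,
    make_grid,
    make_sobol,
)

STAGES = ("sample", "evaluate", "preprocess", "train", "select", "optimize")


def load_config(source: "str | Path | dict") -> dict:
    """Load a run configuration from YAML (path or mapping)."""
    if isinstance(source, dict):
        cfg = source
    else:
        with open(source) as fh:
            cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("configuration must be a mapping")
    for key in ("sampling", "oracle", "harness", "optimizer"):
        if key not in cfg:
            raise ConfigError(f"configuration missing required block {key!r}")
    return cfg


def load_preset(name: str) -> dict:
    """Load one of the shipped presets ('paper' or 'desk')."""
    ref = resources.files("smaopt").joinpath(f"presets/{name}.yaml")
    if not ref.is_file():
        raise ConfigError(f"unknown preset {name!r}")
    with ref.open() as fh:
        return yaml.safe_load(fh)


def _space_from_bounds(bounds: dict) -> ParameterSpace:
    lower = tuple(float(bounds[n][0]) for n in LJ_PARAM_NAMES)
    upper = tuple(float(bounds[n][1]) for n in LJ_PARAM_NAMES)
    return ParameterSpace(LJ_PARAM_NAMES, lower, upper)


def build_designs(sampling_cfg: dict, global_seed: int) -> dict[str, np.ndarray]:
    """Materialize every configured design as an (n, 4) point array."""
    designs = {}
    for entry in sampling_cfg.get("designs", []):
        name, kind = entry["name"], entry["kind"]
        if kind == "grid":
            axes = entry["axes"]
            spec = GridSpec(
                names=LJ_PARAM_NAMES,
                minima=tuple(float(axes[n][0]) for n in LJ_PARAM_NAMES),
                steps=tuple(float(axes[n][1]) for n in LJ_PARAM_NAMES),
                maxima=tuple(float(axes[n][2]) for n in LJ_PARAM_NAMES),
            )
            designs[name] = make_grid(spec)
        elif kind == "sobol":
            space = _space_from_bounds(entry["bounds"])
            scramble = entry.get("scramble_seed")
            if scramble == "derive":
                scramble = _stage_seed(global_seed, f"scramble/{name}")
            designs[name] = make_sobol(space, int(entry["m"]), scramble)
        else:
            raise ConfigError(f"design {name!r}: unknown kind {kind!r}")
    if not designs:
        raise ConfigError("sampling block defines no designs")
    return designs


def _stage_seed(global_seed: int, tag: str) -> int:
    """Deterministic per-stage sub-seed below 2**31."""
    digest = hashlib.sha256(f"{global_seed}/{tag}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: dict, outdir: "str | Path", global_seed: int | None = None) -> dict:
    """Execute the full workflow; returns the run manifest.

    Every stochastic stage derives its seed deterministically from the global
    seed, so re-running with an unchanged configuration reproduces identical
    artifact files byte for byte.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0) if global_seed is None else global_seed)
    manifest = {"seed": seed, "stages": []}

    def record(stage: str, outputs: list[Path], info: dict, t0: float) -> None:
        manifest["stages"].append(
            {
                "stage": stage,
                "outputs": [str(p) for p in outputs],
                "hashes": {p.name: _sha256(p) for p in outputs},
                "wall_time_s": round(time.monotonic() - t0, 3),
                **info,
            }
        )

    # -- stage 1: sample ----------------------------------------------------
    t0 = time.monotonic()
    try:
        designs = build_designs(cfg["sampling"], seed)
    except Exception as exc:
        raise StageError("sample", str(exc)) from exc
    sample_files = []
    for name, pts in designs.items():
        path = outdir / f"samples_{name}.csv"
        pd.DataFrame(pts, columns=list(LJ_PARAM_NAMES)).to_csv(
            path, index=False, float_format="%.12g"
        )
        sample_files.append(path)
    record("sample", sample_files, {"designs": {k: len(v) for k, v in designs.items()}}, t0)

    # -- stage 2: evaluate --------------------------------------------------
    t0 = time.monotonic()
    oracle_cfg = OracleConfig(
        **{**cfg.get("oracle", {}), "master_seed": _stage_seed(seed, "oracle")}
    )
    raw: dict[str, DensityDataset] = {}
    eval_files = []
    for name, pts in designs.items():
        ds = evaluate_samples(pts, oracle_cfg, name=name)
        raw[name] = ds
        path = outdir / f"dataset_{name}.csv"
        write_dataset(path, ds)
        eval_files.append(path)
    record("evaluate", eval_files, {"oracle_seed": oracle_cfg.master_seed}, t0)

    # -- stage 3: preprocess ------------------------------------------------
    t0 = time.monotonic()
    pp = cfg.get("preprocess", {})
    low, high = float(pp.get("plaus_low", 0.0)), float(pp.get("plaus_high", 1500.0))
    clean: dict[str, DensityDataset] = {}
    removed: dict[str, int] = {}
    pp_files = []
    for name, ds in raw.items():
        clean_ds, n_removed = preprocess(ds, low, high)
        clean[name] = clean_ds
        removed[name] = n_removed
        path = outdir / f"clean_{name}.csv"
        write_dataset(path, clean_ds)
        pp_files.append(path)
    record("preprocess", pp_files, {"removed": removed}, t0)

    # -- stage 4: train -----------------------------------------------------
    t0 = time.monotonic()
    hcfg = cfg["harness"]
    r = hcfg["ratios"]
    ratios = harness.enumerate_ratios(float(r["start"]), float(r["stop"]), float(r["step"]))
    seeds_per_ratio = int(hcfg.get("seeds_per_ratio", 3))
    families = hcfg.get("families", {"polynomial": [{"degree": 3}]})
    names = sorted(clean)
    reports = []
    run_rows = []
    try:
        for ds_name in names:
            ds = clean[ds_name]
            others = [clean[o] for o in names if o != ds_name]
            for ratio in ratios:
                for j in range(seeds_per_ratio):
                    split_seed = _stage_seed(seed, f"split/{ds_name}/{ratio}/{j}")
                    s = harness.SplitSpec(ratio, split_seed)
                    for family, grid in families.items():
                        for hp in grid:
                            spec = surrogates.ModelSpec.make(
                                family, train_seed=split_seed, **hp
                            )
                            ist, ost = harness.run_ist_ost(spec, ds, s, others)
                            for rep in (ist, ost):
                                reports.append((spec, ds_name, s, rep))
                                run_rows.append(
                                    {
                                        "family": family,
                                        "hyperparams": json.dumps(hp, sort_keys=True),
                                        "dataset": ds_name,
                                        "ratio": ratio,
                                        "seed": split_seed,
                                        "mode": rep.mode,
                                        "mape": rep.mape,
                                        "r2": rep.r2,
                                    }
                                )
    except Exception as exc:
        raise StageError("train", str(exc)) from exc
    results_path = outdir / "results.csv"
    pd.DataFrame(run_rows).to_csv(results_path, index=False, float_format="%.12g")
    agg_path = outdir / "results_agg.csv"
    harness.aggregate(reports).to_csv(agg_path, index=False, float_format="%.12g")
    record("train", [results_path, agg_path], {"n_runs": len(run_rows) // 2}, t0)

    # -- stage 5: select ----------------------------------------------------
    t0 = time.monotonic()
    k = int(cfg.get("selection", {}).get("k", 3))
    frame = pd.DataFrame(run_rows)
    ist = frame[frame["mode"] == "IST"]
    entries = [
        (f"{row.family}|{row.hyperparams}|{row.dataset}|{row.ratio}|{row.seed}",
         float(row.mape), float(row.r2))
        for row in ist.itertuples(index=False)
    ]
    selection = harness.select_top(entries, min(k, len(entries)))
    sel_path = outdir / "selection.csv"
    with open(sel_path, "w") as fh:
        fh.write("rank,list,model_id\n")
        for i, mid in enumerate(selection.by_mape):
            fh.write(f"{i + 1},by_mape,{mid}\n")
        for i, mid in enumerate(selection.by_r2):
            fh.write(f"{i + 1},by_r2,{mid}\n")
    record("select", [sel_path], {"union_size": len(selection.union)}, t0)

    # retrain the best-by-MAPE model as the optimization surrogate
    best_id = selection.by_mape[0]
    family, hp_json, ds_name, ratio, split_seed = best_id.split("|")
    spec = surrogates.ModelSpec.make(
        family, train_seed=int(split_seed), **json.loads(hp_json)
    )
    train_ds, _ = harness.split(clean[ds_name], harness.SplitSpec(float(ratio), int(split_seed)))
    surrogate = surrogates.train(spec, train_ds, fingerprint=best_id)

    # -- stage 6: optimize + verify -----------------------------------------
    t0 = time.monotonic()
    ocfg = cfg["optimizer"]
    weights = tuple(float(w) for w in ocfg.get("weights", (1.0, 1.0)))
    conf = None
    if weights[1] > 0:
        ccfg = cfg.get("conformers", {})
        conf = make_conformer_fixture(
            n_conformers=int(ccfg.get("n", 97)),
            seed=_stage_seed(seed, "conformers"),
        )
    targets = OptimizationTargets(
        target_density=float(cfg.get("oracle", {}).get("target_density", 700.0)),
        conformers=conf,
    )
    opt_cfg = OptimizerConfig(
        weights=weights,
        tol=float(ocfg.get("tol", 1e-3)),
        max_iter=int(ocfg.get("max_iter", 20)),
        h_rel=float(ocfg.get("h_rel", 0.01)),
        alpha0=float(ocfg.get("alpha0", 0.1)),
    )
    space = _space_from_bounds(
        cfg["sampling"].get("optimization_bounds")
        or cfg["sampling"]["designs"][0].get("bounds")
        or _grid_bounds(cfg["sampling"]["designs"][0])
    )
    n_starts = int(ocfg.get("n_starts", 3))
    rng = np.random.default_rng(_stage_seed(seed, "starts"))
    opt_files = []
    verif_rows = []
    try:
        for run_idx in range(n_starts):
            x0 = space.denormalize(rng.uniform(0.15, 0.85, size=space.ndim))
            p0 = LJParamSet.from_array(x0)
            traj = optimize(p0, targets, surrogate.predict, space, opt_cfg)
            traj_path = outdir / f"trajectory_{run_idx}.csv"
            with open(traj_path, "w") as fh:
                fh.write("iter,sigma_C,sigma_H,eps_C,eps_H,err_dens,err_rce,loss,n_evals\n")
                for pt in traj.points:
                    p = pt.params
                    fh.write(
                        f"{pt.iteration},{p.sigma_C:.9g},{p.sigma_H:.9g},"
                        f"{p.eps_C:.9g},{p.eps_H:.9g},{pt.report.err_dens:.9g},"
                        f"{pt.report.err_rce:.9g},{pt.report.loss:.9g},{pt.n_evals}\n"
                    )
            opt_files.append(traj_path)
            final = traj.final
            vr = verify(
                final.params,
                targets,
                oracle_cfg,
                n_rep=int(cfg.get("verify", {}).get("n_rep", 3)),
                rho_pred=float(surrogate.predict(final.params)),
            )
            verif_rows.append(
                {
                    "run": run_idx,
                    **{n: getattr(final.params, n) for n in LJ_PARAM_NAMES},
                    "rho_pred": vr.rho_pred,
                    "rho_sim_mean": vr.rho_sim_mean,
                    "rho_sim_sd": vr.rho_sim_sd,
                    "err_dens": vr.err_dens,
                    "err_rce": vr.err_rce,
                    "iterations": final.iteration,
                    "termination": traj.termination,
                    "total_evals": traj.total_evals,
                }
            )
    except Exception as exc:
        raise StageError("optimize", str(exc)) from exc
    verif_path = outdir / "verification.csv"
    pd.DataFrame(verif_rows).to_csv(verif_path, index=False, float_format="%.12g")
    opt_files.append(verif_path)
    record("optimize", opt_files, {"surrogate": best_id, "n_starts": n_starts}, t0)

    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _grid_bounds(entry: dict) -> dict:
    axes = entry["axes"]
    return {n: [axes[n][0], axes[n][2]] for n in LJ_PARAM_NAMES}
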