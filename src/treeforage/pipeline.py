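"""End-to-end driver: simulate (or load) -> availability -> DIR -> tree-use
model -> residence-time model -> report bundle."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from treeforage import __version__
from treeforage.bbmm import build_availability
from treeforage.decay import build_dir_table
from treeforage.io import read_routes, read_trees, write_table
from treeforage.mcmc import rank_models
from treeforage.residence import (
    CoxGammaConfig,
    build_residence_records,
    fit_cox_gamma,
    remaining_probability,
)
from treeforage.selection import (
    SelectionConfig,
    build_observations,
    fit_candidate_set,
    fit_selection_model,
)
from treeforage.synthetic import SimulationConfig, generate_landscape, simulate_routes

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    trees_path: str | None = None
    routes_path: str | None = None
    simulation: SimulationConfig | None = None
    delta: float = 3.0
    max_lag: int = 4
    min_route_length: int = 6
    selection: SelectionConfig = field(default_factory=lambda: SelectionConfig(
        chains=3, iterations=4000, burnin=2000, thin=2))
    residence: CoxGammaConfig = field(default_factory=lambda: CoxGammaConfig(
        chains=3, iterations=4000, burnin=2000, thin=2))
    out_dir: str = "treeforage_out"
    seed: int = 0
    censor_last: bool = False

    def validate(self) -> None:
        if self.max_lag < 1:
            raise ValueError("max_lag must be >= 1")
        if self.min_route_length < 3:
            raise ValueError("min_route_length must be >= 3 (disks need triplets)")
        if self.trees_path is None and self.simulation is None:
            raise ValueError("either input paths or a simulation config is required")


def _config_hash(config: RunConfig) -> str:
    def enc(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(type(o).__name__)

    payload = dataclasses.asdict(config)
    payload.pop("out_dir", None)  # analysis identity, not output location
    blob = json.dumps(payload, sort_keys=True, default=enc)
    return hashlib.sha256(blob.encode()).hexdigest()


def filter_short_routes(routes: pd.DataFrame, min_length: int) -> tuple[pd.DataFrame, int]:
    """Drop routes shorter than ``min_length`` used trees."""
    sizes = routes.groupby("route_id")["step"].size()
    keep = sizes.index[sizes >= min_length]
    dropped = int((sizes < min_length).sum())
    if dropped:
        logger.info("discarded %d route(s) shorter than %d trees", dropped, min_length)
    return routes[routes["route_id"].isin(keep)].copy(), dropped


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the report bundle under ``out_dir``.

    Returns a manifest dict (also written as ``manifest.json``) recording
    seeds, versions, per-stage counts and the config hash.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "stages": {},
    }

    # --- load or simulate ---
    try:
        if config.simulation is not None:
            sim = config.simulation
            trees = generate_landscape(sim, rng=np.random.default_rng(config.seed))
            routes, truth = simulate_routes(trees, sim, seed=config.seed + 1)
            (out / "ground_truth.json").write_text(json.dumps(truth, indent=2))
        else:
            trees = read_trees(config.trees_path)
            routes = read_routes(config.routes_path)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("input", str(exc)) from exc
    routes, dropped = filter_short_routes(routes, config.min_route_length)
    if routes.empty:
        raise PipelineError("input", "no route of sufficient length")
    write_table(trees, out / "trees.csv")
    write_table(routes, out / "routes.csv")
    manifest["stages"]["input"] = {
        "n_trees": int(len(trees)),
        "n_routes": int(routes["route_id"].nunique()),
        "n_routes_discarded_short": dropped,
    }

    # --- availability ---
    try:
        disks, avail, sigma2_m = build_availability(trees, routes, delta=config.delta)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("availability", str(exc)) from exc
    write_table(avail, out / "availability.csv")
    sizes = [len(d.available_tree_ids) for d in disks]
    manifest["stages"]["availability"] = {
        "sigma2_m": sigma2_m,
        "n_disks": len(disks),
        "mean_disk_size": float(np.mean(sizes)) if sizes else 0.0,
    }

    # --- decay-index ratios ---
    try:
        dir_table = build_dir_table(trees, routes, disks, max_lag=config.max_lag)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("dir", str(exc)) from exc
    write_table(dir_table, out / "dir.csv")
    used_mean = dir_table.loc[dir_table["used"] == 1, ["dir_local", "dir_route"]].mean()
    manifest["stages"]["dir"] = {
        "n_records": int(len(dir_table)),
        "used_mean_dir_local": float(used_mean["dir_local"]),
        "used_mean_dir_route": float(used_mean["dir_route"]),
    }

    # --- tree-use model, staged per-lag candidate sets ---
    try:
        obs = build_observations(dir_table, routes)

        # interaction screen: keep eta (dir_route x route length) only if
        # its credible interval excludes zero
        eta_cfg = dataclasses.replace(config.selection,
                                      fixed_effects=("dir_route",),
                                      include_eta=True)
        eta_fit = fit_selection_model(obs, eta_cfg, seed=config.seed + 7,
                                      name="eta-screen")
        eta_row = eta_fit.summary.set_index("parameter").loc["eta"]
        eta_significant = bool(eta_row["bci_2.5"] * eta_row["bci_97.5"] > 0)
        if eta_significant:
            config = dataclasses.replace(config, selection=dataclasses.replace(
                config.selection, include_eta=True))

        rankings = {}
        best_fit = None
        scale_cols = ["dir_local"] + [f"dir_lag{k}" for k in range(1, config.max_lag + 1)]
        for scale_col in scale_cols:
            block = obs[obs[scale_col].notna()].copy()
            if block.empty or (block["used"] == 1).sum() < 5:
                continue
            fits = fit_candidate_set(block, scale_col, config.selection,
                                     seed=config.seed + 11)
            rank = rank_models(fits)
            rankings[scale_col] = rank
            top_name = rank["model"].iloc[0]
            top = {f.name: f for f in fits}[top_name]
            if best_fit is None or top.dic < best_fit.dic:
                best_fit = top
        ranking_table = pd.concat(
            [r.assign(block=k) for k, r in rankings.items()], ignore_index=True)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("fit-selection", str(exc)) from exc
    write_table(ranking_table, out / "model_ranking.csv")
    best_fit.summary.to_csv(out / "selection_fit.csv", index=False)
    (out / "selection_fit.json").write_text(json.dumps(
        {
            "best_model": best_fit.name,
            "dic": best_fit.dic,
            "p_d": best_fit.p_d,
            "max_psrf": best_fit.max_psrf,
            "v_mean": best_fit.v_mean,
            "coefficients": dict(zip(best_fit.summary["parameter"],
                                     best_fit.summary["mean"])),
        }, indent=2))
    manifest["stages"]["selection"] = {
        "best_model": best_fit.name, "dic": best_fit.dic,
        "converged": bool(best_fit.converged),
        "eta_retained": eta_significant,
    }

    # --- residence-time model on foraging trees ---
    try:
        records = build_residence_records(dir_table, routes, trees,
                                          censor_last=config.censor_last)
        cox = fit_cox_gamma(records, config.residence, seed=config.seed + 13)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("fit-residence", str(exc)) from exc
    cox.summary.to_csv(out / "cox_fit.csv", index=False)
    hr = cox.hazard_ratios()[["parameter", "mean", "hr"]]
    (out / "cox_fit.json").write_text(json.dumps(
        {
            "dic": cox.dic, "p_d": cox.p_d, "max_psrf": cox.max_psrf,
            "coefficients": dict(zip(hr["parameter"], hr["mean"])),
            "hazard_ratios": dict(zip(hr["parameter"], hr["hr"])),
        }, indent=2))
    times = np.linspace(0.0, float(records["T"].quantile(0.95)), 50)
    curves = []
    for q, label in ((0.25, "dir_q25"), (0.5, "dir_median"), (0.75, "dir_q75")):
        profile = {
            "dir": float(records["dir"].quantile(q)),
            "dis": float(records["dis"].median()),
            "dbh": float(records["dbh"].median()),
            "ht": float(records["ht"].median()),
            "family_size": float(records["family_size"].median()),
        }
        s = remaining_probability(cox, profile, times)
        curves.append(pd.DataFrame({"profile": label, "time_min": times, "survival": s}))
    write_table(pd.concat(curves, ignore_index=True), out / "survival_curves.csv")
    manifest["stages"]["residence"] = {
        "n_records": int(len(records)), "dic": cox.dic,
        "converged": bool(cox.converged),
    }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
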