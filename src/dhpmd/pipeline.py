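"""End-to-end screen orchestration: condition grid → region volume
series → β_T → sensitivity ranking → virtual saturation → consensus
filter, with a TOML config, a run-plan calculator and a provenance
manifest.

Two trajectory modes are supported.  ``geometric`` generates breathing
coordinate trajectories and measures region volumes by Voronoi
tessellation — the full mechanical path, at a computational cost that
grows with system size.  ``series`` (default) generates the per-region
volume series directly from the same fluctuation statistics, and uses a
jittered coordinate trajectory for the RMSD/RMSF stage; it exercises
the identical estimator and screening stages at a fraction of the cost.
"""

from __future__ import annotations

import json
import sys
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .compressibility import beta_T, beta_T_from_samples, sensitivity_ranking
from .io_formats import Condition, Frame, Topology
from .mutscreen import (
    attach_scores,
    candidates_frame,
    consensus_filter,
    enumerate_saturation,
    heatmap_matrix,
    score_candidates,
)
from .regions import RegionPartition, assign_secondary_structure
from .volumetrics import VolumeSeries, region_volume_series
from . import flexibility, io_formats, synthetic_data

__all__ = ["RunPlan", "ConfigError", "StageError", "plan_grid", "load_config",
           "run_screen", "derive_seed"]


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass(frozen=True)
class RunPlan:
    """The simulation grid: parallels × pressures × ethanol fractions,
    each of ``run_length_ns``."""

    parallels: int
    pressures: tuple[float, ...]
    ethanol_fractions: tuple[float, ...]
    run_length_ns: float
    runs: tuple[tuple[int, float, float], ...]  # (parallel, pressure, fraction)

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def total_ns(self) -> float:
        return self.n_runs * self.run_length_ns

    def to_dict(self) -> dict:
        return {
            "parallels": self.parallels,
            "pressures": list(self.pressures),
            "ethanol_fractions": list(self.ethanol_fractions),
            "run_length_ns": self.run_length_ns,
            "n_runs": self.n_runs,
            "total_ns": self.total_ns,
        }


def plan_grid(
    parallels: int,
    pressures: Sequence[float],
    ethanol_fractions: Sequence[float],
    run_length_ns: float,
) -> RunPlan:
    """Enumerate the (parallel, pressure, fraction) grid and its totals.

    n_runs = parallels × |pressures| × |fractions|; total simulated time
    = n_runs × run_length_ns.
    """
    if parallels < 1:
        raise ConfigError("parallels must be ≥ 1")
    if not pressures or not ethanol_fractions:
        raise ConfigError("pressures and ethanol_fractions must be non-empty")
    if run_length_ns <= 0:
        raise ConfigError("run_length_ns must be positive")
    runs = tuple(
        (par, float(p), float(x))
        for par in range(1, parallels + 1)
        for p in pressures
        for x in ethanol_fractions
    )
    return RunPlan(
        parallels=parallels,
        pressures=tuple(float(p) for p in pressures),
        ethanol_fractions=tuple(float(x) for x in ethanol_fractions),
        run_length_ns=float(run_length_ns),
        runs=runs,
    )


def derive_seed(base_seed: int, *parts) -> int:
    """Stable sub-seed (< 2³¹) from a base seed and context labels."""
    key = ":".join([str(base_seed), *map(str, parts)]).encode()
    return zlib.crc32(key) % (2**31)


# ---------------------------------------------------------------------------
# configuration

_DEFAULT_CONFIG = {
    "seed": 0,
    "out_dir": "screen_out",
    "grid": {
        "parallels": 5,
        "pressures": [1.0, 500.0, 1000.0],
        "ethanol_fractions": [0.1, 0.5, 1.0],
        "temperature": 313.0,
        "run_length_ns": 30.0,
        "sample_interval_ns": 1.0,
    },
    "protein": {"preset": "toy-hydrolase", "margin": 5.0},
    "regions": {"method": "dihedral-heuristic", "top_k": 3},
    "betas": {"default_base": 2.0e-6, "default_amplitude": 1.0e-6, "amplitudes": {}},
    "trajectory": {"mode": "series", "mean_volume_per_heavy_atom": 15.0},
    "solvent": {"n_water": 150, "n_ethanol": 30},
    "screen": {"surrogate": True, "ddg_table": None},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path) -> dict:
    """Read and validate a TOML run configuration."""
    import tomllib

    try:
        with open(path, "rb") as fh:
            user = tomllib.load(fh)
    except FileNotFoundError:
        raise ConfigError(f"config file not found: {path}")
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"invalid TOML in {path}: {exc}")
    return validate_config(_merge(_DEFAULT_CONFIG, user))


def validate_config(config: dict) -> dict:
    config = _merge(_DEFAULT_CONFIG, config)
    grid = config["grid"]
    plan_grid(grid["parallels"], grid["pressures"], grid["ethanol_fractions"],
              grid["run_length_ns"])
    if grid["temperature"] <= 0:
        raise ConfigError("temperature must be positive")
    mode = config["trajectory"]["mode"]
    if mode not in ("series", "geometric"):
        raise ConfigError(f"unknown trajectory mode {mode!r}")
    screen = config["screen"]
    if not screen.get("surrogate") and not screen.get("ddg_table"):
        raise ConfigError(
            "screen needs a ddg_table when the surrogate scorer is disabled"
        )
    if screen.get("ddg_table") and not Path(screen["ddg_table"]).exists():
        raise ConfigError(f"ddg_table not found: {screen['ddg_table']}")
    prot = config["protein"]
    if "segments" not in prot and prot.get("preset") != "toy-hydrolase":
        raise ConfigError("protein needs a preset or explicit segments")
    return config


# ---------------------------------------------------------------------------
# stages


def _build_protein(config: dict):
    prot = config["protein"]
    seed = derive_seed(config["seed"], "protein")
    if "segments" in prot:
        segments = [(str(c), int(l)) for c, l in prot["segments"]]
        sequence = prot.get("sequence")
    else:
        segments = synthetic_data.toy_hydrolase_segments()
        sequence = synthetic_data.toy_hydrolase_sequence()
    topology, frame = synthetic_data.generate_toy_protein(
        segments, sequence=sequence, seed=seed, margin=float(prot.get("margin", 5.0))
    )
    method = config["regions"]["method"]
    partition = assign_secondary_structure(
        topology, frame, method=method,
        ss_file=config["regions"].get("ss_file"),
    )
    return topology, frame, partition


def _region_targets(config: dict, partition: RegionPartition) -> dict[str, dict]:
    betas = config["betas"]
    targets = {}
    for seg in partition.loops():
        targets[seg.name] = {
            "base": float(betas.get("bases", {}).get(seg.name, betas["default_base"])),
            "amplitude": float(betas["amplitudes"].get(seg.name, betas["default_amplitude"])),
        }
    return targets


def _volume_series_for_run(
    config: dict,
    topology: Topology,
    frame: Frame,
    partition: RegionPartition,
    targets: dict[str, dict],
    condition: Condition,
    parallel: int,
) -> list[VolumeSeries]:
    grid = config["grid"]
    n_samples = int(round(grid["run_length_ns"] / grid["sample_interval_ns"]))
    mode = config["trajectory"]["mode"]
    series = []
    if mode == "series":
        vol_per_atom = float(config["trajectory"]["mean_volume_per_heavy_atom"])
        from .regions import region_atoms

        for name, spec in targets.items():
            target = synthetic_data.condition_beta(
                spec["base"], spec["amplitude"], condition,
                max_pressure=max(grid["pressures"]),
            )
            n_heavy = len(region_atoms(partition, topology, name, scope="heavy-atom"))
            series.append(
                synthetic_data.generate_volume_series(
                    target,
                    mean_volume=vol_per_atom * n_heavy,
                    temperature=condition.temperature,
                    n=n_samples,
                    dt=grid["sample_interval_ns"],
                    seed=derive_seed(config["seed"], "series", name,
                                     condition.label(), parallel),
                    region_name=name,
                    condition=condition,
                )
            )
    else:
        solv = config["solvent"]
        stop, sfr = synthetic_data.generate_solvated_box(
            topology, frame,
            n_water=int(solv["n_water"]), n_ethanol=int(solv["n_ethanol"]),
            seed=derive_seed(config["seed"], "solvent"),
        )
        per_region = {
            name: synthetic_data.condition_beta(
                spec["base"], spec["amplitude"], condition,
                max_pressure=max(grid["pressures"]),
            )
            for name, spec in targets.items()
        }
        frames = synthetic_data.generate_volume_trajectory(
            stop, sfr, partition, per_region,
            n_frames=n_samples, dt=grid["sample_interval_ns"],
            temperature=condition.temperature,
            seed=derive_seed(config["seed"], "traj", condition.label(), parallel),
            condition=condition,
        )
        for name in targets:
            series.append(
                region_volume_series(
                    frames, stop, partition, name,
                    sample_interval=grid["sample_interval_ns"],
                    condition=condition,
                )
            )
    return series


def _flex_stage(config, topology, frame, partition):
    n_frames = 20
    frames = synthetic_data.generate_jitter_trajectory(
        topology, frame, partition, n_frames=n_frames,
        seed=derive_seed(config["seed"], "flex"),
    )
    return flexibility.flexibility_profile(topology, frames)


def run_screen(config: dict | str | Path, out_dir: Optional[str | Path] = None) -> dict:
    """Execute the full screen and write all stage outputs.

    Returns a manifest dict (also written as ``manifest.json``).  Any
    stage failure raises :class:`StageError` naming the stage, after
    writing a partial manifest.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        config = validate_config(config)
    out = Path(out_dir if out_dir is not None else config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "tool": "dhpmd",
        "version": __version__,
        "seed": config["seed"],
        "config": config,
        "stages": [],
        "outputs": {},
    }

    def _finish_stage(name: str, **info):
        manifest["stages"].append({"name": name, **info})

    def _fail(stage: str, exc: Exception):
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise StageError(stage, str(exc)) from exc

    grid = config["grid"]
    try:
        plan = plan_grid(grid["parallels"], grid["pressures"],
                         grid["ethanol_fractions"], grid["run_length_ns"])
        (out / "runplan.json").write_text(json.dumps(plan.to_dict(), indent=2))
        manifest["outputs"]["runplan"] = "runplan.json"
        _finish_stage("plan", n_runs=plan.n_runs, total_ns=plan.total_ns)
    except Exception as exc:
        _fail("plan", exc)

    try:
        topology, frame, partition = _build_protein(config)
        _finish_stage("protein", n_atoms=topology.n_atoms,
                      segments=partition.names())
    except Exception as exc:
        _fail("protein", exc)

    try:
        profile = _flex_stage(config, topology, frame, partition)
        pd.DataFrame({"frame": np.arange(len(profile.rmsd)),
                      "rmsd_A": profile.rmsd}).to_csv(
            out / "rmsd.tsv", sep="\t", index=False)
        profile.rmsf.rename("rmsf_A").to_csv(out / "rmsf.tsv", sep="\t")
        manifest["outputs"]["rmsd"] = "rmsd.tsv"
        manifest["outputs"]["rmsf"] = "rmsf.tsv"
        _finish_stage("flex", n_frames=len(profile.rmsd))
    except Exception as exc:
        _fail("flex", exc)

    try:
        targets = _region_targets(config, partition)
        temperature = grid["temperature"]
        pooled: dict[tuple[str, str], list[np.ndarray]] = {}
        conditions: dict[str, Condition] = {}
        for parallel, pressure, fraction in plan_grid(
            grid["parallels"], grid["pressures"], grid["ethanol_fractions"],
            grid["run_length_ns"],
        ).runs:
            condition = Condition(pressure, fraction, temperature)
            conditions[condition.label()] = condition
            for series in _volume_series_for_run(
                config, topology, frame, partition, targets, condition, parallel
            ):
                pooled.setdefault(
                    (series.region_name, condition.label()), []
                ).append(series.volumes)
        _finish_stage("volumes", n_series=len(pooled))
    except Exception as exc:
        _fail("volumes", exc)

    try:
        estimates = []
        rows = []
        from .compressibility import CompressibilityEstimate

        for (region, cond_label), chunks in sorted(pooled.items()):
            volumes = np.concatenate(chunks)
            value, mean, var = beta_T_from_samples(volumes, temperature)
            estimates.append(CompressibilityEstimate(
                region_name=region, condition=conditions[cond_label],
                mean_volume=mean, volume_variance=var,
                beta_T=value, n_samples=len(volumes),
            ))
            rows.append({"region": region, "condition": cond_label,
                         "beta_T_per_bar": value, "n_samples": len(volumes)})
        pd.DataFrame(rows).to_csv(out / "beta_t.tsv", sep="\t", index=False)
        manifest["outputs"]["beta_t"] = "beta_t.tsv"
        _finish_stage("beta_T", n_estimates=len(estimates))
    except Exception as exc:
        _fail("beta_T", exc)

    try:
        ranking = sensitivity_ranking(estimates)
        top_k = int(config["regions"]["top_k"])
        top_regions = ranking.top(top_k)
        (out / "ranking.json").write_text(json.dumps({
            "scores": [{"region": r, "score_per_bar": s} for r, s in ranking.scores],
            "top": top_regions,
            "beta_table": json.loads(ranking.table.to_json(orient="index")),
        }, indent=2))
        manifest["outputs"]["ranking"] = "ranking.json"
        _finish_stage("ranking", top=top_regions)
    except Exception as exc:
        _fail("ranking", exc)

    try:
        sequence = topology.sequence()
        candidates = enumerate_saturation(sequence, top_regions, partition=partition)
        screen = config["screen"]
        if screen.get("ddg_table"):
            scores = io_formats.read_ddg_table(screen["ddg_table"], sequence=sequence)
            candidates = attach_scores(candidates, scores)
        else:
            candidates = score_candidates(
                sequence, candidates, seed=derive_seed(config["seed"], "ddg")
            )
        scored, stabilizing = consensus_filter(candidates)
        candidates_frame(scored).to_csv(out / "candidates.tsv", sep="\t", index=False)
        candidates_frame(stabilizing).to_csv(out / "stabilizing.tsv", sep="\t", index=False)
        (out / "heatmap.json").write_text(json.dumps(heatmap_matrix(scored), indent=2))
        manifest["outputs"].update({
            "candidates": "candidates.tsv",
            "stabilizing": "stabilizing.tsv",
            "heatmap": "heatmap.json",
        })
        _finish_stage("screen", n_candidates=len(scored),
                      n_stabilizing=len(stabilizing))
    except Exception as exc:
        _fail("screen", exc)

    manifest["outputs"]["manifest"] = "manifest.json"
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
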