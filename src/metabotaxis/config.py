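"""Configuration, presets, serialization and experiment runners.

Experiments are described by an :class:`ExperimentConfig` (YAML/JSON
round-trippable) and executed by :func:`run_experiment`, which writes
tabular results as CSV, summaries as JSON, and a run manifest recording
the fully resolved configuration, the master seed and a checksum
inventory of every output file — enough to bit-reproduce any
deterministic run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behaviors import (
    PARAM_RANGES,
    BehaviorSpec,
    MotorLimit,
    default_spec,
)
from .metabolism import MetabolismParams, SystemState, bifurcation_scan, calibrate_default_params
from .optimize import (
    GAConfig,
    InitialGrid,
    LatticeSearchConfig,
    fitness,
    lattice_search,
    microbial_ga,
    spec_from_genes,
)
from .simulate import IntegratorConfig, simulate_trajectory, survivability_map
from .spatial import Environment1D, PopulationConfig, run_population

__all__ = [
    "ExperimentConfig",
    "RunManifest",
    "load_behavior_presets",
    "behavior_spec_from_preset",
    "save_config",
    "load_config",
    "run_experiment",
]

log = logging.getLogger("metabotaxis")

TASKS = ("bifurcation", "trajectory", "map", "search-lattice", "evolve", "spatial")


def load_behavior_presets() -> dict[str, dict[str, Any]]:
    """The shipped optimised parameter presets for all four behaviors.

    Returns ``{kind: {"method": str, "params": {name: value},
    "ranges": {name: (lo, hi)}}}`` read from the package's read-only
    preset file.
    """
    text = resources.files("metabotaxis.data").joinpath("behavior_presets.yaml").read_text()
    raw = yaml.safe_load(text)
    out: dict[str, dict[str, Any]] = {}
    for kind, block in raw.items():
        out[kind] = {
            "method": block["method"],
            "params": {k: float(v) for k, v in block["params"].items()},
            "ranges": {k: tuple(map(float, v)) for k, v in block["ranges"].items()},
        }
    return out


def behavior_spec_from_preset(
    kind: str,
    overrides: Optional[dict[str, float]] = None,
    r_max: float = 1.0,
) -> BehaviorSpec:
    """Build a BehaviorSpec from the shipped preset plus optional overrides."""
    presets = load_behavior_presets()
    params = dict(presets[kind]["params"])
    if overrides:
        unknown = set(overrides) - set(params)
        if unknown:
            raise ValueError(f"unknown parameters for {kind}: {sorted(unknown)}")
        params.update(overrides)
    return spec_from_genes(kind, [params[k] for k in PARAM_RANGES[kind]], r_max=r_max)


@dataclass(frozen=True)
class ExperimentConfig:
    """Fully resolved description of one reproducible experiment."""

    task: str
    seed: int = 0
    outdir: str = "runs"
    metabolism: MetabolismParams = field(default_factory=calibrate_default_params)
    behavior_kind: str = "B1"
    behavior_overrides: dict = field(default_factory=dict)
    r_max: float = 1.0
    integrator: IntegratorConfig = field(default_factory=IntegratorConfig)
    grid: InitialGrid = field(default_factory=InitialGrid)
    ga: GAConfig = field(default_factory=GAConfig)
    lattice: LatticeSearchConfig = field(default_factory=LatticeSearchConfig)
    environment: Environment1D = field(default_factory=Environment1D)
    population: PopulationConfig = field(default_factory=PopulationConfig)
    initial_A: float = 4.0
    initial_F: float = 1.0

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}")
        if self.behavior_kind not in ("B1", "B2", "B3", "B4"):
            raise ValueError("behavior_kind must be B1..B4")

    def behavior(self) -> BehaviorSpec:
        return behavior_spec_from_preset(
            self.behavior_kind, self.behavior_overrides, r_max=self.r_max
        )


@dataclass(frozen=True)
class RunManifest:
    """Record of one run: resolved config, seed, timing, output inventory."""

    config: dict
    package_version: str
    seed: int
    started: str
    finished: str
    outputs: dict[str, str]  # relative path -> sha256


def _to_jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: _to_jsonable(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
        }
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def config_to_dict(cfg: ExperimentConfig) -> dict:
    return _to_jsonable(cfg)


def config_from_dict(d: dict) -> ExperimentConfig:
    d = dict(d)
    nested = {
        "metabolism": MetabolismParams,
        "integrator": IntegratorConfig,
        "grid": InitialGrid,
        "ga": GAConfig,
        "lattice": LatticeSearchConfig,
        "environment": Environment1D,
        "population": PopulationConfig,
    }
    for key, cls in nested.items():
        if key in d and isinstance(d[key], dict):
            sub = d[key]
            if key == "lattice" and sub.get("ranges"):
                sub = dict(sub)
                sub["ranges"] = {
                    k: tuple(v) for k, v in sub["ranges"].items()
                }
            d[key] = cls(**sub)
    return ExperimentConfig(**d)


def save_config(cfg: ExperimentConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=False))


def load_config(path: str | Path) -> ExperimentConfig:
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return config_from_dict(data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(_to_jsonable(payload), indent=2, sort_keys=True))


def run_experiment(cfg: ExperimentConfig) -> RunManifest:
    """Dispatch one experiment, write its outputs and a run manifest."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    started = datetime.now(timezone.utc).isoformat()
    p = cfg.metabolism
    outputs: list[Path] = []
    log.info("task=%s seed=%d behavior=%s", cfg.task, cfg.seed, cfg.behavior_kind)

    if cfg.task == "bifurcation":
        scan = bifurcation_scan(p, cfg.grid.F_min, cfg.grid.F_max)
        path = outdir / "bifurcation.csv"
        scan.to_csv(path, index=False)
        outputs.append(path)

    elif cfg.task == "trajectory":
        res = simulate_trajectory(
            SystemState(cfg.initial_A, cfg.initial_F),
            cfg.behavior(),
            p,
            cfg.integrator,
        )
        path = outdir / "trajectory.csv"
        res.to_dataframe().to_csv(path, index=False)
        outputs.append(path)
        summary = outdir / "trajectory_summary.json"
        _write_json(
            summary,
            {
                "outcome": res.outcome.value,
                "time_of_death": res.time_of_death,
                "final_A": res.final_A,
                "final_F": res.final_F,
                "reached_steady": res.reached_steady,
            },
        )
        outputs.append(summary)

    elif cfg.task == "map":
        g = survivability_map(cfg.grid, cfg.behavior(), p, cfg.integrator)
        path = outdir / "survivability.csv"
        g.to_dataframe().to_csv(path, index=False)
        outputs.append(path)
        summary = outdir / "survivability_summary.json"
        _write_json(summary, g.proportions())
        outputs.append(summary)

    elif cfg.task == "search-lattice":
        best, score, surface = lattice_search(
            cfg.behavior_kind,
            cfg.lattice,
            p,
            grid=cfg.grid,
            integrator=cfg.integrator,
            r_max=cfg.r_max,
        )
        path = outdir / "lattice_surface.csv"
        surface.to_csv(path, index=False)
        outputs.append(path)
        preset = outdir / "best_preset.yaml"
        preset.write_text(
            yaml.safe_dump(
                {
                    cfg.behavior_kind: {
                        "method": "Lattice Sampling",
                        "params": best,
                        "fitness": {"S": score.S, "V": score.V, "total": score.total},
                    }
                }
            )
        )
        outputs.append(preset)

    elif cfg.task == "evolve":
        names = list(PARAM_RANGES[cfg.behavior_kind])
        ranges = np.array([PARAM_RANGES[cfg.behavior_kind][n] for n in names])

        def fitness_fn(genes: np.ndarray) -> float:
            spec = spec_from_genes(cfg.behavior_kind, genes, r_max=cfg.r_max)
            return fitness(spec, p, cfg.grid, cfg.integrator).total

        ga_cfg = dataclasses.replace(cfg.ga, seed=cfg.seed)
        best, best_fit, trace = microbial_ga(ga_cfg, fitness_fn, ranges, names)
        path = outdir / "ga_trace.csv"
        pd.DataFrame(
            {"tournament": np.arange(1, trace.size + 1), "best_fitness": trace}
        ).to_csv(path, index=False)
        outputs.append(path)
        preset = outdir / "best_preset.yaml"
        preset.write_text(
            yaml.safe_dump(
                {
                    cfg.behavior_kind: {
                        "method": "Genetic Algorithm",
                        "params": {
                            n: float(v) for n, v in zip(best.names, best.values)
                        },
                        "fitness": {"total": best_fit},
                    }
                }
            )
        )
        outputs.append(preset)

    elif cfg.task == "spatial":
        pop_cfg = dataclasses.replace(cfg.population, seed=cfg.seed)
        res = run_population(cfg.behavior(), cfg.environment, p, pop_cfg)
        path = outdir / "snapshots.csv"
        pd.concat([s.to_dataframe() for s in res.snapshots]).to_csv(path, index=False)
        outputs.append(path)
        summary = outdir / "spatial_summary.json"
        _write_json(
            summary,
            {
                "survival_fraction": res.survival_fraction,
                "by_cause": res.fractions_by_cause(),
            },
        )
        outputs.append(summary)

    finished = datetime.now(timezone.utc).isoformat()
    manifest = RunManifest(
        config=config_to_dict(cfg),
        package_version=__version__,
        seed=cfg.seed,
        started=started,
        finished=finished,
        outputs={str(f.relative_to(outdir)): _sha256(f) for f in outputs},
    )
    _write_json(
        outdir / "manifest.json",
        {
            "config": manifest.config,
            "package_version": manifest.package_version,
            "seed": manifest.seed,
            "started": manifest.started,
            "finished": manifest.finished,
            "outputs": manifest.outputs,
        },
    )
    return manifest
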