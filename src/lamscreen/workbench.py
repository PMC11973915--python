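"""Experiment orchestration: config, end-to-end runs, reports, manifest.

An experiment compares screening protocols on one site: for each
protocol it flattens, produces, estimates, and diagnoses, then writes
per-protocol estimate tables (TSV), accuracy reports against the
system's quadrature truth over the shared subset, transition and
deviation reports, and a JSON manifest with seeds, checksums and
timings.  Outputs are deterministic per seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .constants import DEFAULT_ENDSTATE_THRESHOLD, DEFAULT_MIN_COUNT
from .toy_systems import AlchemicalSystem, preset_site, true_ddg
from .flattening import FlatteningSchedule
from .screening import ProtocolSchedule, ScreeningRun, run_cs, run_legacy_linear, run_tlf
from .estimation import FreeEnergyEstimate, estimate_run
from .diagnostics import (accuracy_metrics, aggregate_deviation,
                          aggregate_transitions, shared_subset)

logger = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "run_experiment", "load_config", "save_config"]


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one comparison experiment."""

    # system: either a preset (kind + seed) or a JSON file path
    preset_kind: str = "surface"          # surface | core | file
    preset_seed: int = 0
    system_file: str = ""
    protocols: list[str] = field(default_factory=lambda: ["CS", "TLF"])
    trials: int = 5
    seed: int = 0
    # schedule
    flatten_iterations: int = 14
    flatten_steps_initial: int = 10_000
    flatten_growth: float = 1.5
    flatten_steps_max: int = 600_000
    production_steps: int = 400_000
    production_stride: int = 10
    # thresholds
    endstate_threshold: float = DEFAULT_ENDSTATE_THRESHOLD
    min_count: int = DEFAULT_MIN_COUNT
    # bootstrap
    n_boot: int = 1000
    boot_seed: int = 0
    # output
    out_dir: str = "experiment_out"
    save_trajectories: bool = False

    def schedule(self) -> ProtocolSchedule:
        return ProtocolSchedule(
            flattening=FlatteningSchedule(
                n_iterations=self.flatten_iterations,
                steps_initial=self.flatten_steps_initial,
                growth=self.flatten_growth,
                steps_max=self.flatten_steps_max,
                endstate_threshold=self.endstate_threshold),
            production_steps=self.production_steps,
            production_stride=self.production_stride)

    def load_system(self) -> AlchemicalSystem:
        if self.preset_kind == "file":
            path = Path(self.system_file)
            if not path.exists():
                raise FileNotFoundError(f"system file not found: {path}")
            return AlchemicalSystem.load(path)
        return preset_site(self.preset_kind, self.preset_seed)


def save_config(config: ExperimentConfig, path: str | Path) -> None:
    """Write the config as TOML (lossless round-trip)."""
    lines = []
    for key, val in asdict(config).items():
        if isinstance(val, bool):
            lines.append(f"{key} = {'true' if val else 'false'}")
        elif isinstance(val, (int, float)):
            lines.append(f"{key} = {val!r}")
        elif isinstance(val, str):
            lines.append(f"{key} = {json.dumps(val)}")
        elif isinstance(val, list):
            lines.append(f"{key} = {json.dumps(val)}")
        else:  # pragma: no cover - config only holds scalars and lists
            raise TypeError(f"unsupported config field type for {key}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_config(path: str | Path) -> ExperimentConfig:
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    return ExperimentConfig(**data)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _run_protocol(protocol: str, system: AlchemicalSystem,
                  config: ExperimentConfig) -> ScreeningRun:
    schedule = config.schedule()
    if protocol.upper() == "TLF":
        return run_tlf(system, trials=config.trials, schedule=schedule,
                       seed=config.seed)
    if protocol.upper() == "CS":
        return run_cs(system, trials=config.trials, schedule=schedule,
                      seed=config.seed)
    if protocol.upper() == "LEGACY":
        truth = true_ddg(system)
        ref = truth.g_unfolded - truth.g_unfolded[system.native_index]
        return run_legacy_linear(system, ref, trials=config.trials,
                                 schedule=schedule, seed=config.seed)
    raise ValueError(f"unknown protocol {protocol!r}")


def _estimate(run: ScreeningRun, system: AlchemicalSystem,
              config: ExperimentConfig) -> FreeEnergyEstimate:
    return estimate_run(
        run.folded_trajs, run.unfolded_trajs, run.folded_biases,
        run.unfolded_biases, kT=system.kT, native_index=system.native_index,
        endstate_threshold=config.endstate_threshold,
        min_count=config.min_count, n_boot=config.n_boot,
        boot_seed=config.boot_seed, labels=system.labels)


def run_experiment(config: ExperimentConfig) -> dict:
    """Execute all configured protocols and write the report bundle.

    Stage errors are captured in the manifest rather than aborting the
    whole experiment; partial outputs are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    manifest: dict = {"version": __version__, "config": asdict(config),
                      "stages": {}, "files": {}, "seeds": {"experiment": config.seed,
                                                           "bootstrap": config.boot_seed,
                                                           "preset": config.preset_seed}}
    results: dict = {"manifest": manifest}
    system = config.load_system()
    system.save(out / "system.json")
    truth = true_ddg(system)
    reference = dict(zip(system.labels, truth.ddg))
    pd.DataFrame({"substituent": system.labels, "ddG_true": truth.ddg,
                  "G_folded": truth.g_folded, "G_unfolded": truth.g_unfolded}
                 ).to_csv(out / "truth.tsv", sep="\t", index=False)

    estimates: dict[str, FreeEnergyEstimate] = {}
    for protocol in config.protocols:
        tag = protocol.upper()
        stage = {"status": "ok"}
        t0 = time.time()
        try:
            run = _run_protocol(tag, system, config)
            est = _estimate(run, system, config)
            estimates[tag] = est
            est.to_frame().to_csv(out / f"estimates_{tag}.tsv", sep="\t",
                                  index=False)
            trans = aggregate_transitions(run.folded_trajs,
                                          config.endstate_threshold)
            pd.DataFrame({"substituent": system.labels,
                          "arrivals": trans["arrivals_total"]}
                         ).to_csv(out / f"transitions_{tag}.tsv", sep="\t",
                                  index=False)
            dev = aggregate_deviation(run.folded_trajs)
            dev_df = pd.DataFrame({"deviation_mean": dev.deviation,
                                   "running_mean": dev.running_mean})
            if dev.sem is not None:
                dev_df["sem"] = dev.sem
            dev_df.to_csv(out / f"deviation_{tag}.tsv", sep="\t", index=False)
            sampled = est.sampled & ~est.insufficient
            subset = [l for l, s in zip(est.labels, sampled) if s]
            report = accuracy_metrics(est, reference, subset,
                                      subset_tag=f"{tag}-sampled")
            stage.update({
                "transitions_total": trans["total"],
                "flattening_converged": {k: v.converged
                                         for k, v in run.flattening.items()},
                "flattening_steps": run.flattening_steps,
                "accuracy_vs_truth": {"rmse": report.rmse,
                                      "pearson_r": report.pearson_r,
                                      "n": report.n_common},
            })
            results[tag] = {"run": run, "estimate": est, "accuracy": report,
                            "transitions": trans, "deviation": dev}
            if config.save_trajectories:
                for k, traj in enumerate(run.folded_trajs):
                    traj.save(out / f"traj_{tag}_folded_{k}")
                for k, traj in enumerate(run.unfolded_trajs):
                    traj.save(out / f"traj_{tag}_unfolded_{k}")
        except Exception as exc:  # capture, do not abort the experiment
            logger.exception("stage %s failed", tag)
            stage = {"status": "error", "error": f"{type(exc).__name__}: {exc}"}
        stage["seconds"] = round(time.time() - t0, 2)
        manifest["stages"][tag] = stage

    if len(estimates) >= 2:
        tags = sorted(estimates)
        a, b = estimates[tags[0]], estimates[tags[1]]
        common = shared_subset(a, b)
        shared = {"subset": common, "n_common": len(common)}
        if len(common) >= 2:
            for tag in tags[:2]:
                rep = accuracy_metrics(estimates[tag], reference, common,
                                       subset_tag="shared")
                shared[tag] = {"rmse": rep.rmse, "pearson_r": rep.pearson_r}
        manifest["shared_subset"] = shared
        (out / "comparison.json").write_text(json.dumps(shared, indent=1))

    manifest["seconds_total"] = round(time.time() - t_start, 2)
    for f in sorted(out.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest["files"][f.name] = _checksum(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return results
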