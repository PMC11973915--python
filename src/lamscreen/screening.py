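"""Screening protocols: traditional landscape flattening (TLF),
competitive screening (CS), and the legacy linear-reference screen.

TLF trains separate biases in the folded and unfolded ensembles so every
substituent is sampled comparably in both — including deleterious
chemistries that disrupt the folded conformation.  CS trains biases in
the unfolded (reference) ensemble only and transfers them to the folded
ensemble: sampling then self-focuses on substituents whose folded free
energy beats their unfolded reference, so strongly destabilizing
chemistries are simply never visited, at half the flattening cost.  The
legacy screen reproduces the historical approach of using externally
supplied reference energies as the slope of a primitive linear bias.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .biasing import BiasSet, transfer
from .flattening import FlatteningResult, FlatteningSchedule, flatten, FlatteningLoss
from .lambda_dynamics import IntegratorParams, LambdaTrajectory, run_trajectory
from .toy_systems import AlchemicalSystem

logger = logging.getLogger(__name__)

__all__ = ["ProtocolSchedule", "ScreeningRun", "run_tlf", "run_cs",
           "run_legacy_linear"]


@dataclass
class ProtocolSchedule:
    """Sampling budget for one screening protocol."""

    flattening: FlatteningSchedule = field(default_factory=FlatteningSchedule)
    production_steps: int = 400_000
    production_stride: int = 10
    burn_in: float = 0.1
    integrator: IntegratorParams | None = None  # template for engine constants

    def production_params(self, seed: int) -> IntegratorParams:
        t = self.integrator or IntegratorParams()
        return IntegratorParams(
            n_steps=self.production_steps, stride=self.production_stride,
            dt=t.dt, gamma=t.gamma, m_theta=t.m_theta, m_x=t.m_x,
            steepness=t.steepness, ic_height=t.ic_height, ic_alpha=t.ic_alpha,
            seed=seed, burn_in=self.burn_in)


@dataclass
class ScreeningRun:
    """All artifacts of one protocol execution on one system."""

    protocol: str                       # TLF | CS | LEGACY
    system_id: str
    folded_trajs: list[LambdaTrajectory]
    unfolded_trajs: list[LambdaTrajectory]
    folded_biases: BiasSet
    unfolded_biases: BiasSet
    flattening: dict[str, FlatteningResult]
    trial_seeds: list[int]
    production_steps: int
    flattening_steps: int = 0           # total sampling spent on flattening
    meta: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return len(self.folded_trajs)


def _spawn_seeds(seed: int, tag: int, count: int) -> list[int]:
    ss = np.random.SeedSequence([int(seed), tag])
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(count)]


def _flattening_cost(schedule: FlatteningSchedule, result: FlatteningResult) -> int:
    return sum(schedule.steps_at(i) for i in range(result.iterations))


def _produce(system, ensemble, biases, schedule, seeds):
    trajs = []
    for s in seeds:
        trajs.append(run_trajectory(system, ensemble, biases,
                                    params=schedule.production_params(s),
                                    discard_burnin=True))
    return trajs


def _flatten_schedule(base: FlatteningSchedule, seed: int,
                      integrator: IntegratorParams | None) -> FlatteningSchedule:
    return FlatteningSchedule(
        n_iterations=base.n_iterations, steps_initial=base.steps_initial,
        growth=base.growth, steps_max=base.steps_max, stride=base.stride,
        n_bins=base.n_bins, endstate_threshold=base.endstate_threshold,
        flatness_target=base.flatness_target, seed=seed,
        integrator=integrator or base.integrator)


def run_tlf(system: AlchemicalSystem, trials: int = 5,
            schedule: ProtocolSchedule | None = None, seed: int = 0,
            loss_params: FlatteningLoss | None = None) -> ScreeningRun:
    """Traditional landscape flattening: train in both ensembles, produce
    in both under each ensemble's own biases.

    Flattening non-convergence does not abort: production proceeds with
    the flattest iteration's biases and the pathology stays visible in
    ``flattening[...].converged``.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    schedule = schedule or ProtocolSchedule()
    loss = loss_params or FlatteningLoss(kT=system.kT)
    flat_seeds = _spawn_seeds(seed, 0xF0, 2)
    results = {}
    for ens, fseed in zip(("folded", "unfolded"), flat_seeds):
        results[ens] = flatten(system, ens,
                               _flatten_schedule(schedule.flattening, fseed,
                                                 schedule.integrator), loss)
        if not results[ens].converged:
            logger.warning("TLF flattening did not converge in the %s ensemble "
                           "(best flatness %.1f)", ens,
                           min(results[ens].flatness_history))
    trial_seeds = _spawn_seeds(seed, 0x70, 2 * trials)
    folded = _produce(system, "folded", results["folded"].final_bias_set,
                      schedule, trial_seeds[:trials])
    unfolded = _produce(system, "unfolded", results["unfolded"].final_bias_set,
                        schedule, trial_seeds[trials:])
    cost = sum(_flattening_cost(schedule.flattening, r) for r in results.values())
    return ScreeningRun(
        protocol="TLF", system_id=f"{system.site_class}:N={system.n}",
        folded_trajs=folded, unfolded_trajs=unfolded,
        folded_biases=results["folded"].final_bias_set,
        unfolded_biases=results["unfolded"].final_bias_set,
        flattening=results, trial_seeds=trial_seeds,
        production_steps=schedule.production_steps, flattening_steps=cost,
        meta={"seed": seed, "trials": trials, "replica_exchange": "none"})


def run_cs(system: AlchemicalSystem, trials: int = 5,
           schedule: ProtocolSchedule | None = None, seed: int = 0,
           loss_params: FlatteningLoss | None = None) -> ScreeningRun:
    """Competitive screening: flatten the unfolded ensemble only and
    transfer its biases to the folded ensemble.

    No sampling is spent flattening the folded ensemble; folded
    production under transferred biases visits only substituents at
    least as favorable folded as unfolded, which filters out strongly
    destabilizing chemistries automatically.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    schedule = schedule or ProtocolSchedule()
    loss = loss_params or FlatteningLoss(kT=system.kT)
    fseed = _spawn_seeds(seed, 0xF0, 2)[1]  # same stream position as TLF's unfolded
    result = flatten(system, "unfolded",
                     _flatten_schedule(schedule.flattening, fseed,
                                       schedule.integrator), loss)
    if not result.converged:
        logger.warning("CS flattening did not converge (best flatness %.1f)",
                       min(result.flatness_history))
    transferred = transfer(result.final_bias_set, "folded")
    trial_seeds = _spawn_seeds(seed, 0x70, 2 * trials)
    folded = _produce(system, "folded", transferred, schedule,
                      trial_seeds[:trials])
    unfolded = _produce(system, "unfolded", result.final_bias_set, schedule,
                        trial_seeds[trials:])
    cost = _flattening_cost(schedule.flattening, result)
    return ScreeningRun(
        protocol="CS", system_id=f"{system.site_class}:N={system.n}",
        folded_trajs=folded, unfolded_trajs=unfolded,
        folded_biases=transferred, unfolded_biases=result.final_bias_set,
        flattening={"unfolded": result}, trial_seeds=trial_seeds,
        production_steps=schedule.production_steps, flattening_steps=cost,
        meta={"seed": seed, "trials": trials, "replica_exchange": "none"})


def run_legacy_linear(system: AlchemicalSystem, reference_energies: np.ndarray,
                      trials: int = 5, schedule: ProtocolSchedule | None = None,
                      seed: int = 0) -> ScreeningRun:
    """Legacy screen: reference energies as the slope of a primitive linear
    bias; folded production only, no flattening."""
    ref = np.asarray(reference_energies, dtype=float)
    if ref.shape != (system.n,) or not np.all(np.isfinite(ref)):
        raise ValueError("reference energies must be finite, one per substituent")
    if trials < 1:
        raise ValueError("trials must be >= 1")
    schedule = schedule or ProtocolSchedule()
    biases = BiasSet(b=ref.copy(), ensemble="folded",
                     provenance={"status": "trained",
                                 "trained_on": "reference-energies",
                                 "alf_iterations": 0})
    trial_seeds = _spawn_seeds(seed, 0x70, trials)
    folded = _produce(system, "folded", biases, schedule, trial_seeds)
    return ScreeningRun(
        protocol="LEGACY", system_id=f"{system.site_class}:N={system.n}",
        folded_trajs=folded, unfolded_trajs=[],
        folded_biases=biases, unfolded_biases=biases,
        flattening={}, trial_seeds=trial_seeds,
        production_steps=schedule.production_steps,
        meta={"seed": seed, "trials": trials})
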