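"""Langevin sampling of the joint (theta, x) space under the hybrid potential.

The alchemical coupling vector lambda lives on the probability simplex via
the implicit-constraint map

    lambda_i = exp(c sin theta_i) / sum_j exp(c sin theta_j)

over unbounded theta variables.  A large steepness c (default 8)
concentrates the stationary density near the simplex vertices, i.e. at
pure chemical end states, so the walker spends most of its time in
physically meaningful chemistries and transits the nonphysical alchemical
intermediates quickly.  The joint potential is

    U(theta, x) = sum_i lambda_i(theta) U_i^{ensemble}(x) + U_bias(lambda)

integrated with BAOAB Langevin splitting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .constants import DEFAULT_IC_ALPHA, DEFAULT_IC_HEIGHT, DEFAULT_STEEPNESS
from .biasing import BiasSet, bias_energy
from .toy_systems import AlchemicalSystem
from . import _kernels

__all__ = ["ThetaState", "IntegratorParams", "LambdaTrajectory",
           "lambda_from_theta", "hybrid_energy", "run_trajectory"]


class IntegrationError(RuntimeError):
    pass


@dataclass
class ThetaState:
    """Instantaneous state of the sampler."""

    theta: np.ndarray
    x: float = 0.0
    v_theta: np.ndarray | None = None
    v_x: float = 0.0
    time: float = 0.0

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        if self.v_theta is None:
            self.v_theta = np.zeros_like(self.theta)
        else:
            self.v_theta = np.asarray(self.v_theta, dtype=float)
        if not (np.all(np.isfinite(self.theta)) and np.isfinite(self.x)):
            raise ValueError("state entries must be finite")


@dataclass
class IntegratorParams:
    """Engine-level constants for the BAOAB integrator.

    Time units are arbitrary; with unit masses and force constants of a
    few kcal/mol the conformational well period is ~2 time units, so
    dt = 0.01 resolves the stiffest theta modes comfortably.
    """

    n_steps: int = 100_000
    stride: int = 10
    dt: float = 0.01
    gamma: float = 1.0
    m_theta: float = 0.1
    m_x: float = 1.0
    steepness: float = DEFAULT_STEEPNESS
    ic_height: float = DEFAULT_IC_HEIGHT
    ic_alpha: float = DEFAULT_IC_ALPHA
    seed: int = 0
    burn_in: float = 0.1  # fraction of frames dropped when requested

    def __post_init__(self):
        if self.dt <= 0 or self.gamma < 0 or self.m_theta <= 0 or self.m_x <= 0:
            raise ValueError("dt > 0, gamma >= 0, masses > 0 required")
        if self.steepness <= 0:
            raise ValueError("steepness must be > 0")
        if self.stride < 1 or self.n_steps < 1:
            raise ValueError("n_steps and stride must be >= 1")
        if not 0 <= self.burn_in < 1:
            raise ValueError("burn_in must be in [0, 1)")


@dataclass
class LambdaTrajectory:
    """Recorded (lambda, x) frames from one run."""

    times: np.ndarray
    lam: np.ndarray           # (frames, N), rows on the simplex
    x: np.ndarray             # (frames,)
    ensemble: str
    labels: list[str]
    seed: int
    bias_id: str = "untrained"
    meta: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.lam.shape[0]

    @property
    def n(self) -> int:
        return self.lam.shape[1]

    def validate(self, atol: float = 1e-9) -> None:
        if self.lam.shape[0] != self.x.shape[0]:
            raise ValueError("lam and x frame counts differ")
        if np.any(self.lam < -atol) or np.any(self.lam > 1 + atol):
            raise ValueError("lambda entries outside [0, 1]")
        if np.max(np.abs(self.lam.sum(axis=1) - 1.0)) > atol:
            raise ValueError("lambda rows must sum to 1")

    def save(self, path: str | Path) -> None:
        """Columnar binary container + JSON sidecar with run metadata."""
        path = Path(path)
        np.savez_compressed(path.with_suffix(".npz"),
                            times=self.times, lam=self.lam, x=self.x)
        sidecar = {"ensemble": self.ensemble, "labels": self.labels,
                   "seed": int(self.seed), "bias_id": self.bias_id,
                   "meta": self.meta}
        path.with_suffix(".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, path: str | Path) -> "LambdaTrajectory":
        path = Path(path)
        arrays = np.load(path.with_suffix(".npz"))
        sidecar = json.loads(path.with_suffix(".json").read_text())
        return cls(times=arrays["times"], lam=arrays["lam"], x=arrays["x"],
                   ensemble=sidecar["ensemble"], labels=sidecar["labels"],
                   seed=sidecar["seed"], bias_id=sidecar["bias_id"],
                   meta=sidecar.get("meta", {}))

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd
        df = pd.DataFrame(self.lam, columns=[f"lam_{l}" for l in self.labels])
        df.insert(0, "time", self.times)
        df["x"] = self.x
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def lambda_from_theta(theta: np.ndarray, steepness: float = DEFAULT_STEEPNESS
                      ) -> np.ndarray:
    """Map unbounded theta onto the lambda simplex (implicit constraints)."""
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    if not np.all(np.isfinite(theta)):
        raise ValueError("theta must be finite")
    if steepness <= 0:
        raise ValueError("steepness must be > 0")
    f = steepness * np.sin(theta)
    f -= f.max()
    e = np.exp(f)
    return e / e.sum()


def implicit_constraint_energy(lam: np.ndarray,
                               height: float = DEFAULT_IC_HEIGHT,
                               alpha: float = DEFAULT_IC_ALPHA) -> float:
    """Activity restraint U_ic = height * sum_i (1 - exp(-lam_i / alpha)).

    Part of the implicit-constraint scheme: a saturating count of
    alchemically active substituents that presses spectator lambdas to
    zero and penalizes mixed alchemical intermediates.  The common
    single-active-substituent offset is subtracted, so the restraint is
    exactly zero at every pure end state.
    """
    lam = np.asarray(lam, dtype=float)
    total = float(np.sum(1.0 - np.exp(-lam / alpha)))
    return height * (total - (1.0 - np.exp(-1.0 / alpha)))


def hybrid_energy(lam: np.ndarray, x: float, system: AlchemicalSystem,
                  biases: BiasSet,
                  ic_height: float = DEFAULT_IC_HEIGHT,
                  ic_alpha: float = DEFAULT_IC_ALPHA) -> float:
    """U = sum_i lam_i U_i^{ensemble}(x) + U_bias(lam) + U_ic(lam).

    The ensemble is taken from the bias set's label.  At a pure end state
    both U_bias pairwise families and U_ic vanish, so U reduces to that
    substituent's potential minus its linear bias.
    """
    lam = np.asarray(lam, dtype=float)
    if lam.shape != (system.n,):
        raise ValueError(f"lambda shape {lam.shape} does not match system N={system.n}")
    u = np.array([s.energy(x, biases.ensemble) for s in system.substituents])
    return (float(lam @ u) + bias_energy(lam, biases)
            + implicit_constraint_energy(lam, ic_height, ic_alpha))


def _auto_init(system: AlchemicalSystem, ensemble: str,
               params: IntegratorParams, rng: np.random.Generator) -> ThetaState:
    n = system.n
    theta = rng.uniform(-np.pi, np.pi, size=n)
    if ensemble == "folded":
        x = 0.0  # native basin center by convention
    else:
        x = float(system.substituents[system.native_index].u_center)
    kT = system.kT
    v_theta = rng.normal(0.0, np.sqrt(kT / params.m_theta), size=n)
    v_x = float(rng.normal(0.0, np.sqrt(kT / params.m_x)))
    return ThetaState(theta=theta, x=x, v_theta=v_theta, v_x=v_x)


def run_trajectory(system: AlchemicalSystem, ensemble: str, biases: BiasSet,
                   init: ThetaState | str = "auto",
                   params: IntegratorParams | None = None,
                   discard_burnin: bool = False,
                   kT_override: float | None = None) -> LambdaTrajectory:
    """Sample a lambda trajectory with BAOAB Langevin dynamics.

    Deterministic given ``params.seed``.  With ``discard_burnin`` the first
    ``params.burn_in`` fraction of recorded frames is dropped (equilibration).
    ``kT_override`` substitutes the thermostat temperature only (the
    potential is unchanged); it exists for zero-temperature descent tests.
    """
    if params is None:
        params = IntegratorParams()
    if ensemble not in ("folded", "unfolded"):
        raise ValueError(f"unknown ensemble {ensemble!r}")
    if biases.n != system.n:
        raise ValueError("bias set size does not match system")
    ss = np.random.SeedSequence([int(params.seed), 0x1A5C])
    init_rng = np.random.default_rng(ss.spawn(1)[0])
    kernel_seed = int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
    if init == "auto":
        state = _auto_init(system, ensemble, params, init_rng)
    else:
        state = init
        if state.theta.shape != (system.n,):
            raise ValueError("init state size does not match system")
    kT = system.kT if kT_override is None else float(kT_override)

    n_frames = params.n_steps // params.stride
    lam_frames = np.empty((n_frames, system.n))
    x_frames = np.empty(n_frames)
    theta = state.theta.copy()
    v_theta = state.v_theta.copy()
    pmat = system.param_matrix(ensemble)
    if biases.family != "default":
        raise ValueError("the sampling engine supports the 'default' bias family")
    status, step, x_fin, v_x_fin = _kernels.baoab_run_kernel(
        theta, float(state.x), v_theta, float(state.v_x), pmat,
        biases.b, biases.c_mat, biases.s_mat, biases.x_mat,
        biases.alpha, biases.alpha_skew, params.steepness,
        params.ic_height, params.ic_alpha,
        params.dt, params.gamma, kT, params.m_theta, params.m_x,
        int(params.n_steps), int(params.stride), kernel_seed,
        lam_frames, x_frames)
    if status != _kernels.STATUS_OK:
        raise IntegrationError(
            f"non-finite energy at step {step} (ensemble={ensemble}, "
            f"seed={params.seed}, theta={theta}, x={x_fin})")
    first = int(np.floor(params.burn_in * n_frames)) if discard_burnin else 0
    times = (np.arange(n_frames) + 1) * params.stride * params.dt
    bias_id = (f"{biases.provenance.get('status', 'untrained')}:"
               f"{biases.provenance.get('trained_on', '-')}:"
               f"iter{biases.provenance.get('alf_iterations', 0)}")
    traj = LambdaTrajectory(
        times=times[first:], lam=lam_frames[first:], x=x_frames[first:],
        ensemble=ensemble, labels=system.labels, seed=int(params.seed),
        bias_id=bias_id,
        meta={"params": asdict(params), "burned_frames": first,
              "final_state": {"x": x_fin, "v_x": v_x_fin}})
    return traj
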