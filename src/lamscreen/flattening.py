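"""Adaptive landscape flattening (ALF).

Iteratively trains a :class:`~lamscreen.biasing.BiasSet` so that all
substituents of a site are sampled comparably in a given ensemble.  Each
iteration runs a trajectory under the current biases, histograms the
lambda coordinates, and updates the coefficients:

* linear terms move by the log-ratio of observed end-state populations to
  the uniform target (the stochastic estimator of the end-state free
  energy differences), smoothed, capped per iteration, with a declared
  rule for never-visited substituents;
* pairwise terms (quadratic / endpoint / skew) are fit per substituent
  pair to the residual profile free energy -kT ln h(lambda) along the
  pair's alchemical path, under a saturating (Huber) loss so sparsely
  sampled bins cannot dominate the fit.

Convergence is declared when the end-state population max/min ratio stays
at or below the flatness target for two consecutive iterations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .constants import DEFAULT_ENDSTATE_THRESHOLD, KT_ROOM
from .biasing import BiasSet
from .lambda_dynamics import IntegratorParams, LambdaTrajectory, run_trajectory
from .toy_systems import AlchemicalSystem

logger = logging.getLogger(__name__)

__all__ = ["LambdaProfiles", "FlatteningLoss", "FlatteningSchedule",
           "FlatteningResult", "estimate_profiles", "update_biases", "flatten"]


@dataclass
class LambdaProfiles:
    """Histograms of the lambda coordinates from one trajectory."""

    hist: np.ndarray              # (N, n_bins) per-substituent lambda_i counts
    bin_edges: np.ndarray         # (n_bins + 1,)
    endstate_counts: np.ndarray   # (N,) frames with lambda_i > threshold
    occupied: np.ndarray          # (N, n_bins) bool, bins with >= min samples
    pair_hist: np.ndarray         # (N, N, n_bins) lambda_i counts on (i, j)-dominant frames
    n_frames: int
    endstate_threshold: float

    @property
    def n(self) -> int:
        return self.hist.shape[0]


@dataclass
class FlatteningLoss:
    """Tunables of the ALF update rule."""

    kT: float = KT_ROOM
    eps_count: float = 0.5        # additive smoothing on end-state counts
    db_max: float = 2.0           # per-iteration cap on linear increments (kcal/mol)
    huber_scale_kT: float = 2.0   # saturation scale of the profile-fit loss, in kT
    pair_cap: float = 2.0         # per-iteration cap on pairwise increments (kcal/mol)
    min_bin_count: int = 5        # bin occupancy below this is masked
    min_pair_bins: int = 6        # occupied interior bins needed for a pair fit
    pair_dominance: float = 0.8   # lam_i + lam_j above this marks an (i, j) frame


@dataclass
class FlatteningSchedule:
    """Iteration budget for ALF; step counts grow geometrically."""

    n_iterations: int = 14
    steps_initial: int = 10_000
    growth: float = 1.5
    steps_max: int = 600_000
    stride: int = 5
    n_bins: int = 20
    endstate_threshold: float = DEFAULT_ENDSTATE_THRESHOLD
    flatness_target: float = 5.0
    seed: int = 0
    integrator: IntegratorParams | None = None  # template; n_steps/seed overridden

    def steps_at(self, iteration: int) -> int:
        s = self.steps_initial * self.growth ** iteration
        return int(min(s, self.steps_max))


@dataclass
class FlatteningResult:
    bias_set: BiasSet             # best iteration: most substituents, flattest
    final_bias_set: BiasSet       # biases after the last update
    iterations: int
    flatness_history: list[float] = field(default_factory=list)
    converged: bool = False
    trajectory_seeds: list[int] = field(default_factory=list)

    def save(self, path) -> None:
        """Write a JSON summary plus the trained BiasSet next to it, and
        the per-iteration flatness diagnostics as TSV."""
        import json
        from pathlib import Path
        path = Path(path)
        base = path.with_suffix("")
        self.final_bias_set.save(base.with_name(base.name + "_biases.json"))
        summary = {"iterations": self.iterations, "converged": self.converged,
                   "flatness_history": self.flatness_history,
                   "trajectory_seeds": self.trajectory_seeds,
                   "bias_file": base.name + "_biases.json"}
        path.write_text(json.dumps(summary, indent=1))
        lines = ["iteration\tsteps_seed\tflatness"]
        for i, (s, m) in enumerate(zip(self.trajectory_seeds,
                                       self.flatness_history)):
            lines.append(f"{i}\t{s}\t{m:.4f}")
        base.with_name(base.name + "_iterations.tsv").write_text(
            "\n".join(lines) + "\n")


def estimate_profiles(traj: LambdaTrajectory, n_bins: int = 20,
                      endstate_threshold: float = DEFAULT_ENDSTATE_THRESHOLD,
                      min_bin_count: int = 5,
                      pair_dominance: float = 0.8) -> LambdaProfiles:
    """Histogram lambda per substituent and per dominant pair."""
    if not 0.5 < endstate_threshold < 1:
        raise ValueError("endstate_threshold must be in (0.5, 1)")
    lam = traj.lam
    if lam.shape[0] == 0:
        raise ValueError("empty trajectory: no frames to histogram")
    n_frames, n = lam.shape
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    hist = np.stack([np.histogram(lam[:, i], bins=edges)[0] for i in range(n)])
    endstate = (lam > endstate_threshold).sum(axis=0)

    # pair-dominant frames: top two lambdas carry nearly all the weight
    order = np.argpartition(lam, n - 2, axis=1)[:, -2:]
    top_vals = np.take_along_axis(lam, order, axis=1)
    pair_ok = top_vals.sum(axis=1) >= pair_dominance
    a = order.min(axis=1)
    b = order.max(axis=1)
    pair_hist = np.zeros((n, n, n_bins))
    if pair_ok.any():
        ai, bi = a[pair_ok], b[pair_ok]
        lam_ai = lam[pair_ok, ai]
        bins = np.clip(np.digitize(lam_ai, edges) - 1, 0, n_bins - 1)
        np.add.at(pair_hist, (ai, bi, bins), 1.0)
    return LambdaProfiles(hist=hist, bin_edges=edges, endstate_counts=endstate,
                          occupied=hist >= min_bin_count, pair_hist=pair_hist,
                          n_frames=n_frames, endstate_threshold=endstate_threshold)


def _pair_basis(t: np.ndarray, alpha: float, alpha_skew: float) -> np.ndarray:
    """Bias-family shapes along the (i, j) path lam_i = t, lam_j = 1 - t.

    Columns: c_ij, s_ij, s_ji, x_ij, x_ji increments.
    """
    u = 1.0 - t
    return np.column_stack([
        t * u,
        u * t / (t + alpha),
        t * u / (u + alpha),
        t * u * np.exp(-t / alpha_skew),
        t * u * np.exp(-u / alpha_skew),
    ])


def _linear_increments(counts: np.ndarray, loss: FlatteningLoss) -> np.ndarray:
    """End-state population equalization: undersampled substituents get
    positive increments (larger b -> sampled more)."""
    n = counts.shape[0]
    total = counts.sum()
    if total == 0:
        return np.zeros(n)
    visited = counts > 0
    p = (counts + loss.eps_count) / (total + n * loss.eps_count)
    inc = -loss.kT * np.log(p * n)
    if (~visited).any():
        inc[~visited] = inc[visited].max() + loss.kT * np.log(2.0)
    return np.clip(inc, -loss.db_max, loss.db_max)


def update_biases(profiles: LambdaProfiles, current: BiasSet,
                  loss_params: FlatteningLoss | None = None) -> BiasSet:
    """One ALF update: linear end-state equalization + pairwise profile fit."""
    loss = loss_params or FlatteningLoss()
    if profiles.n != current.n:
        raise ValueError("profiles and bias set sizes differ")
    new = current.copy()
    new.b = new.b + _linear_increments(profiles.endstate_counts, loss)

    kT = loss.kT
    edges = profiles.bin_edges
    centers = 0.5 * (edges[:-1] + edges[1:])
    interior = (centers > 0.025) & (centers < 0.975)
    n = profiles.n
    for i in range(n):
        for j in range(i + 1, n):
            h_ij = profiles.pair_hist[i, j]
            mask = interior & (h_ij >= loss.min_bin_count)
            if mask.sum() < loss.min_pair_bins:
                continue
            t = centers[mask]
            f = -kT * np.log(h_ij[mask])
            f -= f.mean()
            X = _pair_basis(t, current.alpha, current.alpha_skew)

            def residual(beta, f=f, X=X):
                return f + X @ beta

            fit = least_squares(residual, np.zeros(5), loss="huber",
                                f_scale=loss.huber_scale_kT * kT,
                                bounds=(-loss.pair_cap, loss.pair_cap),
                                max_nfev=200)
            beta = fit.x
            new.c_mat[i, j] += beta[0]
            new.c_mat[j, i] += beta[0]
            new.s_mat[i, j] += beta[1]
            new.s_mat[j, i] += beta[2]
            new.x_mat[i, j] += beta[3]
            new.x_mat[j, i] += beta[4]

    prov = dict(current.provenance)
    prov["status"] = "trained"
    prov["alf_iterations"] = prov.get("alf_iterations", 0) + 1
    prov.setdefault("trained_on", current.ensemble)
    new.provenance = prov
    return new


def flatness_metric(counts: np.ndarray, eps: float = 0.5) -> float:
    """(max end-state population + eps) / (min + eps); 1 is perfectly flat."""
    return float((counts.max() + eps) / (counts.min() + eps))


def flatten(system: AlchemicalSystem, ensemble: str,
            schedule: FlatteningSchedule | None = None,
            loss_params: FlatteningLoss | None = None) -> FlatteningResult:
    """Train a BiasSet by alternating sampling, profiling and updating.

    Never raises on non-convergence: the result carries ``converged=False``
    and the bias set from the flattest iteration, so callers can surface
    the pathology instead of crashing mid-protocol.
    """
    schedule = schedule or FlatteningSchedule()
    loss = loss_params or FlatteningLoss(kT=system.kT)
    if schedule.n_iterations < 3:
        raise ValueError("flattening needs at least 3 iterations")
    ss = np.random.SeedSequence([int(schedule.seed), 0xF1A7])
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(schedule.n_iterations)]

    template = schedule.integrator or IntegratorParams()
    biases = BiasSet.zeros(system.n, ensemble=ensemble)
    history: list[float] = []
    best_key = (-1, np.inf)  # (substituents visited, -flatness): coverage first
    best_biases = biases
    converged = False
    iterations = 0
    for it in range(schedule.n_iterations):
        params = IntegratorParams(
            n_steps=schedule.steps_at(it), stride=schedule.stride,
            dt=template.dt, gamma=template.gamma, m_theta=template.m_theta,
            m_x=template.m_x, steepness=template.steepness,
            ic_height=template.ic_height, ic_alpha=template.ic_alpha,
            seed=seeds[it], burn_in=template.burn_in)
        traj = run_trajectory(system, ensemble, biases, params=params,
                              discard_burnin=True)
        profiles = estimate_profiles(
            traj, n_bins=schedule.n_bins,
            endstate_threshold=schedule.endstate_threshold,
            min_bin_count=loss.min_bin_count,
            pair_dominance=loss.pair_dominance)
        metric = flatness_metric(profiles.endstate_counts, loss.eps_count)
        history.append(metric)
        iterations = it + 1
        key = (int((profiles.endstate_counts > 0).sum()), -metric)
        if key > best_key:
            best_key = key
            best_biases = biases
        logger.info("ALF %s iteration %d: flatness %.2f (%d steps)",
                    ensemble, it, metric, params.n_steps)
        biases = update_biases(profiles, biases, loss)
        if (len(history) >= 2 and history[-1] <= schedule.flatness_target
                and history[-2] <= schedule.flatness_target):
            converged = True
            break

    final = biases
    if not best_biases.trained:
        # the flattest iteration can be the first (untrained zeros); fall back
        # to the latest trained set so provenance reflects actual training
        best_biases = final
    return FlatteningResult(bias_set=best_biases, final_bias_set=final,
                            iterations=iterations, flatness_history=history,
                            converged=converged, trajectory_seeds=seeds[:iterations])
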