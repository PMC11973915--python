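"""Free energies from lambda trajectories.

With end-state-focused sampling, the relative free energy of substituent i
in one ensemble follows from end-state populations:

    dG_i = -kT ln(N_i / N_native) - [U_bias(e_i) - U_bias(e_native)]

where N_i counts frames with lambda_i above the end-state threshold and
the bias evaluated at pure end states undoes the sampling bias (for the
default families this reduces to +(b_i - b_native), since the pairwise
terms vanish at end states).  Relative unfolding free energies close the
thermodynamic cycle,

    ddG_i = -[dG_folded,i - dG_unfolded,i]

(negative = destabilizing to folding); protonation sub-states of one
parent chemistry are combined by a Boltzmann average dominated by the
most favorable state; uncertainties come from bootstrapping over
independent trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .constants import (DEFAULT_ENDSTATE_THRESHOLD, DEFAULT_MIN_COUNT, KT_ROOM)
from .biasing import BiasSet
from .lambda_dynamics import LambdaTrajectory

__all__ = ["FreeEnergyEstimate", "endstate_counts", "relative_free_energies",
           "unfolding_ddg", "combine_protonation_states",
           "bootstrap_over_trials", "estimate_run"]


class EstimationError(RuntimeError):
    pass


@dataclass
class FreeEnergyEstimate:
    """Per-substituent free energies for one screening run.

    Unsampled substituents carry NaN; ``insufficient`` flags those with
    fewer than two trials of finite ddG (no bootstrap uncertainty).
    """

    labels: list[str]
    dg_folded: np.ndarray
    dg_unfolded: np.ndarray
    ddg: np.ndarray
    per_trial_ddg: np.ndarray          # (trials, N), NaN where unsampled
    boot_mean: np.ndarray
    boot_sd: np.ndarray
    sampled_folded: np.ndarray
    sampled_unfolded: np.ndarray
    insufficient: np.ndarray
    native_index: int
    endstate_threshold: float
    min_count: int
    meta: dict = field(default_factory=dict)

    @property
    def sampled(self) -> np.ndarray:
        return self.sampled_folded & self.sampled_unfolded

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "substituent": self.labels,
            "dG_folded": self.dg_folded, "dG_unfolded": self.dg_unfolded,
            "ddG": self.ddg, "boot_mean": self.boot_mean,
            "boot_sd": self.boot_sd,
            "sampled_folded": self.sampled_folded,
            "sampled_unfolded": self.sampled_unfolded,
            "n_trials": np.sum(np.isfinite(self.per_trial_ddg), axis=0),
        })


def endstate_counts(traj: LambdaTrajectory,
                    threshold: float = DEFAULT_ENDSTATE_THRESHOLD) -> np.ndarray:
    """Frames per substituent with lambda_i > threshold (exclusive above 0.5)."""
    if not 0.5 < threshold < 1:
        raise ValueError("threshold must be in (0.5, 1)")
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    return (traj.lam > threshold).sum(axis=0)


def relative_free_energies(traj: LambdaTrajectory, biases: BiasSet,
                           kT: float = KT_ROOM,
                           min_count: int = DEFAULT_MIN_COUNT,
                           native_index: int = 0,
                           endstate_threshold: float = DEFAULT_ENDSTATE_THRESHOLD,
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Per-substituent dG (native = 0) and sampled flags from one trajectory."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    counts = endstate_counts(traj, endstate_threshold)
    if counts[native_index] < min_count:
        raise EstimationError(
            f"native substituent has only {counts[native_index]} end-state "
            f"frames (< {min_count}); no reference for relative free energies")
    sampled = counts >= min_count
    bias_end = biases.endstate_energies()
    dg = np.full(traj.n, np.nan)
    with np.errstate(divide="ignore"):
        ratio = counts / counts[native_index]
    dg[sampled] = (-kT * np.log(ratio[sampled])
                   - (bias_end[sampled] - bias_end[native_index]))
    return dg, sampled


def unfolding_ddg(folded: np.ndarray, unfolded: np.ndarray) -> np.ndarray:
    """ddG_i = -(dG_folded,i - dG_unfolded,i); negative destabilizes folding."""
    folded = np.asarray(folded, dtype=float)
    unfolded = np.asarray(unfolded, dtype=float)
    if folded.shape != unfolded.shape:
        raise ValueError("folded and unfolded vectors must align")
    return -(folded - unfolded)


def combine_protonation_states(ddg_states: np.ndarray, weights: np.ndarray,
                               kT: float = KT_ROOM) -> tuple[float, int]:
    """Boltzmann-average ddG over protonation sub-states.

    ddG_comb = +kT ln sum_s w_s exp(ddG_s / kT), so the most favorable
    (largest-ddG) state dominates in the large-separation limit.  NaN
    (unsampled) states are dropped with weight renormalization; returns
    (value, number of states used) with value NaN when none are sampled.
    """
    g = np.asarray(ddg_states, dtype=float)
    w = np.asarray(weights, dtype=float)
    if g.shape != w.shape or g.ndim != 1 or g.size < 1:
        raise ValueError("states and weights must be equal-length vectors")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    ok = np.isfinite(g)
    if not ok.any() or w[ok].sum() == 0:
        return float("nan"), 0
    w_used = w[ok] / w[ok].sum()
    val = kT * logsumexp(g[ok] / kT, b=w_used)
    return float(val), int(ok.sum())


def bootstrap_over_trials(per_trial_ddg: np.ndarray, n_boot: int = 1000,
                          seed: int = 0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Resample trials with replacement; per-substituent mean and expanded
    sd of the resampled trial means.

    With only a handful of trials the raw bootstrap sd of the mean is
    biased low (by sqrt((n-1)/n)) and, worse, +/-2-sd intervals built
    from any variance estimate at small n need Student-t rather than
    normal width to cover at the nominal rate.  The reported sd is
    therefore the expanded bootstrap standard error,

        sd = sd_raw * sqrt(n/(n-1)) * t_{0.975, n-1} / z_{0.975},

    so that mean +/- 2 sd behaves like a ~95% interval even at n = 5.
    Substituents finite in < 2 trials are flagged insufficient (their sd
    is NaN).
    """
    from scipy import stats as _stats

    data = np.atleast_2d(np.asarray(per_trial_ddg, dtype=float))
    n_trials, n = data.shape
    if n_trials < 1:
        raise ValueError("need at least one trial")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng([int(seed), 0xB007])
    idx = rng.integers(0, n_trials, size=(n_boot, n_trials))
    resampled = data[idx]                      # (n_boot, n_trials, N)
    with np.errstate(invalid="ignore"):
        means = np.nanmean(resampled, axis=1)  # (n_boot, N)
        boot_mean = np.nanmean(means, axis=0)
        boot_sd = np.nanstd(means, axis=0)
    n_eff = np.isfinite(data).sum(axis=0)
    insufficient = n_eff < 2
    ok = ~insufficient
    z975 = _stats.norm.ppf(0.975)
    expand = np.ones(n)
    expand[ok] = (np.sqrt(n_eff[ok] / (n_eff[ok] - 1))
                  * _stats.t.ppf(0.975, n_eff[ok] - 1) / z975)
    boot_sd = boot_sd * expand
    boot_sd[insufficient] = np.nan
    boot_mean[insufficient] = np.nan
    return boot_mean, boot_sd, insufficient


def estimate_run(folded_trajs: list[LambdaTrajectory],
                 unfolded_trajs: list[LambdaTrajectory],
                 folded_biases: BiasSet, unfolded_biases: BiasSet,
                 kT: float = KT_ROOM, native_index: int = 0,
                 endstate_threshold: float = DEFAULT_ENDSTATE_THRESHOLD,
                 min_count: int = DEFAULT_MIN_COUNT,
                 n_boot: int = 1000, boot_seed: int = 0,
                 labels: list[str] | None = None) -> FreeEnergyEstimate:
    """Full per-trial estimation + cycle closure + bootstrap for one run.

    Folded and unfolded trials are paired positionally; a trial whose
    native substituent is unsampled in either ensemble contributes NaN
    for every substituent of that ensemble.
    """
    if len(folded_trajs) != len(unfolded_trajs):
        raise ValueError("need matching folded/unfolded trial lists")
    n_trials = len(folded_trajs)
    n = folded_trajs[0].n
    labels = labels or folded_trajs[0].labels
    per_trial_f = np.full((n_trials, n), np.nan)
    per_trial_u = np.full((n_trials, n), np.nan)
    for t, (tf, tu) in enumerate(zip(folded_trajs, unfolded_trajs)):
        for traj, biases, store in ((tf, folded_biases, per_trial_f),
                                    (tu, unfolded_biases, per_trial_u)):
            try:
                dg, _ = relative_free_energies(
                    traj, biases, kT=kT, min_count=min_count,
                    native_index=native_index,
                    endstate_threshold=endstate_threshold)
                store[t] = dg
            except EstimationError:
                pass  # whole trial unusable in this ensemble; stays NaN
    per_trial_ddg = -(per_trial_f - per_trial_u)

    def _mean(a):
        with np.errstate(invalid="ignore"):
            out = np.nanmean(a, axis=0)
        return out

    with np.errstate(invalid="ignore"):
        dg_f = _mean(per_trial_f)
        dg_u = _mean(per_trial_u)
        ddg = _mean(per_trial_ddg)
    sampled_f = np.isfinite(per_trial_f).any(axis=0)
    sampled_u = np.isfinite(per_trial_u).any(axis=0)
    boot_mean, boot_sd, insufficient = bootstrap_over_trials(
        per_trial_ddg, n_boot=n_boot, seed=boot_seed)
    return FreeEnergyEstimate(
        labels=labels, dg_folded=dg_f, dg_unfolded=dg_u, ddg=ddg,
        per_trial_ddg=per_trial_ddg, boot_mean=boot_mean, boot_sd=boot_sd,
        sampled_folded=sampled_f, sampled_unfolded=sampled_u,
        insufficient=insufficient, native_index=native_index,
        endstate_threshold=endstate_threshold, min_count=min_count,
        meta={"n_trials": n_trials, "n_boot": n_boot, "boot_seed": boot_seed})
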