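"""Run diagnostics: alchemical transitions, conformational disruption,
shared-subset selection, and accuracy metrics.

Transition counting is the convergence proxy: frames are reduced to the
sequence of end-state visits (lambda above threshold), consecutive
repeats collapse, and each identity change counts as one transition
attributed to the arriving substituent.  Frames with no lambda above
threshold (alchemical no-man's-land) are ignored rather than treated as
a state, which makes the count robust to the exact threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .constants import DEFAULT_ENDSTATE_THRESHOLD
from .estimation import FreeEnergyEstimate
from .lambda_dynamics import LambdaTrajectory

logger = logging.getLogger(__name__)

__all__ = ["TransitionReport", "DeviationTrace", "ComparisonReport",
           "count_transitions", "aggregate_transitions", "deviation_trace",
           "aggregate_deviation", "shared_subset", "accuracy_metrics"]


@dataclass
class TransitionReport:
    arrivals: np.ndarray     # per-substituent arrival counts
    total: int
    threshold: float
    labels: list[str] = field(default_factory=list)


@dataclass
class DeviationTrace:
    deviation: np.ndarray        # per-frame |x - x_native|
    running_mean: np.ndarray
    sem: np.ndarray | None = None  # across trials, set by aggregate_deviation


@dataclass
class ComparisonReport:
    rmse: float
    pearson_r: float | None
    n_common: int
    subset: list[str]
    residuals: np.ndarray
    subset_tag: str = ""


def _visit_sequence(traj: LambdaTrajectory, threshold: float) -> np.ndarray:
    if not 0.5 < threshold < 1:
        raise ValueError("threshold must be in (0.5, 1)")
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    lam = traj.lam
    mx = lam.max(axis=1)
    above = mx > threshold
    dom = lam.argmax(axis=1)[above]
    if dom.size == 0:
        return dom
    keep = np.concatenate(([True], np.diff(dom) != 0))
    return dom[keep]


def count_transitions(traj: LambdaTrajectory,
                      threshold: float = DEFAULT_ENDSTATE_THRESHOLD
                      ) -> TransitionReport:
    """Arrivals per substituent; a transition is a change of dominant
    end-state identity between successive end-state visits."""
    seq = _visit_sequence(traj, threshold)
    arrivals = np.zeros(traj.n, dtype=int)
    if seq.size > 1:
        np.add.at(arrivals, seq[1:], 1)
    return TransitionReport(arrivals=arrivals, total=int(arrivals.sum()),
                            threshold=threshold, labels=traj.labels)


def aggregate_transitions(trajs: list[LambdaTrajectory],
                          threshold: float = DEFAULT_ENDSTATE_THRESHOLD
                          ) -> dict:
    """Per-trial and pooled transition counts across trials."""
    reports = [count_transitions(t, threshold) for t in trajs]
    arrivals = np.stack([r.arrivals for r in reports])
    # pooled granularity: identity changes in the concatenated visit
    # sequence, counting switches across trial boundaries too
    pooled_seq = np.concatenate([_visit_sequence(t, threshold) for t in trajs])
    pooled = 0
    if pooled_seq.size > 1:
        pooled = int((np.diff(pooled_seq) != 0).sum())
    return {"per_trial": reports,
            "arrivals_total": arrivals.sum(axis=0),
            "total": int(arrivals.sum()),
            "pooled_total": pooled}


def deviation_trace(traj: LambdaTrajectory, native_x: float = 0.0
                    ) -> DeviationTrace:
    """Per-frame |x - x_native| with running mean (toy analog of a
    backbone-RMSD trace)."""
    dev = np.abs(traj.x - native_x)
    running = np.cumsum(dev) / np.arange(1, dev.size + 1)
    return DeviationTrace(deviation=dev, running_mean=running)


def aggregate_deviation(trajs: list[LambdaTrajectory], native_x: float = 0.0
                        ) -> DeviationTrace:
    """Mean +/- SEM per frame index across trials, aligned on the shortest."""
    traces = [np.abs(t.x - native_x) for t in trajs]
    n_min = min(len(d) for d in traces)
    if any(len(d) != n_min for d in traces):
        logger.warning("trial lengths differ; aligning on %d frames", n_min)
    mat = np.stack([d[:n_min] for d in traces])
    mean = mat.mean(axis=0)
    sem = (mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0])
           if mat.shape[0] >= 2 else None)
    running = np.cumsum(mean) / np.arange(1, n_min + 1)
    return DeviationTrace(deviation=mean, running_mean=running, sem=sem)


def shared_subset(a: FreeEnergyEstimate, b: FreeEnergyEstimate) -> list[str]:
    """Labels sampled in both ensembles of both estimates, with bootstrap
    uncertainties available in both (the fair-comparison subset)."""
    if a.labels != b.labels:
        raise ValueError("estimates cover different substituent labels")
    ok = (a.sampled & b.sampled & ~a.insufficient & ~b.insufficient)
    return [l for l, keep in zip(a.labels, ok) if keep]


def accuracy_metrics(est: dict[str, float] | FreeEnergyEstimate,
                     reference: dict[str, float],
                     subset: list[str], subset_tag: str = "") -> ComparisonReport:
    """RMSE and Pearson R of estimated vs reference ddG over a subset."""
    if isinstance(est, FreeEnergyEstimate):
        est = dict(zip(est.labels, est.ddg))
    missing = [l for l in subset if l not in est or l not in reference]
    if missing:
        raise ValueError(f"subset labels missing from inputs: {missing}")
    if len(subset) < 2:
        raise ValueError("accuracy metrics need at least 2 substituents")
    e = np.array([est[l] for l in subset])
    r = np.array([reference[l] for l in subset])
    resid = e - r
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    pearson = None
    if len(subset) >= 3:
        pearson = float(stats.pearsonr(e, r).statistic)
    return ComparisonReport(rmse=rmse, pearson_r=pearson, n_common=len(subset),
                            subset=list(subset), residuals=resid,
                            subset_tag=subset_tag)
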