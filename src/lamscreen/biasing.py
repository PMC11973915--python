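"""Alchemical bias potentials acting on the lambda vector.

The bias is the object landscape flattening trains.  Four coefficient
families act on the simplex:

    U_bias(lam) = - sum_i b_i lam_i
                  + sum_{i<j} c_ij lam_i lam_j
                  + sum_{i!=j} s_ij lam_j lam_i / (lam_i + alpha)
                  + sum_{i!=j} x_ij lam_i lam_j exp(-lam_i / alpha_skew)

Linear terms b shift end-state populations (larger b_i -> substituent i
sampled MORE, since the term enters with a minus sign); the quadratic,
endpoint and skew families shape the barriers between end states without
moving the end states themselves: all three pairwise families vanish at
every pure end state, so end-state free energies are corrected by the
linear terms alone.  The exact functional forms sit behind a named
registry ("default" above) so alternative endpoint/skew shapes can be
registered without touching downstream logic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["BiasSet", "bias_energy", "bias_gradient", "transfer",
           "BIAS_FAMILIES", "register_family"]

DEFAULT_ALPHA = 0.017
DEFAULT_ALPHA_SKEW = 0.18


def _default_energy(lam, b, c_mat, s_mat, x_mat, alpha, alpha_skew):
    lam = np.asarray(lam, dtype=float)
    e = -float(b @ lam)
    e += 0.5 * float(lam @ c_mat @ lam)  # c_mat symmetric, zero diagonal
    frac = lam / (lam + alpha)           # lam_i/(lam_i+alpha) per row i
    e += float(frac @ s_mat @ lam)       # sum_{i!=j} s_ij lam_j lam_i/(lam_i+a)
    sk = lam * np.exp(-lam / alpha_skew)
    e += float(sk @ x_mat @ lam)
    return e


def _default_gradient(lam, b, c_mat, s_mat, x_mat, alpha, alpha_skew):
    lam = np.asarray(lam, dtype=float)
    g = -b.copy()
    g += c_mat @ lam
    # endpoint: d/dlam_k [ sum_{i!=j} s_ij lam_j lam_i/(lam_i+a) ]
    frac = lam / (lam + alpha)
    dfrac = alpha / (lam + alpha) ** 2
    g += dfrac * (s_mat @ lam)     # i = k
    g += s_mat.T @ frac            # j = k
    # skew: sum_{i!=j} x_ij lam_i lam_j exp(-lam_i/as)
    ex = np.exp(-lam / alpha_skew)
    g += ex * (1.0 - lam / alpha_skew) * (x_mat @ lam)  # i = k
    g += x_mat.T @ (lam * ex)                           # j = k
    return g


BIAS_FAMILIES = {"default": (_default_energy, _default_gradient)}


def register_family(name, energy_fn, gradient_fn):
    """Register an alternative (energy, gradient) bias family."""
    BIAS_FAMILIES[name] = (energy_fn, gradient_fn)


@dataclass
class BiasSet:
    """Bias coefficients for one ensemble.

    ``c_mat``/``s_mat``/``x_mat`` are (N, N) with zero diagonal; ``c_mat``
    is kept symmetric (the i<j coefficients mirrored), the endpoint and
    skew matrices are direction-dependent (entry [i, j] multiplies the
    term keyed on lam_i with partner lam_j).
    """

    b: np.ndarray
    c_mat: np.ndarray | None = None
    s_mat: np.ndarray | None = None
    x_mat: np.ndarray | None = None
    alpha: float = DEFAULT_ALPHA
    alpha_skew: float = DEFAULT_ALPHA_SKEW
    ensemble: str = "unfolded"
    family: str = "default"
    provenance: dict = field(default_factory=lambda: {"status": "untrained"})

    def __post_init__(self):
        self.b = np.asarray(self.b, dtype=float)
        n = self.b.shape[0]
        for name in ("c_mat", "s_mat", "x_mat"):
            m = getattr(self, name)
            if m is None:
                m = np.zeros((n, n))
            else:
                m = np.asarray(m, dtype=float)
                if m.shape != (n, n):
                    raise ValueError(f"{name} must be ({n}, {n})")
            np.fill_diagonal(m, 0.0)
            setattr(self, name, m)
        if not (self.alpha > 0 and np.isfinite(self.alpha)):
            raise ValueError("alpha must be positive and finite")
        if not (self.alpha_skew > 0 and np.isfinite(self.alpha_skew)):
            raise ValueError("alpha_skew must be positive and finite")
        arrays = [self.b, self.c_mat, self.s_mat, self.x_mat]
        if not all(np.all(np.isfinite(a)) for a in arrays):
            raise ValueError("bias coefficients must be finite")
        if "status" not in self.provenance:
            raise ValueError("provenance must carry a status tag")

    @property
    def n(self) -> int:
        return self.b.shape[0]

    @property
    def trained(self) -> bool:
        return self.provenance.get("status") == "trained"

    @classmethod
    def zeros(cls, n: int, ensemble: str = "unfolded") -> "BiasSet":
        return cls(b=np.zeros(n), ensemble=ensemble)

    def copy(self) -> "BiasSet":
        return BiasSet(b=self.b.copy(), c_mat=self.c_mat.copy(),
                       s_mat=self.s_mat.copy(), x_mat=self.x_mat.copy(),
                       alpha=self.alpha, alpha_skew=self.alpha_skew,
                       ensemble=self.ensemble, family=self.family,
                       provenance=dict(self.provenance))

    def endstate_energies(self) -> np.ndarray:
        """U_bias at each pure end state (exact for any registered family)."""
        out = np.empty(self.n)
        for i in range(self.n):
            e = np.zeros(self.n)
            e[i] = 1.0
            out[i] = bias_energy(e, self)
        return out

    # ---- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "b": self.b.tolist(), "c_mat": self.c_mat.tolist(),
            "s_mat": self.s_mat.tolist(), "x_mat": self.x_mat.tolist(),
            "alpha": self.alpha, "alpha_skew": self.alpha_skew,
            "ensemble": self.ensemble, "family": self.family,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BiasSet":
        return cls(b=np.array(d["b"]), c_mat=np.array(d["c_mat"]),
                   s_mat=np.array(d["s_mat"]), x_mat=np.array(d["x_mat"]),
                   alpha=d["alpha"], alpha_skew=d["alpha_skew"],
                   ensemble=d["ensemble"], family=d.get("family", "default"),
                   provenance=d["provenance"])

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "BiasSet":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _check_lam(lam: np.ndarray, biases: BiasSet) -> np.ndarray:
    lam = np.asarray(lam, dtype=float)
    if lam.shape != (biases.n,):
        raise ValueError(f"lambda has shape {lam.shape}, bias set expects ({biases.n},)")
    return lam


def bias_energy(lam: np.ndarray, biases: BiasSet) -> float:
    """U_bias(lambda) in kcal/mol for the bias set's registered family."""
    lam = _check_lam(lam, biases)
    energy_fn, _ = BIAS_FAMILIES[biases.family]
    return energy_fn(lam, biases.b, biases.c_mat, biases.s_mat, biases.x_mat,
                     biases.alpha, biases.alpha_skew)


def bias_gradient(lam: np.ndarray, biases: BiasSet) -> np.ndarray:
    """Analytic dU_bias/dlambda (kcal/mol per unit lambda)."""
    lam = _check_lam(lam, biases)
    _, grad_fn = BIAS_FAMILIES[biases.family]
    return grad_fn(lam, biases.b, biases.c_mat, biases.s_mat, biases.x_mat,
                   biases.alpha, biases.alpha_skew)


def transfer(biases: BiasSet, new_ensemble: str) -> BiasSet:
    """Transfer a trained bias set to another ensemble (competitive screening).

    Coefficients are copied bit-identically; only the ensemble label and
    provenance change.  Untrained bias sets are refused: transferring an
    untrained bias would silently run unbiased sampling in the target
    ensemble.
    """
    if not biases.trained:
        raise ValueError(
            "refusing to transfer an untrained bias set; train it with "
            "flattening first (provenance status must be 'trained')")
    out = biases.copy()
    out.ensemble = new_ensemble
    prov = dict(biases.provenance)
    prov["transferred_from"] = biases.ensemble
    prov.setdefault("trained_on", biases.provenance.get(
        "trained_on", biases.ensemble))
    out.provenance = prov
    return out
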