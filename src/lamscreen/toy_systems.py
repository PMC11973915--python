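"""Analytically tractable single-site alchemical systems.

A system holds N candidate substituents at one mutation site.  Each
substituent carries a 1-D conformational potential per thermodynamic
ensemble: a single harmonic well for the unfolded peptide and a double
well (native basin at x = 0, disrupted basin at x = d) for the folded
protein, so that destabilising chemistries can push the folded ensemble
into a partially unfolded conformation, mimicking the slow structural
rearrangements seen around deleterious mutations in real proteins.

Because the conformational space is one-dimensional, every ensemble free
energy is available exactly by quadrature, giving an independent oracle
for the sampling-based estimators:

    G = -kT ln \\int exp(-U(x)/kT) dx

Relative unfolding free energies close the thermodynamic cycle,

    ddG_i = -[(G_f,i - G_f,nat) - (G_u,i - G_u,nat)]

with the convention that negative ddG destabilises folding (a folding
penalty), so "deleterious beyond -4 kcal/mol" reads ddG <= -4.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.integrate import quad

from .constants import KB, DEFAULT_TEMPERATURE
from ._potentials import (
    PURE_QUADRATIC_SLOPE,
    SOFTMIN_SMOOTHING,
    double_well_row,
    harmonic_row,
    pot_energy,
)

__all__ = [
    "SubstituentPotential",
    "AlchemicalSystem",
    "TrueFreeEnergies",
    "exact_ensemble_free_energy",
    "true_ddg",
    "generate_system",
    "preset_site",
    "packaged_preset",
    "harmonic_free_energy",
]

SCHEMA_VERSION = 1

#: ddG below which a substituent counts as deleterious (folding penalty
#: large enough to unfold the protein)
DELETERIOUS_DDG = -4.0

AMINO_ACIDS = list("ACDEFGIKLMNPQRSTVWY")  # 19 letters; His enters as 3 sub-states
HIS_STATES = ["HSD", "HSE", "HSP"]


@dataclass
class SubstituentPotential:
    """Per-ensemble 1-D potential parameters for one substituent.

    Unfolded: harmonic well ``u_offset + u_k/2 (x - u_center)^2``.
    Folded: double well with native basin at 0 (offset ``f_native_offset``,
    force constant ``f_native_k``), disrupted basin at ``f_disrupted_center``
    and a C^1 ridge of height ``f_barrier`` between them.
    """

    label: str
    u_center: float = 0.0
    u_k: float = 4.0
    u_offset: float = 0.0
    f_native_k: float = 5.0
    f_native_offset: float = 0.0
    f_disrupted_center: float = 3.0
    f_disrupted_k: float = 5.0
    f_disrupted_offset: float = 3.0
    f_barrier: float = 2.0
    #: native-facing slope of the disrupted arm; the large default keeps
    #: the arm purely quadratic, small values model a long gentle grade
    #: into the disrupted conformation
    f_disrupted_slope: float = PURE_QUADRATIC_SLOPE
    parent: str | None = None  # protonation-state parent label, if any
    smoothing: float = SOFTMIN_SMOOTHING

    def __post_init__(self):
        params = [self.u_k, self.f_native_k, self.f_disrupted_k]
        if not all(np.isfinite(p) and p > 0 for p in params):
            raise ValueError(f"{self.label}: force constants must be finite and > 0")
        others = [self.u_center, self.u_offset, self.f_native_offset,
                  self.f_disrupted_center, self.f_disrupted_offset, self.f_barrier]
        if not all(np.isfinite(p) for p in others):
            raise ValueError(f"{self.label}: non-finite potential parameter")
        if self.f_barrier < 0:
            raise ValueError(f"{self.label}: barrier height must be >= 0")

    def param_row(self, ensemble: str) -> np.ndarray:
        if ensemble == "unfolded":
            return harmonic_row(self.u_offset, self.u_k, self.u_center)
        if ensemble == "folded":
            return double_well_row(self.f_native_offset, self.f_native_k,
                                   self.f_disrupted_offset, self.f_disrupted_k,
                                   self.f_disrupted_center, self.f_barrier,
                                   self.smoothing, self.f_disrupted_slope)
        raise ValueError(f"unknown ensemble {ensemble!r}")

    def energy(self, x: float, ensemble: str) -> float:
        return float(pot_energy(self.param_row(ensemble), float(x)))

    def shift(self, ensemble: str, c: float) -> None:
        """Add a constant to this substituent's potential in one ensemble."""
        if ensemble == "unfolded":
            self.u_offset += c
        elif ensemble == "folded":
            self.f_native_offset += c
            self.f_disrupted_offset += c
        else:
            raise ValueError(f"unknown ensemble {ensemble!r}")


@dataclass
class AlchemicalSystem:
    """One mutation site with N competing substituents."""

    substituents: list[SubstituentPotential]
    native_index: int = 0
    temperature: float = DEFAULT_TEMPERATURE
    site_class: str = "custom"

    def __post_init__(self):
        if len(self.substituents) < 2:
            raise ValueError("need at least two substituents")
        if not 0 <= self.native_index < len(self.substituents):
            raise ValueError("native index out of range")
        labels = [s.label for s in self.substituents]
        if len(set(labels)) != len(labels):
            raise ValueError("substituent labels must be unique")
        if not (np.isfinite(self.temperature) and self.temperature > 0):
            raise ValueError("temperature must be positive and finite")

    @property
    def n(self) -> int:
        return len(self.substituents)

    @property
    def kT(self) -> float:
        return KB * self.temperature

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.substituents]

    def param_matrix(self, ensemble: str) -> np.ndarray:
        return np.stack([s.param_row(ensemble) for s in self.substituents])

    def protonation_groups(self) -> dict[str, list[int]]:
        """Indices of substituents sharing a protonation parent label."""
        groups: dict[str, list[int]] = {}
        for i, s in enumerate(self.substituents):
            if s.parent is not None:
                groups.setdefault(s.parent, []).append(i)
        return groups

    # ---- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "native_index": self.native_index,
            "temperature": self.temperature,
            "site_class": self.site_class,
            "substituents": [asdict(s) for s in self.substituents],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AlchemicalSystem":
        if d.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(f"unsupported schema version {d.get('schema_version')}")
        subs = [SubstituentPotential(**s) for s in d["substituents"]]
        return cls(substituents=subs, native_index=d["native_index"],
                   temperature=d["temperature"], site_class=d["site_class"])

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "AlchemicalSystem":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class TrueFreeEnergies:
    """Exact quadrature free energies and cycle-closed ddG for a system."""

    labels: list[str]
    g_folded: np.ndarray
    g_unfolded: np.ndarray
    ddg: np.ndarray  # negative = destabilizing to folding
    native_index: int


def _quadrature_domain(row: np.ndarray, kT: float) -> tuple[float, float]:
    """[min center - 8 sigma, max center + 8 sigma], sigma from smallest k."""
    if row[0] == 0.0:  # harmonic
        centers = [row[3]]
        k_min = row[2]
    else:
        centers = [0.0, row[5]]
        k_min = min(row[2], row[4])
    sigma = math.sqrt(kT / k_min)
    return min(centers) - 8.0 * sigma, max(centers) + 8.0 * sigma


def exact_ensemble_free_energy(system: AlchemicalSystem, ensemble: str,
                               substituent_index: int) -> float:
    """Exact G = -kT ln Z of one substituent in one ensemble, by quadrature."""
    if not 0 <= substituent_index < system.n:
        raise IndexError("substituent index out of range")
    row = system.substituents[substituent_index].param_row(ensemble)
    kT = system.kT
    lo, hi = _quadrature_domain(row, kT)
    # subtract a reference so the integrand is O(1) regardless of offsets
    grid = np.linspace(lo, hi, 64)
    u0 = min(pot_energy(row, float(x)) for x in grid)
    val, err = quad(lambda x: math.exp(-(pot_energy(row, x) - u0) / kT),
                    lo, hi, epsabs=1e-12, epsrel=1e-11, limit=200)
    if not np.isfinite(val) or val <= 0:
        raise ValueError("quadrature failed: non-finite partition function")
    return u0 - kT * math.log(val)


def harmonic_free_energy(offset: float, k: float, kT: float) -> float:
    """Closed form for a single harmonic well: eps - kT ln sqrt(2 pi kT / k)."""
    return offset - kT * math.log(math.sqrt(2.0 * math.pi * kT / k))


def true_ddg(system: AlchemicalSystem) -> TrueFreeEnergies:
    """Exact relative unfolding free energies by closing the cycle."""
    n = system.n
    g_f = np.array([exact_ensemble_free_energy(system, "folded", i) for i in range(n)])
    g_u = np.array([exact_ensemble_free_energy(system, "unfolded", i) for i in range(n)])
    nat = system.native_index
    ddg = -((g_f - g_f[nat]) - (g_u - g_u[nat]))
    ddg[nat] = 0.0
    return TrueFreeEnergies(labels=system.labels, g_folded=g_f, g_unfolded=g_u,
                            ddg=ddg, native_index=nat)


def _default_labels(n: int) -> tuple[list[str], list[str | None]]:
    """Labels for an n-substituent site; for n = 22 use 19 amino acids plus
    the three histidine protonation sub-states."""
    if n == 22:
        labels = AMINO_ACIDS + HIS_STATES
        parents: list[str | None] = [None] * 19 + ["H"] * 3
        return labels, parents
    labels = [f"S{i}" for i in range(n)]
    return labels, [None] * n


def generate_system(n_substituents: int,
                    target_ddg: np.ndarray,
                    site_class: str = "custom",
                    disruption_strength: float = 5.5,
                    seed: int = 0,
                    native_index: int = 0,
                    temperature: float = DEFAULT_TEMPERATURE,
                    labels: list[str] | None = None,
                    parents: list[str | None] | None = None) -> AlchemicalSystem:
    """Build a system whose exact ddG matches ``target_ddg``.

    Shape parameters (well positions, force constants, barrier heights and
    the unfolded free-energy spread) are drawn deterministically from
    ``seed``; the folded well offsets are then solved so that the quadrature
    ddG reproduces the target exactly (free energies shift additively with
    offsets).  Substituents with target ddG <= -4 kcal/mol get a disrupted
    basin ``disruption_strength`` kcal/mol below their native basin so the
    folded Boltzmann weight sits predominantly in the disrupted
    conformation; all others get a disrupted basin well above native.
    """
    target = np.asarray(target_ddg, dtype=float)
    n = int(n_substituents)
    if n < 2:
        raise ValueError("need at least two substituents")
    if target.shape != (n,):
        raise ValueError("target_ddg must have one entry per substituent")
    if not np.all(np.isfinite(target)):
        raise ValueError("target_ddg entries must be finite")
    if abs(target[native_index]) > 0:
        raise ValueError("target ddG must be 0 at the native index")
    if not np.isfinite(disruption_strength):
        raise ValueError("disruption_strength must be finite")

    rng = np.random.default_rng(seed)
    kT = KB * temperature
    if labels is None:
        labels, auto_parents = _default_labels(n)
        if parents is None:
            parents = auto_parents
    if parents is None:
        parents = [None] * n

    # unfolded relative free energies: the chemistry-dependent part of the
    # unfolded peptide, a few kcal/mol spread
    g_u_rel = rng.uniform(-2.0, 2.0, size=n)
    g_u_rel[native_index] = 0.0

    deleterious_mask = target <= DELETERIOUS_DDG
    del_rank = np.cumsum(deleterious_mask) - 1  # 0, 1, ... among deleterious
    subs = []
    for i in range(n):
        u_k = rng.uniform(2.0, 6.0)
        u_center = rng.uniform(-0.5, 0.5)
        # set the harmonic offset so G_unfolded,i - G_unfolded,nat = g_u_rel
        u_offset = g_u_rel[i] + kT * math.log(math.sqrt(2.0 * math.pi * kT / u_k))
        f_k_n = rng.uniform(3.0, 7.0)
        deleterious = bool(deleterious_mask[i])
        if deleterious:
            # deleterious chemistries slide down a long gentle grade into
            # a chemistry-specific disrupted conformation far below the
            # strained native basin: disruption happens readily whenever
            # such a chemistry is sampled (sub-kT..~1.5 kT forward
            # barrier), but the return climb (the full depth of the
            # grade) makes partial unfolding effectively irreversible at
            # production timescales, and the stiff outer walls plus
            # staggered centres block hops between different disrupted
            # conformations — lambda biases cannot cancel a gap in x.
            d = 3.4 + 0.8 * float(del_rank[i])
            f_k_d = rng.uniform(20.0, 30.0)
            slope = rng.uniform(1.8, 2.2)
            h = rng.uniform(0.1, 0.3)
            entry_barrier = rng.uniform(0.4, 0.9)
            x_cross = math.sqrt(2.0 * entry_barrier / f_k_n)
            t0 = slope / f_k_d
            eps_d_rel = (entry_barrier - slope * (d - x_cross)
                         + 0.5 * slope * t0)
            eps_d_rel = min(eps_d_rel, -abs(disruption_strength))
        else:
            d = rng.uniform(2.5, 3.5)
            f_k_d = rng.uniform(3.0, 7.0)
            slope = PURE_QUADRATIC_SLOPE
            h = rng.uniform(1.0, 3.0)
            eps_d_rel = 6.0
        subs.append(SubstituentPotential(
            label=labels[i], parent=parents[i],
            u_center=u_center, u_k=u_k, u_offset=u_offset,
            f_native_k=f_k_n, f_native_offset=0.0,
            f_disrupted_center=d, f_disrupted_k=f_k_d,
            f_disrupted_offset=eps_d_rel, f_barrier=h,
            f_disrupted_slope=slope))

    system = AlchemicalSystem(substituents=subs, native_index=native_index,
                              temperature=temperature, site_class=site_class)

    # solve the folded offsets: shifting both wells by s_i moves G_f,i by s_i
    g_f0 = np.array([exact_ensemble_free_energy(system, "folded", i) for i in range(n)])
    g_u = np.array([exact_ensemble_free_energy(system, "unfolded", i) for i in range(n)])
    nat = native_index
    shift = -target - (g_f0 - g_f0[nat]) + (g_u - g_u[nat])
    shift -= shift[nat]
    for i, s in enumerate(system.substituents):
        s.shift("folded", float(shift[i]))
    return system


def preset_site(kind: str, seed: int = 0) -> AlchemicalSystem:
    """A protein-G-like 22-substituent site.

    ``surface``: every mutation mild, ddG drawn uniformly in [-2, +1]
    kcal/mol.  ``core``: 13 of the 21 mutations deleterious with ddG in
    [-9, -5] (beyond the -4 kcal/mol unfolding threshold), the rest in
    [-1, +1].  Three substituents are protonation sub-states of histidine.
    Deterministic per (kind, seed).
    """
    rng = np.random.default_rng([seed, 2025])
    n = 22
    target = np.zeros(n)
    if kind == "surface":
        target[1:] = rng.uniform(-2.0, 1.0, size=n - 1)
        site_class = "surface-like"
    elif kind == "core":
        non_native = np.arange(1, n)
        deleterious = rng.choice(non_native, size=13, replace=False)
        target[1:] = rng.uniform(-1.0, 1.0, size=n - 1)
        target[deleterious] = rng.uniform(-9.0, -5.0, size=13)
        site_class = "core-like"
    else:
        raise ValueError(f"unknown preset kind {kind!r} (surface|core)")
    return generate_system(n, target, site_class=site_class,
                           disruption_strength=5.5, seed=seed * 7919 + 11)


def packaged_preset(kind: str) -> AlchemicalSystem:
    """Load the canonical preset fixture shipped with the package
    (identical to ``preset_site(kind, seed=1)``)."""
    from importlib.resources import files
    path = files("lamscreen").joinpath(f"presets/{kind}_site_seed1.json")
    return AlchemicalSystem.from_dict(json.loads(path.read_text()))
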