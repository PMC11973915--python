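import numpy as np
import pytest

from lamscreen import (AlchemicalSystem, BiasSet, IntegratorParams,
                       LambdaTrajectory, SubstituentPotential, generate_system)


@pytest.fixture(scope="session")
def flat_pair_system() -> AlchemicalSystem:
    """Two substituents with identical potentials in both ensembles."""
    a = SubstituentPotential(label="A")
    b = SubstituentPotential(label="B")
    return AlchemicalSystem([a, b], site_class="custom")


@pytest.fixture(scope="session")
def offset_pair_system() -> AlchemicalSystem:
    """Two substituents whose unfolded free energies differ by exactly
    1.0 kcal/mol (identical wells, shifted offset)."""
    a = SubstituentPotential(label="A", u_k=4.0, u_offset=0.0)
    b = SubstituentPotential(label="B", u_k=4.0, u_offset=1.0)
    return AlchemicalSystem([a, b], site_class="custom")


@pytest.fixture(scope="session")
def small_system() -> AlchemicalSystem:
    """Deterministic 4-substituent site with mild ddG spread."""
    target = np.array([0.0, -0.8, 0.5, -1.5])
    return generate_system(4, target, site_class="custom", seed=11)


def make_trajectory(lam: np.ndarray, x: np.ndarray | None = None,
                    ensemble: str = "folded") -> LambdaTrajectory:
    lam = np.asarray(lam, dtype=float)
    n_frames, n = lam.shape
    if x is None:
        x = np.zeros(n_frames)
    labels = [f"S{i}" for i in range(n)]
    return LambdaTrajectory(times=np.arange(n_frames, dtype=float), lam=lam,
                            x=np.asarray(x, dtype=float), ensemble=ensemble,
                            labels=labels, seed=0)


@pytest.fixture
def hand_trajectory() -> LambdaTrajectory:
    """20 frames over 3 substituents with hand-countable end-state visits.

    Visit sequence at threshold 0.99: S0 x3, S1 x2, S0 x2, S2 x4 with
    intermediates in between (no lambda above threshold).
    """
    rows = []
    def vertex(i, n=3, eps=1e-4):
        v = np.full(n, eps / 2)
        v[i] = 1.0 - eps
        return v
    mixed = np.array([0.5, 0.3, 0.2])
    seq = ([vertex(0)] * 3 + [mixed] + [vertex(1)] * 2 + [mixed] * 2
           + [vertex(0)] * 2 + [mixed] + [vertex(2)] * 4 + [mixed] * 5)
    rows = np.stack(seq)
    return make_trajectory(rows)
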