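"""Toy-system generation and the quadrature free-energy oracle."""

import copy

import numpy as np
import pytest

from lamscreen import (AlchemicalSystem, SubstituentPotential,
                       exact_ensemble_free_energy, generate_system,
                       preset_site, true_ddg)
from lamscreen.toy_systems import harmonic_free_energy
from lamscreen._potentials import pot_energy

KT = 0.593  # kcal/mol at ~298 K


def kelvin(kT):
    from lamscreen.constants import KB
    return kT / KB


class TestQuadratureOracle:
    def test_harmonic_well_matches_gaussian_closed_form(self):
        sub = SubstituentPotential(label="A", u_k=3.7, u_offset=1.2, u_center=0.4)
        system = AlchemicalSystem([sub, SubstituentPotential(label="B")],
                                  temperature=kelvin(KT))
        g = exact_ensemble_free_energy(system, "unfolded", 0)
        assert g == pytest.approx(harmonic_free_energy(1.2, 3.7, KT), abs=1e-8)

    def test_constant_shift_moves_free_energy_by_constant(self):
        sub = SubstituentPotential(label="A", u_k=2.5, u_offset=0.0)
        system = AlchemicalSystem([sub, SubstituentPotential(label="B")],
                                  temperature=kelvin(KT))
        g0 = exact_ensemble_free_energy(system, "unfolded", 0)
        sub.shift("unfolded", 3.25)
        g1 = exact_ensemble_free_energy(system, "unfolded", 0)
        assert g1 - g0 == pytest.approx(3.25, abs=1e-8)

    def test_double_well_matches_dense_trapezoid_reference(self):
        # reference computed with a 1e5-point trapezoid rule over the same
        # construction (centers 0 and 3, both k=5, offsets 0 and -2,
        # barrier 4, kT=0.593) before wiring up the adaptive quadrature
        sub = SubstituentPotential(label="A", f_native_k=5.0,
                                   f_native_offset=0.0, f_disrupted_center=3.0,
                                   f_disrupted_k=5.0, f_disrupted_offset=-2.0,
                                   f_barrier=4.0)
        system = AlchemicalSystem([sub, SubstituentPotential(label="B")],
                                  temperature=kelvin(KT))
        g = exact_ensemble_free_energy(system, "folded", 0)
        assert g == pytest.approx(-1.8594511647, abs=1e-6)

    def test_quadrature_stable_under_grid_refinement(self):
        sub = SubstituentPotential(label="A", f_disrupted_offset=-1.0,
                                   f_barrier=2.5)
        row = sub.param_row("folded")
        x1 = np.linspace(-6, 9, 20001)
        x2 = np.linspace(-6, 9, 40001)
        g = []
        for x in (x1, x2):
            u = np.array([pot_energy(row, xi) for xi in x])
            g.append(-KT * np.log(np.trapezoid(np.exp(-u / KT), x)))
        assert abs(g[1] - g[0]) < 1e-6

    def test_folded_potential_equals_native_offset_at_origin(self):
        sub = SubstituentPotential(label="A", f_native_offset=1.75,
                                   f_disrupted_offset=-3.0, f_barrier=2.0)
        assert sub.energy(0.0, "folded") == pytest.approx(1.75, abs=1e-9)

    def test_folded_potential_is_c1_continuous(self):
        # a derivative jump would leave max|diff(dU)| constant under grid
        # refinement; for a C1 potential it scales linearly with the step
        sub = SubstituentPotential(label="A", f_disrupted_offset=-2.0,
                                   f_barrier=3.0)
        row = sub.param_row("folded")
        jumps = []
        for npts in (20001, 40001):
            x = np.linspace(-1.0, 4.0, npts)
            u = np.array([pot_energy(row, xi) for xi in x])
            du = np.gradient(u, x)
            jumps.append(np.max(np.abs(np.diff(du))))
        assert jumps[1] < 0.7 * jumps[0]
        assert jumps[0] < 0.2


class TestTrueDdg:
    def test_identical_ensembles_close_the_cycle(self):
        subs = [SubstituentPotential(label=f"S{i}", u_k=5.0, u_offset=0.3 * i,
                                     f_native_k=5.0, f_native_offset=0.3 * i,
                                     f_disrupted_offset=50.0)
                for i in range(3)]
        # make folded effectively the same harmonic well as unfolded
        system = AlchemicalSystem(subs, temperature=kelvin(KT))
        ddg = true_ddg(system).ddg
        assert np.allclose(ddg, 0.0, atol=1e-6)

    def test_swapping_ensembles_negates_ddg(self, small_system):
        fwd = true_ddg(small_system).ddg
        swapped = copy.deepcopy(small_system)
        for s in swapped.substituents:
            # exchange the two ensembles' potentials by swapping parameters
            u_off, u_k, u_c = s.u_offset, s.u_k, s.u_center
            s.u_offset, s.u_k, s.u_center = s.f_native_offset, s.f_native_k, 0.0
            s.f_native_offset, s.f_native_k = u_off, u_k
            s.f_disrupted_offset = 50.0  # suppress the double-well arm
        # the swap is only exact when both potentials are single wells, so
        # rebuild a pure-harmonic pair instead
        subs_f = []
        for i, lab in enumerate("ABCD"):
            subs_f.append(SubstituentPotential(
                label=lab, u_k=4.0, u_offset=0.5 * i,
                f_native_k=6.0, f_native_offset=-0.2 * i,
                f_disrupted_offset=60.0))
        sys_f = AlchemicalSystem(subs_f, temperature=kelvin(KT))
        ddg_f = true_ddg(sys_f).ddg
        subs_r = []
        for i, lab in enumerate("ABCD"):
            subs_r.append(SubstituentPotential(
                label=lab, u_k=6.0, u_offset=-0.2 * i,
                f_native_k=4.0, f_native_offset=0.5 * i,
                f_disrupted_offset=60.0))
        sys_r = AlchemicalSystem(subs_r, temperature=kelvin(KT))
        ddg_r = true_ddg(sys_r).ddg
        assert np.allclose(ddg_f, -ddg_r, atol=1e-6)

    def test_native_entry_is_exactly_zero(self, small_system):
        assert true_ddg(small_system).ddg[0] == 0.0

    def test_gauge_invariance_per_substituent(self, small_system):
        base = true_ddg(small_system).ddg
        shifted = copy.deepcopy(small_system)
        shifted.substituents[2].shift("folded", 4.0)
        shifted.substituents[2].shift("unfolded", 4.0)
        assert np.allclose(true_ddg(shifted).ddg, base, atol=1e-9)


class TestGenerateSystem:
    def test_round_trip_hits_target_ddg(self):
        rng = np.random.default_rng(7)
        target = np.concatenate([[0.0], rng.uniform(-2, 1, size=21)])
        system = generate_system(22, target, site_class="surface-like", seed=7)
        assert np.allclose(true_ddg(system).ddg, target, atol=1e-6)

    def test_zero_target_reproduces_zero_ddg(self):
        system = generate_system(5, np.zeros(5), seed=3)
        assert np.allclose(true_ddg(system).ddg, 0.0, atol=1e-6)

    def test_deleterious_weight_sits_in_disrupted_well(self):
        target = np.array([0.0, -6.0, 0.5])
        system = generate_system(3, target, seed=9)
        sub = system.substituents[1]
        row = sub.param_row("folded")
        x = np.linspace(-5, sub.f_disrupted_center + 5, 40001)
        u = np.array([pot_energy(row, xi) for xi in x])
        w = np.exp(-(u - u.min()) / system.kT)
        mid = 0.5 * sub.f_disrupted_center
        disrupted_fraction = w[x > mid].sum() / w.sum()
        assert disrupted_fraction > 0.9

    def test_rejects_nonzero_native_target(self):
        with pytest.raises(ValueError):
            generate_system(3, np.array([0.5, 0.0, 0.0]), seed=1)

    def test_rejects_nonfinite_target(self):
        with pytest.raises(ValueError):
            generate_system(3, np.array([0.0, np.inf, 0.0]), seed=1)


class TestPresets:
    def test_surface_preset_has_no_deleterious_mutations(self):
        system = preset_site("surface", 4)
        assert np.all(true_ddg(system).ddg > -4.0)

    def test_core_preset_majority_deleterious(self):
        # mirrors buried sites where most substitutions carry folding
        # penalties beyond the unfolding threshold
        system = preset_site("core", 4)
        ddg = true_ddg(system).ddg
        assert np.sum(ddg <= -4.0) >= 12

    def test_preset_is_deterministic(self):
        a = preset_site("core", 2)
        b = preset_site("core", 2)
        assert a.to_dict() == b.to_dict()

    def test_preset_has_histidine_substates(self):
        system = preset_site("surface", 0)
        assert system.n == 22
        groups = system.protonation_groups()
        assert list(groups) == ["H"] and len(groups["H"]) == 3

    def test_packaged_fixture_matches_generator(self):
        from lamscreen.toy_systems import packaged_preset
        assert packaged_preset("core").to_dict() == preset_site("core", 1).to_dict()

    def test_json_round_trip(self, tmp_path, small_system):
        path = tmp_path / "system.json"
        small_system.save(path)
        loaded = AlchemicalSystem.load(path)
        assert loaded.to_dict() == small_system.to_dict()


class TestValidation:
    def test_negative_force_constant_rejected(self):
        with pytest.raises(ValueError, match="force constants"):
            SubstituentPotential(label="A", u_k=-1.0)

    def test_negative_barrier_rejected(self):
        with pytest.raises(ValueError, match="barrier"):
            SubstituentPotential(label="A", f_barrier=-0.1)

    def test_duplicate_labels_rejected(self):
        subs = [SubstituentPotential(label="A"), SubstituentPotential(label="A")]
        with pytest.raises(ValueError, match="unique"):
            AlchemicalSystem(subs)
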