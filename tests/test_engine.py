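"""Sampler correctness: moves, acceptance rule, determinism, equilibrium."""

import math

import numpy as np
import pytest

from polyplexmc.composition import (
    SystemComposition,
    build_dna,
    g2_template,
)
from polyplexmc.energy import InteractionParams, total_energy
from polyplexmc.engine import (
    MOVE_MOLECULE,
    MOVE_PIVOT,
    MOVE_SINGLE,
    SimulationConfig,
    build_system,
    initialize_state,
    metropolis_accept,
    pivot_tables,
    propose_move,
    run,
    run_replicates,
)
from polyplexmc.fixtures import (
    make_two_particle_system,
    two_particle_mean_separation_quadrature,
)


def _draw_move_of_kind(state, cfg, rng, kind):
    for _ in range(1000):
        mv = propose_move(state, cfg, rng)
        if mv.kind == kind:
            return mv
    raise AssertionError("move kind never drawn")


class TestMoves:
    def test_pivot_preserves_bond_lengths(self, small_state, rng):
        cfg = SimulationConfig()
        system = small_state.system
        mv = _draw_move_of_kind(small_state, cfg, rng, MOVE_PIVOT)
        new = small_state.coords.copy()
        new[mv.indices] = mv.new_pos
        d_old = np.linalg.norm(
            small_state.coords[system.bonds[:, 0]]
            - small_state.coords[system.bonds[:, 1]],
            axis=1,
        )
        d_new = np.linalg.norm(
            new[system.bonds[:, 0]] - new[system.bonds[:, 1]], axis=1
        )
        np.testing.assert_allclose(d_new, d_old, rtol=1e-9)

    def test_pivot_moves_only_the_subtree(self, small_state, rng):
        """Graph-reachability oracle: the moved set of every pivot
        candidate is exactly one component of the bond-deleted graph."""
        import networkx as nx

        system = small_state.system
        piv, members, offs = pivot_tables(system)
        g = nx.Graph([tuple(b) for b in system.bonds])
        checked = 0
        for p in range(len(piv)):
            moved = set(members[offs[p] : offs[p + 1]].tolist())
            pivot_bead = int(piv[p])
            # find the bond joining the pivot bead to the moved component
            joining = [
                tuple(b) for b in system.bonds
                if (b[0] == pivot_bead and b[1] in moved)
                or (b[1] == pivot_bead and b[0] in moved)
            ]
            assert joining
            h = g.copy()
            h.remove_edge(*joining[0])
            comp = nx.node_connected_component(
                h, joining[0][1] if joining[0][0] == pivot_bead else joining[0][0]
            )
            assert moved == set(comp)
            checked += 1
        assert checked == len(system.bonds)

    def test_molecule_translation_preserves_internal_distances(
        self, small_state, rng
    ):
        cfg = SimulationConfig()
        mv = _draw_move_of_kind(small_state, cfg, rng, MOVE_MOLECULE)
        old = small_state.coords[mv.indices]
        rel_old = old - old[0]
        rel_new = mv.new_pos - mv.new_pos[0]
        np.testing.assert_allclose(rel_new, rel_old, atol=1e-12)

    def test_single_particle_move_is_bounded(self, small_state, rng):
        cfg = SimulationConfig(bead_max_disp=1.0, ion_max_disp=5.0)
        mv = _draw_move_of_kind(small_state, cfg, rng, MOVE_SINGLE)
        i = mv.indices[0]
        amp = 5.0 if small_state.system.molecule_id[i] < 0 else 1.0
        assert np.all(np.abs(mv.new_pos - small_state.coords[i]) <= amp)


class TestMetropolis:
    def test_downhill_always_accepted(self, rng):
        assert all(metropolis_accept(0.0, rng) for _ in range(100))
        assert all(metropolis_accept(-3.0, rng) for _ in range(100))

    def test_infinite_always_rejected(self, rng):
        assert not any(metropolis_accept(math.inf, rng) for _ in range(100))

    def test_acceptance_frequency_one_kt(self, rng):
        """Binomial oracle: empirical rate for dU = 1 kT is e^-1."""
        n = 100_000
        acc = sum(metropolis_accept(1.0, rng) for _ in range(n))
        p = math.exp(-1.0)
        sigma = math.sqrt(n * p * (1 - p))
        assert abs(acc - n * p) < 3 * sigma

    def test_detailed_balance_single_move(self, rng):
        """Forward/backward acceptance ratio between two fixed states
        equals exp(-dU)."""
        from polyplexmc.energy import delta_energy_rigid_subset

        params = InteractionParams(cell_radius=50.0)
        coords = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        charges = np.array([1.0, 1.0])
        radii = np.array([1.0, 1.0])
        bonds = np.zeros((0, 2), dtype=np.int64)
        target = np.array([6.0, 0, 0])
        du_f = delta_energy_rigid_subset(
            coords, charges, radii, np.array([1]), target, bonds, params
        )
        n = 60_000
        acc_f = sum(metropolis_accept(du_f, rng) for _ in range(n)) / n
        acc_b = sum(metropolis_accept(-du_f, rng) for _ in range(n)) / n
        assert acc_f / acc_b == pytest.approx(math.exp(-du_f), rel=0.05)


class TestRun:
    def test_zero_production_gives_initial_frame_only(self):
        comp = SystemComposition().add(build_dna(10))
        cfg = SimulationConfig(
            equilibration_steps=100, production_steps=0, sample_interval=10
        )
        traj, _ = run(comp, cfg, InteractionParams(cell_radius=300.0), seed=4)
        assert traj.n_frames == 1

    def test_same_seed_bit_identical(self):
        comp = SystemComposition().add(build_dna(15)).add(g2_template())
        cfg = SimulationConfig(
            equilibration_steps=3000, production_steps=5000, sample_interval=500
        )
        params = InteractionParams(cell_radius=300.0)
        t1, _ = run(comp, cfg, params, seed=99)
        t2, _ = run(comp, cfg, params, seed=99)
        assert np.array_equal(t1.frames, t2.frames)

    def test_different_seeds_differ(self):
        comp = SystemComposition().add(build_dna(15))
        cfg = SimulationConfig(
            equilibration_steps=2000, production_steps=2000, sample_interval=500
        )
        params = InteractionParams(cell_radius=300.0)
        t1, _ = run(comp, cfg, params, seed=1)
        t2, _ = run(comp, cfg, params, seed=2)
        assert not np.array_equal(t1.frames, t2.frames)

    def test_sampled_frames_valid(self):
        """No accepted state contains a non-bonded overlap or an
        out-of-cell bead; total system charge is exactly zero."""
        comp = SystemComposition().add(build_dna(20)).add(
            g2_template(bond_rest_length=0.0)
        )
        cfg = SimulationConfig(
            equilibration_steps=20_000, production_steps=30_000,
            sample_interval=1000,
        )
        params = InteractionParams(cell_radius=300.0, screening_length=8.0)
        traj, _ = run(comp, cfg, params, seed=7)
        system = traj.system
        assert system.charges.sum() == 0.0
        soft = {(int(i), int(j)) for i in range(system.n_particles)
                for j in system.soft_nbrs[i] if j >= 0}
        for frame in traj.frames:
            assert np.all(np.linalg.norm(frame, axis=1) <= params.cell_radius)
            d = np.linalg.norm(frame[:, None, :] - frame[None, :, :], axis=-1)
            rr = system.radii[:, None] + system.radii[None, :]
            bad = np.argwhere(d < rr * (1 - 1e-9))
            for i, j in bad:
                if i == j:
                    continue
                assert (int(i), int(j)) in soft, (i, j, d[i, j])

    def test_replicate_ensemble_seeding(self):
        comp = SystemComposition().add(build_dna(10))
        cfg = SimulationConfig(
            equilibration_steps=500, production_steps=500,
            sample_interval=250, n_replicates=3, seed=11,
        )
        params = InteractionParams(cell_radius=300.0)
        reps = run_replicates(comp, cfg, params)
        assert len(reps) == 3
        seeds = [t.seed for t, _ in reps]
        assert seeds == [11, 12, 13]

    def test_energy_trace_is_finite(self):
        comp = SystemComposition().add(build_dna(15))
        cfg = SimulationConfig(
            equilibration_steps=5000, production_steps=5000, sample_interval=1000
        )
        traj, _ = run(comp, cfg, InteractionParams(cell_radius=300.0), seed=3)
        assert np.all(np.isfinite(traj.energies))


class TestEquilibrium:
    def test_two_particle_mean_separation_matches_quadrature(self):
        """Sampled mean ion-pair separation vs 3D Boltzmann quadrature."""
        comp, params = make_two_particle_system(radius=4.0, cell_radius=30.0)
        cfg = SimulationConfig(
            equilibration_steps=20_000,
            production_steps=400_000,
            sample_interval=40,
            move_weights=(1.0, 0.0, 0.0),
            ion_max_disp=15.0,
            bead_max_disp=15.0,
        )
        traj, _ = run(comp, cfg, params, seed=5)
        seps = np.linalg.norm(traj.frames[:, 0] - traj.frames[:, 1], axis=1)
        expected = two_particle_mean_separation_quadrature(
            params.bjerrum_length, -1.0, 5.2, params.cell_radius
        )
        assert np.mean(seps) == pytest.approx(expected, rel=0.02)

    def test_athermal_chain_matches_saw_reference(self):
        """With charges off, the engine's chain statistics agree with the
        independent pivot-only SAW sampler."""
        from polyplexmc.analysis import asphericity_invariants
        from polyplexmc.composition import MoleculeTemplate
        from polyplexmc.fixtures import make_chain_ensemble

        n = 40
        neutral = MoleculeTemplate(
            kind="DNA",
            charges=(0,) * n,
            radii=(4.0,) * n,
            bonds=tuple((i, i + 1) for i in range(n - 1)),
        )
        comp = SystemComposition().add(neutral)
        cfg = SimulationConfig(
            equilibration_steps=40_000,
            production_steps=400_000,
            sample_interval=200,
            move_weights=(0.2, 0.1, 0.7),
        )
        traj, _ = run(comp, cfg, InteractionParams(cell_radius=2000.0), seed=21)
        dna = traj.system.role_mask("DNA")
        pairs = [asphericity_invariants(f, dna) for f in traj.frames]
        a_engine = sum(p[0] for p in pairs) / sum(p[1] for p in pairs)
        ens = make_chain_ensemble("saw_chain", n, 8.0, 4000, seed=9,
                                  pivots_per_sample=40)
        pairs2 = [asphericity_invariants(f) for f in ens]
        a_ref = sum(p[0] for p in pairs2) / sum(p[1] for p in pairs2)
        assert a_engine == pytest.approx(a_ref, abs=0.04)
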