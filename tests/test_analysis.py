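"""Shape observables: Rg, asphericity, RDF, contacts, condensation table."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from polyplexmc.analysis import (
    asphericity,
    asphericity_density,
    asphericity_invariants,
    condensation_curve,
    contact_profile,
    modal_distance,
    radius_of_gyration,
    rdf,
    rms_rg,
    trajectory_asphericity,
)
from polyplexmc.engine import ParticleSystem, Trajectory
from polyplexmc.fixtures import make_shape


def _rotation(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


class TestRadiusOfGyration:
    def test_symmetric_dumbbell(self):
        coords = np.array([[0.0, 0, 0], [6.0, 0, 0]])
        assert radius_of_gyration(coords) == pytest.approx(3.0)

    def test_ring_equals_radius(self):
        ring = make_shape("ring", n=64, radius=12.5)
        assert radius_of_gyration(ring) == pytest.approx(12.5, abs=1e-10)

    def test_empty_selection_raises(self):
        with pytest.raises(ValueError):
            radius_of_gyration(np.zeros((5, 3)), np.array([], dtype=int))

    def test_selection_subsets(self):
        coords = np.vstack([make_shape("ring", n=10, radius=5.0), [[100.0, 0, 0]]])
        sel = np.arange(10)
        assert radius_of_gyration(coords, sel) == pytest.approx(5.0, abs=1e-10)


class TestAsphericity:
    def test_collinear_rod_is_one(self):
        rod = make_shape("rod", n=50, bond=3.0)
        assert asphericity(rod) == pytest.approx(1.0, abs=1e-12)

    def test_thin_ring_is_quarter(self):
        # eigenvalues (R^2/2, R^2/2, 0) by hand give exactly 1/4
        ring = make_shape("ring", n=100, radius=10.0)
        assert asphericity(ring) == pytest.approx(0.25, abs=1e-10)

    def test_cube_face_centers_are_spherical(self):
        pts = np.array(
            [
                [1.0, 0, 0], [-1.0, 0, 0],
                [0, 1.0, 0], [0, -1.0, 0],
                [0, 0, 1.0], [0, 0, -1.0],
            ]
        )
        assert asphericity(pts) == pytest.approx(0.0, abs=1e-12)

    def test_coincident_beads_raise(self):
        with pytest.raises(ValueError):
            asphericity(np.zeros((4, 3)))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_bounds_and_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.normal(scale=5.0, size=(15, 3))
        a = asphericity(coords)
        assert 0.0 <= a <= 1.0
        moved = coords @ _rotation(rng).T + rng.normal(scale=50.0, size=3)
        assert asphericity(moved) == pytest.approx(a, rel=1e-10)
        assert radius_of_gyration(moved) == pytest.approx(
            radius_of_gyration(coords), rel=1e-10
        )


class TestRdf:
    def test_two_fixed_beads_single_bin(self):
        frames = np.array([[[0.0, 0, 0], [7.3, 0, 0]]])
        prof = rdf(frames, np.array([0]), np.array([1]), bin_width=0.5)
        occupied = prof[prof["counts"] > 0]
        assert len(occupied) == 1
        assert occupied["r"].iloc[0] == pytest.approx(7.25)
        assert modal_distance(prof) == pytest.approx(7.25)

    def test_uniform_gas_matches_ball_pair_density(self, rng):
        """Uniform points in a ball: binned pair counts follow the exact
        pair-separation density f(r) (uniform-sampling oracle), and the
        shell-normalised g is flat at separations small against the
        container (finite-size depletion is first order in r/R)."""
        R = 100.0
        pts = rng.normal(size=(80, 150, 3))
        pts *= (
            R * rng.uniform(0, 1, size=(80, 150, 1)) ** (1 / 3)
            / np.linalg.norm(pts, axis=-1, keepdims=True)
        )
        idx = np.arange(150)
        prof = rdf(pts, idx, idx, bin_width=4.0, r_max=120.0,
                   volume=4 / 3 * np.pi * R**3)
        n_pairs = 150 * 149 / 2

        def f(r):  # exact density of |x - y| for x, y uniform in the ball
            return (3 * r**2 / R**3) * (1 - 3 * r / (4 * R) + r**3 / (16 * R**3))

        expected = n_pairs * f(prof["r"].to_numpy()) * 4.0
        counts = prof["counts"].to_numpy()
        sel = expected > 50
        assert np.all(np.abs(counts[sel] - expected[sel]) / expected[sel] < 0.1)
        # g equals the boundary-depletion factor 1 - 3r/(4R) + O((r/R)^3)
        near = prof[(prof["r"] > 8) & (prof["r"] < 30)]
        depletion = 1 - 3 * near["r"] / (4 * R)
        assert np.allclose(near["g"], depletion, atol=0.08)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            rdf(np.zeros((1, 4, 3)), np.array([], dtype=int), np.array([0]))


def _make_traj(frames, roles_codes, radii=None):
    from polyplexmc.engine import ROLE_CODES

    n = frames.shape[1]
    system = ParticleSystem(
        charges=np.zeros(n),
        radii=np.ones(n) if radii is None else radii,
        roles=np.asarray(roles_codes, dtype=np.int8),
        molecule_id=np.zeros(n, dtype=np.int32),
        bonds=np.zeros((0, 2), dtype=np.int64),
        bond_r0=np.zeros(0),
        soft_nbrs=np.full((n, 1), -1, dtype=np.int64),
        mol_slices=[(0, n)],
        labels=["synthetic"],
    )
    return Trajectory(
        system=system, frames=frames, energies=np.zeros(len(frames)),
        cell_radius=1200.0,
    )


class TestContactProfile:
    def test_hand_built_frame(self):
        """All 16 terminals near monomer 60, nothing else in range."""
        from polyplexmc.engine import ROLE_CODES

        dna = make_shape("rod", n=120, bond=8.0)
        terminals = dna[60] + np.array([12.0, 0, 0]) + np.random.default_rng(0).normal(
            scale=1.0, size=(16, 3)
        )
        coords = np.vstack([dna, terminals])[None]
        roles = [ROLE_CODES["DNA"]] * 120 + [ROLE_CODES["G2T"]] * 16
        traj = _make_traj(coords, roles)
        prof = contact_profile(traj, cutoff=20.0)
        assert prof.g2_terminals[60] == 16
        # rod spacing 8 A: monomers within 2 beads of 60 may also be in range
        assert np.all(prof.g2_terminals[:57] == 0)
        assert np.all(prof.g2_terminals[64:] == 0)
        assert np.all(prof.tail_beads == 0)

    def test_no_vectors_gives_zero_profile(self):
        from polyplexmc.engine import ROLE_CODES

        dna = make_shape("rod", n=120, bond=8.0)[None]
        traj = _make_traj(dna, [ROLE_CODES["DNA"]] * 120)
        prof = contact_profile(traj)
        assert np.all(prof.g2_terminals == 0)
        assert len(prof.g2_terminals) == 120

    def test_matches_double_loop(self, rng):
        from polyplexmc.engine import ROLE_CODES

        n_dna, n_t = 30, 10
        coords = rng.uniform(-40, 40, size=(3, n_dna + n_t, 3))
        roles = [ROLE_CODES["DNA"]] * n_dna + [ROLE_CODES["G2T"]] * n_t
        traj = _make_traj(coords, roles)
        prof = contact_profile(traj, cutoff=20.0)
        ref = np.zeros(n_dna)
        for f in coords:
            for i in range(n_dna):
                for j in range(n_dna, n_dna + n_t):
                    if np.linalg.norm(f[i] - f[j]) < 20.0:
                        ref[i] += 1
        np.testing.assert_allclose(prof.g2_terminals, ref / 3)

    def test_no_dna_raises(self):
        from polyplexmc.engine import ROLE_CODES

        coords = np.zeros((1, 5, 3))
        traj = _make_traj(coords, [ROLE_CODES["G2T"]] * 5)
        with pytest.raises(ValueError):
            contact_profile(traj)


class TestCondensationCurve:
    def _traj_with_rg(self, scale, seed=0):
        from polyplexmc.engine import ROLE_CODES

        rng = np.random.default_rng(seed)
        frames = rng.normal(scale=scale, size=(5, 40, 3))
        return _make_traj(frames, [ROLE_CODES["DNA"]] * 40)

    def test_reference_alone_is_unity(self):
        groups = {0.0: [self._traj_with_rg(10.0)]}
        table = condensation_curve(groups)
        assert table["rms_rg_norm"].iloc[0] == pytest.approx(1.0)

    def test_normalization_matches_hand_computation(self):
        ref = [self._traj_with_rg(10.0, seed=1)]
        small = [self._traj_with_rg(4.0, seed=2), self._traj_with_rg(4.0, seed=3)]
        table = condensation_curve({0.0: ref, 1.0: small})
        expected = rms_rg(small) / rms_rg(ref)
        row = table[table["r_charge"] == 1.0].iloc[0]
        assert row["rms_rg_norm"] == pytest.approx(expected, rel=1e-12)
        assert row["n_replicates"] == 2

    def test_missing_reference_raises(self):
        with pytest.raises(ValueError):
            condensation_curve({1.0: [self._traj_with_rg(4.0)]})


class TestEnsembleAsphericity:
    def test_pooled_mean_is_ratio_of_averages(self):
        rng = np.random.default_rng(3)
        frames = rng.normal(size=(20, 30, 3))
        traj = _make_traj(frames, [0] * 30)
        res = trajectory_asphericity(traj, selection=np.arange(30))
        pairs = [asphericity_invariants(f) for f in frames]
        expected = sum(n for n, _ in pairs) / sum(d for _, d in pairs)
        assert res.pooled_mean == pytest.approx(expected, rel=1e-12)
        assert len(res.per_frame) == 20

    def test_morphology_classification_thresholds(self):
        """Rodlike frames score above 0.6; toroidlike near 1/4."""
        rod = make_shape("rod", n=120, bond=8.0)
        assert asphericity(rod) > 0.6
        ring = make_shape("ring", n=120, radius=30.0)
        assert 0.15 <= asphericity(ring) <= 0.25


class TestAsphericityDensity:
    def test_bimodal_maxima_recovered(self, rng):
        vals = np.concatenate(
            [rng.normal(0.24, 0.02, 300), rng.normal(0.72, 0.03, 500)]
        )
        _, _, maxima = asphericity_density(vals, bandwidth=0.12)
        assert len(maxima) == 2
        assert maxima[0] == pytest.approx(0.24, abs=0.04)
        assert maxima[1] == pytest.approx(0.72, abs=0.04)

    def test_degenerate_input_raises(self):
        with pytest.raises(ValueError):
            asphericity_density(np.array([0.5, 0.5, 0.5]))
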