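"""Superposition and fluctuation statistics against independent oracles."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

import cartraj as ct
from cartraj.io_model import Trajectory, make_topology
from cartraj.selections import AtomSelection
from cartraj.superpose import (average_structure, equilibration_time,
                               kabsch_fit, pairwise_rmsd_matrix, rms2d,
                               rmsd_plain, rmsd_series, rmsf,
                               superpose_frames)


def brute_force_min_rmsd(a, b, n_starts=60, seed=0):
    """Independent oracle: numerically minimize RMSD over rotations
    (multi-start over rotation vectors), translations removed by centering."""
    a = a - a.mean(0)
    b = b - b.mean(0)

    def objective(rotvec):
        r = Rotation.from_rotvec(rotvec).as_matrix()
        return np.sqrt(((a @ r.T - b) ** 2).sum(-1).mean())

    rng = np.random.default_rng(seed)
    best = np.inf
    starts = [np.zeros(3)] + [rng.uniform(-np.pi, np.pi, 3)
                              for _ in range(n_starts)]
    for x0 in starts:
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14,
                                "maxiter": 4000})
        best = min(best, res.fun)
    return best


def _cloud(rng, n):
    return rng.normal(scale=3.0, size=(n, 3))


class TestKabschFit:
    def test_identical_sets_zero_rmsd(self):
        a = _cloud(np.random.default_rng(0), 6)
        assert kabsch_fit(a, a).rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(1)
        a = _cloud(rng, 8)
        r = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        b = a @ r.T + np.array([1.0, 2.0, 3.0])
        fit = kabsch_fit(a, b)
        assert fit.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.linalg.det(fit.rotation) == pytest.approx(1.0)

    def test_matches_dense_rotation_search(self):
        """Least-squares optimality vs a numerical rotation-search oracle."""
        rng = np.random.default_rng(2)
        for k in range(20):
            n = int(rng.integers(3, 11))
            a = _cloud(rng, n)
            b = a + rng.normal(scale=0.5, size=a.shape)
            got = kabsch_fit(a, b).rmsd
            oracle = brute_force_min_rmsd(a, b, seed=k)
            assert got == pytest.approx(oracle, abs=1e-6)
            assert got <= oracle + 1e-9  # never worse than the search

    def test_matches_scipy_align_vectors(self):
        rng = np.random.default_rng(3)
        a = _cloud(rng, 10)
        b = a + rng.normal(scale=0.3, size=a.shape)
        got = kabsch_fit(a, b).rmsd
        rot, rssd = Rotation.align_vectors(b - b.mean(0), a - a.mean(0))
        assert got == pytest.approx(rssd / np.sqrt(len(a)), rel=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            a, b = _cloud(rng, 7), _cloud(rng, 7)
            assert kabsch_fit(a, b).rmsd == pytest.approx(
                kabsch_fit(b, a).rmsd, abs=1e-9)

    def test_proper_rotation_not_reflection(self):
        rng = np.random.default_rng(5)
        a = _cloud(rng, 6)
        b = a.copy()
        b[:, 0] *= -1  # mirrored target
        fit = kabsch_fit(a, b)
        assert np.linalg.det(fit.rotation) == pytest.approx(1.0)
        assert fit.rmsd > 0.1

    def test_too_few_atoms_rejected(self):
        a = np.zeros((2, 3))
        with pytest.raises(ValueError, match="3 atoms"):
            kabsch_fit(a, a)

    def test_collinear_reference_rejected(self):
        a = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(ValueError, match="collinear|degenerate"):
            kabsch_fit(a + 0.0, a)

    def test_mass_weighting_changes_fit(self):
        rng = np.random.default_rng(6)
        a = _cloud(rng, 5)
        b = a + rng.normal(scale=1.0, size=a.shape)
        w = np.array([10.0, 1.0, 1.0, 1.0, 1.0])
        assert kabsch_fit(a, b).rmsd != pytest.approx(
            kabsch_fit(a, b, weights=w).rmsd)


def _traj_from_coords(coords):
    n_atoms = coords.shape[1]
    rows = [(i + 1, "CA", "C", "A", i + 1, "GLY") for i in range(n_atoms)]
    return Trajectory(make_topology(rows), coords,
                      np.arange(float(coords.shape[0])))


class TestAverageStructure:
    def test_static_trajectory(self):
        frame = _cloud(np.random.default_rng(0), 6)
        traj = _traj_from_coords(np.stack([frame] * 4))
        sel = AtomSelection(np.arange(6), "custom")
        np.testing.assert_allclose(average_structure(traj, sel), frame,
                                   atol=1e-9)

    def test_two_mirrored_frames_give_midpoint(self):
        # radial (breathing-mode) displacements carry no net rotation or
        # translation, so superposition is the identity and the iterated
        # average is the exact midpoint
        base = _cloud(np.random.default_rng(1), 6)
        centered = base - base.mean(0)
        delta = 0.05 * centered
        traj = _traj_from_coords(np.stack([base + delta, base - delta]))
        sel = AtomSelection(np.arange(6), "custom")
        np.testing.assert_allclose(average_structure(traj, sel), base,
                                   atol=1e-6)

    def test_matches_single_pass_average_when_aligned(self):
        rng = np.random.default_rng(3)
        frames = _cloud(rng, 8) + rng.normal(scale=0.02, size=(100, 8, 3))
        traj = _traj_from_coords(frames)
        sel = AtomSelection(np.arange(8), "custom")
        avg = average_structure(traj, sel)
        # single pass: superpose every frame onto the first, then average
        single = superpose_frames(frames, frames[0], np.arange(8)).mean(0)
        assert kabsch_fit(avg, single).rmsd < 1e-3


class TestRmsdSeries:
    def test_static_trajectory_all_zero(self):
        frame = _cloud(np.random.default_rng(0), 5)
        traj = _traj_from_coords(np.stack([frame] * 5))
        sel = AtomSelection(np.arange(5), "custom")
        out = rmsd_series(traj, sel, reference="first")
        np.testing.assert_allclose(out["rmsd_A"], 0.0, atol=1e-9)

    def test_single_atom_displacement_closed_form(self):
        """Without superposition, displacing one atom of n by d gives
        RMSD d/sqrt(n)."""
        frame = _cloud(np.random.default_rng(1), 16)
        moved = frame.copy()
        moved[3] += np.array([0.0, 0.0, 2.0])
        assert rmsd_plain(frame, moved) == pytest.approx(2.0 / 4.0)
        # the best-fit value can only be smaller
        assert kabsch_fit(moved, frame).rmsd <= 0.5 + 1e-12

    def test_average_reference_mode(self):
        rng = np.random.default_rng(2)
        frames = _cloud(rng, 6) + rng.normal(scale=0.1, size=(10, 6, 3))
        traj = _traj_from_coords(frames)
        sel = AtomSelection(np.arange(6), "custom")
        out = rmsd_series(traj, sel, reference="average")
        assert (out["rmsd_A"] >= 0).all()
        assert out["reference"].iloc[0] == "average"


class TestRmsf:
    def test_static_trajectory_zero(self):
        frame = _cloud(np.random.default_rng(0), 8)
        traj = _traj_from_coords(np.stack([frame] * 4))
        table = rmsf(traj, traj.topology,
                     [("A", i + 1) for i in range(8)], rule="backbone")
        assert (table["rmsf_A"] < 1e-9).all()

    def test_alternating_atom_closed_form(self):
        """One atom alternating +-0.5 Å along x with the fit held on a
        static anchor recovers RMSF exactly 0.5."""
        rng = np.random.default_rng(1)
        base = _cloud(rng, 10)
        up, down = base.copy(), base.copy()
        up[0, 0] += 0.5
        down[0, 0] -= 0.5
        traj = _traj_from_coords(np.stack([up, down, up, down]))
        anchor = AtomSelection(np.arange(1, 10), "custom")
        table = rmsf(traj, traj.topology, [("A", 1)], rule="backbone",
                     fit_selection=anchor)
        assert table["rmsf_A"].iloc[0] == pytest.approx(0.5, abs=1e-9)

    def test_isotropic_noise_sigma_sqrt3(self):
        """Atomic RMSF converges to sigma*sqrt(3) under isotropic noise."""
        rng = np.random.default_rng(2)
        sigma = 0.3
        base = rng.uniform(-10, 10, size=(120, 3))
        frames = base + rng.normal(scale=sigma, size=(10_000, 120, 3))
        traj = _traj_from_coords(frames)
        table = rmsf(traj, traj.topology,
                     [("A", i + 1) for i in range(120)], rule="backbone")
        mean_rmsf = table["rmsf_A"].mean()
        assert mean_rmsf == pytest.approx(sigma * np.sqrt(3), rel=0.02)

    def test_invariant_to_global_rigid_motion(self):
        rng = np.random.default_rng(3)
        frames = _cloud(rng, 9) + rng.normal(scale=0.2, size=(30, 9, 3))
        traj = _traj_from_coords(frames)
        residues = [("A", i + 1) for i in range(9)]
        base_table = rmsf(traj, traj.topology, residues, rule="backbone")
        rots = Rotation.random(30, random_state=5).as_matrix()
        moved = np.einsum("fij,faj->fai", rots, frames) + rng.normal(
            scale=10.0, size=(30, 1, 3))
        table = rmsf(_traj_from_coords(moved), traj.topology, residues,
                     rule="backbone")
        np.testing.assert_allclose(table["rmsf_A"], base_table["rmsf_A"],
                                   atol=5e-2)

    def test_preset_ordering_recovered(self, r146_bundle, mr146_bundle,
                                       role_map_r146, role_map_mr146):
        """Guanidinium RMSF is larger under the methylated preset."""
        vals = {}
        for bundle, rm in ((r146_bundle, role_map_r146),
                           (mr146_bundle, role_map_mr146)):
            traj = ct.io_model.production_window(
                bundle.replicates.trajectories[0], 20.0)
            roles = {r: rm[r] for r in ct.ROLE_LABELS}
            table = rmsf(traj, traj.topology, roles, rule="core",
                         methylarginine_aliases=rm.methylarginine_aliases)
            vals[bundle.spec.preset] = \
                table.set_index("role")["rmsf_A"]["R146"]
        assert vals["mR146"] > vals["R146"]


class TestRms2d:
    def test_two_identical_frames(self):
        frame = _cloud(np.random.default_rng(0), 5)
        traj = _traj_from_coords(np.stack([frame, frame]))
        sel = AtomSelection(np.arange(5), "custom")
        mat = rms2d([traj], sel)
        np.testing.assert_allclose(mat.values, 0.0, atol=1e-9)

    def test_invariants_on_random_frames(self):
        rng = np.random.default_rng(1)
        trajs = [_traj_from_coords(rng.normal(size=(4, 6, 3)))
                 for _ in range(3)]
        sel = AtomSelection(np.arange(6), "custom")
        mat = rms2d(trajs, sel)
        assert mat.values.shape == (12, 12)
        np.testing.assert_allclose(mat.values, mat.values.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(mat.values), 0.0, atol=1e-12)
        assert (mat.values >= 0).all()
        np.testing.assert_array_equal(mat.trajectory_ids,
                                      np.repeat([0, 1, 2], 4))

    def test_entries_match_pairwise_kabsch(self):
        rng = np.random.default_rng(2)
        frames = rng.normal(size=(5, 7, 3))
        mat = pairwise_rmsd_matrix(frames)
        for i in range(5):
            for j in range(i + 1, 5):
                expected = kabsch_fit(frames[i], frames[j]).rmsd
                assert mat[i, j] == pytest.approx(expected, abs=1e-9)


class TestEquilibrationTime:
    def _series(self, values):
        import pandas as pd
        return pd.DataFrame({"time_ns": np.arange(len(values), dtype=float),
                             "rmsd_A": values})

    def test_flat_series_settles_immediately(self):
        assert equilibration_time(self._series(np.ones(61))) == 0.0

    def test_step_function_settles_at_step(self):
        values = np.concatenate([np.full(20, 3.0), np.full(41, 1.0)])
        t = equilibration_time(self._series(values), window_ns=10, tol=0.2)
        assert abs(t - 20.0) <= 1.0

    def test_monotonic_rise_never_settles(self):
        values = np.linspace(0, 30, 61)  # rises 0.5 Å/ns forever
        assert equilibration_time(self._series(values)) == np.inf
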