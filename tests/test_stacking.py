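"""Center-of-mass distances and sphere-point SASA against analytic oracles."""

import numpy as np
import pytest

import cartraj as ct
from cartraj.io_model import Trajectory, make_topology
from cartraj.selections import AtomSelection
from cartraj.stacking import (center_of_mass, com_distance_series,
                              sasa_frame, sphere_points, stripped_sasa)


def two_sphere_exposed_area(r1, r2, d):
    """Analytic accessible area of sphere 1 (radius r1) partially occluded
    by sphere 2 (radius r2) at center distance d (spherical-cap formula)."""
    if d >= r1 + r2:
        return 4.0 * np.pi * r1 ** 2
    if d + r1 <= r2:
        return 0.0
    cap_height = r1 - (d ** 2 + r1 ** 2 - r2 ** 2) / (2.0 * d)
    return 4.0 * np.pi * r1 ** 2 - 2.0 * np.pi * r1 * cap_height


def _simple_topology(n, element="N"):
    rows = [(i + 1, element, element, "A", i + 1, "GLY") for i in range(n)]
    return make_topology(rows)


class TestCenterOfMass:
    def test_two_equal_masses(self):
        top = _simple_topology(2)
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        sel = AtomSelection(np.arange(2), "custom")
        np.testing.assert_allclose(
            center_of_mass(coords, sel, top.mass), [1.0, 0.0, 0.0])

    def test_single_atom(self):
        top = _simple_topology(1)
        coords = np.array([[3.0, -1.0, 2.0]])
        sel = AtomSelection(np.array([0]), "custom")
        np.testing.assert_allclose(
            center_of_mass(coords, sel, top.mass), coords[0])

    def test_unequal_masses_hand_arithmetic(self):
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [0.0, 2.0, 0]])
        masses = np.array([1.0, 2.0, 3.0])
        sel = AtomSelection(np.arange(3), "custom")
        expected = np.array([2.0 / 6.0, 6.0 / 6.0, 0.0])
        np.testing.assert_allclose(
            center_of_mass(coords, sel, masses), expected)

    def test_invariant_under_rigid_motion(self):
        from scipy.spatial.transform import Rotation
        rng = np.random.default_rng(0)
        top = _simple_topology(6)
        coords = np.stack([rng.normal(size=(6, 3)) for _ in range(4)])
        traj = Trajectory(top, coords, np.arange(4.0))
        a = AtomSelection(np.array([0, 1, 2]), "custom")
        b = AtomSelection(np.array([3, 4, 5]), "custom")
        base = com_distance_series(traj, a, b)["distance_A"]
        rot = Rotation.from_euler("xyz", [20, -40, 65],
                                  degrees=True).as_matrix()
        moved = coords @ rot.T + np.array([5.0, -3.0, 8.0])
        out = com_distance_series(Trajectory(top, moved, traj.times), a, b)
        np.testing.assert_allclose(out["distance_A"], base, atol=1e-9)

    def test_overlapping_selections_rejected(self):
        top = _simple_topology(3)
        traj = Trajectory(top, np.zeros((1, 3, 3)) + np.arange(3)[:, None],
                          np.zeros(1))
        a = AtomSelection(np.array([0, 1]), "custom")
        b = AtomSelection(np.array([1, 2]), "custom")
        with pytest.raises(ValueError, match="disjoint"):
            com_distance_series(traj, a, b)

    def test_constructed_distance(self):
        top = _simple_topology(2)
        coords = np.array([[[0.0, 0, 0], [0.0, 3.5, 0]]])
        a = AtomSelection(np.array([0]), "custom")
        b = AtomSelection(np.array([1]), "custom")
        traj = Trajectory(top, coords, np.zeros(1))
        out = com_distance_series(traj, a, b)
        assert out["distance_A"].iloc[0] == pytest.approx(3.5)

    def test_four_stacking_pairs(self, r146_bundle, role_map_r146):
        """The protocol's four COM pairs each yield a full series."""
        traj = r146_bundle.replicates.trajectories[0]
        top = traj.topology
        rm = role_map_r146
        pairs = [("nt35", "nt34"), ("nt34", "C1054"),
                 ("C1054", "A1196"), ("A1196", "R146")]
        for ra, rb in pairs:
            sa = ct.core_atoms(top, [rm[ra]], rm.methylarginine_aliases)
            sb = ct.core_atoms(top, [rm[rb]], rm.methylarginine_aliases)
            out = com_distance_series(traj, sa, sb, f"{ra}-{rb}")
            assert len(out) == traj.n_frames
            assert (out["distance_A"] > 0).all()

    def test_stacked_preset_recovers_mu(self):
        """A pure stacked preset's A1196-guanidinium COM mean is within
        3 standard errors of mu_stacked."""
        from cartraj import synthetic
        spec = synthetic.preset_spec(
            "R146", replicate_lengths_ns=(400.0,), stacked_fraction=1.0)
        bundle = synthetic.generate_replicates(spec, seed=11)
        traj = bundle.replicates.trajectories[0]
        rm = ct.resolve_roles(synthetic.default_role_map_config(),
                              bundle.topology)
        sa = ct.core_atoms(traj.topology, [rm["R146"]])
        sb = ct.core_atoms(traj.topology, [rm["A1196"]])
        d = com_distance_series(traj, sa, sb)["distance_A"].to_numpy()
        se = d.std(ddof=1) / np.sqrt(len(d))
        assert abs(d.mean() - spec.mu_stacked) < 3 * se


class TestSasaFrame:
    def test_isolated_atom_closed_form(self):
        # nitrogen, r=1.55 Å, water probe 1.4 Å -> 4 pi 2.95^2
        area = sasa_frame(np.zeros((1, 3)), np.array([1.55]), probe=1.4)
        assert area[0] == pytest.approx(4 * np.pi * 2.95 ** 2, rel=1e-12)
        assert area[0] == pytest.approx(109.36, abs=0.01)

    def test_distant_atoms_additive(self):
        coords = np.array([[0.0, 0, 0], [100.0, 0, 0]])
        radii = np.array([1.55, 1.70])
        areas = sasa_frame(coords, radii, probe=1.4)
        iso = [sasa_frame(np.zeros((1, 3)), radii[i:i + 1], probe=1.4)[0]
               for i in range(2)]
        np.testing.assert_allclose(areas, iso, rtol=1e-12)

    @pytest.mark.parametrize("d", [1.0, 2.5, 4.0, 5.5])
    def test_two_sphere_analytic_oracle(self, d):
        radii = np.array([1.55, 1.70])
        probe = 1.4
        r1, r2 = radii + probe
        coords = np.array([[0.0, 0, 0], [d, 0, 0]])
        areas = sasa_frame(coords, radii, probe=probe, n_sphere_points=960)
        exp1 = two_sphere_exposed_area(r1, r2, d)
        exp2 = two_sphere_exposed_area(r2, r1, d)
        assert areas[0] == pytest.approx(exp1, rel=0.01)
        assert areas[1] == pytest.approx(exp2, rel=0.01)

    def test_matches_high_density_sampling(self):
        rng = np.random.default_rng(3)
        coords = rng.normal(scale=2.0, size=(8, 3))
        radii = np.full(8, 1.6)
        lo = sasa_frame(coords, radii, n_sphere_points=960)
        hi = sasa_frame(coords, radii, n_sphere_points=20_000)
        np.testing.assert_allclose(lo.sum(), hi.sum(), rtol=0.01)

    def test_converges_doubling_points(self):
        rng = np.random.default_rng(4)
        for seed in range(5):
            coords = np.random.default_rng(seed).normal(scale=2.5,
                                                        size=(6, 3))
            radii = np.full(6, 1.55)
            a = sasa_frame(coords, radii, n_sphere_points=480).sum()
            b = sasa_frame(coords, radii, n_sphere_points=960).sum()
            assert abs(a - b) / b < 0.01

    def test_matches_biotite_shrake_rupley(self):
        """Independent implementation cross-check on a random cluster."""
        import biotite.structure as struc

        rng = np.random.default_rng(5)
        n = 10
        coords = rng.normal(scale=2.5, size=(n, 3))
        radii = np.full(n, 1.7)
        ours = sasa_frame(coords, radii, probe=1.4, n_sphere_points=960)
        array = struc.AtomArray(n)
        array.coord = coords.astype(np.float32)
        array.chain_id = np.full(n, "A")
        array.res_id = np.arange(1, n + 1)
        array.res_name = np.full(n, "GLY")
        array.atom_name = np.full(n, "CA")
        array.element = np.full(n, "C")
        theirs = struc.sasa(array, probe_radius=1.4, point_number=960,
                            vdw_radii="Single")
        # Single-atom radii in biotite give C 1.70 Å, matching ours
        np.testing.assert_allclose(ours.sum(), theirs.sum(), rtol=0.02)

    def test_sphere_point_set_deterministic(self):
        np.testing.assert_array_equal(sphere_points(960), sphere_points(960))
        assert np.allclose(np.linalg.norm(sphere_points(480), axis=1), 1.0)

    def test_nonfinite_coordinates_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            sasa_frame(np.array([[np.nan, 0, 0]]), np.array([1.5]))


class TestStrippedSasa:
    def _selections(self, bundle, role_map):
        top = bundle.topology
        guan = ct.core_atoms(top, [role_map["R146"]],
                             role_map.methylarginine_aliases)
        a1196 = ct.core_atoms(top, [role_map["A1196"]])
        return guan, a1196

    def test_subadditivity_and_buried_nonnegative(self, r146_bundle,
                                                  role_map_r146):
        traj = ct.sample_frames(r146_bundle.replicates.trajectories[0],
                                20.0, 40.0, 1.0)
        guan, a1196 = self._selections(r146_bundle, role_map_r146)
        out = stripped_sasa(traj, guan, a1196)
        assert (out["sasa_AB_A2"] <= out["sasa_A_only_A2"]
                + out["sasa_B_only_A2"] + 1e-9).all()
        assert (out["buried_A2"] >= -1e-9).all()

    def test_distant_groups_bury_nothing(self):
        rows = ([(i + 1, n, n[0], "A", 1, "ARG")
                 for i, n in enumerate(("CZ", "NE", "NH1", "NH2"))]
                + [(5 + i, n, n[0], "B", 2, "A")
                   for i, n in enumerate(("N1", "C2", "N3", "C4", "C5",
                                          "C6", "N7", "C8", "N9"))])
        top = make_topology(rows)
        coords = np.zeros((1, 13, 3))
        coords[0, :4] = np.random.default_rng(0).normal(size=(4, 3))
        coords[0, 4:] = np.random.default_rng(1).normal(size=(9, 3)) + 100.0
        traj = Trajectory(top, coords, np.zeros(1))
        guan = ct.core_atoms(top, [("A", 1)])
        base = ct.core_atoms(top, [("B", 2)])
        out = stripped_sasa(traj, guan, base)
        assert out["buried_A2"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_destacked_preset_more_accessible(self, r146_bundle,
                                              mr146_bundle, role_map_r146,
                                              role_map_mr146):
        means = {}
        for bundle, rm in ((r146_bundle, role_map_r146),
                           (mr146_bundle, role_map_mr146)):
            traj = ct.sample_frames(bundle.replicates.trajectories[0],
                                    20.0, 60.0, 1.0)
            guan, a1196 = self._selections(bundle, rm)
            out = stripped_sasa(traj, guan, a1196)
            means[bundle.spec.preset] = out["sasa_AB_A2"].mean()
        assert means["mR146"] > means["R146"]

    def test_core_rule_enforced(self, r146_bundle, role_map_r146):
        traj = r146_bundle.replicates.trajectories[0]
        guan, a1196 = self._selections(r146_bundle, role_map_r146)
        bad = AtomSelection(guan.indices[:3], "custom")
        with pytest.raises(ValueError, match="guanidinium"):
            stripped_sasa(traj, bad, a1196)
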