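"""Superposition, overlap, RMSD, PCA, collectivity, non-linearity, scans."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import anmresponse as anm
from anmresponse.constants import rad_s_to_thz
from anmresponse.trajectory_analysis import DESK_PRESET


def _structure_from_coords(coords, source=""):
    n = coords.shape[0]
    return anm.CoarseGrainedStructure(
        coordinates=coords,
        chain_ids=np.array(["A"] * n),
        residue_numbers=np.arange(1, n + 1),
        residue_names=np.array(["ALA"] * n),
        masses=np.full(n, 100.0),
        source_id=source,
    )


class TestSuperpose:
    def test_recovers_known_rotation(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 10, size=(8, 3))
        rot_true = Rotation.from_euler("xyz", [30, -45, 60], degrees=True).as_matrix()
        mobile = _structure_from_coords(coords @ rot_true.T + np.array([1.0, 2.0, 3.0]))
        reference = _structure_from_coords(coords)
        rot, trans, fitted, rmsd, _, _ = anm.superpose(mobile, reference)
        assert rmsd == pytest.approx(0.0, abs=1e-8)
        assert np.allclose(rot @ rot_true, np.eye(3), atol=1e-8)
        assert np.allclose(fitted, coords, atol=1e-8)

    def test_mirror_image_yields_proper_rotation(self):
        rng = np.random.default_rng(1)
        coords = rng.uniform(0, 10, size=(8, 3))
        mirrored = coords * np.array([-1.0, 1.0, 1.0])
        rot, *_ = anm.superpose(_structure_from_coords(mirrored),
                                _structure_from_coords(coords))
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-10)

    def test_optimal_among_random_rotations(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0, 10, size=(10, 3))
        b = a + rng.normal(0, 0.8, size=(10, 3))
        mobile, reference = _structure_from_coords(b), _structure_from_coords(a)
        *_, rmsd_opt, _, _ = anm.superpose(mobile, reference)
        bc = b - b.mean(axis=0)
        ac = a - a.mean(axis=0)
        for seed in range(100):
            r = Rotation.random(rng=np.random.default_rng(seed)).as_matrix()
            rmsd_r = np.sqrt(np.mean(np.sum((bc @ r.T - ac) ** 2, axis=1)))
            assert rmsd_opt <= rmsd_r + 1e-12

    def test_too_few_common_residues(self):
        a = _structure_from_coords(np.eye(3) * 5 + 1)
        b = anm.CoarseGrainedStructure(
            coordinates=np.eye(3) * 5 + 1,
            chain_ids=np.array(["B"] * 3),
            residue_numbers=np.arange(1, 4),
            residue_names=np.array(["ALA"] * 3),
            masses=np.full(3, 100.0),
        )
        with pytest.raises(anm.PairingError):
            anm.superpose(a, b)


class TestConformationalChange:
    def test_identical_structures_leave_no_change(self):
        rng = np.random.default_rng(3)
        coords = rng.uniform(0, 10, size=(6, 3))
        a = _structure_from_coords(coords)
        b = _structure_from_coords(coords.copy())
        try:
            cc = anm.conformational_change_vector(a, b)
            assert np.linalg.norm(cc.cc_vector) < 1e-8
        except anm.UndefinedOverlapError:
            pass  # exactly-zero change is legitimately rejected

    def test_pure_rigid_rotation_is_removed(self):
        rng = np.random.default_rng(4)
        coords = rng.uniform(0, 10, size=(6, 3))
        rot = Rotation.from_euler("z", 25, degrees=True).as_matrix()
        closed = _structure_from_coords(coords @ rot.T)
        cc = anm.conformational_change_vector(_structure_from_coords(coords), closed)
        assert np.linalg.norm(cc.cc_vector) < 1e-6

    def test_hinge_change_is_inplane_counter_rotation(self, hinge):
        """After least-squares superposition the one-lobe rotation shows
        up as the two lobes counter-rotating about the hinge axis, with
        negligible out-of-plane (z) motion."""
        fix, _, _, cc = hinge
        v = cc.cc_vector.reshape(-1, 3)
        assert np.sqrt((v[:, 2] ** 2).mean()) < 0.1 * np.sqrt((v[:, :2] ** 2).mean())
        moving = fix.expected["moving_nodes"]
        static_lobe = [i for i in range(3, len(v)) if i not in moving]
        coords = fix.open_structure.coordinates
        torque_z = np.cross(coords, v)[:, 2]  # sense of rotation about z
        assert np.sign(torque_z[moving].mean()) != np.sign(
            torque_z[static_lobe].mean()
        )


class TestOverlap:
    def test_parallel_and_orthogonal(self, hinge):
        _, _, _, cc = hinge
        assert anm.overlap(2.0 * cc.cc_vector, cc) == pytest.approx(1.0)
        assert anm.overlap(-0.3 * cc.cc_vector, cc) == pytest.approx(1.0)
        v = np.zeros_like(cc.cc_vector)
        v[0], v[1] = cc.cc_vector[1], -cc.cc_vector[0]
        v[2:] = 0.0
        v = v - (v @ cc.cc_vector) / (cc.cc_vector @ cc.cc_vector) * cc.cc_vector
        assert anm.overlap(v, cc) == pytest.approx(0.0, abs=1e-12)

    def test_zero_vector_rejected(self, hinge):
        _, _, _, cc = hinge
        with pytest.raises(anm.UndefinedOverlapError):
            anm.overlap(np.zeros_like(cc.cc_vector), cc)

    def test_first_mode_beats_higher_modes_on_hinge(self, hinge):
        fix, _, modes, cc = hinge
        o7 = anm.overlap(modes.internal_modes[:, 0], cc)
        assert o7 == pytest.approx(fix.expected["mode7_cc_overlap"])
        assert o7 > anm.overlap(modes.internal_modes[:, 13], cc)


class TestOverlapSeries:
    def test_single_mode_trajectory_constant(self, hinge):
        _, _, modes, cc = hinge
        times = np.linspace(0, 100, 50)
        p = np.zeros((modes.n_internal, times.size))
        p[0] = np.sin(0.3 * times) * 1e-12
        traj = anm.synthesize_trajectory(modes, p, times)
        series = anm.overlap_series(traj, cc)
        finite = series.values[np.isfinite(series.values)]
        assert finite.size > 10
        assert np.ptp(finite) < 1e-10

    def test_two_mode_trajectory_varies(self, hinge):
        _, _, modes, cc = hinge
        times = np.linspace(0, 100, 50)
        p = np.zeros((modes.n_internal, times.size))
        p[0] = np.sin(0.3 * times) * 1e-12
        p[1] = np.sin(0.3 * np.sqrt(2) * times) * 1e-12
        traj = anm.synthesize_trajectory(modes, p, times)
        series = anm.overlap_series(traj, cc)
        finite = series.values[np.isfinite(series.values)]
        assert np.ptp(finite) > 1e-3

    def test_max_dominates_every_frame(self, hinge):
        _, _, modes, cc = hinge
        pattern = anm.random_force_pattern(modes.n_nodes, seed=1)
        exc = anm.HarmonicExcitation(pattern=pattern, frequency_thz=0.02, damping=0.05)
        traj = anm.respond(modes, exc, cycles=3)
        series = anm.overlap_series(traj, cc)
        finite = series.values[np.isfinite(series.values)]
        assert series.max >= finite.max()


class TestRmsd:
    def test_unit_displacement(self):
        u = np.tile([1.0, 0.0, 0.0], 7)
        traj = anm.Trajectory(times_ps=np.array([0.0]), displacements=u[None, :])
        assert anm.rmsd_series(traj)[0] == pytest.approx(1.0)

    def test_zero_displacement(self):
        traj = anm.Trajectory(times_ps=np.array([0.0]),
                              displacements=np.zeros((1, 12)))
        assert anm.rmsd_series(traj)[0] == 0.0

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        u = rng.normal(size=(4, 18))
        traj = anm.Trajectory(times_ps=np.arange(4.0), displacements=u)
        got = anm.rmsd_series(traj)
        for t in range(4):
            acc = 0.0
            for i in range(6):
                mag2 = sum(u[t, 3 * i + k] ** 2 for k in range(3))
                acc += mag2
            assert got[t] == pytest.approx(np.sqrt(acc / 6))


class TestDynamicAmplification:
    def test_quasi_static_ratio_near_one(self, hinge):
        _, _, modes, _ = hinge
        pattern = anm.random_force_pattern(modes.n_nodes, seed=2)
        f7 = rad_s_to_thz(modes.omega_internal[0])
        exc = anm.HarmonicExcitation(pattern=pattern, frequency_thz=1e-4 * f7,
                                     damping=0.01)
        traj = anm.respond(modes, exc, cycles=2, transient_cap_ps=0.0)
        ratio = anm.dynamic_amplification(traj, anm.static_response(modes, pattern))
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_resonant_single_mode_ratio(self, diatomic):
        _, _, modes = diatomic
        xi = 0.01
        pattern = anm.ForcePattern(components=np.array([1e-10, 0, 0, -1e-10, 0, 0]))
        exc = anm.HarmonicExcitation(
            pattern=pattern,
            frequency_thz=rad_s_to_thz(modes.omega_internal[0]),
            damping=xi,
        )
        traj = anm.respond(modes, exc, transient_cap_ps=1e9, steps_per_cycle=500)
        ratio = anm.dynamic_amplification(traj, anm.static_response(modes, pattern))
        assert ratio == pytest.approx(1.0 / (2 * xi), rel=0.02)

    def test_oracle_recomputation(self, toy5):
        _, _, modes = toy5
        pattern = anm.random_force_pattern(modes.n_nodes, seed=3)
        exc = anm.HarmonicExcitation(pattern=pattern, frequency_thz=0.1, damping=0.1)
        traj = anm.respond(modes, exc, cycles=3)
        u_static = anm.static_response(modes, pattern)
        got = anm.dynamic_amplification(traj, u_static)
        # naive recomputation from the raw series
        max_rmsd = max(
            np.sqrt(np.mean(np.sum(f.reshape(-1, 3) ** 2, axis=1)))
            for f in traj.displacements
        )
        static_rmsd = np.sqrt(np.mean(np.sum(u_static.reshape(-1, 3) ** 2, axis=1)))
        assert got == pytest.approx(max_rmsd / static_rmsd)

    def test_zero_static_rmsd_rejected(self, toy5):
        _, _, modes = toy5
        traj = anm.Trajectory(times_ps=np.arange(2.0),
                              displacements=np.ones((2, 15)))
        with pytest.raises(anm.UndefinedOverlapError):
            anm.dynamic_amplification(traj, np.zeros(15))


class TestCosineNonlinearity:
    def test_linear_motion_gives_plus_minus_one(self):
        times = np.arange(9.0)
        direction = np.tile([1.0, 2.0, -1.0], 4)
        amp = np.sin(np.linspace(0, 2 * np.pi, 9))
        traj = anm.Trajectory(times_ps=times,
                              displacements=amp[:, None] * direction[None, :])
        cos = anm.cosine_nonlinearity(traj)
        finite = cos[np.isfinite(cos)]
        assert np.all(np.isclose(np.abs(finite), 1.0))

    def test_circular_motion_sweeps_range(self):
        t = np.linspace(0, 2 * np.pi, 60)
        u = np.zeros((60, 3))
        u[:, 0], u[:, 1] = np.cos(t), np.sin(t)
        # one circling node plus one stationary partner (N=2)
        disp = np.hstack([u, np.zeros((60, 3))])
        traj = anm.Trajectory(times_ps=t, displacements=disp)
        cos = anm.cosine_nonlinearity(traj)[0]
        assert np.nanmin(cos) < -0.99
        assert np.nanmax(cos) > 0.99

    def test_matches_brute_force(self):
        rng = np.random.default_rng(6)
        disp = rng.normal(size=(6, 9))
        traj = anm.Trajectory(times_ps=np.arange(6.0), displacements=disp)
        got = anm.cosine_nonlinearity(traj)
        steps = np.diff(disp.reshape(6, 3, 3), axis=0)
        for i in range(3):
            for t in range(5):
                a, b = steps[t, i], steps[0, i]
                expected = a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
                assert got[i, t] == pytest.approx(expected)

    def test_requires_three_frames(self):
        traj = anm.Trajectory(times_ps=np.arange(2.0),
                              displacements=np.ones((2, 6)))
        with pytest.raises(ValueError):
            anm.cosine_nonlinearity(traj)


class TestPCA:
    def test_single_direction_gets_all_variance(self):
        rng = np.random.default_rng(7)
        direction = rng.normal(size=12)
        amps = rng.normal(size=20)
        data = np.outer(amps, direction) + rng.normal(size=12)  # common offset
        res = anm.pca(data)
        assert res.variance_fractions[0] == pytest.approx(1.0, abs=1e-10)

    def test_trace_identity_and_reconstruction(self):
        rng = np.random.default_rng(8)
        data = rng.normal(size=(10, 9))
        res = anm.pca(data)
        centered = data - data.mean(axis=0)
        cov = centered.T @ centered / data.shape[0]
        assert res.eigenvalues.sum() == pytest.approx(np.trace(cov))
        assert np.abs(res.scores @ res.components.T - centered).max() < 1e-8
        assert res.variance_fractions.sum() == pytest.approx(1.0)

    def test_matches_covariance_eigendecomposition(self):
        rng = np.random.default_rng(9)
        data = rng.normal(size=(4, 6))
        res = anm.pca(data)
        centered = data - data.mean(axis=0)
        cov = centered.T @ centered / 4
        evals, evecs = np.linalg.eigh(cov)
        evals = evals[::-1]
        k = min(4 - 1, 6)  # rank of the centered matrix
        assert np.allclose(res.eigenvalues[:k], evals[:k], atol=1e-12)

    def test_supplementary_projection(self, hinge):
        fix, _, modes, _ = hinge
        pattern = anm.random_force_pattern(modes.n_nodes, seed=4)
        exc = anm.HarmonicExcitation(pattern=pattern, frequency_thz=0.02, damping=0.1)
        traj = anm.respond(modes, exc, cycles=3)
        ref = fix.open_structure.coordinates.ravel()
        res = anm.pca(ref[None, :] + traj.displacements)
        open_score = res.project(ref)[0]
        assert open_score.shape == (res.components.shape[1],)

    def test_single_conformation_rejected(self):
        with pytest.raises(ValueError):
            anm.pca(np.ones((1, 6)))


class TestCollectivity:
    def test_equal_motion_is_fully_collective(self):
        v = np.tile([0.3, -0.4, 1.2], 11)
        assert anm.collectivity(v) == pytest.approx(1.0)

    def test_single_residue_limit(self):
        v = np.zeros(3 * 17)
        v[3] = 2.5
        assert anm.collectivity(v) == pytest.approx(1.0 / 17)

    def test_invariance_under_scaling_and_permutation(self):
        rng = np.random.default_rng(10)
        v = rng.normal(size=3 * 9)
        k = anm.collectivity(v)
        assert anm.collectivity(5.0 * v) == pytest.approx(k)
        perm = rng.permutation(9)
        v_perm = v.reshape(9, 3)[perm].ravel()
        assert anm.collectivity(v_perm) == pytest.approx(k)

    def test_hinge_cc_more_collective_than_point_motion(self, hinge):
        _, _, _, cc = hinge
        n = cc.cc_vector.size // 3
        point = np.zeros_like(cc.cc_vector)
        point[0] = 1.0
        assert anm.collectivity(cc.cc_vector) > anm.collectivity(point)


class TestFrequencyScan:
    def test_single_cell_matches_direct_run(self, hinge):
        _, _, modes, cc = hinge
        f, xi, seed = 0.02, 0.05, 3
        scan = anm.frequency_scan(modes, cc, [f], [xi], [seed])
        assert len(scan.table) == 1
        row = scan.table.iloc[0]
        pattern = anm.random_force_pattern(modes.n_nodes, seed=seed)
        exc = anm.HarmonicExcitation(pattern=pattern, frequency_thz=f, damping=xi)
        from anmresponse.trajectory_analysis import _eval_window_grid
        times = _eval_window_grid(modes, exc, 10, 100, True, 2000.0)
        coeff = anm.modal_response_coefficients(modes, exc)
        p = anm.principal_coordinates(coeff, times)
        traj = anm.synthesize_trajectory(modes, p, times)
        assert row["max_overlap"] == pytest.approx(anm.overlap_series(traj, cc).max)
        u_static = anm.static_response(modes, pattern)
        assert row["amplification"] == pytest.approx(
            anm.dynamic_amplification(traj, u_static)
        )

    def test_scan_is_bit_reproducible(self, hinge):
        _, _, modes, cc = hinge
        kwargs = dict(frequencies_thz=[0.01, 0.05], damping_values=[0.01, 0.1],
                      pattern_seeds=[0, 1])
        a = anm.frequency_scan(modes, cc, **kwargs)
        b = anm.frequency_scan(modes, cc, **kwargs)
        assert a.table.equals(b.table)
        assert a.optima.equals(b.optima)

    def test_optimum_lies_in_low_frequency_band(self, hinge):
        _, _, modes, cc = hinge
        f7 = rad_s_to_thz(modes.omega_internal[0])
        f_max = rad_s_to_thz(modes.omega_internal[-1])
        freqs = np.geomspace(0.5 * f7, 3 * f_max, 12)
        scan = anm.frequency_scan(
            modes, cc, freqs, [0.1], [0, 1, 2],
            transient_time_constants=12.0, transient_cap_ps=1e9,
        )
        # every pattern finds its best overlap below the middle of the
        # mode spectrum
        mid = rad_s_to_thz(modes.omega_internal[modes.n_internal // 2])
        assert (scan.optima["optimal_frequency_thz"] <= mid).all()
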