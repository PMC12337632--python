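import numpy as np
import pytest

import afstrat as afs
from afstrat.mesh import fibonacci_sphere
from afstrat.synthetic import spatial_phase


class TestSimulateWavefield:
    def test_planar_field_is_pure_tone_with_linear_phase(self, disk_mesh):
        truth = afs.WaveFieldTruth(frequency_hz=6.0, kind="planar",
                                   direction=[1.0, 0.0, 0.0], wavelength_cm=10.0)
        egms = afs.simulate_wavefield(disk_mesh, truth, 500.0, 4.0)
        # every vertex: cos(2*pi*6*t + offset) with offset linear in x
        t = egms.times
        offsets = spatial_phase(disk_mesh, truth)
        expected = np.cos(2 * np.pi * 6.0 * t[None, :] + offsets[:, None])
        assert np.allclose(egms.samples, expected)
        # offsets linear in the propagation coordinate
        x = disk_mesh.vertices[:, 0]
        fitted = np.polyfit(x, offsets, 1)
        assert np.allclose(np.polyval(fitted, x), offsets, atol=1e-9)

    def test_spiral_phase_winds_by_two_pi_on_loop_around_core(self, disk_mesh):
        truth = afs.WaveFieldTruth(frequency_hz=6.0, kind="spiral", chirality=+1,
                                   core=[0.0, 0.0, 0.0])
        phase0 = spatial_phase(disk_mesh, truth)
        # closed loop: vertices in a ring 1-1.5 cm from the core, sorted by angle
        r = np.linalg.norm(disk_mesh.vertices[:, :2], axis=1)
        ring = np.flatnonzero((r > 1.0) & (r < 1.5))
        ang = np.arctan2(disk_mesh.vertices[ring, 1], disk_mesh.vertices[ring, 0])
        loop = ring[np.argsort(ang)]
        ph = phase0[loop]
        diffs = np.angle(np.exp(1j * np.diff(np.append(ph, ph[0]))))
        assert round(diffs.sum() / (2 * np.pi)) == 1

    def test_focal_field_has_zero_winding_everywhere(self, disk_mesh):
        truth = afs.WaveFieldTruth(frequency_hz=6.0, kind="focal", core=[0.5, 0.0, 0.0])
        phase0 = spatial_phase(disk_mesh, truth)
        from conftest import brute_force_singular_faces

        singular, _ = brute_force_singular_faces(disk_mesh, phase0)
        assert singular.size == 0

    def test_drifting_core_path_echoed_samplewise(self, disk_mesh):
        n = 500
        path = np.column_stack([np.linspace(0.0, 1.0, n), np.zeros(n), np.zeros(n)])
        truth = afs.WaveFieldTruth(frequency_hz=6.0, kind="spiral", core_path=path)
        egms = afs.simulate_wavefield(disk_mesh, truth, 500.0, 1.0)
        assert np.allclose(egms.meta["truth"].core_path, path)

    def test_spiral_core_outside_mesh_rejected(self, disk_mesh):
        truth = afs.WaveFieldTruth(frequency_hz=6.0, kind="spiral", core=[10.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="core"):
            afs.simulate_wavefield(disk_mesh, truth, 500.0, 1.0)

    def test_preconditions(self, disk_mesh):
        truth = afs.WaveFieldTruth(frequency_hz=6.0, kind="planar")
        with pytest.raises(ValueError):
            afs.simulate_wavefield(disk_mesh, truth, 50.0, 4.0)
        with pytest.raises(ValueError):
            afs.simulate_wavefield(disk_mesh, truth, 500.0, 0.5)


class TestSphereTransfer:
    def test_central_source_gives_equal_electrode_potentials(self):
        T = afs.make_sphere_transfer(1.0, 3.0, 1, 32,
                                     source_positions=np.zeros((1, 3)))
        col = T.entries[:, 0]
        assert np.allclose(col, col[0])

    def test_radial_decay_matches_analytic_formula(self):
        # central source: potential = 1/(4*pi*R); doubling the electrode
        # radius halves it, checked by direct evaluation at both radii
        T1 = afs.make_sphere_transfer(1.0, 3.0, 1, 16, source_positions=np.zeros((1, 3)))
        T2 = afs.make_sphere_transfer(1.0, 6.0, 1, 16, source_positions=np.zeros((1, 3)))
        analytic = lambda R: 1.0 / (4.0 * np.pi * R)
        assert np.allclose(T1.entries, analytic(3.0))
        assert np.allclose(T2.entries, analytic(6.0))
        assert np.allclose(T1.entries / T2.entries, 2.0)

    def test_antipodal_opposite_sources_are_antisymmetric(self):
        src = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, -1.0]])
        # electrodes placed in reflection-symmetric pairs about z -> -z
        elec = np.array([[2.0, 0.0, 1.5], [2.0, 0.0, -1.5],
                         [0.0, 2.0, 0.5], [0.0, 2.0, -0.5]])
        T = afs.make_sphere_transfer(1.0, 3.0, 2, 4,
                                     source_positions=src, electrode_positions=elec)
        pot = T.entries @ np.array([1.0, -1.0])  # opposite-sign sources
        assert pot[0] == pytest.approx(-pot[1])
        assert pot[2] == pytest.approx(-pot[3])

    def test_coincident_positions_rejected(self):
        p = np.array([[1.0, 0.0, 0.0]])
        with pytest.raises(ValueError, match="coincident"):
            afs.make_sphere_transfer(1.0, 3.0, 1, 1,
                                     source_positions=p, electrode_positions=p)

    def test_geometry_preconditions(self):
        with pytest.raises(ValueError):
            afs.make_sphere_transfer(3.0, 1.0, 8, 8)


class TestForwardProject:
    def _tone_set(self, n_ch=8, fs=500.0, dur=4.0, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(int(fs * dur)) / fs
        x = np.array([np.cos(2 * np.pi * 6.0 * t + p) for p in rng.uniform(0, 2 * np.pi, n_ch)])
        return afs.NodeSignalSet(x, fs, role="icegm")

    def test_identity_noiseless_is_exact(self):
        egms = self._tone_set()
        T = afs.TransferMatrix(np.eye(8), np.zeros((8, 3)), np.zeros((8, 3)))
        out = afs.forward_project(T, egms)
        assert np.array_equal(out.samples, egms.samples)
        assert out.role == "surface"

    def test_requested_snr_achieved_within_one_db(self):
        egms = self._tone_set(dur=20.0)
        T = afs.TransferMatrix(np.eye(8), np.zeros((8, 3)), np.zeros((8, 3)))
        out = afs.forward_project(T, egms, snr_db=20.0, rng=0)
        clean = T.entries @ egms.samples
        noise = out.meta["noise"]
        snr = 10 * np.log10(np.mean(clean**2) / np.mean(noise**2))
        assert abs(snr - 20.0) < 1.0

    def test_zero_input_gives_pure_noise_with_stated_variance(self):
        egms = self._tone_set(dur=40.0)
        egms = egms.copy_with(np.zeros_like(egms.samples))
        T = afs.TransferMatrix(np.eye(8), np.zeros((8, 3)), np.zeros((8, 3)))
        out = afs.forward_project(T, egms, rng=1, noise_std=0.5)
        assert np.var(out.samples) == pytest.approx(0.25, rel=0.05)
        assert out.meta["noise_var"] == pytest.approx(0.25)

    def test_shape_mismatch_rejected(self):
        egms = self._tone_set(n_ch=5)
        T = afs.TransferMatrix(np.eye(8), np.zeros((8, 3)), np.zeros((8, 3)))
        with pytest.raises(ValueError, match="mismatch"):
            afs.forward_project(T, egms)

    def test_pseudoinverse_inverts_noiseless_full_rank_projection(self):
        rng = np.random.default_rng(3)
        egms = self._tone_set()
        A = rng.normal(size=(8, 8)) + 2 * np.eye(8)
        T = afs.TransferMatrix(A, np.zeros((8, 3)), np.zeros((8, 3)))
        out = afs.forward_project(T, egms)
        rec = np.linalg.pinv(A) @ out.samples
        assert np.allclose(rec, egms.samples, atol=1e-10)


class TestGenerateCohort:
    def test_same_seed_reproduces_cohort_exactly(self):
        a = afs.generate_cohort(afs.CohortSpec(n=500, seed=7))
        b = afs.generate_cohort(afs.CohortSpec(n=500, seed=7))
        assert a.equals(b)

    def test_outcome_rate_matches_monte_carlo_mean_probability(self):
        cohort = afs.generate_cohort(afs.CohortSpec(n=100_000, seed=5))
        # oracle: the Monte-Carlo mean of the generating probability itself
        p_bar = cohort["p_true"].mean()
        se = np.sqrt((cohort["p_true"] * (1 - cohort["p_true"])).mean() / len(cohort))
        assert abs(cohort["outcome_1y"].mean() - p_bar) < 3 * se

    def test_zero_coefficients_give_half_rate(self):
        coeffs = afs.ScoreCoefficients(0.0, 0.0, 0.0, 0.0)
        cohort = afs.generate_cohort(afs.CohortSpec(n=20_000, seed=2), coeffs)
        assert np.allclose(cohort["p_true"], 0.5)
        assert abs(cohort["outcome_1y"].mean() - 0.5) < 3 * 0.5 / np.sqrt(20_000)

    def test_hdf_never_below_median_df(self, default_cohort):
        assert (default_cohort["hdf"] >= default_cohort["median_df"]).all()

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            afs.CohortSpec(n=0)
        with pytest.raises(ValueError):
            afs.CohortSpec(n=10, median_df_range_hz=(9.0, 4.0))
        with pytest.raises(ValueError):
            afs.CohortSpec(n=10, af_type_props={"paroxysmal": 0.7, "persistent": 0.7})


class TestInjectQrs:
    def _tone(self, fs=500.0, dur=10.0):
        t = np.arange(int(fs * dur)) / fs
        return afs.NodeSignalSet(np.cos(2 * np.pi * 6 * t)[None, :], fs)

    def test_zero_amplitude_leaves_signal_unchanged(self):
        sig = self._tone()
        out, peaks = afs.inject_qrs(sig, 60.0, 0.0)
        assert np.allclose(out.samples, sig.samples)

    def test_peak_count_at_60_bpm_over_10_s(self):
        out, peaks = afs.inject_qrs(self._tone(), 60.0, 5.0)
        assert abs(len(peaks) - 10) <= 1

    def test_template_subtraction_restores_original(self):
        sig = self._tone()
        out, peaks = afs.inject_qrs(sig, 60.0, 5.0)
        tmpl = out.meta["qrs_template"]
        half = (len(tmpl) - 1) // 2
        restored = out.samples.copy()
        for tp in peaks:
            c = int(round(tp * sig.fs_hz))
            restored[:, c - half : c + half + 1] -= tmpl
        assert np.allclose(restored, sig.samples, atol=1e-12)

    def test_rate_bounds(self):
        with pytest.raises(ValueError):
            afs.inject_qrs(self._tone(), 20.0, 1.0)


def test_fibonacci_sphere_points_lie_on_sphere():
    pts = fibonacci_sphere(100, 2.5)
    assert np.allclose(np.linalg.norm(pts, axis=1), 2.5)
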