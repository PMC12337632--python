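import numpy as np
import pytest

import afstrat as afs
from afstrat.rotors import LINK_THRESHOLD_CM, PhaseMap, SingularityPoint
from conftest import brute_force_singular_faces


def _sp(x, y, chirality=+1, sample=0, t=0.0):
    return SingularityPoint(
        position=np.array([x, y, 0.0]), vertex=0, sample=sample, t=t,
        chirality=chirality, circles_passing=3,
    )


class TestHilbertPhase:
    def test_tone_phase_advances_linearly(self):
        fs, f = 500.0, 6.0
        t = np.arange(int(fs * 2)) / fs
        sig = afs.NodeSignalSet(np.cos(2 * np.pi * f * t)[None, :], fs)
        ph = afs.hilbert_phase(sig).phase[0]
        mid = slice(200, 800)
        rate = np.diff(np.unwrap(ph[mid])) * fs / (2 * np.pi)
        assert np.allclose(rate, f, atol=0.05)

    def test_quadrature_pair_offset_minus_half_pi(self):
        fs, f = 500.0, 6.0
        t = np.arange(int(fs * 2)) / fs
        sig = afs.NodeSignalSet(
            np.vstack([np.cos(2 * np.pi * f * t), np.sin(2 * np.pi * f * t)]), fs
        )
        ph = afs.hilbert_phase(sig).phase
        diff = np.angle(np.exp(1j * (ph[1] - ph[0])))[200:800]
        assert np.allclose(diff, -np.pi / 2, atol=0.05)

    def test_phase_spans_pi_around_spiral_core(self, disk_mesh, spiral_phase):
        # the triangle enclosing the core sees widely spread phases
        core = np.zeros(3)
        d = np.linalg.norm(disk_mesh.vertices - core, axis=1)
        tri = np.argsort(d)[:3]
        for s in range(100, 900, 100):
            vals = spiral_phase.phase[tri, s]
            spread = np.ptp(np.sort(np.angle(np.exp(1j * vals))))
            assert spread > np.pi / 2

    def test_constant_channel_rejected(self):
        sig = afs.NodeSignalSet(np.ones((1, 500)), 500.0)
        with pytest.raises(ValueError, match="constant"):
            afs.hilbert_phase(sig)


class TestDetectSps:
    def test_planar_field_has_no_singularities(self, disk_mesh, disk_detector, planar_field):
        ph = afs.hilbert_phase(planar_field)
        for s in (100, 400, 700):
            assert disk_detector.detect(ph, s) == []

    def test_centered_spiral_gives_one_sp_near_core(
        self, disk_mesh, disk_detector, spiral_phase
    ):
        for s in (200, 500, 800):
            sps = disk_detector.detect(spiral_phase, s)
            assert len(sps) == 1
            assert np.linalg.norm(sps[0].position) <= disk_mesh.mean_edge_cm
            assert sps[0].chirality == +1

    def test_agrees_with_brute_force_winding_oracle(self, small_disk_mesh):
        truth = afs.WaveFieldTruth(frequency_hz=6.0, kind="spiral", chirality=+1,
                                   core=[0.5, -0.3, 0.0])
        egms = afs.simulate_wavefield(small_disk_mesh, truth, 500.0, 2.0)
        ph = afs.hilbert_phase(egms)
        det = afs.SingularityDetector(small_disk_mesh)
        r0 = small_disk_mesh.mean_edge_cm
        for s in range(150, 900, 75):
            sps = det.detect(ph, s)
            singular_faces, _ = brute_force_singular_faces(
                small_disk_mesh, ph.phase[:, s]
            )
            centers = small_disk_mesh.vertices[
                small_disk_mesh.faces[singular_faces]
            ].mean(axis=1)
            # interior singular faces (detector skips the boundary band)
            interior = centers[np.linalg.norm(centers[:, :2], axis=1) < 4.0 - 3.5 * r0]
            assert len(sps) >= 1
            for sp in sps:
                assert np.min(np.linalg.norm(interior - sp.position, axis=1)) < 2 * r0
            for c in interior:
                assert min(np.linalg.norm(sp.position - c) for sp in sps) < 2 * r0

    def test_chirality_follows_generator(self, disk_mesh, disk_detector):
        truth = afs.WaveFieldTruth(frequency_hz=6.0, kind="spiral", chirality=-1,
                                   core=[0.0, 0.0, 0.0])
        egms = afs.simulate_wavefield(disk_mesh, truth, 500.0, 2.0)
        ph = afs.hilbert_phase(egms)
        sps = disk_detector.detect(ph, 500)
        assert len(sps) == 1 and sps[0].chirality == -1

    def test_global_phase_offset_preserves_sp_count(self, disk_detector, spiral_phase):
        base = disk_detector.detect(spiral_phase, 500)
        shifted = PhaseMap(
            np.angle(np.exp(1j * (spiral_phase.phase + 1.234))), spiral_phase.fs_hz
        )
        moved = disk_detector.detect(shifted, 500)
        assert len(moved) == len(base)

    def test_single_winding_circle_is_not_enough(self, disk_mesh):
        # superpose a counter-rotating source 1.5 mean edges away: at the
        # vertex on the main core only the innermost circle winds (the outer
        # two enclose both cores, net winding zero), so the >= 2-of-3 rule
        # must reject that vertex
        r0 = disk_mesh.mean_edge_cm
        a = np.array([0.0, 0.0])
        b = np.array([1.5 * r0, 0.0])
        v = disk_mesh.vertices[:, :2]
        field = np.arctan2(*(v - a).T[::-1]) - np.arctan2(*(v - b).T[::-1])
        ph = PhaseMap(np.angle(np.exp(1j * field))[:, None], fs_hz=500.0)
        det = afs.SingularityDetector(disk_mesh)
        valid, verdicts = det.circle_verdicts(ph, 0)
        core_vertex = int(np.argmin(np.linalg.norm(v - a, axis=1)))
        row = verdicts[list(valid).index(core_vertex)]
        # only the innermost circle winds at the core vertex ...
        assert row[0] != 0 and row[1] == 0 and row[2] == 0
        # ... hence no SP is declared at that vertex
        sp_vertices = {sp.vertex for sp in det.detect(ph, 0)}
        assert core_vertex not in sp_vertices

    def test_sample_out_of_range_rejected(self, disk_detector, spiral_phase):
        with pytest.raises(ValueError):
            disk_detector.detect(spiral_phase, 10_000)

    def test_functional_wrapper(self, disk_mesh, spiral_phase):
        sps = afs.detect_sps(spiral_phase, disk_mesh, 500)
        assert len(sps) == 1


class TestTrackSps:
    def test_nearby_sps_link_into_one_trajectory(self):
        frames = [[_sp(0.0, 0.0, sample=0, t=0.0)], [_sp(0.5, 0.0, sample=1, t=0.002)]]
        trajs = afs.track_sps(frames, "icegm")
        assert len(trajs) == 1 and len(trajs[0].points) == 2

    def test_distant_sps_stay_separate(self):
        frames = [[_sp(0.0, 0.0, sample=0)], [_sp(2.0, 0.0, sample=1, t=0.002)]]
        assert len(afs.track_sps(frames, "icegm")) == 2

    def test_ecg_mode_links_at_three_cm(self):
        frames = [[_sp(0.0, 0.0)], [_sp(3.0, 0.0, sample=1, t=0.002)]]
        assert len(afs.track_sps(frames, "ecg")) == 1

    def test_distance_equal_to_threshold_not_linked(self):
        for mode in ("icegm", "ecg"):
            d = LINK_THRESHOLD_CM[mode]
            frames = [[_sp(0.0, 0.0)], [_sp(d, 0.0, sample=1, t=0.002)]]
            assert len(afs.track_sps(frames, mode)) == 2

    def test_opposite_chirality_never_links(self):
        frames = [[_sp(0.0, 0.0, +1)], [_sp(0.1, 0.0, -1, sample=1, t=0.002)]]
        assert len(afs.track_sps(frames, "icegm")) == 2

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            afs.track_sps([], "banana")


class TestFilterAndBiomarkers:
    def test_subrotation_trajectories_discarded(self):
        tr = afs.RotorTrajectory(points=[_sp(0, 0), _sp(0.1, 0, sample=1, t=0.1)])
        tr.rotations = 0.5
        assert afs.filter_rotors([tr]) == []
        tr.rotations = 1.2
        assert afs.filter_rotors([tr]) == [tr]

    def test_empty_input_empty_output(self):
        assert afs.filter_rotors([]) == []

    def test_mean_rotor_time_is_mean_of_durations(self):
        def traj(dur):
            t = afs.RotorTrajectory(
                points=[_sp(0, 0, t=0.0), _sp(0.1, 0, sample=1, t=dur)], rotations=2.0
            )
            return t

        mrt, extras = afs.rotor_biomarkers([traj(0.4), traj(0.6)], 1.0)
        assert mrt == pytest.approx(0.5)
        assert extras["rotor_count"] == 2
        assert extras["max_rotor_time_s"] == pytest.approx(0.6)
        assert extras["total_rotor_time_s"] == pytest.approx(1.0)

    def test_no_rotors_convention_zero(self):
        mrt, extras = afs.rotor_biomarkers([], 1.0)
        assert mrt == 0.0 and extras["rotor_count"] == 0

    def test_full_window_spiral_rotor_time_near_one_second(
        self, disk_mesh, disk_detector, spiral_phase
    ):
        fs = spiral_phase.fs_hz
        samples = np.arange(int(0.5 * fs), int(1.5 * fs), 2)  # central 1 s window
        frames = disk_detector.detect_all(spiral_phase, samples)
        trajs = afs.track_sps(frames, "icegm", phase=spiral_phase, mesh=disk_mesh)
        rotors = afs.filter_rotors(trajs)
        mrt, _ = afs.rotor_biomarkers(rotors, 1.0)
        assert abs(mrt - 1.0) < 0.1
        # 6 Hz rotor turning for ~1 s: about six rotations
        assert rotors[0].rotations == pytest.approx(6.0, rel=0.1)


class TestHistogramMap:
    def test_no_rotors_all_zero(self, disk_mesh):
        assert np.all(afs.rotor_histogram_map([], disk_mesh) == 0.0)

    def test_mass_equals_total_duration(self, disk_mesh):
        pts = [_sp(0.1 * k, 0.0, sample=k, t=0.01 * k) for k in range(6)]
        tr = afs.RotorTrajectory(points=pts, rotations=2.0)
        occ = afs.rotor_histogram_map([tr], disk_mesh)
        assert occ.sum() == pytest.approx(tr.duration_s)

    def test_stationary_rotor_mass_concentrates_at_core(
        self, disk_mesh, disk_detector, spiral_phase
    ):
        samples = np.arange(250, 750, 2)
        frames = disk_detector.detect_all(spiral_phase, samples)
        rotors = afs.filter_rotors(
            afs.track_sps(frames, "icegm", phase=spiral_phase, mesh=disk_mesh)
        )
        occ = afs.rotor_histogram_map(rotors, disk_mesh)
        d = np.linalg.norm(disk_mesh.vertices, axis=1)
        near = occ[d <= disk_mesh.mean_edge_cm].sum()
        assert near / occ.sum() > 0.95
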