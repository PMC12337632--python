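"""Detect and track a rotor on a simulated spiral wavefield.

Builds a disk mesh, simulates a 6 Hz spiral wave with a known core at the
origin, computes Hilbert phase maps, finds phase singularities by the
three-circle rule and links them into a rotor trajectory.
"""

import numpy as np

import afstrat as afs

mesh = afs.make_mesh("disk", radius_cm=4.0, target_edge_cm=0.3)
truth = afs.WaveFieldTruth(frequency_hz=6.0, kind="spiral", chirality=+1,
                           core=[0.0, 0.0, 0.0])
egms = afs.simulate_wavefield(mesh, truth, fs_hz=500.0, duration_s=2.0)
phase = afs.hilbert_phase(egms)

detector = afs.SingularityDetector(mesh)
samples = np.arange(250, 750, 2)  # central 1 s window at 4 ms steps
frames = detector.detect_all(phase, samples)
trajectories = afs.track_sps(frames, mode="icegm", phase=phase, mesh=mesh)
rotors = afs.filter_rotors(trajectories)

mrt, extras = afs.rotor_biomarkers(rotors, window_s=1.0)
sp = rotors[0].points[len(rotors[0].points) // 2]
print(f"rotors detected: {len(rotors)}")
print(f"core localized at ({sp.position[0]:+.2f}, {sp.position[1]:+.2f}) cm "
      f"(truth: origin), chirality {sp.chirality:+d}")
print(f"mean rotor time: {mrt:.3f} s over a 1 s window; "
      f"rotations completed: {rotors[0].rotations:.1f}")
# One rotor pivoting at the true core for the whole window, turning ~6 times
# (a 6 Hz spiral): the detector reproduces the generator's ground truth.
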