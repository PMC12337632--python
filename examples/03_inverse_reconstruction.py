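"""Tikhonov reconstruction of atrial electrograms from torso potentials.

Projects known source electrograms through an analytic spherical forward
operator, adds 20 dB measurement noise, picks the regularization weight at
the L-curve corner and compares regularized vs unregularized recovery.
"""

import numpy as np

import afstrat as afs

rng = np.random.default_rng(0)
transfer = afs.make_sphere_transfer(inner_r_cm=2.0, outer_r_cm=6.0,
                                    n_sources=36, n_electrodes=48)

t = np.arange(500) / 500.0
phases = rng.uniform(0, 2 * np.pi, 36)
X = np.cos(2 * np.pi * 6.0 * t[None, :] + phases[:, None])
egms = afs.NodeSignalSet(X, fs_hz=500.0, role="icegm")
surface = afs.forward_project(transfer, egms, snr_db=20.0, rng=1)

lam = afs.choose_lambda(transfer, surface, np.logspace(-8, 0, 30))
regularized = afs.tikhonov_solve(transfer, surface, lam)
naive = afs.tikhonov_solve(transfer, surface, 0.0)

err = lambda sol: np.linalg.norm(sol.sources - X) / np.linalg.norm(X)
print(f"L-curve lambda: {lam:.3g}")
print(f"relative reconstruction error, lambda = 0:       {err(naive):.2f}")
print(f"relative reconstruction error, L-curve lambda:   {err(regularized):.2f}")
# The unregularized solve amplifies noise through the operator's small
# singular values; the L-curve corner damps them and recovers the sources.
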