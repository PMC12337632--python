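"""Dominant-frequency mapping of a two-region wavefield.

Simulates an atrial surface whose left half activates at 5 Hz and right
half at 8 Hz, computes the per-vertex Welch DF map (0.01 Hz grid) and the
two spectral score covariates: highest DF and median DF.
"""

import numpy as np

import afstrat as afs

mesh = afs.make_mesh("disk", radius_cm=4.0, target_edge_cm=0.3)
t = np.arange(2000) / 500.0
left = mesh.vertices[:, 0] < 0
samples = np.where(left[:, None],
                   np.cos(2 * np.pi * 5.0 * t)[None, :],
                   np.cos(2 * np.pi * 8.0 * t)[None, :])
egms = afs.NodeSignalSet(samples, fs_hz=500.0, role="icegm",
                         channel_positions=mesh.vertices)

dmap = afs.df_map(egms, band=(3.0, 15.0))
hdf, mdf = afs.df_summaries(dmap)

print(f"vertices: {mesh.n_vertices}; DF grid spacing: {dmap.resolution_hz:.3f} Hz")
print(f"left-half DF:  {dmap.df_hz[left].mean():.2f} Hz (truth 5.00)")
print(f"right-half DF: {dmap.df_hz[~left].mean():.2f} Hz (truth 8.00)")
print(f"HDF = {hdf:.2f} Hz, MedianDF = {mdf:.2f} Hz")
# HDF picks the fastest-activating region (8 Hz); the median reflects the
# mix of the two regions. Their gap is what drives the complexity score up.
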