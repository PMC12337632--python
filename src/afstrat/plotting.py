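"""Mesh-coloured map rendering (DF maps, rotor histograms)."""

from __future__ import annotations

import numpy as np

from .mesh import AtrialMesh

__all__ = ["plot_vertex_map"]


def plot_vertex_map(mesh: AtrialMesh, values: np.ndarray, title: str = "",
                    cmap: str = "viridis", ax=None):
    """Render a per-vertex scalar map on a (planar) mesh via tripcolor.

    For non-planar meshes the x-y projection is drawn. Returns the axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    v = mesh.vertices
    tpc = ax.tripcolor(v[:, 0], v[:, 1], mesh.faces, np.asarray(values),
                       shading="gouraud", cmap=cmap)
    ax.set_aspect("equal")
    ax.set_xlabel("x (cm)")
    ax.set_ylabel("y (cm)")
    if title:
        ax.set_title(title)
    plt.colorbar(tpc, ax=ax, shrink=0.8)
    return ax
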