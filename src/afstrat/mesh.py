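"""Triangulated atrial surface meshes.

Real recordings are mapped onto a patient-specific bi-atrial geometry; for
simulation and validation work we use analytically constructed disk and
sphere meshes whose edge-length statistics are controlled, so that phase
singularity detection radii (multiples of the mean edge length) behave the
same way they would on an anatomical mesh.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy.spatial import ConvexHull, Delaunay

__all__ = ["AtrialMesh", "make_mesh", "load_mesh"]


@dataclass
class AtrialMesh:
    """Manifold triangulated surface with coordinates in cm.

    Attributes
    ----------
    vertices : (n, 3) float array, cm
    faces : (m, 3) int array of vertex indices
    """

    vertices: np.ndarray
    faces: np.ndarray
    _edges: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (m, 3)")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValueError("face indices out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def edges(self) -> np.ndarray:
        """Unique undirected edges as (k, 2) index pairs."""
        if self._edges is None:
            e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
            e.sort(axis=1)
            self._edges = np.unique(e, axis=0)
        return self._edges

    @property
    def edge_lengths(self) -> np.ndarray:
        e = self.edges
        return np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)

    @property
    def mean_edge_cm(self) -> float:
        return float(self.edge_lengths.mean())

    @property
    def max_edge_cm(self) -> float:
        return float(self.edge_lengths.max())

    @property
    def edge_length_stats(self) -> dict:
        return {"mean": self.mean_edge_cm, "max": self.max_edge_cm}

    def vertex_neighbors(self) -> list[np.ndarray]:
        """Adjacency: for each vertex, the indices of vertices sharing an edge."""
        nbrs: list[list[int]] = [[] for _ in range(self.n_vertices)]
        for a, b in self.edges:
            nbrs[a].append(b)
            nbrs[b].append(a)
        return [np.asarray(v, dtype=int) for v in nbrs]

    def vertex_normals(self) -> np.ndarray:
        tm = trimesh.Trimesh(self.vertices, self.faces, process=False)
        return np.asarray(tm.vertex_normals, dtype=float)

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges) + len(self.faces)

    def boundary_vertices(self) -> np.ndarray:
        """Vertices incident to an edge used by only one face (empty for closed surfaces)."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        e.sort(axis=1)
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        border = uniq[counts == 1]
        return np.unique(border)

    def save(self, path: str | Path) -> None:
        """Write the mesh as OFF or PLY (decided by the file extension)."""
        path = Path(path)
        tm = trimesh.Trimesh(self.vertices, self.faces, process=False)
        tm.export(path)


def load_mesh(path: str | Path) -> AtrialMesh:
    """Read an OFF or PLY surface into an :class:`AtrialMesh`."""
    tm = trimesh.load(str(path), process=False, force="mesh")
    return AtrialMesh(np.asarray(tm.vertices, float), np.asarray(tm.faces, int))


def _disk_mesh(radius_cm: float, target_edge_cm: float) -> AtrialMesh:
    # hexagonal lattice clipped to the disk; Delaunay of a convex region is
    # a proper triangulation of its hull
    h = target_edge_cm
    dy = h * np.sqrt(3.0) / 2.0
    rows = int(np.ceil(radius_cm / dy))
    pts = []
    for j in range(-rows, rows + 1):
        y = j * dy
        x0 = (h / 2.0) if (j % 2) else 0.0
        cols = int(np.ceil(radius_cm / h)) + 1
        for i in range(-cols, cols + 1):
            x = x0 + i * h
            if x * x + y * y <= radius_cm**2:
                pts.append((x, y))
    pts = np.asarray(pts, dtype=float)
    tri = Delaunay(pts)
    verts = np.column_stack([pts, np.zeros(len(pts))])
    return AtrialMesh(verts, tri.simplices)


def _sphere_mesh(radius_cm: float, target_edge_cm: float) -> AtrialMesh:
    # Fibonacci point set; n chosen so the hexagonal-packing edge matches the
    # target: area per vertex A = 4*pi*R^2/n, edge h = sqrt(2A/sqrt(3))
    n = max(12, int(round(8.0 * np.pi * radius_cm**2 / (np.sqrt(3.0) * target_edge_cm**2))))
    pts = fibonacci_sphere(n, radius_cm)
    hull = ConvexHull(pts)
    faces = hull.simplices.copy()
    # orient faces outward
    centroid = pts.mean(axis=0)
    for k, f in enumerate(faces):
        a, b, c = pts[f]
        if np.dot(np.cross(b - a, c - a), a - centroid) < 0:
            faces[k] = f[[0, 2, 1]]
    return AtrialMesh(pts, faces)


def fibonacci_sphere(n: int, radius: float = 1.0) -> np.ndarray:
    """Near-uniform points on a sphere via the golden-angle spiral."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return radius * np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def make_mesh(shape: str, radius_cm: float, target_edge_cm: float) -> AtrialMesh:
    """Build a disk or sphere test surface with a controlled mean edge length.

    Parameters
    ----------
    shape : ``"disk"`` or ``"sphere"``
    radius_cm : overall radius of the surface, cm
    target_edge_cm : requested mean edge length, cm (must be < radius)

    Returns
    -------
    AtrialMesh with mean edge length within 25% of ``target_edge_cm``.
    """
    if radius_cm <= 0:
        raise ValueError("radius_cm must be positive")
    if not 0 < target_edge_cm < radius_cm:
        raise ValueError("target_edge_cm must lie in (0, radius_cm)")
    if shape == "disk":
        return _disk_mesh(radius_cm, target_edge_cm)
    if shape == "sphere":
        return _sphere_mesh(radius_cm, target_edge_cm)
    raise ValueError(f"unknown shape {shape!r} (expected 'disk' or 'sphere')")
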