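"""Phase mapping, phase-singularity detection and rotor tracking.

A rotor (sustained re-entrant activation) pivots around a phase singularity
(SP): a point where the instantaneous phase of the surrounding tissue spans
a full 2*pi. Detection follows the three-circle rule: around each candidate
vertex, phase is sampled on three concentric circles (radii 1x, 2x, 3x the
mesh mean edge length; 6, 9 and 12 points inner to outer) by weighted
interpolation from neighbouring vertices, and the vertex is a singularity
iff on at least two of the three circles the phase progresses monotonically
around the circle for a total of +/-2*pi. The winding sign is the rotor's
chirality.

Interpolation detail: wrapped angles cannot be averaged across the +/-pi
branch cut, so the interpolation acts on the unit phasor e^{i*phase} and
takes the angle of the weighted complex mean. Weights are proportional to
d^-2 over the nearest vertices (the inverse-square reading of the
distance-weighting rule; the literal d^2 variant is selectable).

Singularities are linked across time into trajectories when consecutive
points of equal chirality lie strictly closer than 1 cm (electrogram modes)
or 5 cm (body-surface mode), and only trajectories completing at least one
full rotation count as rotors; shorter-lived singularities are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert
from scipy.spatial import cKDTree

from .mesh import AtrialMesh
from .signals import NodeSignalSet

__all__ = [
    "PhaseMap",
    "SingularityPoint",
    "RotorTrajectory",
    "SingularityDetector",
    "hilbert_phase",
    "detect_sps",
    "track_sps",
    "filter_rotors",
    "rotor_biomarkers",
    "rotor_histogram_map",
    "LINK_THRESHOLD_CM",
]

LINK_THRESHOLD_CM = {"icegm": 1.0, "egm": 1.0, "ecg": 5.0}


@dataclass
class PhaseMap:
    """Per-vertex, per-sample instantaneous phase in (-pi, pi]."""

    phase: np.ndarray  # (n_vertices, n_samples)
    fs_hz: float

    def __post_init__(self) -> None:
        self.phase = np.atleast_2d(np.asarray(self.phase, dtype=float))
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")

    @property
    def n_samples(self) -> int:
        return self.phase.shape[1]


@dataclass
class SingularityPoint:
    position: np.ndarray  # cm
    vertex: int
    sample: int
    t: float  # s
    chirality: int  # +1 / -1
    circles_passing: int

    def __post_init__(self) -> None:
        if self.circles_passing < 2:
            raise ValueError("an SP requires at least 2 passing circles")


@dataclass
class RotorTrajectory:
    """Time-ordered singularity points forming one rotational episode."""

    points: list  # of SingularityPoint
    mode: str = "icegm"
    rotations: float = 0.0

    @property
    def chirality(self) -> int:
        return self.points[0].chirality

    @property
    def duration_s(self) -> float:
        return self.points[-1].t - self.points[0].t

    @property
    def positions(self) -> np.ndarray:
        return np.array([p.position for p in self.points])


def hilbert_phase(egms: NodeSignalSet) -> PhaseMap:
    """Instantaneous phase of the analytic signal, per channel.

    Channels are expected band-filtered and zero-mean; a (numerically)
    constant channel has no defined phase and raises.
    """
    x = egms.samples
    stds = x.std(axis=1)
    if np.any(stds < 1e-12):
        bad = int(np.flatnonzero(stds < 1e-12)[0])
        raise ValueError(f"constant channel {bad}: phase undefined")
    analytic = hilbert(x, axis=1)
    return PhaseMap(phase=np.angle(analytic), fs_hz=egms.fs_hz)


def _wrap(a: np.ndarray) -> np.ndarray:
    return np.angle(np.exp(1j * a))


class SingularityDetector:
    """Three-circle phase-singularity detector with precomputed geometry.

    All circle sampling points and their interpolation weights depend only
    on the mesh, so they are assembled once; evaluating a time sample is
    then a single sparse interpolation.

    Parameters
    ----------
    mesh : AtrialMesh
    radius_scales : circle radii as multiples of the mean edge length
    circle_points : samples per circle, inner to outer
    weight : ``"inv_sq"`` for d^-2 interpolation weights (default) or
        ``"sq"`` for the literal d^2 variant
    k_neighbors : vertices interpolated per circle point
    max_violation : monotonicity tolerance — one backward phase step of at
        most this size is allowed per circle; ``strict=True`` allows none
    min_circles : circles that must wind for a vertex to qualify (>= 2)
    """

    def __init__(
        self,
        mesh: AtrialMesh,
        radius_scales: tuple = (1.0, 2.0, 3.0),
        circle_points: tuple = (6, 9, 12),
        weight: str = "inv_sq",
        k_neighbors: int = 4,
        max_violation: float = np.pi / 6.0,
        strict: bool = False,
        min_circles: int = 2,
    ) -> None:
        if len(radius_scales) != len(circle_points):
            raise ValueError("radius_scales and circle_points lengths differ")
        if weight not in ("inv_sq", "sq"):
            raise ValueError("weight must be 'inv_sq' or 'sq'")
        self.mesh = mesh
        self.radius_scales = tuple(radius_scales)
        self.circle_points = tuple(circle_points)
        self.max_violation = 0.0 if strict else max_violation
        self.min_circles = min_circles
        r0 = mesh.mean_edge_cm
        self.radii = [s * r0 for s in radius_scales]
        self._merge_dist = 1.5 * r0
        self._build(weight, k_neighbors)

    def _build(self, weight: str, k: int) -> None:
        mesh = self.mesh
        verts = mesh.vertices
        normals = mesh.vertex_normals()
        tree = cKDTree(verts)
        r0 = mesh.mean_edge_cm

        # boundary policy: skip vertices whose outer circle could leave the
        # mesh (distance to the boundary below the outer radius)
        boundary = mesh.boundary_vertices()
        valid = np.ones(mesh.n_vertices, dtype=bool)
        if boundary.size:
            btree = cKDTree(verts[boundary])
            d_b, _ = btree.query(verts)
            valid &= d_b > self.radii[-1] + 0.5 * r0
            valid[boundary] = False
        self.valid_vertices = np.flatnonzero(valid)

        # tangent-plane basis per vertex
        n_hat = normals / np.linalg.norm(normals, axis=1, keepdims=True)
        ref = np.tile(np.array([1.0, 0.0, 0.0]), (len(verts), 1))
        close = np.abs(n_hat[:, 0]) > 0.9
        ref[close] = [0.0, 1.0, 0.0]
        e1 = np.cross(n_hat, ref)
        e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
        e2 = np.cross(n_hat, e1)

        # circle sample points for every valid vertex, stacked
        pts = []
        for v in self.valid_vertices:
            for radius, m in zip(self.radii, self.circle_points):
                ang = 2.0 * np.pi * np.arange(m) / m
                circ = (
                    verts[v]
                    + radius * np.cos(ang)[:, None] * e1[v]
                    + radius * np.sin(ang)[:, None] * e2[v]
                )
                pts.append(circ)
        self._n_pts_per_vertex = int(sum(self.circle_points))
        if not len(pts):
            self._nbr_idx = np.zeros((0, k), dtype=int)
            self._nbr_w = np.zeros((0, k))
            return
        P = np.vstack(pts)
        d, idx = tree.query(P, k=k)
        d = np.maximum(d, 1e-9)
        w = d**-2 if weight == "inv_sq" else d**2
        w /= w.sum(axis=1, keepdims=True)
        self._nbr_idx = idx
        self._nbr_w = w

    # -- per-sample evaluation ------------------------------------------

    def _circle_phases(self, phase_t: np.ndarray) -> np.ndarray:
        """Interpolated phase at every circle point, shape (n_valid, sum(points))."""
        phasor = np.exp(1j * phase_t)
        interp = (phasor[self._nbr_idx] * self._nbr_w).sum(axis=1)
        return np.angle(interp).reshape(len(self.valid_vertices), self._n_pts_per_vertex)

    def _circle_verdicts(self, circ_phases: np.ndarray) -> np.ndarray:
        """Per circle: +1 / -1 if it winds monotonically by 2*pi, else 0."""
        n_valid = circ_phases.shape[0]
        verdicts = np.zeros((n_valid, len(self.circle_points)), dtype=int)
        start = 0
        for c, m in enumerate(self.circle_points):
            ph = circ_phases[:, start : start + m]
            start += m
            diffs = _wrap(np.diff(np.column_stack([ph, ph[:, :1]]), axis=1))
            winding = np.rint(diffs.sum(axis=1) / (2.0 * np.pi)).astype(int)
            pos_ok = (diffs > 0) | (np.abs(diffs) <= self.max_violation)
            neg_ok = (diffs < 0) | (np.abs(diffs) <= self.max_violation)
            mono_pos = (diffs <= 0).sum(axis=1) <= 1
            mono_neg = (diffs >= 0).sum(axis=1) <= 1
            up = (winding == 1) & np.all(pos_ok, axis=1) & mono_pos
            dn = (winding == -1) & np.all(neg_ok, axis=1) & mono_neg
            verdicts[:, c] = up.astype(int) - dn.astype(int)
        return verdicts

    def circle_verdicts(self, phase: PhaseMap, sample: int) -> tuple[np.ndarray, np.ndarray]:
        """Per-vertex, per-circle winding verdicts (+1/-1 wind, 0 none).

        Returns ``(valid_vertices, verdicts)`` with verdicts of shape
        (n_valid, n_circles); diagnostic view of the criterion before the
        >= min_circles vote and spatial merging.
        """
        circ = self._circle_phases(phase.phase[:, sample])
        return self.valid_vertices, self._circle_verdicts(circ)

    def detect(self, phase: PhaseMap, sample: int) -> list[SingularityPoint]:
        """Singularity points at one time sample.

        Vertices passing the criterion cluster around each true core; same-
        chirality hits closer than 1.5 mean edges are merged into one SP at
        their centroid.
        """
        if not 0 <= sample < phase.n_samples:
            raise ValueError("sample outside recording")
        if len(self.valid_vertices) == 0:
            return []
        circ = self._circle_phases(phase.phase[:, sample])
        verdicts = self._circle_verdicts(circ)
        n_pos = (verdicts > 0).sum(axis=1)
        n_neg = (verdicts < 0).sum(axis=1)
        hits = []
        for chirality, n_pass in ((+1, n_pos), (-1, n_neg)):
            for j in np.flatnonzero(n_pass >= self.min_circles):
                hits.append((int(self.valid_vertices[j]), chirality, int(n_pass[j])))
        return self._merge(hits, sample, phase.fs_hz)

    def _merge(self, hits, sample: int, fs_hz: float) -> list[SingularityPoint]:
        verts = self.mesh.vertices
        out: list[SingularityPoint] = []
        for chi in (+1, -1):
            members = [(h[0], h[2]) for h in hits if h[1] == chi]
            if not members:
                continue
            idx = np.array([m[0] for m in members])
            npass = np.array([m[1] for m in members])
            pos = verts[idx]
            # connected components under the merge distance
            n = len(idx)
            unassigned = np.ones(n, dtype=bool)
            while unassigned.any():
                seed = int(np.flatnonzero(unassigned)[0])
                comp = [seed]
                unassigned[seed] = False
                frontier = [seed]
                while frontier:
                    cur = frontier.pop()
                    d = np.linalg.norm(pos - pos[cur], axis=1)
                    newly = np.flatnonzero(unassigned & (d <= self._merge_dist))
                    for j in newly:
                        unassigned[j] = False
                        comp.append(int(j))
                        frontier.append(int(j))
                centroid = pos[comp].mean(axis=0)
                nearest = int(idx[comp[int(np.argmin(np.linalg.norm(pos[comp] - centroid, axis=1)))]])
                out.append(
                    SingularityPoint(
                        position=centroid,
                        vertex=nearest,
                        sample=sample,
                        t=sample / fs_hz,
                        chirality=chi,
                        circles_passing=int(npass[comp].max()),
                    )
                )
        return out

    def detect_all(self, phase: PhaseMap, samples) -> list[list[SingularityPoint]]:
        return [self.detect(phase, int(s)) for s in samples]


def detect_sps(
    phase: PhaseMap,
    mesh: AtrialMesh,
    sample: int,
    detector: SingularityDetector | None = None,
    **kwargs,
) -> list[SingularityPoint]:
    """Convenience wrapper: build a detector for ``mesh`` and evaluate one sample."""
    det = detector if detector is not None else SingularityDetector(mesh, **kwargs)
    return det.detect(phase, sample)


def track_sps(
    frames: list[list[SingularityPoint]],
    mode: str = "icegm",
    phase: PhaseMap | None = None,
    mesh: AtrialMesh | None = None,
) -> list[RotorTrajectory]:
    """Link singularity points across time into trajectories.

    Greedy nearest-neighbour linking between consecutive frames: only pairs
    of equal chirality strictly closer than the mode's threshold (1 cm for
    electrogram modes, 5 cm for body-surface ECG) are connected; distances
    equal to the threshold do not link. Unlinked points open new
    trajectories.

    When ``phase`` and ``mesh`` are given, each trajectory's rotation count
    is the accumulated unwrapped phase over its lifetime at the mesh vertex
    nearest its mean position, divided by 2*pi; otherwise rotations stay 0
    and must be set by the caller before filtering.
    """
    if mode not in LINK_THRESHOLD_CM:
        raise ValueError(f"mode must be one of {sorted(LINK_THRESHOLD_CM)}")
    thresh = LINK_THRESHOLD_CM[mode]
    open_trajs: list[list[SingularityPoint]] = []
    closed: list[list[SingularityPoint]] = []
    for frame in frames:
        frame = list(frame)
        if not open_trajs:
            open_trajs = [[sp] for sp in frame]
            continue
        heads = [tr[-1] for tr in open_trajs]
        pairs = []
        for i, h in enumerate(heads):
            for j, sp in enumerate(frame):
                if sp.chirality != h.chirality:
                    continue
                d = float(np.linalg.norm(sp.position - h.position))
                if d < thresh:
                    pairs.append((d, i, j))
        pairs.sort(key=lambda p: p[0])
        used_t, used_s = set(), set()
        links = {}
        for d, i, j in pairs:
            if i in used_t or j in used_s:
                continue
            used_t.add(i)
            used_s.add(j)
            links[i] = j
        next_open: list[list[SingularityPoint]] = []
        for i, tr in enumerate(open_trajs):
            if i in links:
                tr.append(frame[links[i]])
                next_open.append(tr)
            else:
                closed.append(tr)
        for j, sp in enumerate(frame):
            if j not in used_s:
                next_open.append([sp])
        open_trajs = next_open
    closed.extend(open_trajs)

    trajectories = [RotorTrajectory(points=pts, mode=mode) for pts in closed]
    if phase is not None and mesh is not None:
        for tr in trajectories:
            centroid = tr.positions.mean(axis=0)
            v = int(np.argmin(np.linalg.norm(mesh.vertices - centroid, axis=1)))
            s0, s1 = tr.points[0].sample, tr.points[-1].sample
            if s1 > s0:
                seg = np.unwrap(phase.phase[v, s0 : s1 + 1])
                tr.rotations = float(abs(seg[-1] - seg[0]) / (2.0 * np.pi))
    return trajectories


def filter_rotors(
    trajectories: list[RotorTrajectory],
    min_rotations: float = 1.0,
) -> list[RotorTrajectory]:
    """Keep only long-lasting rotors: at least one completed rotation."""
    return [tr for tr in trajectories if tr.rotations >= min_rotations]


def rotor_biomarkers(rotors: list[RotorTrajectory], window_s: float) -> tuple[float, dict]:
    """Rotor summary biomarkers for one analysis window.

    Mean Rotor Time is the mean duration (s) of the rotors detected in the
    window; a window with no rotors contributes 0 s by convention. Extras
    report the rotor count, maximum duration and total rotor time.
    """
    durations = np.array([tr.duration_s for tr in rotors])
    mrt = float(durations.mean()) if durations.size else 0.0
    extras = {
        "rotor_count": float(len(rotors)),
        "max_rotor_time_s": float(durations.max()) if durations.size else 0.0,
        "total_rotor_time_s": float(durations.sum()) if durations.size else 0.0,
    }
    return mrt, extras


def rotor_histogram_map(rotors: list[RotorTrajectory], mesh: AtrialMesh) -> np.ndarray:
    """Per-vertex rotor dwell time (the rotor histogram map).

    Each trajectory segment's duration is split between the mesh vertices
    nearest its two endpoints, so the map's total mass equals the summed
    rotor durations exactly.
    """
    occupancy = np.zeros(mesh.n_vertices)
    tree = cKDTree(mesh.vertices)
    for tr in rotors:
        pts = tr.points
        for a, b in zip(pts[:-1], pts[1:]):
            dt = b.t - a.t
            _, va = tree.query(a.position)
            _, vb = tree.query(b.position)
            occupancy[int(va)] += dt / 2.0
            occupancy[int(vb)] += dt / 2.0
    return occupancy
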