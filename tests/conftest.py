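import numpy as np
import pytest

import afstrat as afs


@pytest.fixture(scope="session")
def disk_mesh():
    """~650-vertex disk, radius 4 cm, mean edge ~0.3 cm."""
    return afs.make_mesh("disk", 4.0, 0.3)


@pytest.fixture(scope="session")
def small_disk_mesh():
    """<=500-vertex disk for brute-force winding comparisons."""
    mesh = afs.make_mesh("disk", 4.0, 0.4)
    assert mesh.n_vertices <= 500
    return mesh


@pytest.fixture(scope="session")
def sphere_mesh():
    return afs.make_mesh("sphere", 3.0, 0.5)


@pytest.fixture(scope="session")
def spiral_field(disk_mesh):
    """Centred stationary counter-clockwise spiral at 6 Hz, 2 s @ 500 Hz."""
    truth = afs.WaveFieldTruth(frequency_hz=6.0, kind="spiral", chirality=+1,
                               core=[0.0, 0.0, 0.0])
    egms = afs.simulate_wavefield(disk_mesh, truth, 500.0, 2.0)
    return egms


@pytest.fixture(scope="session")
def planar_field(disk_mesh):
    truth = afs.WaveFieldTruth(frequency_hz=6.0, kind="planar")
    return afs.simulate_wavefield(disk_mesh, truth, 500.0, 2.0)


@pytest.fixture(scope="session")
def spiral_phase(spiral_field):
    return afs.hilbert_phase(spiral_field)


@pytest.fixture(scope="session")
def disk_detector(disk_mesh):
    return afs.SingularityDetector(disk_mesh)


@pytest.fixture(scope="session")
def default_cohort():
    return afs.generate_cohort(afs.CohortSpec(n=5000, seed=11))


def brute_force_singular_faces(mesh, phase_t):
    """Independent oracle: faces whose vertex phases wind by +/-2*pi.

    Sums wrapped phase differences around each triangle; a nonzero total
    (quantised to 2*pi multiples) marks a phase singularity inside the face.
    """
    windings = []
    for f in mesh.faces:
        total = 0.0
        for a, b in ((0, 1), (1, 2), (2, 0)):
            d = phase_t[f[b]] - phase_t[f[a]]
            total += np.angle(np.exp(1j * d))
        windings.append(int(np.rint(total / (2.0 * np.pi))))
    windings = np.asarray(windings)
    return np.flatnonzero(windings != 0), windings
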