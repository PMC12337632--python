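"""Synthetic ground-truth generators.

Every downstream stage (preprocessing, inversion, dominant-frequency maps,
rotor detection, scoring, stratification) is validated against data produced
here, where the truth — rotor core position and chirality, activation
frequency, forward operator, the outcome-generating score coefficients — is
known exactly.

Wavefields
----------
Three activation patterns are emulated on a mesh:

* ``spiral`` — per-vertex signal ``cos(2*pi*f*t + chi*theta(x; core) -
  2*pi*r/lambda)`` where ``theta`` is the polar angle about the (possibly
  drifting) core in the mesh tangent plane, ``chi`` the chirality and the
  Archimedean term ``2*pi*r/lambda`` makes the arm spiral outward. The phase
  field has exactly one singularity, at the core.
* ``planar`` — a travelling plane wave; spatially linear phase, no
  singularity anywhere.
* ``focal`` — radial propagation from a focus; circular isophase lines, no
  singularity (the winding number about the focus is zero).

Forward model
-------------
The torso stand-in is a homogeneous unbounded volume conductor: electrode
potentials are monopole potentials ``1/(4*pi*|e - s|)`` summed over sources
(unit conductivity). This keeps the operator analytic and exactly testable
while exhibiting the smoothing/ill-conditioning that makes the inverse
problem require regularization.

Cohorts
-------
Patient biomarkers are drawn from configurable ranges (MedianDF uniform,
HDF = MedianDF + exponential gap, MeanRotorTime uniform) and the 1-year
rhythm outcome is Bernoulli with success probability given by the logistic
ECGI complexity score, so score-calibration code can be checked by
parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mesh import AtrialMesh, fibonacci_sphere
from .signals import NodeSignalSet

__all__ = [
    "WaveFieldTruth",
    "TransferMatrix",
    "CohortSpec",
    "simulate_wavefield",
    "make_sphere_transfer",
    "forward_project",
    "generate_cohort",
    "inject_qrs",
    "COHORT_COLUMNS",
]

COHORT_COLUMNS = [
    "patient_id",
    "af_type",
    "treatment",
    "hdf",
    "median_df",
    "mean_rotor_time",
    "outcome_1y",
]


@dataclass
class WaveFieldTruth:
    """Ground truth for one simulated activation pattern.

    core_path : (n_samples, 3) core positions in cm (spiral/focal); for a
        stationary pattern every row is identical. Ignored for planar.
    frequency_hz : activation (rotation) frequency, > 0
    chirality : +1 counter-clockwise, -1 clockwise (spiral only)
    kind : "spiral" | "planar" | "focal"
    direction : unit propagation direction (planar only)
    wavelength_cm : spatial wavelength; defaults to the mesh diameter
    """

    frequency_hz: float
    kind: str = "spiral"
    chirality: int = +1
    core: np.ndarray | None = None
    core_path: np.ndarray | None = None
    direction: np.ndarray | None = None
    wavelength_cm: float | None = None

    def __post_init__(self) -> None:
        if self.frequency_hz <= 0:
            raise ValueError("frequency_hz must be positive")
        if self.kind not in ("spiral", "planar", "focal"):
            raise ValueError("kind must be spiral, planar or focal")
        if self.chirality not in (-1, +1):
            raise ValueError("chirality must be +1 or -1")
        if self.core is not None:
            self.core = np.asarray(self.core, dtype=float)


@dataclass
class TransferMatrix:
    """Electrode x source gain matrix (dimensionless) with geometries in cm."""

    entries: np.ndarray
    electrode_positions: np.ndarray
    source_positions: np.ndarray

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        if not np.all(np.isfinite(self.entries)):
            raise ValueError("transfer matrix entries must be finite")
        ne, ns = self.entries.shape
        if len(self.electrode_positions) != ne or len(self.source_positions) != ns:
            raise ValueError("geometry inconsistent with matrix shape")

    @property
    def n_electrodes(self) -> int:
        return self.entries.shape[0]

    @property
    def n_sources(self) -> int:
        return self.entries.shape[1]


def _resolve_core_path(truth: WaveFieldTruth, n_samples: int) -> np.ndarray:
    if truth.core_path is not None:
        cp = np.asarray(truth.core_path, dtype=float)
        if len(cp) != n_samples:
            # resample the requested path onto the sample grid
            t_in = np.linspace(0.0, 1.0, len(cp))
            t_out = np.linspace(0.0, 1.0, n_samples)
            cp = np.column_stack([np.interp(t_out, t_in, cp[:, k]) for k in range(cp.shape[1])])
        if cp.shape[1] == 2:
            cp = np.column_stack([cp, np.zeros(len(cp))])
        return cp
    core = truth.core if truth.core is not None else np.zeros(3)
    core = np.asarray(core, dtype=float)
    if core.size == 2:
        core = np.append(core, 0.0)
    return np.tile(core, (n_samples, 1))


def spatial_phase(
    mesh: AtrialMesh, truth: WaveFieldTruth, core: np.ndarray | None = None
) -> np.ndarray:
    """Time-independent spatial part of the activation phase at each vertex."""
    v = mesh.vertices
    lam = truth.wavelength_cm
    if lam is None:
        ext = v.max(axis=0) - v.min(axis=0)
        lam = float(np.linalg.norm(ext))
    if truth.kind == "planar":
        d = truth.direction if truth.direction is not None else np.array([1.0, 0.0, 0.0])
        d = np.asarray(d, dtype=float)
        d = d / np.linalg.norm(d)
        return -2.0 * np.pi * (v @ d) / lam
    if core is None:
        core = _resolve_core_path(truth, 1)[0]
    rel = v - core
    r = np.linalg.norm(rel, axis=1)
    if truth.kind == "focal":
        return -2.0 * np.pi * r / lam
    theta = np.arctan2(rel[:, 1], rel[:, 0])
    return truth.chirality * theta - 2.0 * np.pi * r / lam


def simulate_wavefield(
    mesh: AtrialMesh,
    truth: WaveFieldTruth,
    fs_hz: float,
    duration_s: float,
) -> NodeSignalSet:
    """Simulate per-vertex electrograms for a known activation pattern.

    Returns a NodeSignalSet (role ``icegm``) whose ``meta['truth']`` echoes
    the ground truth with the core path resolved samplewise.
    """
    if fs_hz < 100:
        raise ValueError("fs_hz must be >= 100 Hz")
    if duration_s < 1:
        raise ValueError("duration_s must be >= 1 s")
    n = int(round(fs_hz * duration_s))
    t = np.arange(n) / fs_hz
    v = mesh.vertices

    if truth.kind == "spiral":
        cp = _resolve_core_path(truth, n)
        lo, hi = v.min(axis=0), v.max(axis=0)
        if np.any(cp < lo - 1e-9) or np.any(cp > hi + 1e-9):
            raise ValueError("spiral core path leaves the mesh bounding box")
        drifting = not np.allclose(cp, cp[0])
        if drifting:
            samples = np.empty((mesh.n_vertices, n))
            for k in range(n):
                sp = spatial_phase(mesh, truth, core=cp[k])
                samples[:, k] = np.cos(2.0 * np.pi * truth.frequency_hz * t[k] + sp)
        else:
            sp = spatial_phase(mesh, truth, core=cp[0])
            samples = np.cos(2.0 * np.pi * truth.frequency_hz * t[None, :] + sp[:, None])
        truth.core_path = cp
    else:
        sp = spatial_phase(mesh, truth)
        samples = np.cos(2.0 * np.pi * truth.frequency_hz * t[None, :] + sp[:, None])
        if truth.kind == "focal":
            truth.core_path = _resolve_core_path(truth, n)

    return NodeSignalSet(
        samples=samples,
        fs_hz=fs_hz,
        role="icegm",
        channel_positions=v.copy(),
        meta={"truth": truth},
    )


def make_sphere_transfer(
    inner_r_cm: float,
    outer_r_cm: float,
    n_sources: int,
    n_electrodes: int,
    source_positions: np.ndarray | None = None,
    electrode_positions: np.ndarray | None = None,
) -> TransferMatrix:
    """Analytic transfer matrix for concentric spheres in a homogeneous conductor.

    Sources are current monopoles on (or within) the inner sphere, electrodes
    sit on the outer sphere; the closed form for the potential of a unit
    monopole at ``s`` observed at ``e`` in an unbounded homogeneous medium of
    unit conductivity is ``phi(e) = 1 / (4*pi*|e - s|)``. Rows are therefore
    exact evaluations of that kernel; no numerical quadrature is involved.
    """
    if not 0 < inner_r_cm < outer_r_cm:
        raise ValueError("need 0 < inner_r_cm < outer_r_cm")
    if source_positions is None:
        source_positions = fibonacci_sphere(n_sources, inner_r_cm)
    else:
        source_positions = np.asarray(source_positions, dtype=float)
    if electrode_positions is None:
        electrode_positions = fibonacci_sphere(n_electrodes, outer_r_cm)
    else:
        electrode_positions = np.asarray(electrode_positions, dtype=float)
    diff = electrode_positions[:, None, :] - source_positions[None, :, :]
    dist = np.linalg.norm(diff, axis=2)
    if np.any(dist < 1e-12):
        raise ValueError("coincident source and electrode positions")
    entries = 1.0 / (4.0 * np.pi * dist)
    return TransferMatrix(entries, electrode_positions, source_positions)


def forward_project(
    T: TransferMatrix,
    egms: NodeSignalSet,
    snr_db: float = np.inf,
    rng: np.random.Generator | int | None = None,
    noise_std: float | None = None,
) -> NodeSignalSet:
    """Project source electrograms to the body surface, adding white noise.

    ``Y = T X + N`` with ``N`` i.i.d. Gaussian scaled so the empirical SNR of
    the clean projection over the noise equals ``snr_db``; ``snr_db = inf``
    is noiseless. ``noise_std`` fixes the noise standard deviation directly
    instead (needed e.g. for zero input, where an SNR is undefined). The
    realised noise is stored in ``meta['noise']`` so tests can recompute the
    achieved SNR.
    """
    X = egms.samples
    if X.shape[0] != T.n_sources:
        raise ValueError(
            f"source count mismatch: signals have {X.shape[0]} channels, "
            f"transfer matrix expects {T.n_sources}"
        )
    Y = T.entries @ X
    meta = {"snr_db": float(snr_db)}
    if noise_std is not None or np.isfinite(snr_db):
        rng = np.random.default_rng(rng)
        if noise_std is not None:
            p_noise = float(noise_std) ** 2
        else:
            p_sig = float(np.mean(Y**2))
            p_noise = p_sig / 10.0 ** (snr_db / 10.0)
        noise = rng.normal(0.0, np.sqrt(p_noise), size=Y.shape)
        Y = Y + noise
        meta["noise"] = noise
        meta["noise_var"] = p_noise
    return NodeSignalSet(
        samples=Y,
        fs_hz=egms.fs_hz,
        role="surface",
        channel_positions=T.electrode_positions.copy(),
        meta=meta,
    )


# --- cohort generation -----------------------------------------------------

# Treatment mix follows the study population: 137/204 rhythm control (120 of
# them ablation, split between PVI alone and PVI plus driver ablation) and
# 67/204 rate control. AF-type mix over the 200 typed patients: 75 paroxysmal,
# 125 persistent.
_DEFAULT_TREATMENT_PROPS = {
    "ablation_pvi": 0.30,
    "ablation_pvi_drivers": 0.29,
    "pharma_rhythm": 0.08,
    "rate_control": 0.33,
}
_DEFAULT_AF_PROPS = {"paroxysmal": 0.375, "persistent": 0.625}


@dataclass
class CohortSpec:
    """Configuration of the synthetic patient cohort.

    Biomarker law: MedianDF ~ U(median_df_range); HDF = MedianDF +
    Exp(mean=hdf_gap_mean_hz); MeanRotorTime ~ U(mean_rotor_time_range), all
    mutually independent and, by default, independent of AF type and
    treatment. Ranges default to values spanning realistic AF activation
    rates (4-9 Hz) and producing scores on both sides of the 0.4/0.6
    stratification bins.
    """

    n: int
    seed: int = 0
    median_df_range_hz: tuple[float, float] = (4.0, 9.0)
    hdf_gap_mean_hz: float = 1.5
    mean_rotor_time_range_s: tuple[float, float] = (0.2, 3.0)
    af_type_props: dict = field(default_factory=lambda: dict(_DEFAULT_AF_PROPS))
    treatment_props: dict = field(default_factory=lambda: dict(_DEFAULT_TREATMENT_PROPS))

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        lo, hi = self.median_df_range_hz
        if not lo < hi:
            raise ValueError("median_df_range_hz must be increasing")
        if self.hdf_gap_mean_hz < 0:
            raise ValueError("hdf_gap_mean_hz must be >= 0")
        lo, hi = self.mean_rotor_time_range_s
        if lo < 0 or not lo < hi:
            raise ValueError("mean_rotor_time_range_s must be nonnegative increasing")
        for name, props in (("af_type", self.af_type_props), ("treatment", self.treatment_props)):
            total = sum(props.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} proportions sum to {total}, expected 1")


def generate_cohort(spec: CohortSpec, coefficients=None) -> pd.DataFrame:
    """Draw a synthetic cohort whose outcomes follow the logistic score.

    Parameters
    ----------
    spec : CohortSpec
    coefficients : ScoreCoefficients, defaults to the published values
        (-0.11, +0.40, -0.39, -0.04)

    Returns
    -------
    DataFrame with columns ``patient_id, af_type, treatment, hdf, median_df,
    mean_rotor_time, outcome_1y`` (outcome 1 = freedom from AF at 1 year)
    plus the generating probability in ``p_true``.
    """
    from .scoring import ScoreCoefficients, complexity_score

    if coefficients is None:
        coefficients = ScoreCoefficients()
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    median_df = rng.uniform(*spec.median_df_range_hz, size=n)
    gap = (
        rng.exponential(spec.hdf_gap_mean_hz, size=n)
        if spec.hdf_gap_mean_hz > 0
        else np.zeros(n)
    )
    hdf = median_df + gap
    mrt = rng.uniform(*spec.mean_rotor_time_range_s, size=n)
    p = complexity_score(
        {"hdf_hz": hdf, "median_df_hz": median_df, "mean_rotor_time_s": mrt}, coefficients
    )
    outcome = (rng.uniform(size=n) < p).astype(int)

    af_labels = list(spec.af_type_props)
    af = rng.choice(af_labels, size=n, p=[spec.af_type_props[k] for k in af_labels])
    tr_labels = list(spec.treatment_props)
    tr = rng.choice(tr_labels, size=n, p=[spec.treatment_props[k] for k in tr_labels])

    return pd.DataFrame(
        {
            "patient_id": [f"pt{i:06d}" for i in range(n)],
            "af_type": af,
            "treatment": tr,
            "hdf": hdf,
            "median_df": median_df,
            "mean_rotor_time": mrt,
            "outcome_1y": outcome,
            "p_true": p,
        }
    )


def qrs_template(fs_hz: float, width_s: float = 0.08) -> np.ndarray:
    """Biphasic QRS-like deflection (Mexican-hat) normalised to unit peak."""
    half = int(round(width_s * fs_hz / 2.0))
    t = np.arange(-half, half + 1) / fs_hz
    sigma = width_s / 6.0
    w = (1.0 - (t / sigma) ** 2) * np.exp(-(t**2) / (2.0 * sigma**2))
    return w / np.abs(w).max()


def inject_qrs(
    signal: NodeSignalSet,
    heart_rate_bpm: float,
    template_amplitude: float,
) -> tuple[NodeSignalSet, np.ndarray]:
    """Add a periodic ventricular (QRS) deflection to every channel.

    Returns the contaminated signal set and the ground-truth R-peak times in
    seconds, enabling exact validation of QRS-removal code.
    """
    if not 30 <= heart_rate_bpm <= 180:
        raise ValueError("heart_rate_bpm must lie in [30, 180]")
    fs = signal.fs_hz
    period_s = 60.0 / heart_rate_bpm
    peak_times = np.arange(period_s / 2.0, signal.duration_s, period_s)
    tmpl = template_amplitude * qrs_template(fs)
    half = (len(tmpl) - 1) // 2
    out = signal.samples.copy()
    for tp in peak_times:
        c = int(round(tp * fs))
        lo, hi = max(0, c - half), min(signal.n_samples, c + half + 1)
        out[:, lo:hi] += tmpl[lo - (c - half) : len(tmpl) - ((c + half + 1) - hi)]
    res = signal.copy_with(out)
    res.meta["r_peaks_s"] = peak_times
    res.meta["qrs_template"] = tmpl
    return res, peak_times
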