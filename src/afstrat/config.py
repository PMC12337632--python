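"""Pipeline configuration.

Defaults reproduce the study's stated analysis constants: 2-20 Hz band,
three analysis windows (>= 4 s for DF, 1 s for rotors), 0.01 Hz spectral
resolution, singularity linking below 1 cm (electrograms) / 5 cm (surface
ECG), a one-rotation minimum for rotors, the published score coefficients,
the 0.4 / 0.6 paroxysmal score bins and k = 5 neighbours.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # band filtering
    highpass_hz: float = 2.0
    lowpass_hz: float = 20.0
    filter_order: int = 4
    # window plan
    n_windows: int = 3
    df_window_s: float = 4.0
    rotor_window_s: float = 1.0
    # spectral analysis
    df_band_hz: tuple = (3.0, 15.0)
    df_resolution_hz: float = 0.01
    # singularity detection
    circle_radius_scales: tuple = (1.0, 2.0, 3.0)
    circle_points: tuple = (6, 9, 12)
    interp_weight: str = "inv_sq"
    # rotor tracking
    link_threshold_icegm_cm: float = 1.0
    link_threshold_ecg_cm: float = 5.0
    min_rotations: float = 1.0
    # score (published logistic coefficients)
    score_intercept: float = -0.11
    score_beta_hdf: float = 0.40
    score_beta_median_df: float = -0.39
    score_beta_mean_rotor_time: float = -0.04
    # stratification
    parox_score_cuts: tuple = (0.4, 0.6)
    persistent_score_cut: float = 0.5
    knn_k: int = 5
    test_fraction: float = 0.2
    # synthetic demo sizing
    cohort_n: int = 400
    n_signal_patients: int = 3
    signal_fs_hz: float = 500.0
    signal_duration_s: float = 20.0
    mesh_radius_cm: float = 4.0
    mesh_edge_cm: float = 0.45
    n_electrodes: int = 63
    snr_db: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.knn_k != 5:
            warnings.warn(
                f"k = {self.knn_k} differs from the published default k = 5",
                stacklevel=2,
            )
        if self.highpass_hz >= self.lowpass_hz:
            raise ValueError("highpass cutoff must be below lowpass cutoff")
        if self.df_resolution_hz > 0.01 + 1e-12:
            raise ValueError("DF resolution must be <= 0.01 Hz")

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    def config_hash(self) -> str:
        """Stable provenance hash of the effective configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            if path.suffix in (".yaml", ".yml"):
                yaml.safe_dump(self.to_dict(), fh)
            else:
                json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            data = yaml.safe_load(fh) if path.suffix in (".yaml", ".yml") else json.load(fh)
        for k in ("df_band_hz", "circle_radius_scales", "circle_points", "parox_score_cuts"):
            if k in data and isinstance(data[k], list):
                data[k] = tuple(data[k])
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
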