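"""Multichannel signal container and its HDF5 / CSV serialization.

One :class:`NodeSignalSet` holds either body-surface potentials (role
``"surface"``) or reconstructed atrial electrograms (role ``"icegm"``) as a
channels-by-samples matrix in mV with a single sampling rate.

On-disk layout (HDF5): dataset ``signals`` [channels x samples] with root
attributes ``fs_hz`` (float), ``role`` (str) and optional dataset
``channel_positions`` [channels x 3] in cm, plus dataset ``channel_ids``.
Transfer matrices live in the same container format under dataset
``transfer`` (see :mod:`afstrat.synthetic`).

CSV fallback: one row per channel; first column the channel id, remaining
columns the samples; fs_hz and role carried in a ``# fs_hz=...;role=...``
comment on the first line.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

__all__ = ["NodeSignalSet", "save_signals", "load_signals"]


@dataclass
class NodeSignalSet:
    """Per-node (electrode or mesh vertex) time series.

    Attributes
    ----------
    samples : (channels, time) float array, mV
    fs_hz : sampling rate, Hz
    role : "surface" for torso recordings, "icegm" for reconstructed atrial
        electrograms
    channel_positions : optional (channels, 3) array, cm
    meta : free-form provenance (e.g. the noise realisation added by the
        forward projector, ground-truth annotations)
    """

    samples: np.ndarray
    fs_hz: float
    role: str = "surface"
    channel_positions: np.ndarray | None = None
    channel_ids: list[str] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if self.role not in ("surface", "icegm"):
            raise ValueError("role must be 'surface' or 'icegm'")
        if self.channel_positions is not None:
            self.channel_positions = np.asarray(self.channel_positions, dtype=float)
            if len(self.channel_positions) != self.n_channels:
                raise ValueError("channel_positions length mismatch")
        if self.channel_ids is None:
            self.channel_ids = [f"ch{i:03d}" for i in range(self.n_channels)]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs_hz

    def copy_with(self, samples: np.ndarray, **kw) -> "NodeSignalSet":
        """New set sharing this one's metadata but holding new samples."""
        out = NodeSignalSet(
            samples=samples,
            fs_hz=kw.pop("fs_hz", self.fs_hz),
            role=kw.pop("role", self.role),
            channel_positions=kw.pop("channel_positions", self.channel_positions),
            channel_ids=kw.pop("channel_ids", list(self.channel_ids)),
            meta=kw.pop("meta", dict(self.meta)),
        )
        if kw:
            raise TypeError(f"unexpected keys {sorted(kw)}")
        return out


def save_signals(sigset: NodeSignalSet, path: str | Path) -> None:
    """Write a signal set to HDF5 (default) or CSV (``.csv`` extension)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        _save_csv(sigset, path)
        return
    with h5py.File(path, "w") as f:
        f.create_dataset("signals", data=sigset.samples)
        f.attrs["fs_hz"] = float(sigset.fs_hz)
        f.attrs["role"] = sigset.role
        f.create_dataset("channel_ids", data=np.array(sigset.channel_ids, dtype="S"))
        if sigset.channel_positions is not None:
            f.create_dataset("channel_positions", data=sigset.channel_positions)


def load_signals(path: str | Path) -> NodeSignalSet:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return _load_csv(path)
    with h5py.File(path, "r") as f:
        pos = f["channel_positions"][...] if "channel_positions" in f else None
        ids = [s.decode() for s in f["channel_ids"][...]] if "channel_ids" in f else None
        return NodeSignalSet(
            samples=f["signals"][...],
            fs_hz=float(f.attrs["fs_hz"]),
            role=str(f.attrs["role"]),
            channel_positions=pos,
            channel_ids=ids,
        )


def _save_csv(sigset: NodeSignalSet, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# fs_hz={sigset.fs_hz};role={sigset.role}\n")
        for cid, row in zip(sigset.channel_ids, sigset.samples):
            fh.write(cid + "," + ",".join(f"{v:.9g}" for v in row) + "\n")


def _load_csv(path: Path) -> NodeSignalSet:
    with open(path) as fh:
        header = fh.readline().strip().lstrip("# ")
        kv = dict(item.split("=", 1) for item in header.split(";"))
        ids, rows = [], []
        for line in fh:
            parts = line.rstrip("\n").split(",")
            ids.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    return NodeSignalSet(
        samples=np.asarray(rows), fs_hz=float(kv["fs_hz"]), role=kv["role"], channel_ids=ids
    )
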