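"""Recording and probe I/O, batch loading with boundary padding, and
Phy-compatible result output.

Recordings are flat binary files (row = time sample, column = channel,
C order) with int16 as the default sample type. Probe geometry lives in a
JSON/YAML companion file with per-channel ``x``/``y`` coordinates (um) and
a ``channel_map`` selecting/ordering the file columns that carry neural
data. All sample indexing is 0-based; geometry is in um; times are sample
indices until reporting boundaries.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = ["ProbeGeometry", "RecordingHandle", "PaddedBatch", "n_batches",
           "load_batch", "write_phy_output", "read_phy_output"]

_DTYPES = {"int16": np.int16, "uint16": np.uint16, "int32": np.int32,
           "float32": np.float32}


@dataclass
class ProbeGeometry:
    """Channel coordinates (um) and the map from file columns to channels."""

    x: np.ndarray
    y: np.ndarray
    channel_map: np.ndarray

    def __post_init__(self):
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        self.channel_map = np.asarray(self.channel_map, int)
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("probe coordinates must be finite")
        if len(self.x) != len(self.y) or len(self.x) != len(self.channel_map):
            raise ValueError("x, y and channel_map must have equal length")
        if self.n_channels < 1:
            raise ValueError("need at least one channel")
        if len(np.unique(self.channel_map)) != len(self.channel_map):
            raise ValueError("channel_map contains duplicates")

    @property
    def n_channels(self) -> int:
        return len(self.x)

    @property
    def positions(self) -> np.ndarray:
        """(n_channels, 2) array of (x, y)."""
        return np.column_stack([self.x, self.y])

    def nearest_channels(self, channel: int, n: int) -> np.ndarray:
        """Indices of the ``n`` nearest channels to ``channel`` (itself
        included), Euclidean distance in um, ties broken by channel index."""
        d = np.hypot(self.x - self.x[channel], self.y - self.y[channel])
        return np.argsort(d, kind="stable")[:min(n, self.n_channels)]

    def nearest_to_point(self, x: float, y: float, n: int) -> np.ndarray:
        d = np.hypot(self.x - x, self.y - y)
        return np.argsort(d, kind="stable")[:min(n, self.n_channels)]

    @classmethod
    def from_file(cls, path: str | Path) -> "ProbeGeometry":
        path = Path(path)
        with open(path) as fh:
            cfg = (json.load(fh) if path.suffix == ".json"
                   else yaml.safe_load(fh))
        return cls(np.asarray(cfg["x"], float), np.asarray(cfg["y"], float),
                   np.asarray(cfg["channel_map"], int))

    def to_file(self, path: str | Path) -> None:
        payload = {"x": self.x.tolist(), "y": self.y.tolist(),
                   "channel_map": self.channel_map.tolist()}
        path = Path(path)
        with open(path, "w") as fh:
            if path.suffix == ".json":
                json.dump(payload, fh)
            else:
                yaml.safe_dump(payload, fh)


@dataclass
class RecordingHandle:
    """A flat binary recording on disk plus its interpretation metadata."""

    path: Path
    dtype: str = "int16"
    n_channels_total: int = 0
    sampling_rate: float = 30000.0
    n_samples: int = field(default=0)

    def __post_init__(self):
        self.path = Path(self.path)
        if self.dtype not in _DTYPES:
            raise ValueError(f"unsupported dtype {self.dtype!r}; "
                             f"one of {sorted(_DTYPES)}")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        itemsize = np.dtype(_DTYPES[self.dtype]).itemsize
        nbytes = os.path.getsize(self.path)
        frame = itemsize * self.n_channels_total
        if nbytes % frame:
            raise ValueError(
                f"file {self.path} truncated mid-sample: {nbytes} bytes is "
                f"not a multiple of the {frame}-byte frame "
                f"(offset of last full frame: {nbytes - nbytes % frame})")
        inferred = nbytes // frame
        if self.n_samples == 0:
            self.n_samples = inferred
        elif self.n_samples != inferred:
            raise ValueError(f"n_samples={self.n_samples} inconsistent with "
                             f"file size ({inferred} samples)")

    def memmap(self) -> np.ndarray:
        return np.memmap(self.path, dtype=_DTYPES[self.dtype], mode="r",
                         shape=(self.n_samples, self.n_channels_total))


@dataclass
class PaddedBatch:
    """One window of float samples with n_t padding on each side.

    ``data`` has shape (n_channels, N_T + 2 * n_t); the payload occupies
    columns [n_t, n_t + N_T).
    """

    data: np.ndarray
    batch_index: int
    N_T: int
    n_t: int
    start_sample: int = 0     # absolute sample index of payload column 0

    def __post_init__(self):
        if self.n_t < 1:
            raise ValueError("n_t must be >= 1")
        if self.data.shape[1] != self.N_T + 2 * self.n_t:
            raise ValueError("padded length must be N_T + 2*n_t")

    @property
    def payload(self) -> np.ndarray:
        return self.data[:, self.n_t:self.n_t + self.N_T]


def n_batches(rec: RecordingHandle, N_T: int = 60000) -> int:
    return int(np.ceil(rec.n_samples / N_T))


def load_batch(rec: RecordingHandle, geom: ProbeGeometry, batch_index: int,
               N_T: int = 60000, n_t: int = 61,
               gain: float = 1.0) -> PaddedBatch:
    """Load one channel-mapped batch as float with n_t-sample edge pads.

    The first batch's left pad repeats the first sample; a short final
    batch is extended to the full N_T (and its right pad filled) by
    repeating the last value; interior pads are true neighboring data.
    """
    nb = n_batches(rec, N_T)
    if not 0 <= batch_index < nb:
        raise IndexError(f"batch_index {batch_index} out of range [0, {nb})")
    mm = rec.memmap()
    start = batch_index * N_T
    lo = start - n_t
    hi = start + N_T + n_t
    a = max(lo, 0)
    b = min(hi, rec.n_samples)
    chunk = np.asarray(mm[a:b, :], dtype=np.float32).T  # (chan_total, T)
    chunk = chunk[geom.channel_map, :]
    if gain != 1.0:
        chunk = chunk * gain
    out = np.empty((geom.n_channels, N_T + 2 * n_t), np.float32)
    left = a - lo            # columns to fill by repeating first sample
    right = hi - b           # columns to fill by repeating last sample
    out[:, left:left + chunk.shape[1]] = chunk
    if left:
        out[:, :left] = chunk[:, :1]
    if right:
        out[:, left + chunk.shape[1]:] = chunk[:, -1:]
    return PaddedBatch(out, batch_index, N_T, n_t, start_sample=start)


def write_phy_output(out_dir: str | Path, spike_times: np.ndarray,
                     spike_clusters: np.ndarray, amplitudes: np.ndarray,
                     templates: np.ndarray, geom: ProbeGeometry,
                     cluster_groups: dict[int, str] | None = None) -> dict:
    """Write the minimal Phy-compatible result set; returns a manifest.

    Arrays: spike_times (samples, int64), spike_clusters (int32),
    amplitudes (float32), templates (n_templates, n_t, n_channels),
    channel_positions; plus cluster_group.tsv with group in {good, mua}.
    """
    spike_times = np.asarray(spike_times)
    spike_clusters = np.asarray(spike_clusters)
    amplitudes = np.asarray(amplitudes, np.float32)
    if np.any(np.diff(spike_times) < 0):
        raise ValueError("spike_times must be sorted")
    if not np.isfinite(amplitudes).all():
        raise ValueError("amplitudes contain non-finite values")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = {
        "spike_times.npy": spike_times.astype(np.int64),
        "spike_clusters.npy": spike_clusters.astype(np.int32),
        "amplitudes.npy": amplitudes,
        "templates.npy": np.asarray(templates, np.float32),
        "channel_positions.npy": geom.positions.astype(np.float64),
        "channel_map.npy": geom.channel_map.astype(np.int32),
    }
    for name, arr in files.items():
        np.save(out_dir / name, arr)
    if cluster_groups is None:
        cluster_groups = {}
    with open(out_dir / "cluster_group.tsv", "w") as fh:
        fh.write("cluster_id\tgroup\n")
        for cid in sorted(cluster_groups):
            fh.write(f"{cid}\t{cluster_groups[cid]}\n")
    return {"dir": str(out_dir), "files": sorted(files) +
            ["cluster_group.tsv"], "n_spikes": int(len(spike_times)),
            "n_templates": int(len(templates))}


def read_phy_output(out_dir: str | Path) -> dict:
    """Read back what :func:`write_phy_output` wrote (lossless)."""
    out_dir = Path(out_dir)
    out = {name[:-4]: np.load(out_dir / name)
           for name in ["spike_times.npy", "spike_clusters.npy",
                        "amplitudes.npy", "templates.npy",
                        "channel_positions.npy", "channel_map.npy"]}
    groups = {}
    with open(out_dir / "cluster_group.tsv") as fh:
        next(fh)
        for line in fh:
            cid, grp = line.split()
            groups[int(cid)] = grp
    out["cluster_groups"] = groups
    return out
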