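"""Drifting-recording simulator with ground truth.

Renders synthetic extracellular recordings in the sorter's native flat
binary format: a bank of depth-dependent waveforms (one per unit,
sampled every 2 um over a 40-um span and kriging-upsampled x100 in
depth), spike trains with realistic interspike-interval statistics,
vertical drift from one of the five profile families, band-limited
noise, spatial 'unwhitening' through a channel-correlation matrix, and
int16 quantization at a fixed gain.

The waveform bank, ISI library and channel-correlation matrix shipped
here are synthetic, parametric stand-ins with matched statistics
(biphasic shapes with 0.2-1 ms trough-to-peak, Gaussian spatial
footprints of 20-60 um s.d., gamma ISIs with a 12.6-Hz mean rate target
and a refractory floor, an AR(1)-in-space correlation matrix); all bank
processing (top-3 PC denoising across depths, average-norm
normalization, the 0.25 depth-variation filter, kriging upsampling)
runs on them unchanged and accepts a user-supplied bank.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal

from .drift_profiles import DriftProfile, generate_drift
from .io import ProbeGeometry, RecordingHandle

__all__ = ["WaveformBank", "GroundTruth", "make_probe",
           "generate_waveform_bank", "generate_spike_trains",
           "render_recording", "hybrid_insert", "kriging_upsample",
           "depth_variation", "generate_drift", "DriftProfile"]

DEPTHS_UM = np.linspace(-20.0, 20.0, 21)     # 2-um sampling over 40 um
UPSAMPLE = 100
KRIG_SIGMA = 20.0
KRIG_LAMBDA = 0.01
VARIATION_MAX = 0.25
NOISE_SD = 0.76
RENDER_GAIN = 200.0
SINGLE_NORM_BASE = 10.0
SINGLE_NORM_EXP_MEAN = 7.0
MULTI_NORM_RANGE = (4.0, 10.0)
MEAN_RATE_HZ = 12.6
_LIBRARY_SEED = 12345          # packaged synthetic ISI library


def make_probe(n_channels: int, v_pitch: float = 20.0,
               h_pitch: float = 32.0, stagger: float = 16.0,
               n_columns: int = 2) -> ProbeGeometry:
    """Staggered multi-column probe layout (Neuropixels1-like defaults:
    rows of two, 20-um vertical spacing, 32-um horizontal spacing,
    16-um horizontal offset between consecutive rows)."""
    rows = int(np.ceil(n_channels / n_columns))
    x = np.empty(n_channels)
    y = np.empty(n_channels)
    for i in range(n_channels):
        r, c = divmod(i, n_columns)
        x[i] = c * h_pitch + (stagger if r % 2 else 0.0)
        y[i] = r * v_pitch
    return ProbeGeometry(x, y, np.arange(n_channels))


def kriging_upsample(waves: np.ndarray, depths: np.ndarray,
                     fine_depths: np.ndarray, sigma: float = KRIG_SIGMA,
                     lam: float = KRIG_LAMBDA) -> np.ndarray:
    """Gaussian-kriging interpolation of depth-sampled waveforms.

    ``waves`` is (n_depths, ...); returns (len(fine_depths), ...).
    """
    shp = waves.shape[1:]
    W = waves.reshape(len(depths), -1)
    d2 = (depths[:, None] - depths[None, :]) ** 2
    Kdd = np.exp(-0.5 * d2 / sigma ** 2)
    Kfd = np.exp(-0.5 * (fine_depths[:, None] - depths[None, :]) ** 2
                 / sigma ** 2)
    A = np.linalg.solve(Kdd + lam * np.eye(len(depths)), W)
    return (Kfd @ A).reshape((len(fine_depths),) + shp)


def _shift_channels(w: np.ndarray, geom: ProbeGeometry,
                    dy: float) -> np.ndarray:
    """Move a (n_chan, n_t) waveform to channels ``dy`` um higher
    (same x); channels with no source are zeroed."""
    out = np.zeros_like(w)
    for c in range(geom.n_channels):
        src = np.flatnonzero((np.abs(geom.x - geom.x[c]) < 1e-6) &
                             (np.abs(geom.y - (geom.y[c] - dy)) < 1e-6))
        if len(src):
            out[c] = w[src[0]]
    return out


def depth_variation(waves: np.ndarray, geom: ProbeGeometry,
                    span: float = 40.0) -> float:
    """Shape change across depth: Euclidean distance between the waveform
    at the lowest depth and the highest-depth waveform shifted back by
    the full span. Pure translation scores ~0."""
    shifted = _shift_channels(waves[-1], geom, -span)
    return float(np.linalg.norm(waves[0] - shifted))


@dataclass
class WaveformBank:
    """Per-unit waveforms across depth, kriging-upsampled.

    ``fine`` holds (n_fine_depths, n_chan, n_t) float32 per unit;
    ``fine_depths`` maps the first axis to um of unit displacement.
    """

    fine: list[np.ndarray]
    fine_depths: np.ndarray
    base_y: np.ndarray          # nominal unit depth on the probe, um
    base_x: np.ndarray
    unit_class: list[str]       # 'single' | 'multi'
    variation: np.ndarray
    n_t: int = 61

    @property
    def n_units(self) -> int:
        return len(self.fine)

    def waveform_at(self, unit: int, drift_um: float) -> np.ndarray:
        i = int(np.clip(round((drift_um - self.fine_depths[0]) /
                              (self.fine_depths[1] - self.fine_depths[0])),
                        0, len(self.fine_depths) - 1))
        return self.fine[unit][i]


def _interior_sites(geom: ProbeGeometry) -> np.ndarray:
    """Candidate soma sites away from the probe edges; the margin scales
    down with the probe so short test probes keep multiple rows."""
    span = geom.y.max() - geom.y.min()
    margin = 40.0 if span > 400 else 20.0
    sites = np.flatnonzero((geom.y >= geom.y.min() + margin) &
                           (geom.y <= geom.y.max() - margin))
    return sites if len(sites) else np.arange(geom.n_channels)


def _parametric_unit(rng: np.random.Generator, geom: ProbeGeometry,
                     fs: float, n_t: int, morph: float,
                     sigma_range: tuple[float, float] = (20.0, 60.0),
                     c0: int | None = None
                     ) -> tuple[np.ndarray, float, float]:
    """Raw depth-sampled waveforms for one synthetic unit."""
    if c0 is None:
        c0 = int(rng.choice(_interior_sites(geom)))
    x0, y0 = geom.x[c0], geom.y[c0]
    t2p_ms = rng.uniform(0.2, 1.0)               # trough-to-peak time
    t2p = t2p_ms * 1e-3 * fs
    width = rng.uniform(2.0, 5.0)                # sharp trough, samples
    repol = rng.uniform(0.25, 0.6)
    sigma_s = rng.uniform(*sigma_range)
    ecc = rng.uniform(0.6, 1.4)                  # footprint ellipticity
    # action-potential propagation along the probe axis: per-channel
    # temporal lag proportional to vertical distance from the soma
    prop = rng.uniform(0.02, 0.08) * rng.choice([-1.0, 1.0])  # samples/um
    t = np.arange(n_t) - n_t // 2

    def shape_at(tau, wd):
        s = -np.exp(-0.5 * (tau / wd) ** 2) \
            + repol * np.exp(-0.5 * ((tau - t2p) /
                                     (0.45 * t2p + 1.0)) ** 2)
        return s - s.mean()

    waves = np.empty((len(DEPTHS_UM), geom.n_channels, n_t))
    for di, d in enumerate(DEPTHS_UM):
        wd = width * (1.0 + morph * d / 20.0)
        dy = geom.y - (y0 + d)
        amp = np.exp(-0.5 * ((geom.x - x0) ** 2 / (ecc * sigma_s) ** 2 +
                             dy ** 2 / sigma_s ** 2))
        for c in range(geom.n_channels):
            waves[di, c] = amp[c] * shape_at(t - prop * dy[c], wd)
    return waves, x0, y0


def generate_waveform_bank(n_units: int, geom: ProbeGeometry,
                           seed: int | np.random.Generator = 0,
                           fs: float = 30000.0, n_t: int = 61,
                           n_multi: int = 0, morph_sd: float = 0.05,
                           sigma_range: tuple[float, float] = (20.0, 60.0)
                           ) -> WaveformBank:
    """Synthetic waveform bank with the full processing chain applied.

    Each unit gets waveforms at 2-um depth steps over 40 um, denoised by
    reconstruction from the top three PCs across depths, normalized by
    the average norm over depths, filtered at a depth-variation score of
    0.25, and kriging-upsampled x100 in depth (sigma 20 um, lambda
    0.01). Units are placed away from the probe edges; the best-channel
    parity is preserved implicitly by centering on real sites.
    """
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    fine_depths = np.arange(DEPTHS_UM[0], DEPTHS_UM[-1] + 1e-9,
                            (DEPTHS_UM[1] - DEPTHS_UM[0]) / UPSAMPLE)
    fine, bx, by, classes, variations = [], [], [], [], []
    total = n_units + n_multi
    # spread somata over distinct interior sites while possible, so a
    # short probe does not stack many units on the same row
    sites = _interior_sites(geom)
    site_order = list(rng.permutation(sites))
    attempts = 0
    while len(fine) < total and attempts < 20 * total:
        attempts += 1
        is_multi = len(fine) >= n_units
        morph = abs(rng.normal(0, morph_sd))
        c0 = int(site_order.pop(0)) if site_order else None
        waves, x0, y0 = _parametric_unit(rng, geom, fs, n_t, morph,
                                         sigma_range, c0)
        # top-3 PC denoising across depths
        flat = waves.reshape(len(DEPTHS_UM), -1)
        mu = flat.mean(0)
        U, S, Vt = np.linalg.svd(flat - mu, full_matrices=False)
        flat = mu + (U[:, :3] * S[:3]) @ Vt[:3]
        waves = flat.reshape(waves.shape)
        norms = np.linalg.norm(flat, axis=1)
        waves = waves / norms.mean()
        var = depth_variation(waves, geom)
        if var > VARIATION_MAX:
            continue
        up = kriging_upsample(waves, DEPTHS_UM, fine_depths)
        up /= np.linalg.norm(up.reshape(len(up), -1), axis=1).mean()
        fine.append(up.astype(np.float32))
        bx.append(x0)
        by.append(y0)
        classes.append("multi" if is_multi else "single")
        variations.append(var)
    if len(fine) < total:
        raise ValueError("all candidate units exceeded the depth-variation "
                         "filter; lower the morphing perturbation")
    return WaveformBank(fine, fine_depths, np.array(by), np.array(bx),
                        classes, np.array(variations), n_t)


def _isi_library(n_sets: int = 64, n_isis: int = 2000) -> list[np.ndarray]:
    """Packaged synthetic reference ISI sets: gamma-distributed intervals
    with a refractory floor, rates targeting a 12.6-Hz mean."""
    rng = np.random.default_rng(_LIBRARY_SEED)
    sets = []
    mu = np.log(MEAN_RATE_HZ) - 0.125         # lognormal(mean 12.6 Hz)
    for _ in range(n_sets):
        rate = float(np.exp(rng.normal(mu, 0.5)))
        rate = min(max(rate, 0.5), 30.0)
        mean_isi = 1.0 / rate
        floor = 0.0025
        scale = max(mean_isi - floor, 1e-4) / 2.0
        isis = floor + rng.gamma(2.0, scale, n_isis)
        sets.append(isis)
    return sets


@dataclass
class GroundTruth:
    """Per-unit spike trains (samples), norms and metadata."""

    spike_samples: list[np.ndarray]
    norms: np.ndarray
    unit_class: list[str]
    base_y: np.ndarray
    base_x: np.ndarray
    fs: float
    meta: dict = field(default_factory=dict)

    @property
    def n_units(self) -> int:
        return len(self.spike_samples)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "fs": self.fs,
            "norms": self.norms.tolist(),
            "unit_class": self.unit_class,
            "base_y": self.base_y.tolist(),
            "base_x": self.base_x.tolist(),
            "spike_samples": [s.tolist() for s in self.spike_samples],
            "meta": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                     for k, v in self.meta.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            p = json.load(fh)
        return cls([np.asarray(s, np.int64) for s in p["spike_samples"]],
                   np.asarray(p["norms"]), p["unit_class"],
                   np.asarray(p["base_y"]), np.asarray(p["base_x"]),
                   p["fs"], p.get("meta", {}))


def generate_spike_trains(bank: WaveformBank, duration: float,
                          seed: int | np.random.Generator = 0,
                          fs: float = 30000.0,
                          min_single_norm: float | None = None
                          ) -> GroundTruth:
    """Spike trains and norms for every unit of the bank.

    Single units shuffle the ISIs of a randomly chosen reference set
    (preserving the ISI multiset); multi-units are Poisson with rates
    drawn from the reference rate distribution. Norms: single = 10 +
    Exp(mean 7), optionally rejection-conditioned on a minimum; multi =
    Uniform(4, 10).
    """
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    library = _isi_library()
    trains, norms = [], []
    for u in range(bank.n_units):
        if bank.unit_class[u] == "single":
            isis = library[int(rng.integers(len(library)))].copy()
            rng.shuffle(isis)
            need = duration / isis.mean() + 10
            reps = int(np.ceil(need / len(isis)))
            if reps > 1:
                isis = np.tile(isis, reps)
            t = np.cumsum(isis)
            t = t[t < duration]
            nrm = SINGLE_NORM_BASE + rng.exponential(SINGLE_NORM_EXP_MEAN)
            while min_single_norm is not None and nrm < min_single_norm:
                nrm = SINGLE_NORM_BASE + rng.exponential(SINGLE_NORM_EXP_MEAN)
        else:
            lib_rates = [1.0 / s.mean() for s in library]
            rate = float(rng.choice(lib_rates))
            n_exp = rng.poisson(rate * duration)
            t = np.sort(rng.uniform(0, duration, n_exp))
            nrm = float(rng.uniform(*MULTI_NORM_RANGE))
        if len(t) < 2:
            warnings.warn(f"unit {u}: fewer than 2 spikes in {duration} s; "
                          "skipped")
            t = np.empty(0)
        trains.append(np.round(t * fs).astype(np.int64))
        norms.append(nrm)
    return GroundTruth(trains, np.array(norms), list(bank.unit_class),
                       bank.base_y.copy(), bank.base_x.copy(), fs)


def spatial_correlation_matrix(n_channels: int, rho: float = 0.25
                               ) -> np.ndarray:
    """Synthetic AR(1)-in-space channel correlation matrix.

    The default correlation is modest: ZCA whitening divides spatially
    smooth patterns by roughly sqrt((1+rho)/(1-rho)), and spike
    footprints are smooth, so a strong synthetic correlation would
    suppress spike norms relative to the noise far more than the real
    recordings this matrix stands in for."""
    idx = np.arange(n_channels)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def _matrix_sqrt(C: np.ndarray) -> np.ndarray:
    S, U = np.linalg.eigh(C)
    return U @ np.diag(np.sqrt(np.maximum(S, 0))) @ U.T


def render_recording(bank: WaveformBank, truth: GroundTruth,
                     profile: DriftProfile, geom: ProbeGeometry,
                     out_path: str | Path,
                     seed: int | np.random.Generator = 0,
                     noise_sd: float = NOISE_SD, gain: float = RENDER_GAIN,
                     unwhiten: bool = True, chunk_s: float = 30.0
                     ) -> RecordingHandle:
    """Render an int16 flat binary recording plus its truth sidecar.

    Each spike adds the unit's waveform at the depth given by the drift
    profile at that time and the unit's probe position, scaled by the
    unit norm. Per-channel noise is white noise low-pass filtered at
    300 Hz and rescaled to the target s.d.; the frame is then multiplied
    by the square root of a synthetic channel-correlation matrix
    ('unwhitening'), scaled by 200, clipped at +-32767 and written as
    int16 (row = sample, C order). Rendering is chunked and exact under
    spike collisions (pure summation).
    """
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    fs = truth.fs
    out_path = Path(out_path)
    n_t = bank.n_t
    half = n_t // 2
    n_samples = int(round(profile.duration * fs))
    C = geom.n_channels
    corr = spatial_correlation_matrix(C) if unwhiten else np.eye(C)
    unwhiten_mat = _matrix_sqrt(corr)
    # per-unit drift lookup at spike times
    unit_events: list[tuple[int, int, float]] = []   # (sample, unit, drift)
    for u in range(truth.n_units):
        tt = truth.spike_samples[u]
        if len(tt) == 0:
            continue
        d = profile.at(tt / fs, np.full(len(tt), truth.base_y[u]))
        for s, dd in zip(tt, d):
            unit_events.append((int(s), u, float(dd)))
    unit_events.sort()
    ev_samples = np.array([e[0] for e in unit_events], np.int64)
    chunk_len = int(chunk_s * fs)
    carry = np.zeros((n_t, C), np.float32)
    try:
        with open(out_path, "wb") as fh:
            for start in range(0, n_samples, chunk_len):
                end = min(start + chunk_len, n_samples)
                buf = np.zeros((end - start + n_t, C), np.float32)
                buf[:n_t] += carry
                i0 = np.searchsorted(ev_samples, start + half)
                i1 = np.searchsorted(ev_samples, end + half)
                for idx in range(i0, i1):
                    s, u, dd = unit_events[idx]
                    w0 = s - half - start      # window start within chunk
                    wave = bank.waveform_at(u, dd) * truth.norms[u]
                    buf[w0:w0 + n_t] += wave.T
                carry = buf[end - start:].copy()
                frame = buf[:end - start]
                if noise_sd > 0:
                    frame = frame + noise_sd * rng.standard_normal(
                        (end - start, C))
                frame = frame @ unwhiten_mat.T
                np.clip(frame * gain, -32767, 32767, out=frame)
                fh.write(frame.astype(np.int16).tobytes())
    except OSError:
        out_path.unlink(missing_ok=True)
        raise
    truth.meta.update({"noise_sd": noise_sd, "gain": gain,
                       "unwhiten_matrix": unwhiten_mat,
                       "drift_kind": profile.kind})
    truth.to_json(out_path.with_suffix(".truth.json"))
    geom.to_file(out_path.with_suffix(".probe.json"))
    with open(out_path.with_suffix(".meta"), "w") as fh:
        fh.write(f"nSavedChans={C}\nimSampRate={fs}\nfileSizeBytes="
                 f"{out_path.stat().st_size}\n")
    return RecordingHandle(out_path, "int16", C, fs)


def hybrid_insert(rec: RecordingHandle, geom: ProbeGeometry,
                  sorted_units: list[dict], out_path: str | Path,
                  seed: int | np.random.Generator = 0,
                  n_insert: int = 100, site_offset: int = 8,
                  mean_isi: float = 0.5, min_isi: float = 0.002
                  ) -> tuple[RecordingHandle, GroundTruth]:
    """Insert known units back into a real recording at offset sites.

    ``sorted_units`` need ``times`` (samples), ``waveform`` (n_chan x
    n_t, raw recording units), ``best_channel`` and ``contamination``.
    Units with contamination < 0.1 are eligible; each chosen unit's mean
    waveform is re-inserted 8 sites above or below its original
    position, with exponential ISIs (mean ~500 ms) modulated by the
    local firing rate (100-ms bins, smoothed across channels with a
    10-channel-s.d. Gaussian, normalized to mean 1) and a 2-ms floor.
    """
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    fs = rec.sampling_rate
    eligible = [u for u in sorted_units if u.get("contamination", 1.0) < 0.1]
    if len(eligible) < n_insert:
        warnings.warn(f"only {len(eligible)} units with contamination < 0.1; "
                      "using all")
    chosen = list(rng.permutation(len(eligible))[:n_insert])
    duration = rec.n_samples / fs
    # local firing-rate modulation per channel, 100-ms bins
    n_bins = max(1, int(np.ceil(duration / 0.1)))
    rate = np.zeros((n_bins, geom.n_channels))
    for u in sorted_units:
        b = np.minimum((np.asarray(u["times"]) / fs / 0.1).astype(int),
                       n_bins - 1)
        np.add.at(rate[:, u["best_channel"]], b, 1.0)
    from scipy.ndimage import gaussian_filter1d
    rate = gaussian_filter1d(rate, 10.0, axis=1)
    rate /= np.maximum(rate.mean(axis=0, keepdims=True), 1e-12)
    data = np.array(rec.memmap(), np.float32)
    trains, norms, ys, xs, classes = [], [], [], [], []
    n_t = eligible[0]["waveform"].shape[1] if eligible else 61
    half = n_t // 2
    for ui in chosen:
        u = eligible[ui]
        off = site_offset if rng.random() < 0.5 else -site_offset
        src = u["best_channel"]
        dst = int(np.clip(src + off, 0, geom.n_channels - 1))
        shift = dst - src
        w = np.zeros_like(u["waveform"])
        if shift >= 0:
            w[shift:] = u["waveform"][:len(w) - shift]
        else:
            w[:shift] = u["waveform"][-shift:]
        # modulated exponential ISIs
        t, times = 0.0, []
        ch = dst
        while True:
            b = min(int(t / 0.1), n_bins - 1)
            # modulation is floored: an empty 100-ms bin slows the
            # train instead of silencing it outright
            isi = max(min_isi, rng.exponential(mean_isi) /
                      max(rate[b, ch], 0.1))
            t += isi
            if t >= duration:
                break
            times.append(t)
        samp = np.round(np.array(times) * fs).astype(np.int64)
        samp = samp[(samp >= half) & (samp < rec.n_samples - half)]
        for s in samp:
            data[s - half:s - half + n_t] += w.T
        trains.append(samp)
        norms.append(float(np.linalg.norm(w)))
        ys.append(float(geom.y[dst]))
        xs.append(float(geom.x[dst]))
        classes.append("single")
    out_path = Path(out_path)
    with open(out_path, "wb") as fh:
        fh.write(np.clip(data, -32767, 32767).astype(np.int16).tobytes())
    truth = GroundTruth(trains, np.array(norms), classes, np.array(ys),
                        np.array(xs), fs, {"hybrid": True})
    truth.to_json(out_path.with_suffix(".truth.json"))
    return RecordingHandle(out_path, "int16", rec.n_channels_total, fs), truth
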