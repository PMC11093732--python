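"""Drift estimation from universal-template detections and the
interpolation operators that correct it.

Vertical probe motion is estimated in advance, in 2-s bins, from spikes
detected with the simple template bank (pairs of inverted templates
catch both polarities). Each time bin's depth x amplitude histogram of
detections is registered to a reference histogram (the element-wise
median across bins) by maximizing cross-correlation over vertical
shifts, giving a rigid trace; optional per-depth-block refinement gives
a nonrigid trace. Estimated shifts are interpolated linearly to every
channel, and data alignment is a Gaussian-kriging interpolation that is
folded into the whitening matrix multiplication.

Sign convention: a positive drift value means units appear displaced
upward (toward larger y) along the probe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import PaddedBatch, ProbeGeometry
from .templates import SimpleTemplateBank, detect_with_simple_templates

__all__ = ["DriftTrace", "detect_spikes_universal", "estimate_drift",
           "drift_to_channels", "build_shift_matrix"]

DEPTH_BIN_UM = 5.0
N_AMP_BINS = 20
KRIGING_SIGMA_UM = 20.0
KRIGING_LAMBDA = 0.01
MIN_SPIKES_PER_BIN = 10


@dataclass
class DriftTrace:
    """Estimated motion: (n_time_bins, n_blocks) um, 2-s bins."""

    values: np.ndarray
    bin_size: float                 # seconds
    block_centers: np.ndarray       # (n_blocks,) um
    flagged: np.ndarray | None = None   # bins that inherited a neighbor

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def n_blocks(self) -> int:
        return self.values.shape[1]


def detect_spikes_universal(batch: PaddedBatch, bank: SimpleTemplateBank,
                            geom: ProbeGeometry,
                            threshold: float = 9.0) -> dict:
    """Detect spikes of both polarities for drift estimation.

    Thin wrapper over the simple-template detector, which already scores
    each template and its sign-inverted pair through the squared dot
    product. Returns times (samples), depths (um) and amplitudes.
    """
    det = detect_with_simple_templates(batch, bank, geom, threshold)
    return {"time": det["time"], "depth": det["xy"][:, 1],
            "amplitude": np.abs(det["amplitude"])}


def _registration_shift(hist: np.ndarray, ref: np.ndarray,
                        max_shift_bins: int) -> float:
    """Vertical shift (in depth bins, sub-bin refined) maximizing the
    correlation of ``hist`` with ``ref``. Positive = ``hist`` displaced
    upward relative to ``ref``."""
    shifts = np.arange(-max_shift_bins, max_shift_bins + 1)
    cc = np.empty(len(shifts))
    for i, s in enumerate(shifts):
        rolled = np.roll(hist, -s, axis=0)
        if s > 0:
            rolled[-s:] = 0
        elif s < 0:
            rolled[:-s] = 0
        cc[i] = float((rolled * ref).sum())
    b = int(np.argmax(cc))
    # parabolic sub-bin refinement
    if 0 < b < len(shifts) - 1:
        y0, y1, y2 = cc[b - 1], cc[b], cc[b + 1]
        denom = y0 - 2 * y1 + y2
        frac = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        return float(shifts[b] + np.clip(frac, -0.5, 0.5))
    return float(shifts[b])


def estimate_drift(spikes: dict, fs: float, probe_y_range: tuple[float,
                   float], bin_size: float = 2.0, n_blocks: int = 1,
                   max_shift_um: float = 50.0,
                   smooth_s: float = 10.0) -> DriftTrace:
    """Registration of per-bin depth/amplitude histograms.

    ``spikes`` holds ``time`` (samples), ``depth`` (um) and ``amplitude``
    arrays pooled over the recording. Depth bins are 5 um; amplitudes are
    histogrammed in ~20 log-spaced bins. Each 2-s time bin is registered
    rigidly against the median histogram; with ``n_blocks`` > 1 each
    depth block is then refined locally. Bins with too few spikes
    inherit the nearest estimated neighbor and are flagged.
    """
    t = np.asarray(spikes["time"], float) / fs
    depth = np.asarray(spikes["depth"], float)
    amp = np.asarray(spikes["amplitude"], float)
    if len(t) == 0 or t.max() < bin_size:
        raise ValueError("spikes must span at least two time bins")
    y0, y1 = probe_y_range
    dedges = np.arange(y0 - max_shift_um, y1 + max_shift_um + DEPTH_BIN_UM,
                       DEPTH_BIN_UM)
    aedges = np.logspace(np.log10(max(amp.min(), 1e-6)),
                         np.log10(amp.max() + 1e-6), N_AMP_BINS + 1)
    n_bins = int(np.ceil((t.max() + 1e-9) / bin_size))
    tb = np.minimum((t / bin_size).astype(int), n_bins - 1)
    H = np.zeros((n_bins, len(dedges) - 1, N_AMP_BINS))
    di = np.clip(np.searchsorted(dedges, depth) - 1, 0, len(dedges) - 2)
    ai = np.clip(np.searchsorted(aedges, amp) - 1, 0, N_AMP_BINS - 1)
    np.add.at(H, (tb, di, ai), 1.0)
    counts = H.sum(axis=(1, 2))
    ref = np.median(H, axis=0)
    if ref.sum() == 0:
        # histograms too sparse for a median reference (mostly 0/1
        # cells); the mean keeps the registration target informative
        ref = H.mean(axis=0)
    max_shift_bins = int(np.ceil(max_shift_um / DEPTH_BIN_UM))
    rigid = np.zeros(n_bins)
    flagged = counts < MIN_SPIKES_PER_BIN
    for b in range(n_bins):
        if not flagged[b]:
            rigid[b] = _registration_shift(H[b], ref, max_shift_bins) \
                * DEPTH_BIN_UM
    # flagged bins inherit nearest estimated neighbor
    good = np.flatnonzero(~flagged)
    if len(good) == 0:
        raise ValueError("no time bin has enough spikes")
    for b in np.flatnonzero(flagged):
        rigid[b] = rigid[good[np.argmin(np.abs(good - b))]]
    # registration noise per bin is of the same order as slow drift
    # itself; temporal smoothing (drift varies over tens of seconds)
    # keeps the correction from injecting per-batch jitter
    if smooth_s > 0:
        from scipy.ndimage import gaussian_filter1d
        rigid = gaussian_filter1d(rigid, smooth_s / bin_size)
    if n_blocks <= 1:
        return DriftTrace(rigid[:, None], bin_size,
                          np.array([(y0 + y1) / 2]), flagged)
    # nonrigid refinement per depth block, +-10 um around the rigid value
    centers = np.linspace(y0, y1, n_blocks)
    block_half = (y1 - y0) / max(n_blocks - 1, 1)
    values = np.tile(rigid[:, None], (1, n_blocks))
    local_bins = int(np.ceil(10.0 / DEPTH_BIN_UM))
    dcent = (dedges[:-1] + dedges[1:]) / 2
    for bi, c in enumerate(centers):
        sel = np.abs(dcent - c) <= block_half
        if sel.sum() < 3:
            continue
        for b in range(n_bins):
            if flagged[b]:
                continue
            base_bins = rigid[b] / DEPTH_BIN_UM
            shift = _registration_shift(
                np.roll(H[b, sel], -int(round(base_bins)), axis=0),
                ref[sel], local_bins)
            values[b, bi] = int(round(base_bins)) * DEPTH_BIN_UM \
                + shift * DEPTH_BIN_UM
    for b in np.flatnonzero(flagged):
        values[b] = values[good[np.argmin(np.abs(good - b))]]
    if smooth_s > 0:
        from scipy.ndimage import gaussian_filter1d
        values = gaussian_filter1d(values, smooth_s / bin_size, axis=0)
    return DriftTrace(values, bin_size, centers, flagged)


def drift_to_channels(trace: DriftTrace, geom: ProbeGeometry) -> np.ndarray:
    """Linear interpolation of block shifts to every channel.

    Returns (n_time_bins, n_channels) um; constant extrapolation beyond
    the outer block centers.
    """
    if not np.isfinite(trace.values).all():
        raise ValueError("drift trace contains non-finite values")
    out = np.empty((trace.n_bins, geom.n_channels))
    for b in range(trace.n_bins):
        out[b] = np.interp(geom.y, trace.block_centers, trace.values[b])
    return out


def build_shift_matrix(channel_shifts: np.ndarray, geom: ProbeGeometry,
                       sigma: float = KRIGING_SIGMA_UM,
                       lam: float = KRIGING_LAMBDA) -> np.ndarray:
    """Gaussian-kriging operator undoing a per-channel vertical shift.

    With units displaced upward by ``channel_shifts`` (um), channel i
    effectively sampled the tissue at (x_i, y_i - shift_i). The operator
    K(nominal, shifted) (K(shifted, shifted) + lam I)^(-1) evaluates the
    recorded field back at the nominal channel positions; zero shift
    gives (numerically) the identity.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    shifts = np.broadcast_to(np.asarray(channel_shifts, float),
                             (geom.n_channels,))
    if np.abs(shifts).max() < 1e-9:
        return np.eye(geom.n_channels)      # nothing to interpolate
    nominal = geom.positions
    shifted = nominal.copy()
    shifted[:, 1] = shifted[:, 1] - shifts

    def kmat(A, B):
        d2 = ((A[:, None, :] - B[None, :, :]) ** 2).sum(-1)
        return np.exp(-0.5 * d2 / sigma ** 2)

    Kss = kmat(shifted, shifted)
    Kns = kmat(nominal, shifted)
    lam_eff = lam
    for _ in range(5):
        try:
            return Kns @ np.linalg.solve(
                Kss + lam_eff * np.eye(len(Kss)), np.eye(len(Kss)))
        except np.linalg.LinAlgError:
            import warnings
            warnings.warn(f"kriging system singular; raising lambda to "
                          f"{lam_eff * 10}")
            lam_eff *= 10
    raise np.linalg.LinAlgError("kriging system remained singular")
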