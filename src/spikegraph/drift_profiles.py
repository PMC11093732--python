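"""Synthetic probe-motion profiles for drifting-recording simulations.

Five profile families are supported, mirroring the drift patterns seen in
chronic Neuropixels recordings: no drift, medium continuous drift, high
continuous drift, fast transient drift events, and an abrupt 30-um step
(with a site-aligned probe variant handled at the waveform-bank level).

All profiles are defined on a grid of vertical probe positions (9 by
default, equally spaced along the probe) and on a regular time grid of
2-s bins (200 ms for the fast profile). The continuous profiles are built
from Gaussian noise smoothed in time with a 100-s Gaussian filter: an
overall (rigid) component shared by all positions plus a per-position
component smoothed across positions (sigma = 2 positions), scaled by a
profile-specific factor, and the whole field is affinely rescaled so its
minimum and maximum hit the profile's stated extremes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = ["DriftProfile", "generate_drift", "DRIFT_KINDS"]

DRIFT_KINDS = ("none", "medium", "high", "fast", "step", "step_aligned")

#: per-position component scale and (min, max) um extremes per profile
_PROFILE_PARAMS = {
    "medium": (0.4, 7.0),
    "high": (0.26, 18.5),
    "step": (0.58, 4.0),
    "step_aligned": (0.58, 4.0),
}

_TIME_SMOOTH_S = 100.0   # temporal Gaussian sigma, seconds
_POS_SMOOTH = 2.0        # positional Gaussian sigma, in position-grid units
_STEP_UM = 30.0          # abrupt mid-recording offset for step profiles
_FAST_AMP_UM = 10.0      # amplitude of each fast drift event
_FAST_RISE_S = 0.080     # rise time of the difference-of-exponentials kernel
_FAST_DECAY_S = 0.200    # decay time
_N_FAST_EVENTS = 300


@dataclass
class DriftProfile:
    """Vertical probe-motion field: time bins x depth positions, in um."""

    kind: str
    trace: np.ndarray          # (n_bins, n_positions) um
    bin_size: float            # seconds
    position_centers: np.ndarray  # (n_positions,) um along the probe

    @property
    def n_bins(self) -> int:
        return self.trace.shape[0]

    @property
    def n_positions(self) -> int:
        return self.trace.shape[1]

    @property
    def duration(self) -> float:
        return self.n_bins * self.bin_size

    def at(self, t: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Drift (um) at times ``t`` (s) and probe depths ``y`` (um).

        Nearest bin in time, linear interpolation across positions with
        constant extrapolation beyond the outer position centers.
        """
        t = np.atleast_1d(np.asarray(t, float))
        y = np.atleast_1d(np.asarray(y, float))
        ib = np.clip((t / self.bin_size).astype(int), 0, self.n_bins - 1)
        out = np.empty(ib.shape, float)
        for k, (b, yy) in enumerate(zip(ib, y)):
            out[k] = np.interp(yy, self.position_centers, self.trace[b])
        return out


def _smoothed_noise(rng: np.random.Generator, n_bins: int, n_pos: int,
                    bin_s: float) -> tuple[np.ndarray, np.ndarray]:
    """Overall (rigid) trace and per-position deviations, both smoothed."""
    sigma_bins = _TIME_SMOOTH_S / bin_s
    overall = gaussian_filter1d(rng.standard_normal(n_bins), sigma_bins)
    per_pos = rng.standard_normal((n_bins, n_pos))
    per_pos = gaussian_filter1d(per_pos, sigma_bins, axis=0)
    per_pos = gaussian_filter1d(per_pos, _POS_SMOOTH, axis=1)
    # Smoothing shrinks the amplitude of white noise; renormalize each
    # component to unit s.d. so the per-position scale factors act on
    # comparable scales.
    overall /= overall.std()
    per_pos /= per_pos.std()
    return overall, per_pos


def _rescale(field: np.ndarray, extreme: float) -> np.ndarray:
    """Affine rescale so min(field) == -extreme and max(field) == +extreme."""
    lo, hi = field.min(), field.max()
    if hi == lo:
        return np.zeros_like(field)
    return (field - lo) / (hi - lo) * (2 * extreme) - extreme


def generate_drift(kind: str, duration: float = 45 * 60.0,
                   seed: int | np.random.Generator = 0,
                   n_positions: int = 9,
                   probe_span: float = 3840.0) -> DriftProfile:
    """Generate a drift profile of the given kind.

    Parameters
    ----------
    kind
        One of ``none, medium, high, fast, step, step_aligned``.
    duration
        Recording length in seconds (default 45 min).
    seed
        Integer seed or a ``numpy.random.Generator``.
    n_positions
        Number of vertical positions at which the trace is generated.
    probe_span
        Vertical extent of the probe in um; position centers are spread
        evenly over ``[0, probe_span]``.
    """
    if kind not in DRIFT_KINDS:
        raise ValueError(f"unknown drift kind {kind!r}")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    centers = np.linspace(0.0, probe_span, n_positions)

    bin_s = 2.0
    n_bins = max(2, int(round(duration / bin_s)))

    if kind == "none":
        return DriftProfile(kind, np.zeros((n_bins, n_positions)), bin_s,
                            centers)

    if kind == "fast":
        slow = generate_drift("medium", duration, rng, n_positions,
                              probe_span)
        fine_s = 0.2
        n_fine = int(round(duration / fine_s))
        # nearest-neighbor upsampling of the 2-s slow component
        idx = np.clip((np.arange(n_fine) * fine_s / bin_s).round().astype(int),
                      0, slow.n_bins - 1)
        trace = slow.trace[idx].copy()
        # difference-of-exponentials events, peak-normalized to 10 um
        tk = np.arange(0, 5 * _FAST_DECAY_S, fine_s)
        kernel = np.exp(-tk / _FAST_DECAY_S) - np.exp(-tk / _FAST_RISE_S)
        kernel *= _FAST_AMP_UM / kernel.max()
        events = rng.integers(0, n_fine, _N_FAST_EVENTS)
        bump = np.zeros(n_fine)
        for e in events:
            end = min(n_fine, e + len(kernel))
            bump[e:end] += kernel[: end - e]
        trace += bump[:, None]
        return DriftProfile(kind, trace, fine_s, centers)

    scale, extreme = _PROFILE_PARAMS[kind]
    overall, per_pos = _smoothed_noise(rng, n_bins, n_positions, bin_s)
    fld = overall[:, None] + scale * per_pos
    trace = _rescale(fld, extreme)
    if kind in ("step", "step_aligned"):
        trace = trace.copy()
        trace[n_bins // 2:] += _STEP_UM
    return DriftProfile(kind, trace, bin_s, centers)
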