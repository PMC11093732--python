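"""Simple (universal) detection templates and single-channel shape/PC
learning.

A simple template is the outer product of one of six unit-norm
single-channel waveform shapes with an isotropic Gaussian spatial
footprint (five sizes), centered on a grid of candidate positions that
upsamples the channel density by a factor of 2 in each dimension (4x the
site count: 1,536 positions and 46,080 templates for a 384-site
Neuropixels1 probe). Because shape and footprint are separately unit
norm, the variance a template explains at a time point is just the
squared dot product with the data, computed efficiently as a temporal
convolution per shape followed by a footprint matrix product.

Both polarities are detected: a template and its sign-inverted pair give
the same squared dot product, so taking V = (W^T D)^2 covers positive-
and negative-going spikes at once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import maximum_filter1d
from scipy.signal import fftconvolve
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors

from .io import PaddedBatch, ProbeGeometry

__all__ = ["SimpleTemplateBank", "PCBasis", "prototype_shapes",
           "learn_shapes_and_pcs", "build_simple_templates",
           "variance_explained_simple", "detect_with_simple_templates",
           "spike_xy"]

N_SHAPES = 6
N_SIZES = 5
SIZES_UM = (5.0, 10.0, 15.0, 20.0, 30.0)   # Gaussian footprint s.d. values
DETECT_THRESHOLD = 9.0          # on |W^T D|, whitened-norm units
TIME_NEIGHBORHOOD = 20          # peak must be max over +-20 samples
POSITION_NEIGHBORHOOD = 100     # ... and over the 100 nearest positions


def _biphasic(n_t: int, trough_width: float, t2p: float,
              repol: float) -> np.ndarray:
    """Parametric biphasic action-potential shape, trough at n_t // 2.

    ``trough_width`` is the Gaussian s.d. of the (fast) depolarization
    trough in samples; ``t2p`` the trough-to-peak time in samples —
    these are independent in real neurons, where even slow-repolarizing
    cells keep a sharp trough.
    """
    t = np.arange(n_t) - n_t // 2
    w = -np.exp(-0.5 * (t / trough_width) ** 2) \
        + repol * np.exp(-0.5 * ((t - t2p) / (0.45 * t2p + 1.0)) ** 2)
    w -= w.mean()
    return w / np.linalg.norm(w)


def prototype_shapes(n_t: int = 61, n_shapes: int = N_SHAPES) -> np.ndarray:
    """Packaged prototype single-channel waveforms (unit norm,
    trough-aligned), spanning narrow to broad spikes."""
    widths = np.linspace(1.5, 4.5, n_shapes)
    t2p = np.linspace(7.0, 27.0, n_shapes)       # 0.23-0.9 ms at 30 kHz
    repol = np.linspace(0.25, 0.6, n_shapes)
    return np.stack([_biphasic(n_t, w, tp, r)
                     for w, tp, r in zip(widths, t2p, repol)])


@dataclass
class PCBasis:
    """Orthonormal temporal principal components of single-channel
    waveforms; shape (n_pcs, n_t)."""

    components: np.ndarray

    def __post_init__(self):
        G = self.components @ self.components.T
        if not np.allclose(G, np.eye(len(G)), atol=1e-6):
            raise ValueError("PC basis must be orthonormal")

    @property
    def n_pcs(self) -> int:
        return self.components.shape[0]

    def project(self, patch: np.ndarray) -> np.ndarray:
        """(channels x n_t) patch -> (channels x n_pcs) features."""
        return patch @ self.components.T

    def reconstruct(self, feats: np.ndarray) -> np.ndarray:
        return feats @ self.components


def _collect_snippets(batches, n_t: int, threshold: float = 6.0,
                      max_snippets: int = 20000) -> np.ndarray:
    """Threshold-crossing single-channel snippets, trough-aligned."""
    out = []
    half = n_t // 2
    for b in batches:
        d = b.payload
        mad = np.median(np.abs(d), axis=1, keepdims=True) / 0.6745 + 1e-9
        z = d / mad
        for c in range(d.shape[0]):
            x = z[c]
            peaks = np.flatnonzero(
                (x < -threshold) & (x <= np.roll(x, 1)) &
                (x < np.roll(x, -1)))
            peaks = peaks[(peaks >= half) & (peaks < len(x) - half)]
            for p in peaks:
                w = d[c, p - half:p - half + n_t].astype(float)
                nrm = np.linalg.norm(w)
                if nrm > 0:
                    out.append(w / nrm)
                if len(out) >= max_snippets:
                    return np.array(out)
    return np.array(out) if out else np.empty((0, n_t))


def learn_shapes_and_pcs(batches, n_t: int = 61, n_shapes: int = N_SHAPES,
                         n_pcs: int = 6, min_snippets: int = 500,
                         seed: int = 0) -> tuple[np.ndarray, PCBasis]:
    """k-means centroids of single-channel snippets plus their top PCs.

    Falls back to the packaged prototype set (and a PCA basis of jittered
    prototypes) when fewer than ``min_snippets`` snippets are found.
    """
    snips = _collect_snippets(batches, n_t)
    if len(snips) < min_snippets:
        import warnings
        warnings.warn(f"only {len(snips)} snippets; using packaged "
                      "prototype shapes")
        shapes = prototype_shapes(n_t, n_shapes)
        rng = np.random.default_rng(seed)
        fam = np.stack([_biphasic(n_t, rng.uniform(1.2, 5.0),
                                  rng.uniform(6.0, 30.0),
                                  rng.uniform(0.2, 0.7))
                        for _ in range(512)])
        snips = fam
    else:
        km = KMeans(n_clusters=n_shapes, n_init=5, random_state=seed)
        km.fit(snips)
        shapes = km.cluster_centers_
        # trough-align and unit-normalize the centroids
        aligned = []
        for s in shapes:
            shift = n_t // 2 - int(np.argmin(s))
            aligned.append(np.roll(s, shift) / np.linalg.norm(s))
        shapes = np.stack(aligned)
    # uncentered PCA: the basis is applied to raw (trough-aligned)
    # patches, so it must span the waveforms themselves, mean included
    _, _, Vt = np.linalg.svd(snips, full_matrices=False)
    return shapes, PCBasis(Vt[:n_pcs])


@dataclass
class SimpleTemplateBank:
    """Grid of position x shape x size detection templates."""

    positions: np.ndarray       # (n_pos, 2) um
    shapes: np.ndarray          # (n_shapes, n_t), each unit norm
    sizes: np.ndarray           # (n_sizes,) Gaussian s.d. um
    footprints: np.ndarray      # (n_sizes, n_pos, n_chan), rows unit norm
    position_neighbors: np.ndarray  # (n_pos, <=100) nearest-position table

    @property
    def n_templates(self) -> int:
        return len(self.positions) * len(self.shapes) * len(self.sizes)

    @property
    def n_t(self) -> int:
        return self.shapes.shape[1]


def build_simple_templates(geom: ProbeGeometry, shapes: np.ndarray,
                           sizes=SIZES_UM,
                           n_position_neighbors: int = POSITION_NEIGHBORHOOD
                           ) -> SimpleTemplateBank:
    """Instantiate the full position x shape x size bank.

    The position grid doubles the channel density in each dimension:
    every site spawns four candidate positions (itself plus half-pitch
    offsets in x, in y, and in both), so a probe with C sites yields 4C
    positions.
    """
    xs = np.unique(geom.x)
    ys = np.unique(geom.y)
    hx = np.min(np.diff(xs)) / 2 if len(xs) > 1 else 16.0
    hy = np.min(np.diff(ys)) / 2 if len(ys) > 1 else 10.0
    offs = np.array([[0, 0], [hx, 0], [0, hy], [hx, hy]])
    pos = (geom.positions[:, None, :] + offs[None, :, :]).reshape(-1, 2)
    sizes = np.asarray(sizes, float)
    d2 = ((pos[:, 0:1] - geom.x[None, :]) ** 2 +
          (pos[:, 1:2] - geom.y[None, :]) ** 2)
    fp = np.empty((len(sizes), len(pos), geom.n_channels), np.float32)
    for si, s in enumerate(sizes):
        f = np.exp(-0.5 * d2 / s ** 2)
        fp[si] = f / np.linalg.norm(f, axis=1, keepdims=True)
    nn = NearestNeighbors(n_neighbors=min(n_position_neighbors, len(pos)),
                          algorithm="brute").fit(pos)
    _, nbrs = nn.kneighbors(pos)
    return SimpleTemplateBank(pos, np.asarray(shapes, float), sizes, fp,
                              nbrs.astype(np.int32))


def variance_explained_simple(W: np.ndarray, D: np.ndarray) -> float:
    """V = (W^T D)^2 for a unit-norm template W against data patch D."""
    W = np.asarray(W, float)
    if abs(np.linalg.norm(W) - 1.0) > 1e-6:
        raise ValueError("template must be unit norm")
    return float(np.vdot(W, D) ** 2)


def _shape_convolutions(data: np.ndarray, shapes: np.ndarray) -> np.ndarray:
    """Cross-correlate each channel with each shape: out[s, c, t] =
    sum_tau data[c, t + tau - center] * shape[s, tau]."""
    n_t = shapes.shape[1]
    rev = shapes[:, ::-1]
    out = np.empty((len(shapes), data.shape[0], data.shape[1]), np.float32)
    for s in range(len(shapes)):
        full = fftconvolve(data, rev[s][None, :], mode="same", axes=1)
        # 'same' centers the odd-length kernel correctly for n_t odd
        out[s] = full
    return out


def detect_with_simple_templates(batch: PaddedBatch, bank: SimpleTemplateBank,
                                 geom: ProbeGeometry,
                                 threshold: float = DETECT_THRESHOLD,
                                 ) -> dict:
    """Detect candidate spikes of either polarity with the simple bank.

    The best |dot product| over shapes and sizes is kept per (position,
    time); detections are points above threshold that are maxima over
    +-20 samples and over the 100 nearest positions. Intentionally
    under-detects overlapping spikes (a large neighborhood prevents
    double detections); matching pursuit recovers the rest later.

    Returns dict arrays: time (absolute samples), position_index, xy,
    amplitude (signed best dot), shape_index, size_index.
    """
    conv = _shape_convolutions(batch.data, bank.shapes)  # (S, C, T)
    n_pos = len(bank.positions)
    S, C, T = conv.shape
    best = np.zeros((n_pos, T), np.float32)
    # exact screening: footprints are unit norm, so |F . conv(:, t)| can
    # only exceed the threshold where the channel norm of some shape's
    # convolution does (Cauchy-Schwarz)
    colnorm2 = np.einsum("sct,sct->st", conv, conv)
    screen = np.flatnonzero(colnorm2.max(axis=0) > threshold ** 2)
    if len(screen):
        sub = conv[:, :, screen]                       # (S, C, Tc)
        sub_flat = sub.transpose(1, 0, 2).reshape(C, -1)
        acc = np.zeros((n_pos, len(screen)), np.float32)
        for si in range(len(bank.sizes)):
            a = (bank.footprints[si] @ sub_flat).reshape(n_pos, S, -1)
            np.maximum(acc, np.abs(a).max(axis=1), out=acc)
        best[:, screen] = acc
    # temporal local maxima in payload region, above threshold
    tmax = maximum_filter1d(best, 2 * TIME_NEIGHBORHOOD + 1, axis=1)
    lo, hi = batch.n_t, batch.n_t + batch.N_T
    cand_p, cand_t = np.nonzero((best >= tmax) & (best > threshold))
    keep = (cand_t >= lo) & (cand_t < hi)
    cand_p, cand_t = cand_p[keep], cand_t[keep]
    # spatial neighborhood check at candidates only (vectorized gather)
    if len(cand_p):
        nb = bank.position_neighbors[cand_p]          # (n_cand, n_nb)
        vals = best[nb, cand_t[:, None]]              # (n_cand, n_nb)
        own = best[cand_p, cand_t][:, None]
        ok = (vals <= own).all(axis=1)
        # deterministic tie-break: lowest position index wins
        tied_min = np.where(vals >= own, nb, np.iinfo(np.int32).max).min(1)
        ok &= tied_min >= cand_p
        cand_p, cand_t = cand_p[ok], cand_t[ok]
    # recover best (shape, size, sign) at the accepted candidates only
    n_cand = len(cand_p)
    amp = np.empty(n_cand, np.float32)
    shp = np.empty(n_cand, np.int8)
    siz = np.empty(n_cand, np.int8)
    for i in range(n_cand):
        d = bank.footprints[:, cand_p[i], :] @ conv[:, :, cand_t[i]].T
        flat = np.abs(d).argmax()
        siz[i], shp[i] = np.unravel_index(flat, d.shape)
        amp[i] = d[siz[i], shp[i]]
    res = {
        "time": cand_t - batch.n_t + batch.start_sample,
        "position_index": cand_p,
        "xy": bank.positions[cand_p],
        "amplitude": amp,
        "shape_index": shp,
        "size_index": siz,
        "batch_time": cand_t,
    }
    return res


def spike_xy(patch: np.ndarray, shape: np.ndarray, channels: np.ndarray,
             geom: ProbeGeometry) -> np.ndarray:
    """Center of mass of a spike from its projection on the best shape.

    ``patch`` is (len(channels), n_t); per-channel weights are the
    nonnegative projections |shape . patch_c|, and the position is the
    weighted mean of the channel coordinates. All-zero weights fall back
    to the best channel's coordinates.
    """
    p = patch @ shape
    sign = np.sign(p[np.argmax(np.abs(p))]) or 1.0
    w = np.maximum(0.0, p * sign)     # rectified projections
    pos = geom.positions[channels]
    if w.sum() <= 0:
        c = int(np.argmax(np.linalg.norm(patch, axis=1)))
        return pos[c]
    return (w[:, None] * pos).sum(0) / w.sum()
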