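"""Template learning, rank-3 matching pursuit and background-subtracted
PC feature extraction.

Learned templates are cluster centroids of PC-embedded spikes detected
with the simple bank, mapped back to spatiotemporal waveforms,
temporally aligned to the prototype shapes, deduplicated by lagged
correlation, and stored unit-norm together with the average norm x_W of
their member spikes. Detection with a learned template fixes the scale
to x_W, so the variance it explains is

    V_explained = 2 x_W W^T D - x_W^2

which is computed convolutionally through a rank-3 factorization of each
template. Matching pursuit alternates peak picking (local maxima over
+-n_t samples across all templates, above threshold) with exact
subtraction of the accepted spikes, updating the template dot products
locally via precomputed lagged template cross products, for up to 50
rounds. Spike features are PCs of the residual patch plus the spike's
own template contribution, which excludes overlapping neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import maximum_filter1d
from scipy.signal import fftconvolve

from .cluster import cluster_features
from .io import PaddedBatch, ProbeGeometry
from .merges import build_merge_tree, traverse_tree
from .templates import PCBasis, SimpleTemplateBank

__all__ = ["LearnedTemplates", "variance_explained_learned",
           "learn_templates", "matching_pursuit",
           "features_with_background_subtraction", "SECTION_UM"]

SECTION_UM = 40.0              # vertical clustering section height
N_FEATURE_CHANNELS = 10        # PC features on the 10 nearest channels
MP_THRESHOLD = 8.0             # accept when V_explained > threshold^2
MP_ROUNDS = 50
DUP_CORR = 0.9                 # duplicate-merge lagged correlation
DUP_REL_DIFF = 0.45            # ... and relative scaled-mean difference;
                               # equal-norm templates at exactly corr 0.9
                               # differ by sqrt(2 - 2*0.9) ~ 0.45, so the
                               # correlation condition is the binding one
RANK = 3


@dataclass
class LearnedTemplates:
    """Unit-norm spatiotemporal templates with norms and rank-3 factors."""

    templates: np.ndarray      # (K, n_chan, n_t), unit norm
    x_W: np.ndarray            # (K,) average member-spike norm
    spatial: np.ndarray        # (K, n_chan, RANK)  (left factors * svals)
    temporal: np.ndarray       # (K, RANK, n_t)     (right factors)
    cross: np.ndarray          # (K, K, 2*n_t - 1) lagged dot products
    positions: np.ndarray      # (K, 2) template center of mass, um
    feat_channels: np.ndarray  # (K, N_FEATURE_CHANNELS) channel ids

    @property
    def n_templates(self) -> int:
        return len(self.templates)

    @property
    def n_t(self) -> int:
        return self.templates.shape[2]

    def rank_variance(self) -> np.ndarray:
        """Fraction of each template's variance captured by the rank-3
        reconstruction."""
        rec = np.einsum("kcr,krt->kct", self.spatial, self.temporal)
        num = np.linalg.norm((rec - self.templates).reshape(len(rec), -1),
                             axis=1) ** 2
        den = np.linalg.norm(self.templates.reshape(len(rec), -1),
                             axis=1) ** 2
        return 1.0 - num / np.maximum(den, 1e-12)


def variance_explained_learned(W: np.ndarray, x_W: float,
                               D: np.ndarray) -> float:
    """V = 2 x_W W^T D - x_W^2 for unit-norm W at fixed norm x_W > 0."""
    return float(2.0 * x_W * np.vdot(W, D) - x_W ** 2)


def _lagged_cross_products(templates: np.ndarray) -> np.ndarray:
    """cross[j, i, l + n_t - 1] = sum_{c,tau} W_j[c,tau] W_i[c,tau+l]."""
    K, C, n_t = templates.shape
    L = 2 * n_t
    F = np.fft.rfft(templates, L, axis=2)
    cross = np.empty((K, K, 2 * n_t - 1))
    for j in range(K):
        spec = (np.conj(F[j][None]) * F).sum(axis=1)       # (K, freq)
        cc = np.fft.irfft(spec, L, axis=1)
        # index m -> lag l: l = m for m < n_t, l = m - L for m >= n_t
        cross[j] = np.concatenate([cc[:, -(n_t - 1):], cc[:, :n_t]], axis=1)
    return cross


def _anchor_index(trace: np.ndarray) -> int:
    """Temporal anchor of a single-channel waveform: the depolarization
    trough, unless the waveform is genuinely positive-going.

    The trough wins whenever it reaches a third of the dominant positive
    deflection — sharp troughs lose amplitude to smoothing and filtering
    while the broad repolarization peak does not, and anchoring a unit's
    spikes on the wrong phase shifts its whole train by the
    trough-to-peak time."""
    mx, mn = float(trace.max()), float(trace.min())
    return int(np.argmin(trace)) if -mn >= mx / 3.0 else int(np.argmax(trace))


def _shift_time(w: np.ndarray, lag: int) -> np.ndarray:
    """Shift a (chan x time) waveform right by ``lag`` samples, zero
    fill (no circular wrap)."""
    out = np.zeros_like(w)
    if lag >= 0:
        out[:, lag:] = w[:, :w.shape[1] - lag] if lag else w
    else:
        out[:, :lag] = w[:, -lag:]
    return out


def _best_lag(w1: np.ndarray, w2: np.ndarray) -> int:
    """Time lag maximizing the correlation of two (chan x time) waveforms
    (the shift to apply to w2 to align it with w1)."""
    n_t = w1.shape[1]
    xc = np.zeros(2 * n_t - 1)
    for c in range(w1.shape[0]):
        xc += np.correlate(w1[c], w2[c], mode="full")
    return int(np.argmax(xc)) - (n_t - 1)


def _align_to_shapes(w: np.ndarray, shapes: np.ndarray) -> np.ndarray:
    """Shift a (n_chan, n_t) waveform into the prototypes' canonical
    temporal alignment.

    All prototype shapes carry their trough at the center sample, so
    centering the template's best-channel anchor (trough, or positive
    peak for positive-going spikes) is the stable realization of
    maximal-correlation alignment — a raw correlation argmax can lock
    onto a sign-flipped or secondary lobe when waveforms are noisy."""
    n_t = w.shape[1]
    best_c = int(np.argmax(np.linalg.norm(w, axis=1)))
    lag = _anchor_index(w[best_c]) - n_t // 2
    return _shift_time(w, -lag)


def _template_position(w: np.ndarray, geom: ProbeGeometry) -> np.ndarray:
    amp = np.linalg.norm(w, axis=1)
    if amp.sum() == 0:
        return geom.positions[0]
    return (amp[:, None] * geom.positions).sum(0) / amp.sum()


def learn_templates(spike_features: np.ndarray, spike_channels: np.ndarray,
                    spike_xy: np.ndarray, basis: PCBasis,
                    geom: ProbeGeometry, shapes: np.ndarray,
                    section_um: float = SECTION_UM,
                    seed: int = 0, min_section_spikes: int = 20,
                    cluster_kwargs: dict | None = None,
                    spike_patches: np.ndarray | None = None,
                    bimod_threshold: float = 0.2) -> LearnedTemplates:
    """Cluster PC-embedded spikes per 40-um section into templates.

    ``spike_features`` is (n, 10, n_pcs), ``spike_channels`` (n, 10) the
    channel ids those features live on, ``spike_xy`` (n, 2). Within each
    vertical section, features are embedded on the union of member
    channel sets and clustered with the graph method using only the
    bimodality merge criterion (no correlogram information at this
    stage); the split threshold is deliberately low here because extra
    templates per neuron are harmless while a template shared between
    neurons degrades the matching-pursuit subtraction. Cluster templates
    are means of the raw aligned patches (when given), aligned to the
    prototype convention and deduplicated.
    """
    rng = np.random.default_rng(seed)
    ckw = dict(cluster_kwargs or {})
    y = spike_xy[:, 1]
    edges = np.arange(geom.y.min() - section_um / 2,
                      geom.y.max() + section_um, section_um)
    raw: list[tuple[np.ndarray, float]] = []       # (waveform, x_W)
    for lo in edges:
        sel = np.flatnonzero((y >= lo) & (y < lo + section_um))
        if len(sel) < min_section_spikes:
            continue
        chans = np.unique(spike_channels[sel])
        cmap = {c: i for i, c in enumerate(chans)}
        emb = np.zeros((len(sel), len(chans), basis.n_pcs), np.float32)
        for r, si in enumerate(sel):
            idx = [cmap[c] for c in spike_channels[si]]
            emb[r, idx, :] = spike_features[si]
        X = emb.reshape(len(sel), -1)
        assign, graph = cluster_features(
            X, seed=rng.integers(2**31 - 1), **ckw)
        tree = build_merge_tree(graph, assign)
        leaf_feats = {c: X[assign.left == c]
                      for c in range(tree.n_leaves)}
        dummy_t = {c: np.empty(0) for c in range(tree.n_leaves)}
        labels = traverse_tree(tree, leaf_feats, dummy_t,
                               bimod_threshold=bimod_threshold,
                               use_ccg=False)
        final = labels[assign.left]
        for c in np.unique(final):
            msel = sel[final == c]
            if spike_patches is not None:
                # mean of the raw aligned patches, embedded to the union
                # channel set: no PC reconstruction error
                w_local = np.zeros((len(chans), spike_patches.shape[2]))
                for si in msel:
                    idx = [cmap[ch] for ch in spike_channels[si]]
                    w_local[idx] += spike_patches[si]
                w_local /= len(msel)
            else:
                members = X[final == c]
                centroid = members.mean(0).reshape(len(chans), basis.n_pcs)
                w_local = basis.reconstruct(centroid)    # (chans, n_t)
            nrm = np.linalg.norm(w_local)
            if nrm <= 0:
                continue
            wu = w_local / nrm
            if spike_patches is not None:
                dots = []
                for si in msel:
                    idx = [cmap[ch] for ch in spike_channels[si]]
                    dots.append(float(np.sum(wu[idx] * spike_patches[si])))
                x_w = float(np.mean(dots))
            else:
                members = X[final == c]
                centroid = members.mean(0)
                x_w = float(np.mean(members @ (centroid / nrm)))
            if x_w <= 0:
                continue
            w = np.zeros((geom.n_channels, w_local.shape[1]))
            w[chans] = wu
            raw.append((_align_to_shapes(w, shapes), x_w))
    if not raw:
        raise ValueError("no templates could be learned (too few spikes)")
    # deduplicate: high lagged correlation AND similar scaled means
    kept: list[list] = []      # [waveform*weight..., x_w, n]
    merged: list[tuple[np.ndarray, float]] = []
    used = np.zeros(len(raw), bool)
    from .merges import waveform_similarity
    for i in range(len(raw)):
        if used[i]:
            continue
        wi, xi = raw[i]
        group = [(wi, xi)]
        used[i] = True
        for j in range(i + 1, len(raw)):
            if used[j]:
                continue
            wj, xj = raw[j]
            if waveform_similarity(wi, wj) <= DUP_CORR:
                continue
            # similar means: scaled mean waveforms close at the best lag
            lag = _best_lag(wi, wj)
            wj_al = _shift_time(wj, lag)
            rel = np.linalg.norm(xi * wi - xj * wj_al) / max(xi, xj)
            if rel < DUP_REL_DIFF:
                group.append((wj_al, xj))
                used[j] = True
        wsum = np.sum([w for w, _ in group], axis=0)
        nrm = np.linalg.norm(wsum)
        merged.append((wsum / nrm, float(np.mean([x for _, x in group]))))
    # discard truncated templates: with the trough anchored at the
    # center, waveform energy cannot concentrate left of it — a
    # left-shifted energy center marks a patch cluster anchored on the
    # repolarization peak whose real trough fell outside the window
    n_t_ = merged[0][0].shape[1]
    tgrid = np.arange(n_t_)
    kept_m = []
    for w, x in merged:
        en = (w ** 2).sum(axis=0)
        com = float((en * tgrid).sum() / max(en.sum(), 1e-12))
        if com >= n_t_ // 2 - 6:
            kept_m.append((w, x))
    if kept_m:
        merged = kept_m
    templates = np.stack([w for w, _ in merged])
    x_W = np.array([x for _, x in merged])
    K, C, n_t = templates.shape
    spatial = np.zeros((K, C, RANK))
    temporal = np.zeros((K, RANK, n_t))
    for k in range(K):
        U, S, Vt = np.linalg.svd(templates[k], full_matrices=False)
        r = min(RANK, len(S))
        spatial[k, :, :r] = U[:, :r] * S[:r]
        temporal[k, :r, :] = Vt[:r]
    positions = np.stack([_template_position(w, geom) for w in templates])
    feat_channels = np.stack([
        geom.nearest_to_point(p[0], p[1], N_FEATURE_CHANNELS)
        for p in positions])
    if feat_channels.shape[1] < N_FEATURE_CHANNELS:
        pad = np.repeat(feat_channels[:, -1:],
                        N_FEATURE_CHANNELS - feat_channels.shape[1], axis=1)
        feat_channels = np.concatenate([feat_channels, pad], axis=1)
    cross = _lagged_cross_products(templates)
    return LearnedTemplates(templates, x_W, spatial, temporal, cross,
                            positions, feat_channels.astype(np.int32))


def _template_dot_products(data: np.ndarray, lt: LearnedTemplates
                           ) -> np.ndarray:
    """B[i, t] = W_i^T D centered at t, via the rank-3 factorization."""
    K, _, n_t = lt.templates.shape
    T = data.shape[1]
    B = np.zeros((K, T), np.float32)
    for k in range(K):
        s = lt.spatial[k].T @ data                     # (RANK, T)
        rev = lt.temporal[k][:, ::-1]
        B[k] = fftconvolve(s, rev, mode="same", axes=1).sum(0)
    return B


def matching_pursuit(batch: PaddedBatch, lt: LearnedTemplates,
                     threshold: float = MP_THRESHOLD,
                     n_rounds: int = MP_ROUNDS) -> tuple[dict, PaddedBatch]:
    """Iterative detect-and-subtract spike extraction.

    Each round keeps peaks of V_explained that are local maxima over
    +-n_t samples across all templates and exceed threshold^2, subtracts
    x_W-scaled templates from the residual, and updates the dot products
    locally with the precomputed lagged cross products. Returns the
    spike table (time, template, amplitude) and the residual batch.
    """
    n_t = lt.n_t
    half = n_t // 2
    D = batch.data.astype(np.float32).copy()
    B = _template_dot_products(D, lt)
    thr2 = threshold ** 2
    lo, hi = batch.n_t, batch.n_t + batch.N_T
    times, ids, amps = [], [], []
    for _ in range(n_rounds):
        V = 2.0 * lt.x_W[:, None] * B - (lt.x_W ** 2)[:, None]
        Vmax = V.max(axis=0)
        tmax = maximum_filter1d(Vmax, 2 * n_t + 1)
        peaks = np.flatnonzero((Vmax >= tmax) & (Vmax > thr2))
        peaks = peaks[(peaks >= lo) & (peaks < hi)]
        if len(peaks) == 0:
            break
        # enforce one peak per +-n_t window (ties in flat maxima)
        keep = []
        last = -10 * n_t
        for t in peaks:
            if t - last > n_t:
                keep.append(t)
                last = t
        for t in keep:
            i = int(np.argmax(V[:, t]))
            x = lt.x_W[i]
            D[:, t - half:t - half + n_t] -= x * lt.templates[i]
            # B[j, t+l] -= x * cross[j, i, l], l in [-(n_t-1), n_t-1]
            sl = slice(t - (n_t - 1), t + n_t)
            B[:, sl] -= x * lt.cross[:, i, :]
            times.append(t)
            ids.append(i)
            amps.append(float(B[i, t] + x))   # post-update diagnostic
    order = np.argsort(times, kind="stable")
    spikes = {
        "time": np.array(times, np.int64)[order] - batch.n_t
        + batch.start_sample,
        "batch_time": np.array(times, np.int64)[order],
        "template": np.array(ids, np.int32)[order],
        "amplitude": np.array(amps, np.float32)[order],
    }
    resid = PaddedBatch(D, batch.batch_index, batch.N_T, batch.n_t,
                        batch.start_sample)
    return spikes, resid


def features_with_background_subtraction(residual: PaddedBatch, spikes: dict,
                                         lt: LearnedTemplates,
                                         basis: PCBasis) -> np.ndarray:
    """Per-spike PC features that exclude overlapping spikes.

    Projects the residual patch on the template's 10 nearest channels
    onto the PC basis and adds back the precomputed contribution of the
    spike's own template at norm x_W. Shape (n_spikes, 10, n_pcs).
    """
    n_t = lt.n_t
    half = n_t // 2
    D = residual.data
    pc_contrib = np.einsum(
        "kct,pt->kcp",
        lt.templates[np.arange(lt.n_templates)[:, None],
                     lt.feat_channels, :],
        basis.components) * lt.x_W[:, None, None]
    out = np.empty((len(spikes["time"]), lt.feat_channels.shape[1],
                    basis.n_pcs), np.float32)
    for s, (t, k) in enumerate(zip(spikes["batch_time"],
                                   spikes["template"])):
        chans = lt.feat_channels[k]
        patch = D[chans, t - half:t - half + n_t]
        out[s] = patch @ basis.components.T + pc_contrib[k]
    return out
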