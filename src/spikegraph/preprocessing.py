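"""Per-batch preprocessing: common average reference, high-pass filtering,
and local ZCA channel whitening.

The order is fixed — CAR, then temporal filter, then whitening — so that
large shared artifacts are removed before any operation that could smear
them across samples or channels. The high-pass filter is a causal FIR
whose impulse response is that of a 3rd-order Butterworth high-pass
(forward pass), applied in FFT space via the convolution theorem;
circular-wrap artifacts are confined to the n_t pads of each batch.
Whitening uses one ZCA vector per channel estimated from its 32 nearest
channels, with epsilon-smoothed singular values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io import PaddedBatch, ProbeGeometry, RecordingHandle, load_batch, \
    n_batches

__all__ = ["FilterKernel", "WhiteningModel", "common_average_reference",
           "build_highpass_kernel", "apply_filter_fft", "fit_whitening",
           "apply_whitening_and_alignment", "preprocess_batch"]


@dataclass
class FilterKernel:
    """Causal FIR impulse response of length N_T matching a Butterworth
    high-pass at ``cutoff`` Hz (order ``order``, forward pass)."""

    kernel: np.ndarray
    cutoff: float
    fs: float
    order: int = 3

    def frequency_response(self, freqs: np.ndarray) -> np.ndarray:
        """Complex response of the underlying recursive filter at ``freqs``."""
        sos = signal.butter(self.order, self.cutoff, "highpass",
                            fs=self.fs, output="sos")
        _, h = signal.sosfreqz(sos, worN=np.asarray(freqs, float), fs=self.fs)
        return h


@dataclass
class WhiteningModel:
    """Local ZCA whitening: one spatially local vector per channel,
    embedded into an n_chan x n_chan matrix."""

    W: np.ndarray              # (n_chan, n_chan), row c = channel c's vector
    n_neighbors: int
    epsilon: float
    C: np.ndarray              # full covariance used for the fit
    U: np.ndarray              # eigenvectors of C (diagnostics)
    S: np.ndarray              # eigenvalues of C (diagnostics)


def common_average_reference(batch: PaddedBatch) -> PaddedBatch:
    """Remove each channel's temporal mean, then the cross-channel median
    at every sample."""
    d = batch.data - batch.data.mean(axis=1, keepdims=True)
    if d.shape[0] >= 2:
        d -= np.median(d, axis=0, keepdims=True)
    else:
        warnings.warn("single-channel batch: skipping median reference")
    return PaddedBatch(d, batch.batch_index, batch.N_T, batch.n_t,
                       batch.start_sample)


def build_highpass_kernel(cutoff: float, N_T: int, fs: float,
                          order: int = 3) -> FilterKernel:
    """Impulse response of the reference Butterworth high-pass.

    A unit impulse at index floor(N_T / 2) of a zero vector of length N_T
    is filtered forward through the recursive filter; the result is the
    FIR kernel used in FFT space.
    """
    if not 0 < cutoff < fs / 2:
        raise ValueError(f"cutoff must lie in (0, fs/2); got {cutoff}")
    x = np.zeros(N_T)
    x[N_T // 2] = 1.0
    sos = signal.butter(order, cutoff, "highpass", fs=fs, output="sos")
    return FilterKernel(signal.sosfilt(sos, x), cutoff, fs, order)


def apply_filter_fft(batch: PaddedBatch, kernel: FilterKernel) -> PaddedBatch:
    """Apply the FIR kernel by circular convolution in FFT space.

    The kernel's impulse position is rolled to index 0 so the operation is
    causal; wrap-around artifacts land in the padding.
    """
    T = batch.data.shape[1]
    if len(kernel.kernel) > T:
        raise ValueError("kernel longer than padded batch")
    k = np.zeros(T)
    k[:len(kernel.kernel)] = kernel.kernel
    k = np.roll(k, -(len(kernel.kernel) // 2))
    out = np.fft.irfft(np.fft.rfft(batch.data, axis=1) * np.fft.rfft(k),
                       n=T, axis=1).astype(np.float32)
    return PaddedBatch(out, batch.batch_index, batch.N_T, batch.n_t,
                       batch.start_sample)


def fit_whitening(rec: RecordingHandle, geom: ProbeGeometry,
                  n_neighbors: int = 32, epsilon: float | None = None,
                  cutoff: float = 300.0, N_T: int = 60000, n_t: int = 61,
                  max_batches: int = 100) -> WhiteningModel:
    """Estimate per-channel ZCA whitening vectors from CAR-ed, filtered data.

    Covariance is accumulated (biased, 1/T) over at most ``max_batches``
    evenly spaced batches. For each channel, the covariance of its
    ``n_neighbors`` nearest channels (Euclidean um distance, ties by
    index) is eigendecomposed and the transform U (S + eps I)^(-1/2) U^T
    is formed; only the row belonging to the channel is kept, embedded at
    its neighbors' columns in the full matrix.
    """
    nb = n_batches(rec, N_T)
    picks = np.unique(np.linspace(0, nb - 1, min(max_batches, nb)).astype(int))
    kern = build_highpass_kernel(cutoff, N_T, rec.sampling_rate)
    C = np.zeros((geom.n_channels, geom.n_channels))
    total = 0
    for bi in picks:
        b = load_batch(rec, geom, int(bi), N_T, n_t)
        b = apply_filter_fft(common_average_reference(b), kern)
        d = b.payload.astype(np.float64)
        # robust (spike-masked) covariance: samples where any channel
        # exceeds 6 robust s.d. are spike-dominated; including them makes
        # the ZCA transform actively suppress the spike subspace, which
        # shrinks spike norms relative to the detection thresholds
        mad = np.median(np.abs(d), axis=1, keepdims=True) / 0.6745 + 1e-12
        quiet = (np.abs(d) / mad).max(axis=0) < 6.0
        if quiet.sum() < d.shape[1] // 4:
            quiet = np.ones(d.shape[1], bool)
        d = d[:, quiet]
        C += d @ d.T
        total += d.shape[1]
    C /= total
    if not np.isfinite(C).all():
        raise ValueError("non-finite covariance")
    Sg, Ug = np.linalg.eigh(C)
    if epsilon is None:
        epsilon = 1e-6 * float(np.mean(Sg))
    n_nb = min(n_neighbors, geom.n_channels)
    W = np.zeros_like(C)
    for c in range(geom.n_channels):
        nbrs = geom.nearest_channels(c, n_nb)
        Cl = C[np.ix_(nbrs, nbrs)]
        S, U = np.linalg.eigh(Cl)
        Wl = U @ np.diag(1.0 / np.sqrt(np.maximum(S, 0) + epsilon)) @ U.T
        row = int(np.where(nbrs == c)[0][0])
        W[c, nbrs] = Wl[row]
    return WhiteningModel(W, n_nb, float(epsilon), C, Ug, Sg)


def apply_whitening_and_alignment(batch: PaddedBatch, model: WhiteningModel,
                                  shift_matrix: np.ndarray | None = None
                                  ) -> PaddedBatch:
    """Apply (W_white @ shift_matrix) in a single matrix multiplication.

    ``shift_matrix`` is the per-batch drift-interpolation operator
    (identity / None when drift correction is off). Combining the two
    linear maps first is bit-identical to applying them in sequence up to
    floating-point round-off.
    """
    M = model.W if shift_matrix is None else model.W @ shift_matrix
    if M.shape[1] != batch.data.shape[0]:
        raise ValueError("operator/channel dimension mismatch")
    out = (M @ batch.data).astype(np.float32)
    return PaddedBatch(out, batch.batch_index, batch.N_T, batch.n_t,
                       batch.start_sample)


def preprocess_batch(rec: RecordingHandle, geom: ProbeGeometry,
                     batch_index: int, kernel: FilterKernel,
                     model: WhiteningModel | None = None,
                     shift_matrix: np.ndarray | None = None,
                     N_T: int = 60000, n_t: int = 61) -> PaddedBatch:
    """On-demand CAR + filter (+ whitening/alignment) for one batch."""
    b = load_batch(rec, geom, batch_index, N_T, n_t)
    b = apply_filter_fft(common_average_reference(b), kernel)
    if model is not None:
        b = apply_whitening_and_alignment(b, model, shift_matrix)
    return b
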