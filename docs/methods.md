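# Methods

This note documents the models and procedures implemented in
`spikegraph`, the parameters that matter, the numerical choices made
where the design was genuinely open, and what the synthetic fixtures do
and do not demonstrate.

## Signal model and preprocessing

A recording is modeled as a sum of spatiotemporal spike waveforms,
spatially correlated noise, and shared artifacts, sampled as int16 at
`fs` (default 30 kHz) on a probe with known channel coordinates (µm).
Processing is per batch (`N_T = 60,000` samples, user-modifiable), with
`n_t = 61` samples of padding on each side so temporal operations are
valid at batch edges; the first/last pads repeat the edge sample.

* **CAR.** Per-channel temporal mean removal, then the cross-channel
  median at every sample. Order is fixed before filtering/whitening so
  large shared artifacts cannot leak across samples or channels. On
  probes with few channels the median absorbs part of any waveform that
  covers most of the probe; the simulator therefore scales unit
  footprints down with the probe (see *Fixtures*).
* **High-pass filter.** The impulse response of a 3rd-order Butterworth
  high-pass at 300 Hz (forward pass; order and cutoff are config keys)
  is captured as an FIR kernel and applied by FFT circular convolution;
  wrap-around artifacts are confined to the padding. The filter order
  and single-pass (causal) choice follow common extracellular practice;
  both are exposed in the configuration.
* **Whitening.** One ZCA vector per channel from the covariance of its
  32 nearest channels: `W = U (S + εI)^(−1/2) Uᵀ`, keeping only the
  center row. `ε` defaults to `1e−6 ×` the mean eigenvalue. The
  covariance is accumulated (biased, 1/T) over at most 100 evenly
  spaced batches **from spike-masked samples**: time points where any
  channel exceeds 6 robust standard deviations are excluded (falling
  back to all samples if fewer than 25% remain). Without masking, the
  spike subspace dominates the covariance on spike-dense data and the
  ZCA transform actively suppresses spike amplitudes relative to the
  detection thresholds — we verified on simulation that a noise-only
  covariance preserves whitened spike norms at `norm/0.76` while a
  spike-laden one halves them.

## Drift estimation and alignment

Vertical motion is estimated in advance in 2-s bins from spikes
detected with the simple-template bank (both polarities through
sign-inverted template pairs). Each bin's depth × amplitude histogram
(5-µm depth bins, 20 log-spaced amplitude bins) is registered against
the element-wise median histogram by maximizing cross-correlation over
vertical shifts with parabolic sub-bin refinement; bins with fewer than
10 spikes inherit their nearest estimated neighbor and are flagged.
With `n_blocks > 1`, per-depth-block refinement (±10 µm around the
rigid value) yields a nonrigid trace. The registration here is a
deliberately simple histogram-correlation scheme; more elaborate
iterative registration exists in the literature and would slot in
behind the same interface.

The per-bin estimate is then smoothed in time (Gaussian, σ = 10 s,
config key `smooth_s`). On desk-scale fixtures the per-bin registration
noise (~2 µm RMS) is comparable to medium drift itself, and applying it
raw injects per-batch waveform jitter that fragments template learning;
smoothing at a timescale well below the drift correlation length
removes the noise without distorting the motion. Shifts are
interpolated linearly across block centers to every channel (constant
extrapolation beyond the outer blocks). Alignment is a Gaussian-kriging
interpolation `K(nominal, shifted) (K(shifted, shifted) + λI)^(−1)`
with σ = 20 µm and λ = 0.01 — the same kernel family and values used
for waveform depth-interpolation in the simulator — composed with the
whitening matrix into a single per-batch operator. A zero shift returns
the exact identity.

## Simple templates and detection

The detection bank is the outer product of six unit-norm single-channel
shapes with isotropic Gaussian footprints at five sizes (σ ∈ {5, 10,
15, 20, 30} µm), placed on a grid that doubles the channel density in
each dimension (4 positions per site; 1,536 positions and 46,080
templates on a 384-site staggered probe). Shapes are learned by k-means
on threshold-crossing snippets of the recording, falling back to a
packaged parametric family (biphasic, sharp trough, 0.2–1 ms
trough-to-peak) when fewer than 500 snippets exist. Because shape and
footprint are separately unit norm, the variance explained at a time
point is the squared dot product, computed as a per-shape temporal
convolution followed by a footprint matrix product. Detections are
peaks above threshold 9 (whitened-norm units) that are maxima over ±20
samples and their 100 nearest positions — intentionally under-detecting
overlaps; matching pursuit recovers them later.

Each detection's patch (10 nearest channels × `n_t`) is re-anchored on
the trough of the energy-weighted multi-channel trace (3-point
smoothed). Two failure modes motivated this specific anchor: a raw
per-channel extremum flips ±1 sample on noise and splits each unit into
discrete alignment subclusters, and an unsigned energy peak can lock
onto the repolarization lobe and shift a unit's whole train by its
trough-to-peak time. A trough is preferred whenever it reaches a third
of the dominant positive deflection. Flank detections of large spikes
collapse onto the same anchor and are removed by keeping the largest of
any detections within 45 samples and 40 µm — the span of the
correlation tail that survives the detector's ±20-sample suppression
for the largest units.

## Template learning and matching pursuit

Per 40-µm vertical section, spike PC features (six components of an
uncentered PCA of trough-aligned snippets — the basis is applied to raw
patches, so it must span the waveforms themselves) are embedded on the union of member
channel sets and clustered with the graph method below, using the
bimodality criterion only (no correlogram information at this stage).
Cluster templates are means of the raw aligned patches — not PC
reconstructions, which measurably blur the waveforms — normalized to
unit norm with `x_W` the mean member projection. Templates are aligned
to the prototypes' trough-at-center convention and deduplicated when
their lagged correlation exceeds 0.9 and their scaled mean waveforms
differ by less than 45% (the difference two equal-norm templates have
at exactly the correlation bound, so the correlation is the binding
condition). Templates whose
temporal energy centers more than 6 samples left of the anchored trough
are discarded: they are truncation artifacts (patch clusters anchored
on the repolarization peak with the real trough outside the window)
that extract their parent unit's spikes one trough-to-peak time late.
Rank-3 factorization (truncated SVD per template) drives the
convolutional dot products.

Matching pursuit accepts peaks of `V = 2 x_W WᵀD − x_W²` above
threshold 8² that are local maxima over ±`n_t` samples across all
templates, subtracts `x_W W` at each accepted time, updates all
templates' dot products locally through precomputed lagged
cross-products, and repeats for up to 50 rounds (stopping early when no
peaks remain). Each subtraction reduces the residual norm by exactly
`V > 0`. Features are the PC projection of the residual patch plus the
spike's own template contribution in PC space — equivalent to the raw
patch with all *other* spikes removed.

## Graph clustering

All spikes of a section are 'left' nodes; a uniform subsample of
`n_sub = 25,000` (or all, when fewer) is copied to the 'right' side and
each left node links to its `k = 10` exact nearest landmarks
(brute-force Euclidean search). Under the bipartite modularity, left
labels given right labels decouple, so full parallel sweeps
(`σ_t = argmax_c (n_tc − γ k_t K_c^right / 2m)`, ties to the lowest
id) alternate sides from a k-means++ initialization until no label
changes (cap 30 sweeps); modularity is non-decreasing across sweeps by
construction. The initialization requests 200 seeds, capped at one seed
per 125 points so small sections keep the same per-seed occupancy as
the full-scale setting. The converged local minimum is deliberately
oversplit.

## Merging tree and curation

Clusters aggregate into a binary tree by repeatedly merging the pair
with the largest `γ̂_ij = 2m K_ij / (k_i k_j)`; the sequence of `γ̂`
is provably non-increasing toward the root. Traversal is top-down; a
node kept merged closes its subtree. At each node:

1. `γ̂ < 0.2` (a merge only favorable at very low resolution) splits
   unconditionally — this guards the top-level splits.
2. A refractory cross-correlogram between the two groups marks them as
   pieces of one neuron and merges them *even when the feature
   projection is bimodal* — the drift/nonstationarity case this
   criterion exists for. The one-neuron claim is verified on the merged
   autocorrelogram; if the merge would leave central violations, the
   node splits instead.
3. Otherwise the node splits iff the projection on the weighted
   regression axis between the groups is bimodal (`bimod > 0.5`).

**Correlogram statistics.** ACGs/CCGs are exact pair-difference
histograms in 1-ms bins over ±0.5 s (ACGs excluding self-pairs). With
`n_k` the counts in the central ±k bins, shoulder rate `R` the larger
of the left/right shoulder means (|δt| ∈ [50, 500] ms), `λ_k = (2k+1)R`
and `P_k = ½(1 + erf((n_k − λ_k)/√(ε + 2λ_k)))`, refractoriness
requires `R₁₂ = min_k n_k/λ_k` and `Q₁₂ = min_k P_k` below (0.25,
0.05) for CCGs and (0.10, 0.20) for ACGs. The central scan runs over
k = 2..10: the extractor's own peak rule empties the sub-millisecond
bins of *every* cluster pair (its collision dead time), so k = 0..1
carries no biological information — without this guard the merge tree
collapses whole sections.

**Bimodality.** The weighted least-squares axis (labels ±1, weights
`n₂/(n₁+n₂)`, `n₁/(n₁+n₂)`) is solved with a proportional ridge
(`1e−3 ×` mean diagonal), and projections are computed *out of fold*
(axis fit on one interleaved half, applied to the other): with few
points per feature dimension the in-sample axis separates any two
groups perfectly, and cross-validation removes exactly that overfit
while genuine separation survives. Projections are standardized
(out-of-fold projections shrink, and the fixed histogram assumes the
±1 scale of the in-sample fit; after standardizing, separated classes
sit near ±1 while an inseparable pair stays one central cloud), then
histogrammed in 400 bins on [−2, 2], Gaussian-smoothed (σ = 4 bins;
mass-conserving reflection); the trough is searched in bins [175, 225]
and `bimod = 1 − max(x_min/x₁, x_min/x₂)`.

After all sections, units with lagged waveform correlation above 0.5
are tested for global merges (largest first, refractory CCG plus the
merged-ACG verification; merged units retested until complete). Pieces
of one unit that are separated *in time* — drift epochs cut at a
section boundary — have an evidence-free CCG, so when the expected
central CCG count is below 2 and the waveform correlation exceeds 0.9,
the decision falls to the merged autocorrelogram alone. A unit
is labeled `good` when its ACG contamination `R₁₂ < 0.2`; units with
fewer than 50 spikes, or whose expected central count `(2K+1)R` is
below 2, cannot demonstrate a refractory period and are conservatively
`mua`.

## Simulator

The generator renders the conditions the sorter is tested under:

* **Waveform bank.** Parametric stand-ins for a recorded bank: biphasic
  shapes (Gaussian trough σ = 2–5 samples, trough-to-peak 0.2–1 ms,
  repolarization 0.25–0.6 of trough), elliptical Gaussian footprints
  (σ = 20–60 µm at full probe scale), per-channel propagation lag
  (0.02–0.08 samples/µm), sampled at 21 depths over ±20 µm. The bank is
  denoised by top-3 PC reconstruction across depths, normalized by the
  mean norm over depths, filtered at a depth-variation score of 0.25
  (distance between the −20 µm waveform and the +20 µm waveform shifted
  back by 40 µm), and kriging-upsampled ×100 in depth (σ = 20 µm,
  λ = 0.01). Somata are spread over distinct interior sites; the edge
  margin scales from 40 µm down to 20 µm on short probes so test probes
  keep several rows available.
* **Drift.** Five families on 9 probe positions: smoothed Gaussian
  noise in time (σ = 100 s) and across positions (σ = 2 positions),
  each component renormalized to unit s.d. before the per-position
  scale (0.4 / 0.26 / 0.58), then affinely rescaled to exact extremes
  (±7, ±18.5, ±4 µm); the step families add 30 µm at the midpoint; the
  fast family adds 300 difference-of-exponentials events (10 µm, 80 ms
  rise, 200 ms decay) on a 200-ms grid.
* **Spike trains.** Single units shuffle the ISIs of one of 64 packaged
  gamma-ISI reference sets (2.5-ms floor, lognormal rates with mean
  12.6 Hz, σ = 0.5, clipped at 30 Hz — the spread is kept moderate so
  the spike power per channel stays realistic); multi-units are Poisson
  with rates drawn from the same sets. Norms: single = 10 + Exp(mean
  7), optionally rejection-conditioned on a floor; multi = Uniform(4,
  10), in units of the 0.76-s.d. noise.
* **Rendering.** Spikes add the depth-appropriate waveform (nearest of
  the 2001 upsampled depths at the unit's drift); summation is exact
  under collisions. White Gaussian noise at 0.76 s.d. per channel; the
  frame is multiplied by the square root of an AR(1)-in-space channel
  correlation (ρ = 0.25 — a modest value, because ZCA whitening divides
  smooth spatial modes by roughly √((1+ρ)/(1−ρ)) and spike footprints
  are smooth), scaled ×200, clipped, and written int16 with a JSON
  ground-truth sidecar.

## Benchmarking

Each ground-truth unit is compared with its 40 closest detected units
(best-channel distance); spikes match greedily one-to-one within
0.2 ms, `FP` is the candidate's unmatched fraction, `FN` the truth's
missed fraction, and the best `score = 1 − FP − FN` is kept. Detected
units labeled `good` that match no truth unit count as false-positive
units. The drift-range summary is the 5th-to-95th percentile range of
the median drift across positions (linear-interpolation percentiles).

## Problem sizes and what the fixtures show

The test suite exercises the full pipeline on a 16-channel, 5-minute,
12-unit medium-drift rendering (~48,000 spikes), and unit tests on
smaller constructions; the drift-range statistics use the full
45-minute profiles. These sizes were chosen so the whole suite runs on
a single CPU core in minutes.

Passing on these fixtures demonstrates the algorithmic machinery —
detection, deconvolution, clustering, tree curation, scoring — under
controlled conditions. It does not demonstrate performance on real
recordings: the synthetic waveform family is far smoother than real
extracellular fields, within-unit amplitude is constant (no bursting
attenuation), noise is white rather than structured by distant neurons,
and a 16-channel probe leaves the correlogram statistics and the
whitening estimator much less evidence than a full-length shank.
Conversely, some small-probe artifacts (CAR absorbing broad footprints,
spike-dominated covariance) are *harsher* here than at full scale.

## Known limitations

* The registration step is a simplified histogram correlation; fast
  (sub-second) drift is invisible to the 2-s bins (200-ms bins exist in
  the simulator's fast profile precisely to expose this).
* Matching pursuit fixes each template's amplitude to `x_W`; units with
  strong amplitude modulation are split into amplitude clusters first
  and must be repaired by the tree.
* The matching-pursuit peak rule suppresses sub-millisecond collisions
  probe-wide within a round; unrecovered collisions bias the innermost
  correlogram bins (hence the k ≥ 2 scan) and put a floor on the false
  negative rate of densely colliding pairs.
* Cluster counts and merge decisions on recordings shorter than a few
  minutes are limited by correlogram evidence, not by the clustering
  itself.
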