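"""Merging tree over oversplit clusters and the split/merge criteria.

The graph clustering intentionally oversplits; merges are then decided on
a hierarchy ordered by the resolution value at which each merge becomes
favorable under the modularity cost. For clusters i, j with aggregated
between-edges K_ij, degrees k_i, k_j and total edge count m, the merge
turns favorable at

    gamma_hat_ij = 2 m K_ij / (k_i k_j)

and gamma_hat decreases monotonically toward the root. The tree is
traversed top-down: a refractory cross-correlogram (empty central
bins) marks the two groups as pieces of one neuron and merges them even
when their feature projection is bimodal; otherwise the split happens
iff the projection on the weighted regression axis between the two
groups is bimodal; top-level nodes whose merge is only favorable below
a small resolution (gamma_hat < 0.2) split unconditionally. Once a node
is kept merged, its subtree is not visited.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.special import erf

from .cluster import BipartiteGraph, ClusterAssignment

__all__ = ["MergeTree", "MergeNode", "BimodalityResult", "CorrelogramStats",
           "build_merge_tree", "bimodality_score", "compute_correlograms",
           "is_refractory", "traverse_tree", "global_merges", "label_good",
           "waveform_similarity"]

BIMOD_SPLIT_THRESHOLD = 0.5      # bimod score above which a node splits
MODULARITY_FLOOR = 0.2           # K_ij / m below which a split is automatic
CCG_THRESH = (0.25, 0.05)        # (R12, Q12) for a refractory CCG
ACG_THRESH = (0.10, 0.20)        # (R12, Q12) for a refractory ACG
GOOD_R12 = 0.2                   # ACG contamination bound for 'good' label
K_MAX = 10                       # widest central range checked (k = K_MIN..K_MAX)
K_MIN = 2                        # innermost ranges skipped: the extractor's
                                 # own +-n_t peak suppression empties the
                                 # sub-ms bins of every pair, so k < 2
                                 # carries no biological information


@dataclass
class MergeNode:
    node_id: int
    children: tuple[int, int] | None    # None for leaves
    gamma_hat: float
    K_between: float                    # K_ij at merge time
    degree: float                       # aggregated degree k_i
    leaves: list[int]


@dataclass
class MergeTree:
    nodes: list[MergeNode]
    n_leaves: int
    m: int

    @property
    def root(self) -> MergeNode:
        return self.nodes[-1]


def build_merge_tree(graph: BipartiteGraph, assign: ClusterAssignment
                     ) -> MergeTree:
    """Aggregate the graph over leaf clusters and merge greedily by
    descending gamma_hat.

    K[i, j] counts edges between clusters i and j (K[i, i] internal);
    k_i sums member degrees over both sides. Disconnected pairs have
    gamma_hat = 0 and merge last in deterministic (lowest-index) order.
    """
    n_cl = max(int(assign.left.max()), int(assign.right.max())) + 1
    m = graph.m
    rl = assign.right[graph.neighbors].ravel()
    ll = assign.left.repeat(graph.k)
    E = np.zeros((n_cl, n_cl))
    np.add.at(E, (ll, rl), 1.0)          # directed left-cluster -> right-cluster
    K = E + E.T                          # K_ij: edges between clusters i, j
    np.fill_diagonal(K, np.diag(E))      # K_ii: internal edges, counted once
    deg = (np.bincount(assign.left, weights=graph.left_degree.astype(float),
                       minlength=n_cl) +
           np.bincount(assign.right, weights=graph.right_degree.astype(float),
                       minlength=n_cl))
    nodes = [MergeNode(i, None, np.inf, 0.0, float(deg[i]), [i])
             for i in range(n_cl)]
    active = list(range(n_cl))
    Kw = K.copy()
    dg = deg.copy().astype(float)
    idmap = {i: i for i in range(n_cl)}       # active slot -> node id
    while len(active) > 1:
        best = (-1.0, None)
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                gh = 2 * m * Kw[i, j] / (dg[i] * dg[j]) if dg[i] * dg[j] > 0 \
                    else 0.0
                if gh > best[0]:
                    best = (gh, (ai, aj))
        gh, (ai, aj) = best
        i, j = active[ai], active[aj]
        nid = len(nodes)
        nodes.append(MergeNode(nid, (idmap[i], idmap[j]), float(gh),
                               float(Kw[i, j]), float(dg[i] + dg[j]),
                               nodes[idmap[i]].leaves +
                               nodes[idmap[j]].leaves))
        # aggregate j into i: K_ii' = K_ii + K_jj + K_ij; K_il' = K_il + K_jl
        kij = Kw[i, j]
        Kw[i, :] += Kw[j, :]
        Kw[:, i] += Kw[:, j]
        Kw[i, i] -= kij                  # row+col adds double-count K_ij
        dg[i] += dg[j]
        idmap[i] = nid
        del active[aj]
    return MergeTree(nodes, n_cl, m)


@dataclass
class BimodalityResult:
    axis: np.ndarray
    projections: np.ndarray
    histogram: np.ndarray
    smoothed: np.ndarray
    i_min: int
    x_min: float
    x1: float
    x2: float
    bimod: float


def bimodality_score(features_i: np.ndarray, features_j: np.ndarray,
                     n_bins: int = 400, smooth_sd: float = 4.0,
                     ridge: float = 1e-3) -> BimodalityResult:
    """Bimodality of projections on the weighted regression axis.

    Labels are -1 / +1 for the two clusters with weights w_-1 = n2/(n1+n2),
    w_+1 = n1/(n1+n2) to balance unequal cluster sizes; the weighted
    least-squares axis u is solved from the ridge-regularized normal
    equations. Projections are binned in ``n_bins``
    linearly spaced bins on [-2, 2] and Gaussian-smoothed (s.d. 4 bins);
    the trough is searched in the central bins [175, 225], peaks on
    either side, and bimod = 1 - max(x_min/x1, x_min/x2).
    """
    Xi = np.atleast_2d(np.asarray(features_i, float))
    Xj = np.atleast_2d(np.asarray(features_j, float))
    n1, n2 = len(Xi), len(Xj)
    if n1 == 0 or n2 == 0:
        raise ValueError("both clusters must be non-empty")
    X = np.vstack([Xi, Xj])
    y = np.concatenate([-np.ones(n1), np.ones(n2)])
    w = np.where(y < 0, n2 / (n1 + n2), n1 / (n1 + n2))

    def axis(sel):
        Xs, ys, ws = X[sel], y[sel], w[sel]
        A = (Xs * ws[:, None]).T @ Xs
        b = (Xs * ws[:, None]).T @ ys
        A = A + ridge * np.trace(A) / len(A) * np.eye(len(A))
        return np.linalg.solve(A, b)

    u = axis(np.ones(len(X), bool))
    # out-of-fold projections: with few points per feature dimension the
    # in-sample axis separates ANY two groups perfectly; projecting each
    # interleaved half on the axis fit to the other half removes that
    # overfit bimodality while genuine separation survives
    proj = np.empty(len(X))
    fold = np.arange(len(X)) % 2 == 0
    if fold.sum() >= 2 and (~fold).sum() >= 2:
        proj[~fold] = X[~fold] @ axis(fold)
        proj[fold] = X[fold] @ axis(~fold)
    else:
        proj = X @ u
    # standardize: the fixed [-2, 2] histogram assumes projections on
    # the +-1 scale the in-sample regression produces, but out-of-fold
    # projections shrink; after standardizing, genuinely separated
    # classes sit near -1/+1 (the spread IS the separation) while an
    # inseparable pair stays one central unimodal cloud
    sd = proj.std()
    if sd > 1e-12:
        proj = (proj - proj.mean()) / sd
    hist, _ = np.histogram(proj, bins=n_bins, range=(-2, 2))
    sm = gaussian_filter1d(hist.astype(float), smooth_sd, mode="reflect")
    lo, hi = int(n_bins * 175 / 400), int(n_bins * 225 / 400)
    i_min = lo + int(np.argmin(sm[lo:hi + 1]))
    x_min = sm[i_min]
    x1 = sm[:i_min].max() if i_min > 0 else 0.0
    x2 = sm[i_min + 1:].max() if i_min + 1 < n_bins else 0.0
    if x1 <= 0 or x2 <= 0:
        bimod = 0.0 if x_min > 0 else 1.0
    else:
        bimod = 1.0 - max(x_min / x1, x_min / x2)
    return BimodalityResult(u, proj, hist, sm, i_min, float(x_min),
                            float(x1), float(x2), float(bimod))


@dataclass
class CorrelogramStats:
    counts: np.ndarray          # 1-ms bins over [-0.5 s, 0.5 s]
    n_k: np.ndarray             # coincidences in the central -k..k range
    shoulder_rate: float        # R, max of left/right shoulder means
    R12: float
    Q12: float
    insufficient: bool = False


def compute_correlograms(times_a: np.ndarray, times_b: np.ndarray | None =
                         None, window: float = 0.5, bin_size: float = 1e-3,
                         k_max: int = K_MAX,
                         k_min: int = K_MIN) -> CorrelogramStats:
    """Auto- (times_b None) or cross-correlogram statistics.

    Spike times are in seconds. Counts are exact pair differences binned
    at 1 ms over [-0.5, 0.5] s; the ACG excludes zero-lag self pairs.
    R is the larger of the mean per-bin counts over the left/right
    shoulders (|dt| in [0.05, 0.5] s); R12 = min_k n_k / ((2k+1) R) and
    Q12 = min_k P_k with the Gaussian-approximated Poisson lower tail
    P_k = (1 + erf((n_k - lam_k) / sqrt(eps + 2 lam_k))) / 2, the min
    running over k = k_min..k_max (the innermost ranges are blind to the
    extractor's collision dead time and are skipped).
    """
    ta = np.sort(np.asarray(times_a, float))
    is_acg = times_b is None
    tb = ta if is_acg else np.sort(np.asarray(times_b, float))
    n_half = int(round(window / bin_size))
    edges = (np.arange(2 * n_half + 2) - n_half - 0.5) * bin_size
    counts = np.zeros(2 * n_half + 1)
    if len(ta) < 2 or len(tb) < (2 if is_acg else 1):
        return CorrelogramStats(counts, np.zeros(k_max + 1), 0.0, 0.0, 1.0,
                                insufficient=True)
    lo = np.searchsorted(tb, ta - window - bin_size)
    hi = np.searchsorted(tb, ta + window + bin_size)
    diffs = []
    for i in range(len(ta)):
        d = tb[lo[i]:hi[i]] - ta[i]
        diffs.append(d)
    d = np.concatenate(diffs) if diffs else np.empty(0)
    if is_acg:
        # remove one zero per spike (the self pair)
        h, _ = np.histogram(d, bins=edges)
        h[n_half] -= len(ta)
        counts = h.astype(float)
    else:
        counts, _ = np.histogram(d, bins=edges)
        counts = counts.astype(float)
    center = n_half
    n_k = np.array([counts[center - k:center + k + 1].sum()
                    for k in range(k_max + 1)])
    shoulder = int(round(0.05 / bin_size))
    left = counts[:center - shoulder + 1]
    right = counts[center + shoulder:]
    R = max(left.mean(), right.mean())
    eps = 1e-10
    lam = (2 * np.arange(k_max + 1) + 1) * R
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(lam > 0, n_k / lam, np.inf)
    P = 0.5 * (1.0 + erf((n_k - lam) / np.sqrt(eps + 2 * lam)))
    k_min = min(k_min, k_max)
    R12 = float(ratios[k_min:].min())
    Q12 = float(P[k_min:].min())
    return CorrelogramStats(counts, n_k, float(R), R12, Q12)


def is_refractory(stats: CorrelogramStats, mode: str = "ccg") -> bool:
    """Both R12 and Q12 must be under the mode's thresholds."""
    if stats.insufficient:
        return False
    r_thr, q_thr = CCG_THRESH if mode == "ccg" else ACG_THRESH
    return stats.R12 < r_thr and stats.Q12 < q_thr


def traverse_tree(tree: MergeTree, leaf_features: dict[int, np.ndarray],
                  leaf_times: dict[int, np.ndarray],
                  bimod_threshold: float = BIMOD_SPLIT_THRESHOLD,
                  modularity_floor: float = MODULARITY_FLOOR,
                  use_ccg: bool = True,
                  audit: list | None = None) -> np.ndarray:
    """Walk the tree top-down, deciding merge/split at each internal node.

    ``leaf_times`` are spike times in seconds per leaf cluster. Returns a
    final label per leaf; leaves sharing a label are merged.

    Decision order at each node: (1) a merge only favorable at very low
    resolution (gamma_hat below ``modularity_floor``) splits
    unconditionally — gamma_hat decreases monotonically toward the root,
    so this guarantees the top-level splits are made; (2) a refractory
    cross-correlogram (empty central bins) indicates the two groups are
    pieces of one neuron — they are merged even when the regression-axis
    projection is bimodal, which is exactly the drift/nonstationarity
    case the correlogram criterion exists for; (3) otherwise the node
    splits iff the projection is bimodal.
    """
    labels = np.arange(tree.n_leaves)
    next_label = [0]
    out = np.full(tree.n_leaves, -1)

    def assign(node: MergeNode, label: int):
        for lf in node.leaves:
            out[lf] = label

    def visit(node: MergeNode):
        if node.children is None:
            out[node.leaves[0]] = next_label[0]
            next_label[0] += 1
            return
        left, right = (tree.nodes[c] for c in node.children)
        ta = np.concatenate([leaf_times[lf] for lf in left.leaves])
        tb = np.concatenate([leaf_times[lf] for lf in right.leaves])
        forced = node.gamma_hat < modularity_floor
        ccg_refr = False
        bimod = np.nan
        if not forced and use_ccg:
            ccg_refr = is_refractory(compute_correlograms(ta, tb), "ccg")
            if ccg_refr:
                # one-neuron claim must survive the ACG check: pieces of a
                # single neuron merge into a clean autocorrelogram, while
                # a dominant unit straddling this node drags unrelated
                # spikes along and leaves central violations
                merged = np.sort(np.concatenate([ta, tb]))
                ccg_refr = is_refractory(compute_correlograms(merged),
                                         "acg")
        if forced:
            split = True
        elif ccg_refr:
            split = False       # mutual refractoriness: one neuron
        else:
            fa = np.vstack([leaf_features[lf] for lf in left.leaves])
            fb = np.vstack([leaf_features[lf] for lf in right.leaves])
            bimod = bimodality_score(fa, fb).bimod
            split = bimod > bimod_threshold
        if audit is not None:
            audit.append({"node": node.node_id, "gamma_hat": node.gamma_hat,
                          "ccg_refractory": ccg_refr,
                          "bimod": bimod, "decision":
                          "split" if split else "merge"})
        if split:
            visit(left)
            visit(right)
        else:
            assign(node, next_label[0])
            next_label[0] += 1

    visit(tree.root)
    return out


def waveform_similarity(w1: np.ndarray, w2: np.ndarray) -> float:
    """Maximum normalized correlation of two (channels x time) waveforms
    over all time lags."""
    n1 = np.linalg.norm(w1)
    n2 = np.linalg.norm(w2)
    if n1 == 0 or n2 == 0:
        return 0.0
    T = w1.shape[1]
    f1 = np.fft.rfft(w1, 2 * T, axis=1)
    f2 = np.fft.rfft(w2, 2 * T, axis=1)
    xc = np.fft.irfft(f1 * np.conj(f2), 2 * T, axis=1).sum(0)
    return float(xc.max() / (n1 * n2))


def global_merges(units: list[dict], fs: float,
                  similarity_threshold: float = 0.5) -> list[dict]:
    """Cross-section merges: test high-similarity pairs for a refractory
    CCG, largest units first.

    Each unit dict needs ``times`` (samples), ``waveform`` (channels x
    time). Merged units concatenate spikes and keep the larger unit's
    waveform. Completed units are removed from future testing.
    """
    units = [dict(u) for u in units]
    alive = list(range(len(units)))
    completed: set[int] = set()

    def sim(i, j):
        return waveform_similarity(units[i]["waveform"], units[j]["waveform"])

    order = sorted(alive, key=lambda i: -len(units[i]["times"]))
    i_ptr = 0
    while i_ptr < len(order):
        i = order[i_ptr]
        if i not in alive:
            i_ptr += 1
            continue
        merged_any = True
        while merged_any:
            merged_any = False
            cands = [(sim(i, j), j) for j in alive
                     if j != i and j not in completed]
            cands = sorted([c for c in cands if c[0] > similarity_threshold],
                           reverse=True)
            for s, j in cands:
                ccg = compute_correlograms(units[i]["times"] / fs,
                                           units[j]["times"] / fs)
                merged_t = np.sort(np.concatenate(
                    [units[i]["times"], units[j]["times"]])) / fs
                ok = is_refractory(ccg, "ccg")
                if ok:
                    # the one-neuron claim must leave the merged
                    # autocorrelogram clean
                    ok = is_refractory(compute_correlograms(merged_t),
                                       "acg")
                elif (2 * K_MAX + 1) * ccg.shoulder_rate < 2.0 and s > 0.9:
                    # temporally disjoint pieces (e.g. drift epochs cut
                    # at a section boundary): the CCG carries no
                    # evidence either way, so near-identical waveforms
                    # plus a clean merged autocorrelogram decide
                    ok = is_refractory(compute_correlograms(merged_t),
                                       "acg")
                if ok:
                    if len(units[j]["times"]) > len(units[i]["times"]):
                        units[i]["waveform"] = units[j]["waveform"]
                    units[i]["times"] = np.sort(np.concatenate(
                        [units[i]["times"], units[j]["times"]]))
                    alive.remove(j)
                    merged_any = True
                    break
        completed.add(i)
        i_ptr += 1
    return [units[i] for i in sorted(alive)]


def label_good(times_samples: np.ndarray, fs: float,
               min_spikes: int = 50, min_expected: float = 2.0) -> str:
    """'good' iff the ACG contamination estimate R12 < 0.2, else 'mua'.

    A unit with too few spikes — or whose expected central-bin count
    (2 K_max + 1) * R is below ``min_expected`` — cannot demonstrate a
    refractory period (its empty center is vacuous) and is labeled 'mua'
    conservatively.
    """
    if len(times_samples) < min_spikes:
        return "mua"
    stats = compute_correlograms(np.asarray(times_samples, float) / fs)
    if stats.insufficient or \
            (2 * K_MAX + 1) * stats.shoulder_rate < min_expected:
        return "mua"
    return "good" if stats.R12 < GOOD_R12 else "mua"
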