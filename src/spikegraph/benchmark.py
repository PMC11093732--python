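"""Ground-truth benchmarking: unit matching, scores and summaries.

A sorter's output is compared against simulated ground truth unit by
unit. Each ground-truth unit is compared with its 40 closest detected
units (by best-channel distance); spikes are matched greedily one-to-one
within a 0.2-ms tolerance, and the candidate maximizing

    score = 1 - FP - FN

is kept, where FP is the fraction of the candidate's spikes without a
match and FN the fraction of ground-truth spikes missed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MatchResult", "match_spike_trains", "match_units", "summarize",
           "drift_range"]


@dataclass
class MatchResult:
    truth_id: int
    matched_id: int          # -1 when no detected unit exists
    fp: float
    fn: float
    score: float


def _greedy_matches(truth: np.ndarray, det: np.ndarray, tol: float) -> int:
    """Number of one-to-one matches between two sorted spike-time arrays.

    Two-pointer sweep: each pair within ``tol`` is matched at most once,
    always consuming the earlier unmatched spike first.
    """
    i = j = n = 0
    nt, nd = len(truth), len(det)
    while i < nt and j < nd:
        dt = det[j] - truth[i]
        if abs(dt) <= tol:
            n += 1
            i += 1
            j += 1
        elif dt < 0:
            j += 1
        else:
            i += 1
    return n


def match_spike_trains(truth_times: np.ndarray, det_times: np.ndarray,
                       tol: float) -> tuple[float, float, float]:
    """(FP, FN, score) for one truth train vs one detected train (same units
    of time for both; ``tol`` in those units)."""
    truth_times = np.sort(np.asarray(truth_times, float))
    det_times = np.sort(np.asarray(det_times, float))
    if len(det_times) == 0 or len(truth_times) == 0:
        return 1.0, 1.0, -1.0
    n = _greedy_matches(truth_times, det_times, tol)
    fp = 1.0 - n / len(det_times)
    fn = 1.0 - n / len(truth_times)
    return fp, fn, 1.0 - fp - fn


def match_units(truth_units: list[dict], detected_units: list[dict],
                fs: float, tol_ms: float = 0.2,
                n_candidates: int = 40) -> list[MatchResult]:
    """Match each ground-truth unit to its best-scoring detected unit.

    ``truth_units`` and ``detected_units`` are lists of dicts with keys
    ``times`` (spike times in samples) and ``position`` (best-channel or
    center-of-mass position, um; scalar depth or (x, y)).
    """
    tol = tol_ms * 1e-3 * fs  # samples
    results: list[MatchResult] = []
    if not detected_units:
        return [MatchResult(i, -1, 1.0, 1.0, float("nan"))
                for i in range(len(truth_units))]
    det_pos = np.array([np.atleast_1d(u["position"]) for u in detected_units],
                       float)
    for ti, tu in enumerate(truth_units):
        tp = np.atleast_1d(np.asarray(tu["position"], float))
        d = np.linalg.norm(det_pos - tp[None, :], axis=1)
        order = np.argsort(d, kind="stable")[:n_candidates]
        best = MatchResult(ti, -1, 1.0, 1.0, -np.inf)
        for di in order:
            fp, fn, sc = match_spike_trains(tu["times"],
                                            detected_units[di]["times"], tol)
            if sc > best.score:
                best = MatchResult(ti, int(di), fp, fn, sc)
        results.append(best)
    return results


def summarize(matches: list[MatchResult], good_flags: dict[int, bool],
              score_threshold: float = 0.8) -> dict:
    """Counts of matched units, matched-and-good units, and false-positive
    units (good-labeled detected units matching no ground truth)."""
    hit = [m for m in matches if m.score > score_threshold]
    matched_ids = {m.matched_id for m in hit}
    n_matched_good = sum(1 for m in hit if good_flags.get(m.matched_id, False))
    fp_units = [u for u, g in good_flags.items()
                if g and u not in matched_ids]
    return {
        "n_truth": len(matches),
        "n_matched": len(hit),
        "n_matched_good": n_matched_good,
        "n_false_positive_units": len(fp_units),
        "false_positive_units": sorted(fp_units),
    }


def drift_range(trace: np.ndarray) -> float:
    """Drift range of a (time x positions) trace, in um.

    Median across positions at every time bin, then the difference between
    the 95th and 5th percentile over time (linear-interpolation
    percentiles).
    """
    trace = np.asarray(trace, float)
    med = np.median(trace, axis=1) if trace.ndim == 2 else trace
    return float(np.percentile(med, 95) - np.percentile(med, 5))
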