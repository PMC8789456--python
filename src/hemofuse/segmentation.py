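"""Multilevel Otsu thresholding driven by the seagull optimizer.

Otsu's criterion picks thresholds t_1 < ... < t_k that maximise the
between-class variance of the k+1 intensity segments they induce:

    d(t_1..t_k) = sum_{n < m} w_n w_m (u_n - u_m)^2

with w_n the probability mass and u_n the mean intensity of segment n
(segment n covers intensities t_n < i <= t_{n+1}, t_0 = -1).  Empty
segments contribute 0.  For k = 1 this reduces to the classic
w_0 w_1 (u_0 - u_1)^2 and satisfies the decomposition
sigma^2_total = sigma^2_within + sigma^2_between at every threshold.

``otsu_exhaustive`` enumerates every threshold tuple (k <= 3) and is the
global-optimum oracle; ``otsu_soa`` searches the same criterion with the
seagull optimizer, which is how the pipeline scales past enumeration.
Hemorrhage is hyperdense on CT, so the lesion mask defaults to the
highest-intensity segment.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from .optimizers import ObjectiveSpec, OptimizeResult, SOAParams, soa_optimize

__all__ = [
    "histogram",
    "class_stats",
    "between_class_variance",
    "within_class_variance",
    "total_variance",
    "otsu_exhaustive",
    "otsu_soa",
    "apply_thresholds",
    "lesion_mask",
]


def histogram(image: np.ndarray, levels: int = 256) -> np.ndarray:
    """Normalised intensity histogram p_i, i in {0..levels-1}."""
    arr = np.asarray(image)
    counts = np.bincount(arr.reshape(-1), minlength=levels).astype(float)
    if counts.size > levels:
        raise ValueError("image holds intensities outside [0, levels-1]")
    return counts / counts.sum()


def _check_thresholds(thresholds, levels: int) -> np.ndarray:
    t = np.asarray(thresholds, dtype=int)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("need at least one threshold")
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"thresholds must be strictly increasing, got {t}")
    if t[0] < 0 or t[-1] > levels - 2:
        raise ValueError(f"thresholds must lie in [0, {levels - 2}], got {t}")
    return t


def class_stats(hist: np.ndarray, thresholds) -> tuple[np.ndarray, np.ndarray]:
    """Per-segment mass w_n and mean u_n; empty segments get mass 0, mean 0."""
    hist = np.asarray(hist, dtype=float)
    t = _check_thresholds(thresholds, hist.size)
    edges = np.concatenate(([-1], t, [hist.size - 1]))
    levels = np.arange(hist.size)
    w = np.empty(t.size + 1)
    u = np.empty(t.size + 1)
    for n in range(t.size + 1):
        sel = slice(edges[n] + 1, edges[n + 1] + 1)
        w[n] = hist[sel].sum()
        u[n] = (levels[sel] * hist[sel]).sum() / w[n] if w[n] > 0 else 0.0
    return w, u


def between_class_variance(hist: np.ndarray, thresholds) -> float:
    """d(t) = sum over segment pairs of w_n w_m (u_n - u_m)^2."""
    w, u = class_stats(hist, thresholds)
    d = 0.0
    for n in range(w.size - 1):
        for m in range(n + 1, w.size):
            d += w[n] * w[m] * (u[n] - u[m]) ** 2
    return float(d)


def within_class_variance(hist: np.ndarray, thresholds) -> float:
    hist = np.asarray(hist, dtype=float)
    t = _check_thresholds(thresholds, hist.size)
    edges = np.concatenate(([-1], t, [hist.size - 1]))
    levels = np.arange(hist.size)
    total = 0.0
    for n in range(t.size + 1):
        sel = slice(edges[n] + 1, edges[n + 1] + 1)
        w = hist[sel].sum()
        if w > 0:
            u = (levels[sel] * hist[sel]).sum() / w
            total += ((levels[sel] - u) ** 2 * hist[sel]).sum()
    return float(total)


def total_variance(hist: np.ndarray) -> float:
    hist = np.asarray(hist, dtype=float)
    levels = np.arange(hist.size)
    mu = (levels * hist).sum()
    return float(((levels - mu) ** 2 * hist).sum())


def otsu_exhaustive(hist: np.ndarray, k: int) -> tuple[np.ndarray, float]:
    """Global argmax of the between-class variance by full enumeration.

    Supports k in {1, 2, 3}; ties resolved to the lexicographically
    smallest threshold tuple.  Thresholds range over 0 < t_1 < ... < t_k
    <= L-2.
    """
    hist = np.asarray(hist, dtype=float)
    if k not in (1, 2, 3):
        raise ValueError(f"exhaustive enumeration supports k in {{1,2,3}}, got {k}")
    from math import comb

    if comb(hist.size - 2, k) > 300_000:
        raise ValueError(
            f"enumeration budget exceeded for k={k} at L={hist.size}; "
            "use otsu_soa or a coarser histogram"
        )
    candidates = range(1, hist.size - 1)
    best_t, best_d = None, -np.inf
    for tup in combinations(candidates, k):
        d = between_class_variance(hist, tup)
        if d > best_d + 1e-15:
            best_d, best_t = d, tup
    return np.asarray(best_t, dtype=int), float(best_d)


def _soa_objective(hist: np.ndarray, k: int) -> ObjectiveSpec:
    levels = hist.size

    def fitness(position: np.ndarray) -> float:
        t = np.sort(np.rint(position).astype(int))
        if np.any(np.diff(t) <= 0):
            return -np.inf  # degenerate candidate: duplicate thresholds
        return between_class_variance(hist, t)

    return ObjectiveSpec(fitness, [(1.0, float(levels - 2))] * k, sense="maximize")


def otsu_soa(
    image: np.ndarray,
    k: int,
    params: SOAParams | None = None,
    levels: int = 256,
) -> tuple[np.ndarray, float, OptimizeResult]:
    """SOA search over k continuous threshold coordinates in [1, L-2].

    Candidates are sorted then rounded to integers before evaluation;
    candidates whose rounded thresholds collide are assigned the worst
    fitness rather than repaired.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= levels - 1:
        raise ValueError(f"k={k} leaves no valid thresholds for L={levels}")
    params = params or SOAParams()
    hist = histogram(image, levels)
    result = soa_optimize(_soa_objective(hist, k), params)
    t = np.sort(np.rint(result.position).astype(int))
    if np.any(np.diff(t) <= 0):  # pathological landscape: fall back to a grid scan
        t, score = otsu_exhaustive(hist, min(k, 3))
        return t, score, result
    return t, between_class_variance(hist, t), result


def apply_thresholds(image: np.ndarray, thresholds, levels: int = 256) -> np.ndarray:
    """Label map: pixel v gets label n where t_n < v <= t_{n+1} (t_0 = -1)."""
    t = _check_thresholds(thresholds, levels)
    return np.searchsorted(t, np.asarray(image), side="left").astype(np.int64)


def lesion_mask(
    labels: np.ndarray, n_segments: int | None = None, segment: int | None = None
) -> np.ndarray:
    """Binary lesion mask — by default the highest-intensity segment,
    acute haemorrhage being hyperdense on CT."""
    if segment is None:
        segment = (n_segments - 1) if n_segments is not None else int(labels.max())
    return labels == segment
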