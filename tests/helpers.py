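"""Independent brute-force oracles used across the test suite.

These deliberately avoid the library code paths they check: Otsu by
exhaustive threshold sweep, connected components by BFS flood fill,
staircase segmentation by full enumeration, KS by an explicit ECDF sweep.
"""

from collections import deque
from itertools import combinations

import numpy as np


def brute_otsu_threshold(values: np.ndarray, n_bins: int = 256) -> float:
    """Otsu cutoff by exhaustive search over all histogram bins: for every
    candidate split of the n-bin histogram, compute the between-class
    variance w0 * w1 * (mu0 - mu1)^2 from the bin counts and centres, and
    return the centre of the bin with the maximal value (first bin wins
    ties)."""
    values = np.asarray(values, dtype=float).ravel()
    counts, edges = np.histogram(values, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    total = counts.sum()
    best_var, best_center = -1.0, centers[0]
    for k in range(1, n_bins):
        n0, n1 = counts[:k].sum(), counts[k:].sum()
        if n0 == 0 or n1 == 0:
            continue
        mu0 = (counts[:k] * centers[:k]).sum() / n0
        mu1 = (counts[k:] * centers[k:]).sum() / n1
        var = (n0 / total) * (n1 / total) * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_center = var, centers[k - 1]
    return float(best_center)


def brute_otsu_mask(values: np.ndarray, n_bins: int = 256) -> np.ndarray:
    """Upper-class mask of the exhaustive-sweep Otsu threshold."""
    values = np.asarray(values, dtype=float)
    return values > brute_otsu_threshold(values, n_bins)


def binned_between_class_variance(
    values: np.ndarray, threshold: float, n_bins: int = 256
) -> float:
    """Between-class variance of the n-bin histogram split at the bin
    whose centre is nearest ``threshold`` (the quantity the Otsu sweep
    maximizes)."""
    values = np.asarray(values, dtype=float).ravel()
    counts, edges = np.histogram(values, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    k = int(np.argmin(np.abs(centers - threshold))) + 1
    n0, n1 = counts[:k].sum(), counts[k:].sum()
    if n0 == 0 or n1 == 0:
        return 0.0
    total = counts.sum()
    mu0 = (counts[:k] * centers[:k]).sum() / n0
    mu1 = (counts[k:] * centers[k:]).sum() / n1
    return float((n0 / total) * (n1 / total) * (mu0 - mu1) ** 2)


def flood_fill_count(mask: np.ndarray, connectivity: int = 26) -> int:
    """Connected-component count via BFS flood fill."""
    mask = np.asarray(mask, dtype=bool)
    ndim = mask.ndim
    if ndim == 3:
        rank = {6: 1, 18: 2, 26: 3}[connectivity]
    else:
        rank = {4: 1, 8: 2}[connectivity]
    offsets = []
    for delta in np.ndindex(*(3,) * ndim):
        d = np.array(delta) - 1
        nz = int(np.sum(d != 0))
        if 0 < nz <= rank:
            offsets.append(tuple(d))
    seen = np.zeros(mask.shape, dtype=bool)
    count = 0
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        count += 1
        q = deque([start])
        seen[start] = True
        while q:
            p = q.popleft()
            for off in offsets:
                nb = tuple(p[i] + off[i] for i in range(ndim))
                if all(0 <= nb[i] < mask.shape[i] for i in range(ndim)):
                    if mask[nb] and not seen[nb]:
                        seen[nb] = True
                        q.append(nb)
    return count


def exhaustive_staircase_count(
    amps: np.ndarray, noise_sd: float, min_step: float
) -> int:
    """Input count via exhaustive segmentation (all breakpoint subsets).

    Minimizes sum of within-segment SSE plus ``2 noise_sd^2 ln(n)`` per
    segment over every contiguous segmentation, then applies the same
    plateau-merge and step-count definition as the analysis: merge
    adjacent plateaus closer than ``min_step`` (smallest gap first,
    weighted means), prepend a zero level if needed, count upward
    transitions.
    """
    amps = np.asarray(amps, dtype=float)
    n = len(amps)
    penalty = 2.0 * noise_sd**2 * np.log(n)

    def sse(seg: np.ndarray) -> float:
        return float(np.sum((seg - seg.mean()) ** 2))

    best_cost, best_levels = np.inf, None
    for k in range(n):  # k interior breakpoints
        for bps in combinations(range(1, n), k):
            bounds = [0, *bps, n]
            cost = penalty * (len(bounds) - 1)
            levels = []
            for i, j in zip(bounds[:-1], bounds[1:]):
                seg = amps[i:j]
                cost += sse(seg)
                levels.append((float(seg.mean()), j - i))
            if cost < best_cost - 1e-12:
                best_cost, best_levels = cost, levels

    levels = list(best_levels)
    while len(levels) > 1:
        gaps = [abs(levels[i + 1][0] - levels[i][0]) for i in range(len(levels) - 1)]
        i = int(np.argmin(gaps))
        if gaps[i] >= min_step:
            break
        (m1, c1), (m2, c2) = levels[i], levels[i + 1]
        levels[i : i + 2] = [((m1 * c1 + m2 * c2) / (c1 + c2), c1 + c2)]
    vals = [lv for lv, _ in levels]
    if abs(vals[0]) >= min_step:
        vals = [0.0] + vals
    return int(np.sum(np.diff(vals) > 0))


def ks_statistic_bruteforce(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample KS statistic as an explicit sup over all ECDF
    evaluation points."""
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    best = 0.0
    for x in np.concatenate([a, b]):
        fa = np.sum(a <= x) / len(a)
        fb = np.sum(b <= x) / len(b)
        best = max(best, abs(fa - fb))
    return float(best)
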