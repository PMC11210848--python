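"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (pure-Python loops, exhaustive
enumeration) and shares no code path with the package implementation.
"""

from __future__ import annotations

import itertools
import math
from collections import deque

import numpy as np
from scipy import stats


# --- k-NN + leave-one-participant-out searchlight -----------------------


def knn_vote(train, labels, test_row, k):
    """Reference k-NN single prediction: stable (distance, index) order,
    majority vote, vote ties -> nearest label, then lower class code."""
    dists = sorted(
        (math.dist(test_row, row), idx) for idx, row in enumerate(train)
    )
    top = [labels[idx] for _, idx in dists[:k]]
    counts = {}
    for lab in top:
        counts[lab] = counts.get(lab, 0) + 1
    best = max(counts.values())
    tied = sorted(c for c, n in counts.items() if n == best)
    if len(tied) == 1:
        return tied[0]
    nearest = labels[dists[0][1]]
    return nearest if nearest in tied else tied[0]


def searchlight_oracle(pattern_sets, radius_mm, k):
    """Per-voxel pooled LOPO k-NN accuracy by exhaustive loops."""
    grid = pattern_sets[0].grid
    mask = pattern_sets[0].mask
    vs = grid.voxel_size
    coords = np.argwhere(mask)
    col_of = {tuple(c): i for i, c in enumerate(coords)}

    acc = np.full(grid.shape, np.nan)
    for center in coords:
        cols = []
        for other in coords:
            d = math.sqrt(sum(((center[a] - other[a]) * vs[a]) ** 2 for a in range(3)))
            if d <= radius_mm:
                cols.append(col_of[tuple(other)])
        correct = total = 0
        for held in range(len(pattern_sets)):
            train_rows, train_labels = [], []
            for s_idx, ps in enumerate(pattern_sets):
                if s_idx == held:
                    continue
                for r in range(ps.data.shape[0]):
                    train_rows.append(ps.data[r, cols])
                    train_labels.append(0 if ps.labels["time_point"][r] == "baseline" else 1)
            ps = pattern_sets[held]
            for r in range(ps.data.shape[0]):
                truth = 0 if ps.labels["time_point"][r] == "baseline" else 1
                pred = knn_vote(train_rows, train_labels, ps.data[r, cols], k)
                correct += pred == truth
                total += 1
        acc[tuple(center)] = correct / total
    return acc


# --- connected components ------------------------------------------------


def flood_fill_components(mask, connectivity):
    """Connected components of a 3D boolean mask as frozensets of voxels."""
    if connectivity == 6:
        neigh = [
            (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)
        ]
    else:
        neigh = [
            (di, dj, dk)
            for di in (-1, 0, 1)
            for dj in (-1, 0, 1)
            for dk in (-1, 0, 1)
            if (di, dj, dk) != (0, 0, 0)
        ]
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    comps = []
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        queue = deque([start])
        seen[start] = True
        comp = []
        while queue:
            v = queue.popleft()
            comp.append(v)
            for off in neigh:
                w = tuple(v[a] + off[a] for a in range(3))
                if all(0 <= w[a] < mask.shape[a] for a in range(3)) and mask[w] and not seen[w]:
                    seen[w] = True
                    queue.append(w)
        comps.append(frozenset(comp))
    return set(comps)


# --- exact Wilcoxon enumerations -----------------------------------------


def signed_rank_p_enumeration(differences):
    """Two-sided exact p by enumerating all 2^n sign assignments."""
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = stats.rankdata(np.abs(d))
    w_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w_plus = sum(r for r, s in zip(ranks, signs) if s)
        if w_plus <= w_obs + 1e-9:
            count += 1
    return min(1.0, 2.0 * count / 2**n)


def rank_sum_p_enumeration(a, b):
    """Two-sided exact p by enumerating all rank subsets (no ties)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    w_obs = ranks[: a.size].sum()
    n = pooled.size
    lo = hi = total = 0
    for subset in itertools.combinations(range(1, n + 1), a.size):
        w = sum(subset)
        total += 1
        lo += w <= w_obs + 1e-9
        hi += w >= w_obs - 1e-9
    return min(1.0, 2.0 * min(lo, hi) / total)


def signed_rank_exact_size(n, alpha=0.05):
    """Achieved type-I error of the exact two-sided signed-rank test at
    level alpha for untied samples of size n, from full enumeration."""
    ranks = np.arange(1, n + 1)
    w_plus_all = np.array(
        [sum(r for r, s in zip(ranks, signs) if s) for signs in itertools.product((0, 1), repeat=n)]
    )
    total_sum = n * (n + 1) / 2
    rejections = 0
    for w_plus in w_plus_all:
        w = min(w_plus, total_sum - w_plus)
        p = min(1.0, 2.0 * np.mean(w_plus_all <= w + 1e-9))
        rejections += p < alpha
    return rejections / w_plus_all.size


def rank_sum_exact_size(n_a, n_b, alpha=0.05):
    """Achieved type-I error of the exact two-sided rank-sum test."""
    n = n_a + n_b
    sums = np.array([sum(c) for c in itertools.combinations(range(1, n + 1), n_a)])
    rejections = 0
    for w in sums:
        lo = np.mean(sums <= w + 1e-9)
        hi = np.mean(sums >= w - 1e-9)
        p = min(1.0, 2.0 * min(lo, hi))
        rejections += p < alpha
    return rejections / sums.size


# --- discrete Gaussian kernel --------------------------------------------


def gaussian_kernel_1d(sigma_vox, truncate=4.0):
    """Sampled, normalised 1D Gaussian kernel as used by separable filters."""
    radius = int(truncate * sigma_vox + 0.5)
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma_vox) ** 2)
    return k / k.sum()
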