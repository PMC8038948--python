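"""Independent reference computations used to check the implementation.

These deliberately avoid the package's own code paths: the greedy-matching
oracle re-scans a dense distance matrix, the permutation oracle enumerates
label assignments exhaustively, and the disc-distance CDF comes from
numeric integration of the classical line-picking density.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.integrate import quad
from scipy.spatial.distance import cdist


def disc_distance_cdf(d: float, radius: float) -> float:
    """P(|X - Y| <= d) for X, Y independent uniform in a disc of given radius.

    Numeric integration of the disc line-picking density for the unit disc,
    scaled by ``radius``.
    """

    def pdf(s: float) -> float:
        return (4 * s / np.pi) * np.arccos(s / 2) - (2 * s**2 / np.pi) * np.sqrt(
            1 - s**2 / 4
        )

    upper = min(max(d / radius, 0.0), 2.0)
    return quad(pdf, 0.0, upper)[0]


def greedy_pairs_bruteforce(A, B):
    """O(n^3) greedy exclusive closest-pair matching.

    Repeatedly finds the minimum of the remaining distance matrix (ties
    broken by lowest idA then idB) and removes both members.  Returns a
    list of (idA, idB, distance).
    """
    pa = A[["x", "y"]].to_numpy(dtype=float)
    pb = B[["x", "y"]].to_numpy(dtype=float)
    ida = A["id"].to_numpy()
    idb = B["id"].to_numpy()
    d = cdist(pa, pb)
    aliveA = list(range(len(pa)))
    aliveB = list(range(len(pb)))
    out = []
    while aliveA and aliveB:
        best = None
        for i in aliveA:
            for j in aliveB:
                key = (d[i, j], ida[i], idb[j])
                if best is None or key < best[0]:
                    best = (key, i, j)
        (dist, ia, ib), i, j = best
        out.append((ia, ib, dist))
        aliveA.remove(i)
        aliveB.remove(j)
    return out


def exact_label_permutation_p(
    positions_A: np.ndarray,
    positions_B: np.ndarray,
    d_min: float,
    strict: bool = False,
) -> float:
    """Exactly enumerated label-permutation null probability.

    Enumerates every way of assigning kA of the pooled positions to channel
    A and returns the fraction of assignments whose minimum cross-channel
    distance is <= d_min (or < for strict).
    """
    pooled = np.concatenate([positions_A, positions_B], axis=0)
    k, kA = len(pooled), len(positions_A)
    D = cdist(pooled, pooled)
    hits = 0
    total = 0
    idx = set(range(k))
    rtol = 1e-12  # exact ties with d_min must not flip on 1-ulp noise
    for a_set in combinations(range(k), kA):
        b_set = sorted(idx - set(a_set))
        dmin = D[np.ix_(a_set, b_set)].min()
        hits += (dmin < d_min * (1 - rtol)) if strict else (dmin <= d_min * (1 + rtol))
        total += 1
    return hits / total


def neighbor_counts_bruteforce(pos, frames, radius, window):
    """Spatio-temporal neighbor counts (excluding self) by double loop."""
    n = len(pos)
    counts = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if (
                np.hypot(pos[i, 0] - pos[j, 0], pos[i, 1] - pos[j, 1]) <= radius
                and abs(frames[i] - frames[j]) <= window
            ):
                counts[i] += 1
    return counts
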