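"""Independent brute-force oracles used only by the tests.

These deliberately avoid scipy/sklearn code paths: tau-b by explicit
O(n^2) pair counting with tie corrections, and Ward.D2 clustering by naive
greedy agglomeration on cluster centroids (Ward's exact merge cost).
"""

from __future__ import annotations

import math

import numpy as np


def tau_b_oracle(x, y) -> float:
    """Kendall tau-b by explicit concordant/discordant pair counting."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    concordant = discordant = ties_x = ties_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0 and dy == 0:
                ties_x += 1
                ties_y += 1
            elif dx == 0:
                ties_x += 1
            elif dy == 0:
                ties_y += 1
            elif dx * dy > 0:
                concordant += 1
            else:
                discordant += 1
    n0 = n * (n - 1) // 2
    denom = math.sqrt((n0 - ties_x) * (n0 - ties_y))
    return (concordant - discordant) / denom


def naive_ward_d2(X: np.ndarray, labels: list[str]):
    """Greedy Ward agglomeration: at each step merge the pair of clusters
    minimizing sqrt(2 n_i n_j / (n_i + n_j)) * ||centroid_i - centroid_j||
    (the exact increase-of-within-cluster-ESS criterion on unsquared scale).

    Returns (clades, heights): the merged leaf sets in merge order and the
    merge costs.
    """
    clusters = [
        {"leaves": frozenset([lab]), "centroid": np.asarray(row, dtype=float), "n": 1}
        for lab, row in zip(labels, X)
    ]
    clades, heights = [], []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a, b = clusters[i], clusters[j]
                cost = math.sqrt(2 * a["n"] * b["n"] / (a["n"] + b["n"])) * float(
                    np.linalg.norm(a["centroid"] - b["centroid"])
                )
                if best is None or cost < best[0]:
                    best = (cost, i, j)
        cost, i, j = best
        a, b = clusters[i], clusters[j]
        merged = {
            "leaves": a["leaves"] | b["leaves"],
            "centroid": (a["n"] * a["centroid"] + b["n"] * b["centroid"]) / (a["n"] + b["n"]),
            "n": a["n"] + b["n"],
        }
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
        clades.append(merged["leaves"])
        heights.append(cost)
    return clades, heights
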