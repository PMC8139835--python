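"""Independent brute-force oracles used by multiple test modules."""

import itertools

import numpy as np


def brute_force_complete_linkage(points, k):
    """O(n^3) reference agglomeration: repeatedly merge the two clusters
    with the smallest maximum pairwise Euclidean distance."""
    clusters = [[i] for i in range(len(points))]
    while len(clusters) > k:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = max(
                np.linalg.norm(points[i] - points[j])
                for i in clusters[a]
                for j in clusters[b]
            )
            if best is None or d < best[0]:
                best = (d, a, b)
        _, a, b = best
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    labels = np.empty(len(points), dtype=int)
    for ci, members in enumerate(clusters):
        labels[members] = ci
    return labels
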