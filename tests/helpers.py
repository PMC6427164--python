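"""Shared independent oracles for the test suite."""

import itertools

import numpy as np
from scipy.spatial.distance import cdist


def brute_force_assign(prev, dets, gate):
    """Exhaustive minimum-total-distance matching of maximal size.

    Enumerates every injective mapping of k tracks to k detections for
    k from min(n, m) downward, keeping only mappings whose pairs all
    lie within the gate; returns (size, cost) of the best matching.
    Independent of the assignment solver under test.
    """
    prev = np.asarray(prev, float).reshape(-1, 2)
    dets = np.asarray(dets, float).reshape(-1, 2)
    n, m = len(prev), len(dets)
    if n == 0 or m == 0:
        return 0, 0.0
    dist = cdist(prev, dets)
    for k in range(min(n, m), -1, -1):
        best = None
        for tracks in itertools.combinations(range(n), k):
            for ds in itertools.permutations(range(m), k):
                if all(dist[i, j] <= gate for i, j in zip(tracks, ds)):
                    cost = sum(dist[i, j] for i, j in zip(tracks, ds))
                    if best is None or cost < best:
                        best = cost
        if best is not None:
            return k, best
    return 0, 0.0
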