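"""Independent oracles used by the test suite.

These deliberately take different computational routes from the library:
exhaustive pairwise search with per-class direct means for the three-class
threshold, and scipy.sparse.csgraph single-source Dijkstra for seeded
propagation.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra as _dijkstra


def brute_force_three_class(counts, centers):
    """Exhaustive search over boundary pairs; classes end on occupied bins.

    Returns (i, j) bin-boundary indices maximising between-class variance,
    first maximum in (i, j) order.
    """
    counts = np.asarray(counts, dtype=float)
    centers = np.asarray(centers, dtype=float)
    n = counts.size
    w = counts / counts.sum()
    best_val, best_pair = -np.inf, None
    for i in range(n - 2):
        if counts[i] <= 0:
            continue
        for j in range(i + 1, n - 1):
            if counts[j] <= 0:
                continue
            val = 0.0
            ok = True
            for sl in (slice(0, i + 1), slice(i + 1, j + 1), slice(j + 1, n)):
                W = w[sl].sum()
                if W <= 0:
                    ok = False
                    break
                mu = (w[sl] * centers[sl]).sum() / W
                val += W * mu * mu
            if ok and val > best_val:
                best_val, best_pair = val, (i, j)
    return best_pair


def dijkstra_propagation(image, nuclei, lambda_reg, connectivity=8):
    """Nearest-seed labeling under the sqrt(lambda*s^2 + dI^2) step cost.

    Builds the full pixel graph and runs scipy's Dijkstra from every seed
    pixel; each pixel takes the label minimising (distance, label)
    lexicographically. Seed pixels keep their own labels.
    """
    image = np.asarray(image, dtype=float)
    nuclei = np.asarray(nuclei)
    h, w = image.shape
    n = h * w
    steps = [(-1, -1, 2.0), (-1, 0, 1.0), (-1, 1, 2.0), (0, -1, 1.0),
             (0, 1, 1.0), (1, -1, 2.0), (1, 0, 1.0), (1, 1, 2.0)]
    if connectivity == 4:
        steps = [s for s in steps if s[2] == 1.0]
    rows, cols, vals = [], [], []
    flat = image.ravel()
    ys, xs = np.mgrid[0:h, 0:w]
    for dy, dx, s2 in steps:
        ny, nx = ys + dy, xs + dx
        ok = (ny >= 0) & (ny < h) & (nx >= 0) & (nx < w)
        src = (ys * w + xs)[ok]
        dst = (ny * w + nx)[ok]
        di = flat[src] - flat[dst]
        vals.append(np.sqrt(lambda_reg * s2 + di * di))
        rows.append(src)
        cols.append(dst)
    graph = coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    ).tocsr()

    seeds = np.flatnonzero(nuclei.ravel() > 0)
    seed_labels = nuclei.ravel()[seeds]
    dist = _dijkstra(graph, indices=seeds)
    labels = np.unique(seed_labels)
    per_label = np.vstack([dist[seed_labels == lab].min(axis=0) for lab in labels])
    out = np.zeros(n, dtype=np.int32)
    reachable = np.isfinite(per_label).any(axis=0)
    # argmin returns the first (lowest-label) minimiser since labels ascend
    choice = np.argmin(per_label, axis=0)
    out[reachable] = labels[choice[reachable]]
    out[seeds] = seed_labels
    return out.reshape(h, w)


def sorted_median(values) -> float:
    """Median via explicit sort (independent of numpy.median)."""
    xs = sorted(float(v) for v in values)
    n = len(xs)
    if n == 0:
        return float("nan")
    mid = n // 2
    return xs[mid] if n % 2 else 0.5 * (xs[mid - 1] + xs[mid])
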