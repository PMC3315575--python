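"""Seeded propagation of cell labels from nuclei.

Each foreground pixel is assigned the label of the nucleus seed reachable at
minimal accumulated path cost, where a step from pixel p to neighbour q costs

    sqrt(lambda_reg * s(p, q)**2 + (I(p) - I(q))**2)

with s the spatial step length (1 for axial moves, sqrt(2) for diagonal) and
I the cell-boundary stain. Small lambda_reg makes boundaries hug intensity
ridges of the boundary stain; large lambda_reg recovers the nearest-seed
spatial partition. Ties in accumulated cost resolve to the smaller seed
label via deterministic (cost, label) priority ordering.
"""

from __future__ import annotations

import heapq
import math
import warnings

import numpy as np

from .types import ChannelImage, PropagationParams

__all__ = ["propagate_cells"]

_SQRT2 = math.sqrt(2.0)


def propagate_cells(
    boundary,
    nuclei: np.ndarray,
    foreground: np.ndarray | None = None,
    params: PropagationParams = PropagationParams(),
) -> np.ndarray:
    """Grow cell labels outward from nucleus seeds over the foreground.

    Parameters
    ----------
    boundary
        Cell-boundary stain image (ChannelImage or 2-D array), already
        illumination-corrected.
    nuclei
        Integer label mask of nucleus seeds; seed pixels keep their labels.
    foreground
        Boolean mask of pixels eligible for assignment. ``None`` propagates
        over the whole image (confluent-monolayer default). Seed pixels are
        always included.
    params
        Spatial regularisation weight and neighbourhood connectivity.

    Returns
    -------
    Integer label mask; foreground pixels unreachable from any seed stay 0.
    """
    image = boundary.pixels if isinstance(boundary, ChannelImage) else np.asarray(boundary, float)
    nuclei = np.asarray(nuclei)
    if image.shape != nuclei.shape:
        raise ValueError(f"boundary {image.shape} and nuclei {nuclei.shape} shapes differ")
    h, w = image.shape
    if foreground is None:
        fg = np.ones((h, w), dtype=bool)
    else:
        fg = np.asarray(foreground, dtype=bool).copy()
        if fg.shape != image.shape:
            raise ValueError("foreground shape differs from image shape")
        fg |= nuclei > 0  # seeds are always part of the foreground

    labels = np.zeros((h, w), dtype=np.int32)
    if not np.any(nuclei > 0):
        if np.any(fg):
            warnings.warn("no nucleus seeds: returning an all-zero cell mask", stacklevel=2)
        return labels

    lam = params.lambda_reg
    if params.connectivity == 8:
        steps = [(-1, -1, _SQRT2), (-1, 0, 1.0), (-1, 1, _SQRT2), (0, -1, 1.0),
                 (0, 1, 1.0), (1, -1, _SQRT2), (1, 0, 1.0), (1, 1, _SQRT2)]
    else:
        steps = [(-1, 0, 1.0), (0, -1, 1.0), (0, 1, 1.0), (1, 0, 1.0)]
    axial_cost2 = lam  # lambda * 1^2
    diag_cost2 = 2.0 * lam

    img = image.astype(float)
    best_cost = np.full((h, w), np.inf)
    best_label = np.full((h, w), np.iinfo(np.int32).max, dtype=np.int64)
    visited = np.zeros((h, w), dtype=bool)

    heap: list[tuple[float, int, int, int]] = []
    ys, xs = np.nonzero(nuclei > 0)
    for y, x in zip(ys.tolist(), xs.tolist()):
        lab = int(nuclei[y, x])
        heap.append((0.0, lab, y, x))
        best_cost[y, x] = 0.0
        best_label[y, x] = min(best_label[y, x], lab)
    heapq.heapify(heap)

    pop = heapq.heappop
    push = heapq.heappush
    while heap:
        cost, lab, y, x = pop(heap)
        if visited[y, x]:
            continue
        visited[y, x] = True
        labels[y, x] = lab
        ip = img[y, x]
        for dy, dx, s in steps:
            ny, nx = y + dy, x + dx
            if ny < 0 or ny >= h or nx < 0 or nx >= w:
                continue
            if visited[ny, nx] or not fg[ny, nx]:
                continue
            di = ip - img[ny, nx]
            c2 = diag_cost2 if s != 1.0 else axial_cost2
            ncost = cost + math.sqrt(c2 + di * di)
            if ncost < best_cost[ny, nx] or (
                ncost == best_cost[ny, nx] and lab < best_label[ny, nx]
            ):
                best_cost[ny, nx] = ncost
                best_label[ny, nx] = lab
                push(heap, (ncost, lab, ny, nx))

    # seed pixels always keep their own label, even under a foreign wavefront
    seeded = nuclei > 0
    labels[seeded] = nuclei[seeded]
    return labels
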