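"""Scene geometry and noiseless channel rasters for one field of view.

Cells are grown as a multiplicatively weighted Voronoi tessellation around
non-overlapping, dart-thrown centers: centers are rejected closer than the
mean of the two cells' radii, and every pixel joins the center minimising
distance/radius. With full survival the tessellation tiles the field
(confluent monolayer of touching, flat cells); under a toxic effect the
surviving cells keep a bounded footprint and gaps of background remain.

Mitochondrial content is distributed over each cytoplasm as a clumped
mixture-of-Gaussians density (plus a uniform floor), with a small bleed term
inside the nucleus footprint emulating residual nuclear staining that the
downstream nucleus masking is meant to discount.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..errors import PackingError
from .params import EffectSpec, SceneParams

__all__ = ["GroundTruth", "generate_scene"]

# surviving cells' footprint, in units of their weighting radius, when the
# monolayer is no longer confluent (toxic wells)
_SPARSE_REACH = 1.3
_CLUMP_SIGMA_PX = 2.5
_CLUMP_AREA_PX = 80.0  # one clump per ~80 px2 of cytoplasm
_CLUMP_FLOOR = 0.15


@dataclass
class GroundTruth:
    """Per-cell truth table plus the true label masks for one scene."""

    cells: pd.DataFrame  # cell_id, center_y/x, radius_px, areas, true content
    cell_labels: np.ndarray
    nucleus_labels: np.ndarray
    effect: EffectSpec

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def _place_centers(
    rng: np.random.Generator,
    n: int,
    radii: np.ndarray,
    shape: tuple[int, int],
    max_attempts_per_cell: int = 200,
) -> np.ndarray:
    """Dart-throw centers with pairwise separation >= mean of the two radii."""
    h, w = shape
    centers = np.empty((0, 2))
    placed_r: list[float] = []
    margin = 1.0  # keep centers off the exact border
    attempts = n * max_attempts_per_cell
    i = 0
    while len(placed_r) < n and attempts > 0:
        attempts -= 1
        y = rng.uniform(margin, h - margin)
        x = rng.uniform(margin, w - margin)
        r = radii[len(placed_r)]
        if centers.shape[0]:
            d = np.hypot(centers[:, 0] - y, centers[:, 1] - x)
            min_sep = 0.5 * (np.asarray(placed_r) + r)
            if np.any(d < min_sep):
                continue
        centers = np.vstack([centers, [y, x]])
        placed_r.append(r)
        i += 1
    if len(placed_r) < n:
        raise PackingError(requested=n, achieved=len(placed_r))
    return centers


def _weighted_voronoi(
    centers: np.ndarray, radii: np.ndarray, shape: tuple[int, int], confluent: bool
) -> np.ndarray:
    """Assign pixels to argmin_i dist(p, c_i)/r_i; labels are 1..n."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    labels = np.zeros((h, w), dtype=np.int32)
    best = np.full((h, w), np.inf, dtype=np.float32)
    for idx, ((cy, cx), r) in enumerate(zip(centers, radii), start=1):
        d = np.hypot(yy - cy, xx - cx).astype(np.float32) / np.float32(r)
        sel = d < best
        if not confluent:
            sel &= d <= _SPARSE_REACH
        labels[sel] = idx
        best = np.where(sel, d, best)
    return labels


def generate_scene(
    params: SceneParams,
    effect: EffectSpec = EffectSpec(),
    rng_seed: int | np.random.Generator | None = None,
) -> tuple[GroundTruth, dict[str, np.ndarray]]:
    """Generate one ground-truthed scene and its noiseless channel rasters.

    Returns (GroundTruth, {"nuclear": ..., "boundary": ..., "mito": ...}).
    The expected integrated mitochondrial content of each cell is
    content_scale * baseline_area**gamma * content_multiplier; set
    ``content_cv=0`` for the exact value. The realised cell count is
    round(target/area_multiplier), binomially thinned by survival_fraction.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(params.seed if rng_seed is None else rng_seed)
    )
    h, w = params.shape
    rasters = {
        "nuclear": np.zeros((h, w)),
        "boundary": np.zeros((h, w)),
        "mito": np.zeros((h, w)),
    }

    n_target = int(round(params.target_cell_count / effect.area_multiplier))
    n = (
        int(rng.binomial(n_target, effect.survival_fraction))
        if effect.survival_fraction < 1
        else n_target
    )
    empty = GroundTruth(
        cells=pd.DataFrame(
            columns=[
                "cell_id", "center_y", "center_x", "radius_px", "cell_area_px",
                "nucleus_area_px", "cytoplasm_area_px", "true_content_AU",
                "touches_border",
            ]
        ),
        cell_labels=np.zeros((h, w), np.int32),
        nucleus_labels=np.zeros((h, w), np.int32),
        effect=effect,
    )
    if n == 0:
        return empty, rasters

    base_radius = params.cell_radius_mean_px * np.sqrt(effect.area_multiplier)
    radii = base_radius * (1.0 + params.cell_radius_cv * rng.standard_normal(n))
    radii = np.clip(radii, 0.35 * base_radius, None)

    confluent = effect.survival_fraction >= 1.0
    centers = _place_centers(rng, n, radii, (h, w))
    cell_labels = _weighted_voronoi(centers, radii, (h, w), confluent)

    # nucleus: disk of ratio * radius around the center, clipped to the cell
    yy, xx = np.mgrid[0:h, 0:w]
    nucleus_labels = np.zeros((h, w), dtype=np.int32)
    for idx, ((cy, cx), r) in enumerate(zip(centers, radii), start=1):
        rn = params.nucleus_to_cell_radius_ratio * r
        sel = (np.hypot(yy - cy, xx - cx) <= rn) & (cell_labels == idx)
        nucleus_labels[sel] = idx

    nmax = n + 1
    cell_area = np.bincount(cell_labels.ravel(), minlength=nmax)[1:]
    nuc_area = np.bincount(nucleus_labels.ravel(), minlength=nmax)[1:]
    cyto_area = cell_area - nuc_area

    gamma = params.content_area_exponent
    baseline_area = cell_area / effect.area_multiplier
    scatter = (
        np.exp(rng.normal(-0.5 * np.log(1 + params.content_cv**2),
                          np.sqrt(np.log(1 + params.content_cv**2)), n))
        if params.content_cv > 0
        else np.ones(n)
    )
    content = (
        params.content_scale * baseline_area**gamma * effect.content_multiplier * scatter
    )

    border = np.zeros(n, dtype=bool)
    edge_labels = np.unique(
        np.concatenate([cell_labels[0], cell_labels[-1], cell_labels[:, 0], cell_labels[:, -1]])
    )
    border[[int(v) - 1 for v in edge_labels if v > 0]] = True

    # --- channel rasters -------------------------------------------------
    in_cell = cell_labels > 0
    in_nuc = nucleus_labels > 0
    rasters["nuclear"] = np.where(
        in_nuc, params.nuclear_intensity, params.nuclear_background
    ).astype(float)

    boundary = np.where(in_cell, params.boundary_cytoplasm_intensity, params.boundary_background)
    boundary = np.where(in_nuc, params.boundary_nucleus_intensity, boundary)
    # ridge: pixels adjacent to a different label (the cortical actin rim)
    ridge = _label_edges(cell_labels)
    boundary = np.where(ridge, params.boundary_ridge_intensity, boundary)
    rasters["boundary"] = boundary.astype(float)

    mito = np.full((h, w), params.mito_background, dtype=float)
    cyto_labels = np.where(in_nuc, 0, cell_labels)
    for idx in range(1, n + 1):
        cys, cxs = np.nonzero(cyto_labels == idx)
        c = content[idx - 1]
        if cys.size == 0:
            continue
        weights = _clump_density(rng, cys, cxs)
        mito[cys, cxs] += c * weights
        nys, nxs = np.nonzero(nucleus_labels == idx)
        if nys.size:
            mito[nys, nxs] += params.nuclear_bleed_fraction * c / nys.size
    rasters["mito"] = mito

    cells = pd.DataFrame(
        {
            "cell_id": np.arange(1, n + 1),
            "center_y": centers[:, 0],
            "center_x": centers[:, 1],
            "radius_px": radii,
            "cell_area_px": cell_area,
            "nucleus_area_px": nuc_area,
            "cytoplasm_area_px": cyto_area,
            "true_content_AU": content,
            "touches_border": border,
        }
    )
    truth = GroundTruth(
        cells=cells, cell_labels=cell_labels, nucleus_labels=nucleus_labels, effect=effect
    )
    return truth, rasters


def _label_edges(labels: np.ndarray) -> np.ndarray:
    """Pixels whose 4-neighbourhood contains a different (or background) label."""
    edge = np.zeros(labels.shape, dtype=bool)
    edge[:-1, :] |= labels[:-1, :] != labels[1:, :]
    edge[1:, :] |= labels[1:, :] != labels[:-1, :]
    edge[:, :-1] |= labels[:, :-1] != labels[:, 1:]
    edge[:, 1:] |= labels[:, 1:] != labels[:, :-1]
    return edge & (labels > 0)


def _clump_density(rng: np.random.Generator, ys: np.ndarray, xs: np.ndarray) -> np.ndarray:
    """Normalised clumped density over the cytoplasm pixel list (sums to 1)."""
    n_px = ys.size
    k = max(2, int(round(n_px / _CLUMP_AREA_PX)))
    pick = rng.integers(0, n_px, size=k)
    d2 = (ys[:, None] - ys[pick][None, :]) ** 2 + (xs[:, None] - xs[pick][None, :]) ** 2
    dens = np.exp(-d2 / (2.0 * _CLUMP_SIGMA_PX**2)).sum(axis=1) + _CLUMP_FLOOR
    return dens / dens.sum()
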