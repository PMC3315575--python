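"""Cytoplasm definition and per-cell measurement.

The cytoplasm is the whole-cell footprint minus the nucleus footprint;
masking the nucleus discounts residual mitochondrial-stain background there.
Per cell, the total mitochondrial-stain intensity within the cytoplasm and
the cytoplasm area are measured, plus the area-normalized intensity (the
screen's cell-size-corrected mitochondrial-content readout).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..errors import MaskConsistencyError
from .types import CellRecord, ChannelImage

__all__ = [
    "cytoplasm_mask",
    "measure_cells",
    "mito_area_fraction",
    "check_mask_partition",
]


def cytoplasm_mask(cells: np.ndarray, nuclei: np.ndarray) -> np.ndarray:
    """Subtract nucleus pixels from each cell label to define cytoplasm.

    Raises MaskConsistencyError if any nucleus label overlaps more than one
    cell label (a nucleus must lie inside a single cell).
    """
    cells = np.asarray(cells)
    nuclei = np.asarray(nuclei)
    if cells.shape != nuclei.shape:
        raise ValueError("cells and nuclei masks must share a shape")
    nsel = nuclei > 0
    if nsel.any():
        pairs = np.stack([nuclei[nsel], cells[nsel]], axis=1)
        uniq = np.unique(pairs, axis=0)
        nuc_ids, counts = np.unique(uniq[:, 0], return_counts=True)
        spanning = nuc_ids[counts > 1]
        if spanning.size:
            details = {int(n): sorted(int(c) for c in uniq[uniq[:, 0] == n, 1])
                       for n in spanning}
            raise MaskConsistencyError(f"nuclei spanning multiple cell labels: {details}")
    cyto = cells.copy()
    cyto[nsel] = 0
    return cyto


def check_mask_partition(cells: np.ndarray, nuclei: np.ndarray, cytoplasm: np.ndarray) -> None:
    """Assert the segmentation partition contracts; raise on violation.

    nuclei subset of cells (same label under every nucleus pixel), cytoplasm
    disjoint from nuclei, and per label: |cytoplasm| + |nucleus| = |cell|.
    """
    nsel = nuclei > 0
    if np.any(cells[nsel] == 0):
        raise MaskConsistencyError("nucleus pixels outside any cell label")
    if np.any(cytoplasm[nsel] != 0):
        raise MaskConsistencyError("cytoplasm overlaps nuclei")
    n = int(max(cells.max(), nuclei.max(), cytoplasm.max())) + 1
    cell_area = np.bincount(cells.ravel(), minlength=n)
    nuc_area = np.bincount(nuclei.ravel(), minlength=n)
    cyto_area = np.bincount(cytoplasm.ravel(), minlength=n)
    mismatch = np.flatnonzero(cell_area[1:] != nuc_area[1:] + cyto_area[1:]) + 1
    # labels whose nucleus mask uses a different id than the cell mask would
    # trip this; the pipeline seeds cells from nuclei so ids coincide.
    if mismatch.size:
        raise MaskConsistencyError(
            f"cytoplasm+nucleus != cell pixel count for labels {mismatch.tolist()}"
        )


def _border_labels(cells: np.ndarray) -> set[int]:
    edges = np.concatenate([cells[0], cells[-1], cells[:, 0], cells[:, -1]])
    return set(int(v) for v in np.unique(edges) if v > 0)


def measure_cells(
    cytoplasm: np.ndarray,
    cells: np.ndarray,
    nuclei: np.ndarray,
    mito,
    background_cutoff: float = 0.0,
    exclude_border: bool = True,
    background_mode: str = "mask",
) -> pd.DataFrame:
    """Per-cell areas and mitochondrial-stain intensities.

    background_mode "mask": pixels below the cutoff contribute 0, pixels at or
    above contribute their full intensity (a background *threshold*).
    "subtract": each pixel contributes max(I - cutoff, 0).

    Returns a DataFrame with one row per cell, columns as CellRecord.FIELDS.
    Border-touching cells are flagged and, when ``exclude_border``, omitted.
    """
    if background_mode not in ("mask", "subtract"):
        raise ValueError("background_mode must be 'mask' or 'subtract'")
    image = mito.pixels if isinstance(mito, ChannelImage) else np.asarray(mito, float)
    if image.shape != cells.shape:
        raise ValueError("mito image and masks must share a shape")

    if background_mode == "mask":
        contrib = np.where(image >= background_cutoff, image, 0.0)
    else:
        contrib = np.maximum(image - background_cutoff, 0.0)

    n = int(max(cells.max(), nuclei.max(), cytoplasm.max(), 0)) + 1
    cell_area = np.bincount(cells.ravel(), minlength=n)
    nuc_area = np.bincount(nuclei.ravel(), minlength=n)
    cyto_area = np.bincount(cytoplasm.ravel(), minlength=n)
    integrated = np.bincount(cytoplasm.ravel(), weights=contrib.ravel(), minlength=n)

    border = _border_labels(cells)
    rows = []
    for lab in (int(v) for v in np.flatnonzero(cell_area) if v != 0):
        touches = lab in border
        if exclude_border and touches:
            continue
        ca = int(cyto_area[lab])
        integ = float(integrated[lab])
        rows.append(
            CellRecord(
                cell_id=lab,
                nucleus_area_px=int(nuc_area[lab]),
                cell_area_px=int(cell_area[lab]),
                cytoplasm_area_px=ca,
                integrated_mito_AU=integ,
                normalized_mito_AU_per_px=(integ / ca) if ca > 0 else float("nan"),
                touches_border=touches,
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows], columns=list(CellRecord.FIELDS))


def mito_area_fraction(
    mito_foreground: np.ndarray,
    cytoplasm: np.ndarray,
    labels: np.ndarray | None = None,
) -> tuple[pd.Series, float]:
    """Fraction of cytoplasm area occupied by mitochondrial-stain foreground.

    Returns (per-label Series, overall fraction). Labels with empty cytoplasm
    are reported as NaN (undefined), not 0; pass ``labels`` to include cells
    whose cytoplasm vanished entirely.
    """
    fg = np.asarray(mito_foreground, dtype=bool)
    cyto = np.asarray(cytoplasm)
    if fg.shape != cyto.shape:
        raise ValueError("masks must share a shape")
    present = np.unique(cyto[cyto > 0])
    if labels is None:
        labels = present
    labels = np.asarray(sorted(int(v) for v in np.unique(labels) if v > 0))
    n = int(cyto.max()) + 1 if cyto.size else 1
    area = np.bincount(cyto.ravel(), minlength=n)
    inter = np.bincount(cyto.ravel(), weights=fg.ravel().astype(float), minlength=n)
    vals = {}
    for lab in labels:
        a = area[lab] if lab < n else 0
        vals[int(lab)] = (inter[lab] / a) if a > 0 else float("nan")
    per_label = pd.Series(vals, dtype=float)
    total_area = int(area[1:].sum()) if area.size > 1 else 0
    overall = float(inter[1:].sum() / total_area) if total_area > 0 else float("nan")
    return per_label, overall
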