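"""Core imaging containers.

Conventions: rasters are 2-D numpy arrays, row-major, origin at the top-left,
0-based pixel coordinates. Intensities are nonnegative arbitrary units (AU);
areas are pixel counts. Label masks are integer rasters with 0 = background;
labels need not be contiguous 1..K.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

CHANNELS = ("nuclear", "boundary", "mito")


@dataclass
class ChannelImage:
    """One single-plane fluorescence raster plus its acquisition identity.

    ``channel`` is one of ``nuclear`` (DNA stain, segmentation seeds),
    ``boundary`` (F-actin stain delineating cell borders) or ``mito``
    (mitochondrion-accumulating dye whose integrated per-cell intensity is
    the mitochondrial-content proxy).
    """

    pixels: np.ndarray
    channel: str
    plate: str = "plate1"
    well: str = "A01"
    site: int = 1
    day: int = 1

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2-D raster, got shape {self.pixels.shape}")
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}, got {self.channel!r}")
        if not np.all(np.isfinite(self.pixels)) or self.pixels.min() < 0:
            raise ValueError("pixel intensities must be finite and nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "ChannelImage":
        return replace(self, pixels=pixels)


@dataclass
class IlluminationProfile:
    """Smooth, strictly positive, unit-mean shading field for one (plate, channel)."""

    pixels: np.ndarray
    plate: str
    channel: str

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if np.any(self.pixels <= 0):
            raise ValueError("illumination profile must be strictly positive")


@dataclass(frozen=True)
class PropagationParams:
    """Parameters of seeded propagation.

    lambda_reg weights the spatial step length against local image contrast in
    the step cost sqrt(lambda * s^2 + dI^2): at 0 boundaries follow intensity
    structure only, at large values they converge to the nearest-seed
    (spatial geodesic) partition.
    """

    lambda_reg: float = 0.05
    connectivity: int = 8

    def __post_init__(self):
        if self.lambda_reg < 0:
            raise ValueError("lambda_reg must be >= 0")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass(frozen=True)
class CellRecord:
    """Per-cell measurements; the unit row of the screen's data model."""

    cell_id: int
    nucleus_area_px: int
    cell_area_px: int
    cytoplasm_area_px: int
    integrated_mito_AU: float
    normalized_mito_AU_per_px: float
    touches_border: bool

    FIELDS = (
        "cell_id",
        "nucleus_area_px",
        "cell_area_px",
        "cytoplasm_area_px",
        "integrated_mito_AU",
        "normalized_mito_AU_per_px",
        "touches_border",
    )
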