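"""Otsu thresholding.

The screen separates dim mitochondrial-stain background from signal with a
three-class Otsu threshold: the pair of cutoffs (t_low < t_high) that
maximises the between-class variance of the intensity histogram split into
three classes. Which side of the middle class counts as background is a
pipeline choice; by default the middle class is treated as foreground (the
background cutoff is t_low), which preserves dim mitochondrial signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import DegenerateImageError

__all__ = ["ThreeClassThresholds", "otsu_three_class", "histogram_for_otsu"]


@dataclass(frozen=True)
class ThreeClassThresholds:
    t_low: float
    t_high: float
    background_cutoff: float
    between_class_variance: float


def histogram_for_otsu(pixels: np.ndarray, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Histogram an image over its own intensity range, returning (counts, centers)."""
    pixels = np.asarray(pixels, dtype=float).ravel()
    lo, hi = pixels.min(), pixels.max()
    if hi <= lo:
        raise DegenerateImageError("constant image: no histogram structure to threshold")
    counts, edges = np.histogram(pixels, bins=n_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return counts.astype(float), centers


def otsu_three_class(
    image_or_hist,
    n_bins: int = 128,
    middle_class_to: str = "foreground",
) -> ThreeClassThresholds:
    """Three-class Otsu thresholds of an image or a pre-binned histogram.

    Parameters
    ----------
    image_or_hist
        Either a 2-D raster (histogrammed into ``n_bins`` over its range) or a
        ``(counts, bin_centers)`` pair.
    middle_class_to
        ``"foreground"`` returns ``t_low`` as the background cutoff (middle
        class kept as signal), ``"background"`` returns ``t_high``.

    Returns
    -------
    ThreeClassThresholds
        ``t_low < t_high`` are intensity values placed between the last bin of
        one class and the first bin of the next; ties in between-class
        variance resolve to the lexicographically smallest boundary pair.

    Raises
    ------
    DegenerateImageError
        Fewer than 3 distinct occupied bins.
    """
    if middle_class_to not in ("foreground", "background"):
        raise ValueError("middle_class_to must be 'foreground' or 'background'")
    if isinstance(image_or_hist, tuple):
        counts, centers = image_or_hist
        counts = np.asarray(counts, dtype=float)
        centers = np.asarray(centers, dtype=float)
        if counts.shape != centers.shape or counts.ndim != 1:
            raise ValueError("histogram must be (counts, bin_centers) of equal length")
        if np.any(counts < 0):
            raise ValueError("histogram counts must be nonnegative")
    else:
        counts, centers = histogram_for_otsu(image_or_hist, n_bins)

    if int(np.count_nonzero(counts)) < 3:
        raise DegenerateImageError(
            "need at least 3 distinct occupied intensity bins for three classes"
        )

    i_low, i_high, sigma_b = _argmax_between_class_variance(counts, centers)
    t_low = 0.5 * (centers[i_low] + centers[i_low + 1])
    t_high = 0.5 * (centers[i_high] + centers[i_high + 1])
    cutoff = t_low if middle_class_to == "foreground" else t_high
    return ThreeClassThresholds(t_low, t_high, cutoff, sigma_b)


def _argmax_between_class_variance(
    counts: np.ndarray, centers: np.ndarray
) -> tuple[int, int, float]:
    """Vectorised search over all boundary pairs (i, j), i < j.

    Class 1 = bins [0..i], class 2 = bins [i+1..j], class 3 = bins [j+1..].
    Maximises sum_k W_k * mu_k^2 (equivalent to the between-class variance up
    to the constant global mean term); pairs yielding an empty class are
    excluded. Each class must end on an occupied bin (counts[i] > 0,
    counts[j] > 0), so every distinct partition of the occupied bins is
    represented by exactly one boundary pair. First maximum in row-major
    (i, j) order wins.
    """
    n = counts.size
    w = counts / counts.sum()
    cw = np.cumsum(w)
    cm = np.cumsum(w * centers)

    i = np.arange(n - 2)  # candidate low boundary: class 1 = [0..i]
    j = np.arange(n - 1)  # candidate high boundary: class 2 ends at j

    W1 = cw[i][:, None]
    S1 = cm[i][:, None]
    W2 = cw[j][None, :] - W1
    S2 = cm[j][None, :] - S1
    W3 = 1.0 - cw[j][None, :]
    S3 = cm[-1] - cm[j][None, :]

    occupied = counts > 0
    valid = (
        (j[None, :] > i[:, None])
        & (W1 > 0) & (W2 > 0) & (W3 > 0)
        & occupied[i][:, None] & occupied[j][None, :]
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma = S1**2 / W1 + S2**2 / W2 + S3**2 / W3
    sigma = np.where(valid, sigma, -np.inf)
    if not np.any(valid):
        raise DegenerateImageError("no boundary pair yields three nonempty classes")
    flat = int(np.argmax(sigma))
    bi, bj = np.unravel_index(flat, sigma.shape)
    # cm[-1] is the global mean; subtracting its square turns sum W_k mu_k^2
    # into the between-class variance proper.
    return int(i[bi]), int(j[bj]), float(sigma[bi, bj] - cm[-1] ** 2)
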