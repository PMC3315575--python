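"""Retrospective flat-field (illumination) correction.

Uneven illumination multiplies every image of a plate/channel group by the
same smooth shading field. The field is estimated per (plate, channel) by
heavily smoothing the mean of the group's images, rescaling to unit mean and
flooring at a small positive epsilon; correction divides pixelwise by it.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Sequence

from scipy import ndimage as ndi

from ..errors import GroupKeyError, ShapeMismatchError
from .types import ChannelImage, IlluminationProfile

__all__ = ["estimate_illumination", "correct_illumination", "estimate_illumination_profiles"]

_EPS = 1e-6


def estimate_illumination(
    images: Sequence[ChannelImage],
    smoothing_scale_px: float | None = None,
) -> IlluminationProfile:
    """Estimate the shading field shared by one (plate, channel) image group.

    ``smoothing_scale_px`` is the Gaussian sigma; the default, image_width/10,
    passes only slowly varying shading.
    """
    if len(images) == 0:
        raise ValueError("need at least one image to estimate illumination")
    plate, channel = images[0].plate, images[0].channel
    shape = images[0].shape
    bad = [im.well for im in images if im.plate != plate or im.channel != channel]
    if bad:
        raise GroupKeyError(
            f"images must share (plate={plate!r}, channel={channel!r}); offending wells: {bad}"
        )
    bad = [im.well for im in images if im.shape != shape]
    if bad:
        raise ShapeMismatchError(f"images of differing shape in group; offending wells: {bad}")

    if smoothing_scale_px is None:
        smoothing_scale_px = shape[1] / 10.0
    if smoothing_scale_px <= 0:
        raise ValueError("smoothing_scale_px must be positive")

    mean_img = sum(im.pixels for im in images) / len(images)
    smooth = ndi.gaussian_filter(mean_img, sigma=smoothing_scale_px, mode="nearest")
    floor = max(_EPS, _EPS * float(smooth.max()))
    smooth = smooth.clip(min=floor)
    smooth = smooth / smooth.mean()
    return IlluminationProfile(pixels=smooth, plate=plate, channel=channel)


def correct_illumination(img: ChannelImage, profile: IlluminationProfile) -> ChannelImage:
    """Divide an image pixelwise by its group's unit-mean shading profile."""
    if (img.plate, img.channel) != (profile.plate, profile.channel):
        raise GroupKeyError(
            f"image ({img.plate!r}, {img.channel!r}) does not match "
            f"profile ({profile.plate!r}, {profile.channel!r})"
        )
    if img.shape != profile.pixels.shape:
        raise ShapeMismatchError(
            f"image shape {img.shape} != profile shape {profile.pixels.shape}"
        )
    return img.with_pixels(img.pixels / profile.pixels)


def estimate_illumination_profiles(
    images: Iterable[ChannelImage],
    smoothing_scale_px: float | None = None,
) -> dict[tuple[str, str], IlluminationProfile]:
    """Group images by (plate, channel) and estimate one profile per group."""
    groups: dict[tuple[str, str], list[ChannelImage]] = defaultdict(list)
    for im in images:
        groups[(im.plate, im.channel)].append(im)
    return {
        key: estimate_illumination(ims, smoothing_scale_px) for key, ims in groups.items()
    }
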