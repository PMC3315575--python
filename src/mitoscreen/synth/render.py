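"""Rendering of noiseless rasters into camera images.

output = blur(raster * gain) * illumination gradient + Poisson-Gaussian
noise, clipped to the nonnegative range of the declared bit depth. The
gradient is a smooth multiplicative field with max/min ratio exactly
1 + illumination_gradient_amplitude, shared by all wells of a plate/channel
group so the retrospective flat-field correction is estimable downstream.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

from .params import SceneParams

__all__ = ["illumination_field", "render_channels"]


def illumination_field(
    shape: tuple[int, int],
    amplitude: float,
    rng_seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Smooth multiplicative shading with max/min ratio exactly 1 + amplitude.

    A randomly oriented planar ramp plus an off-center smooth bump,
    normalised to [0, 1] and mapped to 1 + amplitude * f.
    """
    if not 0 <= amplitude < 1:
        raise ValueError("amplitude must be in [0, 1)")
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    yn, xn = yy / max(h - 1, 1), xx / max(w - 1, 1)
    if amplitude == 0:
        return np.ones(shape)
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    theta = rng.uniform(0, 2 * np.pi)
    cy, cx = rng.uniform(0.2, 0.8, size=2)
    raw = np.cos(theta) * xn + np.sin(theta) * yn
    raw = raw + 0.5 * np.exp(-((yn - cy) ** 2 + (xn - cx) ** 2) / 0.35)
    raw = raw - raw.min()
    f = raw / raw.max()
    return 1.0 + amplitude * f


def render_channels(
    rasters: dict[str, np.ndarray],
    params: SceneParams,
    rng_seed: int | np.random.Generator | None = None,
    illum_fields: dict[str, np.ndarray] | None = None,
    gains: dict[str, float] | None = None,
) -> dict[str, np.ndarray]:
    """Apply gain, blur, shading and Poisson-Gaussian noise to each raster.

    ``illum_fields`` maps channel -> shading field; when omitted, one field
    per channel is drawn from the rng (a plate-level caller should instead
    pass fields derived from the plate seed so wells share them). ``gains``
    maps channel -> multiplicative staining gain; when omitted, drawn
    lognormally with CV ``params.well_gain_cv``. With all noise, gain and
    gradient parameters at 0 the output equals the input raster.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(params.seed if rng_seed is None else rng_seed)
    )
    out: dict[str, np.ndarray] = {}
    for channel, raster in rasters.items():
        img = np.asarray(raster, dtype=float)
        if np.any(img < 0):
            raise ValueError(f"raster for channel {channel!r} has negative values")
        if gains is not None:
            gain = gains.get(channel, 1.0)
        elif params.well_gain_cv > 0:
            sig2 = np.log(1 + params.well_gain_cv**2)
            gain = float(np.exp(rng.normal(-0.5 * sig2, np.sqrt(sig2))))
        else:
            gain = 1.0
        img = img * gain
        if params.blur_sigma_px > 0:
            img = ndi.gaussian_filter(img, params.blur_sigma_px, mode="nearest")
        if illum_fields is not None and channel in illum_fields:
            img = img * illum_fields[channel]
        elif illum_fields is None and params.illumination_gradient_amplitude > 0:
            img = img * illumination_field(
                img.shape, params.illumination_gradient_amplitude, rng
            )
        if params.poisson_scaling > 0:
            img = rng.poisson(img / params.poisson_scaling) * params.poisson_scaling
        if params.noise_gaussian_sd > 0:
            img = img + rng.normal(0.0, params.noise_gaussian_sd, size=img.shape)
        out[channel] = np.clip(img, 0.0, float(params.bit_depth_max))
    return out
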