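"""Parameters of the synthetic monolayer generator.

The generator emulates a confluent monolayer of flat, touching cells (the
morphology of primary endothelial cells grown to confluence) in which each
cell's integrated mitochondrial content follows a power law of its area,

    E[content] = content_scale * area**gamma * effect multiplier,

so that the coupling between cell size and mitochondrial content — and
compounds that preserve or break it — can be planted with known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = ["SceneParams", "EffectSpec", "EFFECT_CLASSES"]

EFFECT_CLASSES = ("null", "proportional", "mito_only", "mito_down", "toxic")


@dataclass(frozen=True)
class SceneParams:
    """Geometry, intensity and noise settings for one synthetic field of view.

    Defaults describe the study conditions used throughout: a 256x256 px
    field holding ~130 confluent cells (the screen's toxicity cutoff of 40
    cells is ~30% of that), content-area coupling exponent gamma = 1, and
    modest Poisson-Gaussian camera noise under a multiplicative illumination
    gradient.
    """

    image_height_px: int = 256
    image_width_px: int = 256
    target_cell_count: int = 130
    cell_radius_mean_px: float = 12.0
    cell_radius_cv: float = 0.25
    nucleus_to_cell_radius_ratio: float = 0.4
    content_area_exponent: float = 1.0  # gamma of the content-area power law
    content_scale: float = 40.0  # AU per px**gamma
    content_cv: float = 0.15  # per-cell biological scatter around the law
    noise_gaussian_sd: float = 4.0
    poisson_scaling: float = 2.0  # photon-noise variance per AU; 0 disables
    blur_sigma_px: float = 1.0
    illumination_gradient_amplitude: float = 0.3
    well_gain_cv: float = 0.04  # per-(well, channel) lognormal staining gain
    nuclear_bleed_fraction: float = 0.05  # mito stain bleeding into the nucleus
    # channel rendering levels (AU, 16-bit range)
    nuclear_intensity: float = 3000.0
    nuclear_background: float = 100.0
    boundary_ridge_intensity: float = 1600.0
    boundary_cytoplasm_intensity: float = 400.0
    boundary_nucleus_intensity: float = 250.0
    boundary_background: float = 100.0
    mito_background: float = 20.0
    bit_depth_max: int = 65535
    seed: int = 0

    def __post_init__(self):
        if self.image_height_px < 64 or self.image_width_px < 64:
            raise ValueError("image dimensions must be >= 64 px")
        if self.target_cell_count < 0:
            raise ValueError("target_cell_count must be >= 0")
        if self.cell_radius_mean_px <= 0:
            raise ValueError("cell_radius_mean_px must be positive")
        if not 0 <= self.cell_radius_cv < 1:
            raise ValueError("cell_radius_cv must be in [0, 1)")
        if not 0 < self.nucleus_to_cell_radius_ratio < 1:
            raise ValueError("nucleus_to_cell_radius_ratio must be in (0, 1)")
        if self.content_scale <= 0:
            raise ValueError("content_scale must be positive")
        if self.noise_gaussian_sd < 0 or self.poisson_scaling < 0 or self.blur_sigma_px < 0:
            raise ValueError("noise and blur parameters must be >= 0")
        if not 0 <= self.illumination_gradient_amplitude < 1:
            raise ValueError("illumination_gradient_amplitude must be in [0, 1)")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.image_height_px, self.image_width_px)

    def with_(self, **kw) -> "SceneParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class EffectSpec:
    """A planted compound effect.

    Multipliers act on the baseline power law: actual cell area =
    area_multiplier * baseline area and content = content_scale *
    baseline_area**gamma * content_multiplier, i.e. content =
    content_scale * area**gamma * content_multiplier / area_multiplier**gamma.
    A proportional effect (area_multiplier = content_multiplier**(1/gamma))
    therefore leaves the per-cell content/area relationship unchanged, while
    mito_only/mito_down move content off the law at fixed size. In a
    confluent, fixed-area field, scaling cell area by m necessarily divides
    the expected cell count by m (cells tile the field).
    """

    effect_class: str = "null"
    area_multiplier: float = 1.0
    content_multiplier: float = 1.0
    survival_fraction: float = 1.0

    def __post_init__(self):
        if self.effect_class not in EFFECT_CLASSES:
            raise ValueError(f"effect_class must be one of {EFFECT_CLASSES}")
        if self.area_multiplier <= 0 or self.content_multiplier <= 0:
            raise ValueError("multipliers must be positive")
        if not 0 < self.survival_fraction <= 1:
            raise ValueError("survival_fraction must be in (0, 1]")
        ec = self.effect_class
        if ec == "null" and not (
            self.area_multiplier == self.content_multiplier == self.survival_fraction == 1.0
        ):
            raise ValueError("null effect requires all multipliers = 1")
        if ec in ("mito_only", "mito_down") and self.area_multiplier != 1.0:
            raise ValueError(f"{ec} requires area_multiplier = 1")
        if ec == "mito_down" and self.content_multiplier >= 1.0:
            raise ValueError("mito_down requires content_multiplier < 1")
        if ec == "toxic" and self.survival_fraction >= 1.0:
            raise ValueError("toxic requires survival_fraction < 1")

    @classmethod
    def null(cls) -> "EffectSpec":
        return cls()

    @classmethod
    def proportional(cls, content_multiplier: float, gamma: float = 1.0) -> "EffectSpec":
        """Content and size move together: area scales by content**(1/gamma)."""
        return cls(
            effect_class="proportional",
            area_multiplier=content_multiplier ** (1.0 / gamma),
            content_multiplier=content_multiplier,
        )

    @classmethod
    def mito_only(cls, content_multiplier: float) -> "EffectSpec":
        """Content up at unchanged cell size (a size-dissociated effect)."""
        return cls(effect_class="mito_only", content_multiplier=content_multiplier)

    @classmethod
    def mito_down(cls, content_multiplier: float) -> "EffectSpec":
        return cls(effect_class="mito_down", content_multiplier=content_multiplier)

    @classmethod
    def toxic(cls, survival_fraction: float) -> "EffectSpec":
        return cls(effect_class="toxic", survival_fraction=survival_fraction)
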