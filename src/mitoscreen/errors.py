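"""Exception types raised across the pipeline."""


class MitoscreenError(Exception):
    """Base class for all package-specific failures."""


class PackingError(MitoscreenError):
    """Could not place the requested number of cells without overlap."""

    def __init__(self, requested: int, achieved: int):
        self.requested = requested
        self.achieved = achieved
        super().__init__(
            f"could not place {requested} cells without overlap; "
            f"achieved {achieved} after bounded retries"
        )


class MissingEffectError(MitoscreenError):
    """A treatment compound in the plate map has no effect specification."""


class ShapeMismatchError(MitoscreenError):
    """Images that must share a shape do not."""


class GroupKeyError(MitoscreenError):
    """An image/profile pair does not share the required (plate, channel) key."""


class DegenerateImageError(MitoscreenError):
    """Image has too few distinct intensities for the requested thresholding."""


class MaskConsistencyError(MitoscreenError):
    """Label masks violate the nuclei-within-cells containment contract."""


class ControlFitError(MitoscreenError):
    """Too few control wells on a screening day to fit a null distribution."""


class DegenerateControlsError(MitoscreenError):
    """Control wells have zero spread; z-scores are undefined."""


class PlateMapError(MitoscreenError):
    """Malformed plate map (duplicate wells, missing controls, bad roles)."""
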