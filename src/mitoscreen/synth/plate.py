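"""Plate maps and whole-plate scene generation.

Plate map schema (CSV): plate, well, day, role {control|treatment},
compound_id, dose_uM. Every well maps to one image site per channel, named
{plate}_{well}_{site}_{channel}.tif. Per-well seeds derive deterministically
from (master_seed, plate, well) so plates regenerate reproducibly and in any
order; illumination fields derive from (master_seed, plate, channel) so all
wells of a plate share each channel's shading.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from ..errors import MissingEffectError, PlateMapError
from ..imaging.types import CHANNELS, ChannelImage
from .params import EffectSpec, SceneParams
from .render import illumination_field, render_channels
from .scene import GroundTruth, generate_scene

__all__ = [
    "PLATEMAP_COLUMNS",
    "stable_seed",
    "well_name",
    "make_platemap",
    "screen_platemap",
    "validate_platemap",
    "generate_plate",
    "PlateData",
]

PLATEMAP_COLUMNS = ["plate", "well", "day", "role", "compound_id", "dose_uM"]

_ROWS = "ABCDEFGHIJKLMNOP"


def stable_seed(*parts) -> int:
    """Deterministic 31-bit seed from arbitrary string/int parts."""
    digest = hashlib.blake2s("|".join(str(p) for p in parts).encode()).digest()
    return int.from_bytes(digest[:4], "little") & 0x7FFFFFFF


def well_name(index: int, n_cols: int = 24) -> str:
    """0-based well index to 384-well name, row-major: 0 -> A01, 383 -> P24."""
    return f"{_ROWS[index // n_cols]}{index % n_cols + 1:02d}"


def make_platemap(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=PLATEMAP_COLUMNS)
    validate_platemap(df)
    return df


def screen_platemap(
    compounds: list[str],
    days: tuple[int, ...] = (1, 2),
    controls_per_plate: int = 16,
    control_plates_per_day: int = 2,
    dose_uM: float = 10.0,
    n_wells: int = 384,
) -> pd.DataFrame:
    """Duplicate-screen layout: per day, one treatment plate carrying every
    compound once plus ``controls_per_plate`` in-plate DMSO wells, and
    ``control_plates_per_day`` all-DMSO control plates (the day's negative
    control distribution)."""
    if len(compounds) + controls_per_plate > n_wells:
        raise PlateMapError(
            f"{len(compounds)} compounds + {controls_per_plate} controls exceed {n_wells} wells"
        )
    rows = []
    for day in days:
        plate = f"T{day:02d}"
        for i, cpd in enumerate(compounds):
            rows.append(dict(plate=plate, well=well_name(i), day=day, role="treatment",
                             compound_id=cpd, dose_uM=dose_uM))
        for j in range(controls_per_plate):
            rows.append(dict(plate=plate, well=well_name(len(compounds) + j), day=day,
                             role="control", compound_id="DMSO", dose_uM=0.0))
        for c in range(control_plates_per_day):
            cplate = f"C{day:02d}{chr(ord('a') + c)}"
            for i in range(n_wells):
                rows.append(dict(plate=cplate, well=well_name(i), day=day, role="control",
                                 compound_id="DMSO", dose_uM=0.0))
    return make_platemap(rows)


def validate_platemap(platemap: pd.DataFrame) -> None:
    missing = [c for c in PLATEMAP_COLUMNS if c not in platemap.columns]
    if missing:
        raise PlateMapError(f"plate map missing columns: {missing}")
    dup = platemap.duplicated(subset=["plate", "well"])
    if dup.any():
        keys = platemap.loc[dup, ["plate", "well"]].itertuples(index=False, name=None)
        raise PlateMapError(f"duplicate (plate, well) entries: {sorted(set(keys))}")
    bad_roles = set(platemap["role"]) - {"control", "treatment"}
    if bad_roles:
        raise PlateMapError(f"unknown roles: {sorted(bad_roles)}")
    for day, grp in platemap.groupby("day"):
        if not (grp["role"] == "control").any():
            raise PlateMapError(f"day {day} has no control wells")


@dataclass
class PlateData:
    """In-memory product of generate_plate."""

    images: list[ChannelImage]
    truth_cells: pd.DataFrame  # per-cell truth, with plate/well columns
    truth_wells: pd.DataFrame  # per-well effect bookkeeping
    illum_fields: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)


def generate_plate(
    platemap: pd.DataFrame,
    effects: dict[str, EffectSpec],
    params: SceneParams,
    master_seed: int = 0,
    outdir: str | Path | None = None,
    site: int = 1,
) -> PlateData:
    """Generate all wells of a plate map; optionally write TIFFs and truth CSVs.

    ``effects`` maps compound_id -> EffectSpec; control wells are always
    null. A treatment compound without an EffectSpec raises
    MissingEffectError naming it.
    """
    validate_platemap(platemap)
    treatments = platemap.loc[platemap["role"] == "treatment", "compound_id"]
    unknown = sorted(set(treatments) - set(effects))
    if unknown:
        raise MissingEffectError(f"no EffectSpec for compounds: {unknown}")

    fields: dict[tuple[str, str], np.ndarray] = {}
    for plate in platemap["plate"].unique():
        for channel in CHANNELS:
            fields[(plate, channel)] = illumination_field(
                params.shape,
                params.illumination_gradient_amplitude,
                np.random.default_rng(stable_seed(master_seed, plate, channel)),
            )

    images: list[ChannelImage] = []
    truth_cells = []
    truth_wells = []
    for row in platemap.itertuples(index=False):
        effect = EffectSpec.null() if row.role == "control" else effects[row.compound_id]
        rng = np.random.default_rng(stable_seed(master_seed, row.plate, row.well))
        truth, rasters = generate_scene(params, effect, rng)
        rendered = render_channels(
            rasters, params, rng,
            illum_fields={ch: fields[(row.plate, ch)] for ch in CHANNELS},
        )
        for channel in CHANNELS:
            images.append(
                ChannelImage(
                    pixels=rendered[channel], channel=channel, plate=row.plate,
                    well=row.well, site=site, day=int(row.day),
                )
            )
        cells = truth.cells.copy()
        cells.insert(0, "well", row.well)
        cells.insert(0, "plate", row.plate)
        truth_cells.append(cells)
        truth_wells.append(
            dict(plate=row.plate, well=row.well, day=int(row.day), role=row.role,
                 compound_id=row.compound_id, effect_class=effect.effect_class,
                 area_multiplier=effect.area_multiplier,
                 content_multiplier=effect.content_multiplier,
                 survival_fraction=effect.survival_fraction,
                 n_cells_true=truth.n_cells)
        )

    data = PlateData(
        images=images,
        truth_cells=(
            pd.concat(truth_cells, ignore_index=True) if truth_cells else pd.DataFrame()
        ),
        truth_wells=pd.DataFrame(truth_wells),
        illum_fields=fields,
    )
    if outdir is not None:
        write_plate(data, platemap, outdir, site=site)
    return data


def write_plate(
    data: PlateData, platemap: pd.DataFrame, outdir: str | Path, site: int = 1
) -> None:
    """Write 16-bit TIFFs ({plate}_{well}_{site}_{channel}.tif) and truth CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for im in data.images:
        name = f"{im.plate}_{im.well}_{im.site}_{im.channel}.tif"
        tifffile.imwrite(
            outdir / name, np.round(im.pixels).clip(0, 65535).astype(np.uint16)
        )
    data.truth_cells.to_csv(outdir / "truth_cells.csv", index=False)
    data.truth_wells.to_csv(outdir / "truth_wells.csv", index=False)
    platemap.to_csv(outdir / "platemap.csv", index=False)
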