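"""End-to-end orchestration: synthetic plates -> per-image analysis ->
screen statistics, with a run manifest for reproducibility.

Two measurement paths share the same generator model and statistics:
``images`` renders every well and runs the full segmentation/measurement
chain (illumination correction, three-class background threshold, nucleus
segmentation, seeded propagation, nucleus masking, per-cell measurement);
``tabular`` samples the per-cell records directly, which scales to
thousand-well screens. Outputs are CSV tables plus a JSON manifest holding
every parameter and the SHA-256 of each table.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import screenstats, synth
from .errors import MitoscreenError
from .imaging import (
    ChannelImage,
    PropagationParams,
    check_mask_partition,
    correct_illumination,
    cytoplasm_mask,
    estimate_illumination_profiles,
    measure_cells,
    otsu_three_class,
    propagate_cells,
    segment_nuclei,
)
from .synth import EffectSpec, SceneParams

__all__ = [
    "ImagingParams",
    "StatsParams",
    "RunConfig",
    "analyze_well",
    "run_screen",
    "report",
    "effect_from_dict",
    "load_well_images",
]

log = logging.getLogger("mitoscreen")


@dataclass(frozen=True)
class ImagingParams:
    """Knobs of the per-image analysis chain."""

    illumination_smoothing_px: float | None = None  # None -> image width / 10
    otsu_bins: int = 128
    middle_class_to: str = "foreground"
    background_mode: str = "mask"
    min_nucleus_area_px: int = 8
    max_nucleus_area_px: int = 4000
    nucleus_smooth_sigma_px: float = 2.0
    nucleus_h_suppress: float = 1.0
    lambda_reg: float = 0.05
    connectivity: int = 8
    exclude_border: bool = True
    restrict_to_boundary_foreground: bool = False


@dataclass(frozen=True)
class StatsParams:
    estimator: str = "robust"
    min_cells: int = screenstats.DEFAULT_MIN_CELLS
    z_threshold: float = screenstats.DEFAULT_Z_THRESHOLD
    z_null_band: float = screenstats.DEFAULT_Z_NULL_BAND
    hit_metric: str = "normalized_mito"


@dataclass
class RunConfig:
    """Everything a screen run needs; serialised verbatim into the manifest."""

    outdir: str = "mitoscreen_run"
    master_seed: int = 0
    mode: str = "tabular"  # or "images"
    images_dir: str | None = None  # read pre-rendered TIFFs instead of generating
    platemap_path: str | None = None
    compounds: list = field(default_factory=list)  # used when platemap_path is None
    days: tuple = (1, 2)
    controls_per_plate: int = 16
    control_plates_per_day: int = 2
    effects: dict = field(default_factory=dict)  # compound_id -> effect dict
    scene: SceneParams = field(default_factory=SceneParams)
    imaging: ImagingParams = field(default_factory=ImagingParams)
    stats: StatsParams = field(default_factory=StatsParams)
    write_images: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key, klass in (("scene", SceneParams), ("imaging", ImagingParams),
                           ("stats", StatsParams)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = klass(**raw[key])
        if "days" in raw:
            raw["days"] = tuple(raw["days"])
        return cls(**raw)

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["days"] = list(d["days"])
        return d


def effect_from_dict(spec: dict, gamma: float = 1.0) -> EffectSpec:
    """Build an EffectSpec from a config mapping.

    Accepts either explicit multipliers or the shorthand constructors, e.g.
    {"class": "mito_only", "content_multiplier": 1.5},
    {"class": "proportional", "content_multiplier": 1.5},
    {"class": "toxic", "survival_fraction": 0.2}, {"class": "null"}.
    """
    spec = dict(spec)
    klass = spec.pop("class", spec.pop("effect_class", "null"))
    if klass == "proportional" and "area_multiplier" not in spec:
        return EffectSpec.proportional(spec["content_multiplier"], gamma=gamma)
    if klass == "null":
        return EffectSpec.null()
    return EffectSpec(effect_class=klass, **spec)


def analyze_well(
    images: dict[str, ChannelImage],
    profiles,
    iparams: ImagingParams = ImagingParams(),
) -> pd.DataFrame:
    """Run the full per-image chain on one well's three channels.

    ``profiles`` maps (plate, channel) -> IlluminationProfile (or is None to
    skip correction). Returns the per-cell measurement table; the mask
    partition contracts are asserted on every call.
    """
    corrected = {}
    for ch, im in images.items():
        if profiles is not None and (im.plate, ch) in profiles:
            corrected[ch] = correct_illumination(im, profiles[(im.plate, ch)])
        else:
            corrected[ch] = im

    nuclei = segment_nuclei(
        corrected["nuclear"],
        min_area_px=iparams.min_nucleus_area_px,
        max_area_px=iparams.max_nucleus_area_px,
        smooth_sigma_px=iparams.nucleus_smooth_sigma_px,
        h_suppress=iparams.nucleus_h_suppress,
    )

    cutoff = otsu_three_class(
        corrected["mito"].pixels,
        n_bins=iparams.otsu_bins,
        middle_class_to=iparams.middle_class_to,
    ).background_cutoff

    foreground = None
    if iparams.restrict_to_boundary_foreground:
        bnd = corrected["boundary"].pixels
        t = otsu_three_class(bnd, n_bins=iparams.otsu_bins, middle_class_to="foreground")
        foreground = bnd >= t.background_cutoff

    cells = propagate_cells(
        corrected["boundary"], nuclei, foreground,
        PropagationParams(lambda_reg=iparams.lambda_reg, connectivity=iparams.connectivity),
    )
    cyto = cytoplasm_mask(cells, nuclei)
    check_mask_partition(cells, nuclei, cyto)
    return measure_cells(
        cyto, cells, nuclei, corrected["mito"],
        background_cutoff=cutoff,
        exclude_border=iparams.exclude_border,
        background_mode=iparams.background_mode,
    )


def load_well_images(images_dir: str | Path, platemap: pd.DataFrame, site: int = 1):
    """Discover {plate}_{well}_{site}_{channel}.tif files for every well."""
    import tifffile

    images_dir = Path(images_dir)
    out = []
    for row in platemap.itertuples(index=False):
        per_well = {}
        for channel in ("nuclear", "boundary", "mito"):
            path = images_dir / f"{row.plate}_{row.well}_{site}_{channel}.tif"
            if not path.exists():
                raise FileNotFoundError(f"missing image for well {row.plate}/{row.well}: {path}")
            per_well[channel] = ChannelImage(
                pixels=tifffile.imread(path).astype(float), channel=channel,
                plate=row.plate, well=row.well, site=site, day=int(row.day),
            )
        out.append((row, per_well))
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_screen(config: RunConfig) -> Path:
    """Execute a screen per the config; returns the output directory.

    Writes cells.csv, wells.csv, compounds.csv, hits.csv and manifest.json.
    A well whose image analysis fails is skipped with a logged warning and
    listed in the manifest, not fatal.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    gamma = config.scene.content_area_exponent
    effects = {cpd: effect_from_dict(spec, gamma) for cpd, spec in config.effects.items()}

    if config.platemap_path:
        platemap = pd.read_csv(config.platemap_path)
        synth.validate_platemap(platemap)
    else:
        compounds = list(config.compounds) or sorted(effects)
        platemap = synth.screen_platemap(
            compounds, days=tuple(config.days),
            controls_per_plate=config.controls_per_plate,
            control_plates_per_day=config.control_plates_per_day,
        )

    skipped: list[dict] = []
    if config.mode == "tabular":
        cells = synth.simulate_screen_records(
            platemap, effects, config.scene, config.master_seed
        )
    elif config.mode == "images":
        if config.images_dir is not None:
            wells = load_well_images(config.images_dir, platemap)
        else:
            data = synth.generate_plate(
                platemap, effects, config.scene, config.master_seed,
                outdir=(outdir / "images") if config.write_images else None,
            )
            by_well = {}
            for im in data.images:
                by_well.setdefault((im.plate, im.well), {})[im.channel] = im
            wells = [(row, by_well[(row.plate, row.well)])
                     for row in platemap.itertuples(index=False)]
        profiles = estimate_illumination_profiles(
            [im for _, per_well in wells for im in per_well.values()],
            config.imaging.illumination_smoothing_px,
        )
        frames = []
        for row, per_well in wells:
            try:
                df = analyze_well(per_well, profiles, config.imaging)
            except MitoscreenError as exc:
                log.warning("skipping well %s/%s: %s", row.plate, row.well, exc)
                skipped.append(dict(plate=row.plate, well=row.well, reason=str(exc)))
                continue
            df.insert(0, "well", row.well)
            df.insert(0, "plate", row.plate)
            frames.append(df)
        cells = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(columns=["plate", "well"])
        )
    else:
        raise ValueError("mode must be 'tabular' or 'images'")

    wells_df = screenstats.summarize_wells(cells, platemap)
    sp = config.stats
    compounds_df = screenstats.score_compounds(
        wells_df, estimator=sp.estimator, min_cells=sp.min_cells,
        z_threshold=sp.z_threshold, z_null_band=sp.z_null_band,
        hit_metric=sp.hit_metric,
    )
    hits_df = screenstats.call_hits(compounds_df, sp.hit_metric, sp.z_threshold)

    tables = {
        "cells.csv": cells,
        "wells.csv": wells_df,
        "compounds.csv": compounds_df,
        "hits.csv": hits_df,
        "platemap.csv": platemap,
    }
    for name, df in tables.items():
        df.to_csv(outdir / name, index=False)

    manifest = {
        "config": config.to_jsonable(),
        "n_wells": int(len(platemap)),
        "n_cells": int(len(cells)),
        "n_hits": int(len(hits_df)),
        "skipped_wells": skipped,
        "outputs": {name: _sha256(outdir / name) for name in tables},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("run complete: %d wells, %d cells, %d hits", len(platemap), len(cells),
             len(hits_df))
    return outdir


def report(outdir: str | Path, max_gallery: int = 12) -> list[Path]:
    """Render summary figures from a completed run directory.

    A fold-change scatter (mito vs cytoplasm area, the screen's headline
    view: proportional compounds ride the diagonal, size-dissociated ones
    leave it vertically), composite-z histograms for the raw and normalized
    metrics, and a gallery of hit-well mitochondrial images when the run kept
    its TIFFs.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    for required in ("compounds.csv", "wells.csv"):
        if not (outdir / required).exists():
            raise FileNotFoundError(f"missing table {required}; run the screen first")
    compounds = pd.read_csv(outdir / "compounds.csv")
    written: list[Path] = []

    fig, ax = plt.subplots(figsize=(5, 5))
    classes = {
        "none": "0.6", "proportional": "tab:blue",
        "dissociated_up": "tab:red", "dissociated_down": "tab:purple",
    }
    for klass, color in classes.items():
        sel = compounds["effect_class"] == klass
        if sel.any():
            ax.scatter(compounds.loc[sel, "fold_change_area"],
                       compounds.loc[sel, "fold_change_mito"],
                       s=12, c=color, label=klass, alpha=0.7)
    lim = ax.axis()
    hi = max(lim[1], lim[3], 1.2)
    ax.plot([0, hi], [0, hi], "k--", lw=0.8, label="proportionality diagonal")
    ax.set_xlabel("fold change, cytoplasm area (vs DMSO)")
    ax.set_ylabel("fold change, mitochondrial intensity (vs DMSO)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    p = outdir / "fold_scatter.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    written.append(p)

    fig, axes = plt.subplots(1, 2, figsize=(8, 3.2))
    for ax, col, label in zip(
        axes, ("z_integrated_mito", "z_normalized_mito"),
        ("composite z, intensity per cell", "composite z, intensity / cytoplasm area"),
    ):
        vals = compounds[col].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size:
            ax.hist(vals, bins=40, color="0.4")
        ax.axvline(screenstats.DEFAULT_Z_THRESHOLD, color="tab:red", lw=0.8)
        ax.set_xlabel(label)
        ax.set_ylabel("compounds")
    fig.tight_layout()
    p = outdir / "z_histograms.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    written.append(p)

    images_dir = outdir / "images"
    hits_path = outdir / "hits.csv"
    if images_dir.is_dir() and hits_path.exists():
        import tifffile

        hits = pd.read_csv(hits_path)
        wells = pd.read_csv(outdir / "wells.csv")
        gallery = []
        for cpd in hits["compound_id"].head(max_gallery):
            wsel = wells[(wells["compound_id"] == cpd) & (wells["role"] == "treatment")]
            for row in wsel.itertuples(index=False):
                path = images_dir / f"{row.plate}_{row.well}_1_mito.tif"
                if path.exists():
                    gallery.append((cpd, row.well, tifffile.imread(path)))
                    break
        if gallery:
            n = len(gallery)
            cols = min(4, n)
            rows_n = -(-n // cols)
            fig, axes = plt.subplots(rows_n, cols, figsize=(3 * cols, 3 * rows_n),
                                     squeeze=False)
            for ax in axes.ravel():
                ax.axis("off")
            for ax, (cpd, wellname, img) in zip(axes.ravel(), gallery):
                ax.imshow(img, cmap="magma")
                ax.set_title(f"{cpd} ({wellname})", fontsize=8)
            fig.tight_layout()
            p = outdir / "hit_gallery.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            written.append(p)
    return written
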