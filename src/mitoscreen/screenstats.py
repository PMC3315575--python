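"""Screen-level statistics: per-well summaries, day-matched Z-scores against
DMSO controls, composite scores across biological duplicates, toxicity
filtering, hit calling and proportional-vs-dissociated effect classification.

Three per-well metrics are carried throughout, all medians over the well's
measured (non-border) cells: cytoplasm area (the cell-size proxy),
integrated mitochondrial-stain intensity (raw content), and intensity
normalized to cytoplasm area (size-corrected content — the screen's primary
readout). Z-scores are computed per screening day against that day's DMSO
control wells; replicate z's combine by the Stouffer rule sum(z)/sqrt(n),
which has unit variance under the null and reduces to z for one replicate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ControlFitError, DegenerateControlsError

__all__ = [
    "METRICS",
    "WellSummary",
    "ControlDistribution",
    "summarize_well",
    "summarize_wells",
    "fit_controls",
    "well_z",
    "add_well_z",
    "composite_z",
    "toxicity_filter",
    "fold_changes",
    "classify_effect",
    "score_compounds",
    "call_hits",
]

# metric name -> (per-cell column, per-well summary column)
METRICS = {
    "cyto_area": ("cytoplasm_area_px", "median_cyto_area_px"),
    "integrated_mito": ("integrated_mito_AU", "median_integrated_mito_AU"),
    "normalized_mito": ("normalized_mito_AU_per_px", "median_normalized_mito_AU_per_px"),
}

DEFAULT_MIN_CELLS = 40
DEFAULT_Z_THRESHOLD = 1.98
DEFAULT_Z_NULL_BAND = 1.0


@dataclass(frozen=True)
class WellSummary:
    plate: str
    well: str
    cell_count: int
    median_cyto_area_px: float
    median_integrated_mito_AU: float
    median_normalized_mito_AU_per_px: float


@dataclass(frozen=True)
class ControlDistribution:
    """Location/scale of a day's DMSO wells for one metric."""

    day: int
    metric: str
    location: float
    scale: float
    estimator: str
    n_wells: int


def summarize_well(records: pd.DataFrame, plate: str = "", well: str = "") -> WellSummary:
    """Medians of the three metrics over a well's cell records.

    Empty input yields cell_count 0 and missing (NaN) medians.
    """
    n = len(records)
    med = {}
    for cell_col, out_col in METRICS.values():
        med[out_col] = float(np.median(records[cell_col])) if n else float("nan")
    return WellSummary(plate=plate, well=well, cell_count=n, **med)


def summarize_wells(cells: pd.DataFrame, platemap: pd.DataFrame) -> pd.DataFrame:
    """Per-well summary table for every well in the plate map.

    Wells with no measured cells appear with cell_count 0 and NaN medians, so
    a catastrophically toxic well is still represented (and later filtered).
    """
    rows = []
    grouped = dict(iter(cells.groupby(["plate", "well"]))) if len(cells) else {}
    for pm in platemap.itertuples(index=False):
        recs = grouped.get((pm.plate, pm.well))
        if recs is None:
            recs = cells.iloc[0:0]
        s = summarize_well(recs, plate=pm.plate, well=pm.well)
        rows.append(
            dict(
                plate=pm.plate, well=pm.well, day=int(pm.day), role=pm.role,
                compound_id=pm.compound_id, cell_count=s.cell_count,
                median_cyto_area_px=s.median_cyto_area_px,
                median_integrated_mito_AU=s.median_integrated_mito_AU,
                median_normalized_mito_AU_per_px=s.median_normalized_mito_AU_per_px,
            )
        )
    return pd.DataFrame(rows)


def _robust_location_scale(x: np.ndarray) -> tuple[float, float]:
    med = float(np.median(x))
    return med, 1.4826 * float(np.median(np.abs(x - med)))


def fit_controls(
    well_summaries: pd.DataFrame,
    estimator: str = "robust",
    min_control_wells: int = 3,
) -> dict[tuple[int, str], ControlDistribution]:
    """Fit per-(day, metric) null distributions from DMSO control wells.

    ``robust`` uses (median, 1.4826 * MAD); ``moment`` uses (mean, SD).
    Raises ControlFitError for a day with too few control wells and
    DegenerateControlsError when the controls have zero spread.
    """
    if estimator not in ("robust", "moment"):
        raise ValueError("estimator must be 'robust' or 'moment'")
    controls = well_summaries[well_summaries["role"] == "control"]
    days = sorted(well_summaries["day"].unique())
    out: dict[tuple[int, str], ControlDistribution] = {}
    for day in days:
        grp = controls[controls["day"] == day]
        if len(grp) < min_control_wells:
            raise ControlFitError(
                f"day {day} has {len(grp)} control wells; need >= {min_control_wells}"
            )
        for metric, (_, col) in METRICS.items():
            x = grp[col].to_numpy(dtype=float)
            x = x[np.isfinite(x)]
            if x.size < min_control_wells:
                raise ControlFitError(
                    f"day {day}, metric {metric}: only {x.size} finite control medians"
                )
            if estimator == "robust":
                loc, scale = _robust_location_scale(x)
            else:
                loc, scale = float(np.mean(x)), float(np.std(x, ddof=1))
            if scale <= 0:
                raise DegenerateControlsError(
                    f"day {day}, metric {metric}: control scale is zero"
                )
            out[(int(day), metric)] = ControlDistribution(
                day=int(day), metric=metric, location=loc, scale=scale,
                estimator=estimator, n_wells=int(x.size),
            )
    return out


def well_z(value: float, dist: ControlDistribution) -> float:
    """(value - location) / scale; NaN propagates (empty wells)."""
    return (value - dist.location) / dist.scale


def add_well_z(
    well_summaries: pd.DataFrame,
    controls: dict[tuple[int, str], ControlDistribution],
) -> pd.DataFrame:
    """Append z_<metric> columns computed against each well's day controls."""
    df = well_summaries.copy()
    for metric, (_, col) in METRICS.items():
        zcol = f"z_{metric}"
        df[zcol] = [
            well_z(v, controls[(int(d), metric)])
            for v, d in zip(df[col].to_numpy(dtype=float), df["day"])
        ]
    return df


def composite_z(replicate_zs) -> float:
    """Stouffer combination sum(z_i)/sqrt(n) over finite replicate z-scores."""
    z = np.asarray(list(replicate_zs), dtype=float)
    z = z[np.isfinite(z)]
    if z.size == 0:
        return float("nan")
    return float(z.sum() / np.sqrt(z.size))


def toxicity_filter(cell_count: int, min_cells: int = DEFAULT_MIN_CELLS) -> bool:
    """True (keep) iff the well holds at least ``min_cells`` measured cells."""
    return cell_count >= min_cells


def fold_changes(
    well_summaries: pd.DataFrame,
    compound_wells: pd.DataFrame,
) -> tuple[float, float]:
    """(fold mito, fold area) of a compound's wells relative to DMSO.

    Each well's median is divided by the mean of its own day's control
    medians, then folds average over the replicate wells. Computed for
    integrated mitochondrial intensity and cytoplasm area.
    """
    controls = well_summaries[well_summaries["role"] == "control"]
    folds = {"integrated_mito": [], "cyto_area": []}
    for row in compound_wells.itertuples(index=False):
        day_controls = controls[controls["day"] == row.day]
        for metric in folds:
            col = METRICS[metric][1]
            denom = float(day_controls[col].mean())
            if not np.isfinite(denom) or denom == 0:
                raise DegenerateControlsError(
                    f"day {row.day}: control mean for {metric} is zero or undefined"
                )
            folds[metric].append(getattr(row, col) / denom)
    fm = float(np.mean(folds["integrated_mito"])) if folds["integrated_mito"] else float("nan")
    fa = float(np.mean(folds["cyto_area"])) if folds["cyto_area"] else float("nan")
    return fm, fa


def classify_effect(
    z_raw: float,
    z_area: float,
    z_norm: float,
    z_hit: float = DEFAULT_Z_THRESHOLD,
    z_null_band: float = DEFAULT_Z_NULL_BAND,
) -> str:
    """Classify a compound's composite z-profile.

    dissociated_up/down: the size-normalized signal itself scores beyond the
    hit threshold (content moved independently of size). proportional: raw
    content and cell size both score as hits while the normalized signal
    stays inside the null band. Otherwise none.
    """
    if np.isfinite(z_norm) and z_norm > z_hit:
        return "dissociated_up"
    if np.isfinite(z_norm) and z_norm < -z_hit:
        return "dissociated_down"
    if (
        np.isfinite(z_norm) and abs(z_norm) <= z_null_band
        and np.isfinite(z_raw) and z_raw > z_hit
        and np.isfinite(z_area) and z_area > z_hit
    ):
        return "proportional"
    return "none"


def score_compounds(
    well_summaries: pd.DataFrame,
    estimator: str = "robust",
    min_cells: int = DEFAULT_MIN_CELLS,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    z_null_band: float = DEFAULT_Z_NULL_BAND,
    hit_metric: str = "normalized_mito",
) -> pd.DataFrame:
    """Score every treatment compound of a summarised screen.

    Wells failing the toxicity filter are dropped before scoring; composite
    z's are formed only from the surviving replicates. A compound passes
    toxicity if at least one replicate well survives, and is a hit iff it
    passes toxicity and its composite z for ``hit_metric`` exceeds
    ``z_threshold`` (strictly).
    """
    controls = fit_controls(well_summaries, estimator=estimator)
    zdf = add_well_z(well_summaries, controls)
    rows = []
    treatments = zdf[zdf["role"] == "treatment"]
    for compound_id, grp in treatments.groupby("compound_id", sort=True):
        passing = grp[[toxicity_filter(c, min_cells) for c in grp["cell_count"]]]
        zs = {m: composite_z(passing[f"z_{m}"]) for m in METRICS}
        passed = len(passing) > 0
        if passed:
            fold_mito, fold_area = fold_changes(zdf, passing)
        else:
            fold_mito = fold_area = float("nan")
        z_hit_metric = zs[hit_metric]
        is_hit = bool(passed and np.isfinite(z_hit_metric) and z_hit_metric > z_threshold)
        rows.append(
            dict(
                compound_id=compound_id,
                n_replicates=int(len(grp)),
                n_passing=int(len(passing)),
                passed_toxicity=passed,
                z_cyto_area=zs["cyto_area"],
                z_integrated_mito=zs["integrated_mito"],
                z_normalized_mito=zs["normalized_mito"],
                fold_change_mito=fold_mito,
                fold_change_area=fold_area,
                is_hit=is_hit,
                effect_class=classify_effect(
                    zs["integrated_mito"], zs["cyto_area"], zs["normalized_mito"],
                    z_hit=z_threshold, z_null_band=z_null_band,
                ),
            )
        )
    return pd.DataFrame(rows)


def call_hits(
    scores: pd.DataFrame,
    metric: str = "normalized_mito",
    z_threshold: float = DEFAULT_Z_THRESHOLD,
) -> pd.DataFrame:
    """Hits: toxicity-passing compounds with composite z strictly above threshold."""
    if len(scores) == 0:
        return scores.copy()
    zcol = f"z_{metric}"
    sel = scores["passed_toxicity"] & (scores[zcol] > z_threshold)
    return scores[sel].sort_values(zcol, ascending=False).reset_index(drop=True)
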