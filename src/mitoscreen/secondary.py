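"""Secondary-assay calculators: mtDNA copy number, relative expression and
respiration fold-changes.

qPCR quantities assume perfect amplification efficiency (factor 2 per
cycle) unless overridden: a mitochondrial-vs-nuclear probe pair converts to
a copy-number ratio 2**(Ct_nuclear - Ct_mito), and expression folds use the
delta-delta-Ct rule against a reference gene. Respiration (oxygen
consumption rate, OCR) fold-changes divide group means of per-sample
normalized OCR, under a selectable normalizer (cell count, cell volume,
total protein, or none) — the dependence of the fold on the normalizer is
itself a readout of whether an effect survives cell-size correction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "mtdna_ratio",
    "ddct_fold",
    "respiration_fold",
    "expression_folds",
    "mtdna_ratio_fold",
]

RESPIRATION_NORMALIZERS = ("cell_count", "cell_volume", "total_protein", "none")
RESPIRATION_STATES = ("basal", "uncoupled")


def mtdna_ratio(ct_mt, ct_nu, efficiency: float = 2.0):
    """Mitochondrial-to-nuclear DNA copy-number ratio from probe Cts.

    ratio = efficiency**(Ct_nuclear - Ct_mito): equal Cts give 1; each cycle
    the mitochondrial probe crosses earlier doubles the ratio. Accepts
    scalars or arrays.
    """
    if efficiency <= 1:
        raise ValueError("amplification efficiency must exceed 1")
    ct_mt = np.asarray(ct_mt, dtype=float)
    ct_nu = np.asarray(ct_nu, dtype=float)
    out = efficiency ** (ct_nu - ct_mt)
    return float(out) if out.ndim == 0 else out


def ddct_fold(
    ct_target_treated,
    ct_ref_treated,
    ct_target_control,
    ct_ref_control,
    efficiency: float = 2.0,
):
    """Relative expression fold by the delta-delta-Ct rule.

    fold = efficiency**(-ddCt) with
    ddCt = (Ct_target - Ct_ref)_treated - (Ct_target - Ct_ref)_control.
    """
    if efficiency <= 1:
        raise ValueError("amplification efficiency must exceed 1")
    ddct = (np.asarray(ct_target_treated, float) - np.asarray(ct_ref_treated, float)) - (
        np.asarray(ct_target_control, float) - np.asarray(ct_ref_control, float)
    )
    out = efficiency ** (-ddct)
    return float(out) if out.ndim == 0 else out


def expression_folds(
    qpcr: pd.DataFrame,
    targets: list[str],
    reference: str = "Actb",
    efficiency: float = 2.0,
) -> pd.Series:
    """Treated/control expression folds for each target gene.

    ``qpcr`` is long-format with columns sample_id, group {control, treated},
    target, Ct; group-mean Cts feed the delta-delta-Ct rule.
    """
    mean_ct = qpcr.groupby(["group", "target"])["Ct"].mean()
    folds = {}
    for t in targets:
        folds[t] = ddct_fold(
            mean_ct[("treated", t)], mean_ct[("treated", reference)],
            mean_ct[("control", t)], mean_ct[("control", reference)],
            efficiency=efficiency,
        )
    return pd.Series(folds, name="fold")


def mtdna_ratio_fold(
    qpcr: pd.DataFrame,
    mito_target: str = "mtND2",
    nuclear_target: str = "Alu",
    efficiency: float = 2.0,
) -> float:
    """Treated/control fold of the mtDNA/nuDNA copy-number ratio."""
    mean_ct = qpcr.groupby(["group", "target"])["Ct"].mean()
    r_treated = mtdna_ratio(
        mean_ct[("treated", mito_target)], mean_ct[("treated", nuclear_target)], efficiency
    )
    r_control = mtdna_ratio(
        mean_ct[("control", mito_target)], mean_ct[("control", nuclear_target)], efficiency
    )
    return float(r_treated / r_control)


def respiration_fold(
    treated: pd.DataFrame,
    control: pd.DataFrame,
    normalizer: str = "total_protein",
    state: str = "uncoupled",
) -> dict:
    """Treated/control fold of group-mean normalized oxygen consumption.

    Rows need columns basal_OCR, uncoupled_OCR and (unless normalizer is
    "none") the normalizer column; per-sample OCR/normalizer values are
    averaged within group, then divided. Zero or negative normalizer values
    fail naming the sample.
    """
    if normalizer not in RESPIRATION_NORMALIZERS:
        raise ValueError(f"normalizer must be one of {RESPIRATION_NORMALIZERS}")
    if state not in RESPIRATION_STATES:
        raise ValueError(f"state must be one of {RESPIRATION_STATES}")
    if len(treated) == 0 or len(control) == 0:
        raise ValueError("need at least one sample per group")
    col = f"{state}_OCR"

    def group_mean(df: pd.DataFrame) -> float:
        ocr = df[col].to_numpy(dtype=float)
        if np.any(ocr < 0):
            raise ValueError("OCR values must be nonnegative")
        if normalizer == "none":
            return float(np.mean(ocr))
        norm = df[normalizer].to_numpy(dtype=float)
        bad = np.asarray(df["sample_id"])[norm <= 0]
        if bad.size:
            raise ValueError(f"nonpositive {normalizer} for samples: {bad.tolist()}")
        return float(np.mean(ocr / norm))

    mt, mc = group_mean(treated), group_mean(control)
    return {
        "fold": mt / mc,
        "treated_mean": mt,
        "control_mean": mc,
        "normalizer": normalizer,
        "state": state,
        "n_treated": int(len(treated)),
        "n_control": int(len(control)),
    }
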