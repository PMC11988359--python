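"""ROI handling: mask erosion, per-lesion summaries, inter-reader agreement.

Mirrors a radiologist workflow: lesion masks are eroded by one 6-connected
iteration to suppress partial-volume voxels at the rim, parameter maps are
averaged over the eroded mask intersected with the converged-fit mask, and
agreement between two readers is quantified with a two-way random-effects,
absolute-agreement, single-measures intraclass correlation coefficient
(ICC(2,1)). A second reader can be emulated on synthetic data by jittering
mask boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .mapfit import ParamMaps

__all__ = [
    "ICCResult",
    "erode_mask",
    "roi_summary",
    "summarize_lesions",
    "icc_two_reader",
    "jitter_mask",
    "average_readers",
]

_STRUCT6 = ndimage.generate_binary_structure(3, 1)  # 6-connected


def erode_mask(mask: np.ndarray, iterations: int = 1, min_voxels: int = 5) -> np.ndarray:
    """6-connected morphological erosion of a binary 3D mask.

    Applied one iteration at a time; an iteration that would leave fewer
    than ``min_voxels`` voxels is skipped with a warning, so small masks
    are never eroded away.
    """
    mask = np.asarray(mask, dtype=bool)
    if iterations < 0:
        raise ValueError("iterations must be non-negative")
    out = mask
    for _ in range(iterations):
        nxt = ndimage.binary_erosion(out, structure=_STRUCT6)
        if nxt.sum() < min_voxels:
            warnings.warn(
                "erosion skipped: would leave fewer than "
                f"{min_voxels} voxels", stacklevel=2)
            break
        out = nxt
    return out


def roi_summary(
    maps: ParamMaps,
    mask: np.ndarray,
    erode_iterations: int = 1,
    lesion_id: int | None = None,
    group: str | None = None,
    reader_id: str = "reader1",
) -> dict:
    """ROI-mean of every parameter map over eroded mask ∩ converged voxels.

    Returns a flat record (lesion_id, group, reader_id, one mean per map).
    Raises if no converged voxel survives inside the eroded mask.
    """
    mask = erode_mask(mask, erode_iterations)
    roi = mask & maps.converged_mask
    if not roi.any():
        raise ValueError("ROI contains no converged voxels")
    rec = {"lesion_id": lesion_id, "group": group, "reader_id": reader_id,
           "n_voxels": int(roi.sum())}
    for name, vol in maps.maps.items():
        rec[name] = float(np.nanmean(vol[roi]))
    return rec


def summarize_lesions(
    maps: ParamMaps,
    label_vol: np.ndarray,
    truth: pd.DataFrame | None = None,
    erode_iterations: int = 1,
    reader_id: str = "reader1",
) -> pd.DataFrame:
    """One ROI summary row per lesion in an integer label volume.

    ``label_vol`` encodes lesion_id + 1 (0 = background), as produced by
    the phantom renderer; ``truth`` optionally supplies group and
    immunohistochemical labels to merge into the records.
    """
    rows = []
    for lab in np.unique(label_vol):
        if lab == 0:
            continue
        lid = int(lab) - 1
        group = None
        if truth is not None:
            group = truth.loc[truth["lesion_id"] == lid, "group"].item()
        rows.append(roi_summary(maps, label_vol == lab, erode_iterations,
                                lesion_id=lid, group=group, reader_id=reader_id))
    records = pd.DataFrame(rows)
    if truth is not None:
        extra = [c for c in truth.columns
                 if c not in ("d", "v_in", "d_ex", "cellularity", "group")]
        records = records.merge(truth[extra], on="lesion_id", how="left")
    return records


def jitter_mask(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Emulate a second reader: randomly dilate or erode the boundary by
    one 6-connected voxel layer (erosion respects the 5-voxel floor)."""
    if rng.random() < 0.5:
        return ndimage.binary_dilation(np.asarray(mask, bool), structure=_STRUCT6)
    return erode_mask(mask, 1)


def average_readers(rec1: pd.DataFrame, rec2: pd.DataFrame,
                    on: str = "lesion_id") -> pd.DataFrame:
    """Average two readers' lesion records parameter-by-parameter."""
    num = [c for c in rec1.columns
           if c in rec2.columns and pd.api.types.is_numeric_dtype(rec1[c])
           and c != on]
    merged = rec1.merge(rec2, on=on, suffixes=("_1", "_2"))
    out = merged[[on]].copy()
    for c in num:
        out[c] = (merged[f"{c}_1"] + merged[f"{c}_2"]) / 2.0
    for c in rec1.columns:
        if c not in out.columns and c != on and not pd.api.types.is_numeric_dtype(rec1[c]):
            out[c] = merged.get(f"{c}_1", rec1[c])
    return out


@dataclass(frozen=True)
class ICCResult:
    """ICC(2,1) estimate with its 95% confidence interval."""

    icc: float
    ci_low: float
    ci_high: float
    n: int


def icc_two_reader(values_reader1, values_reader2) -> ICCResult:
    """Two-way random-effects, absolute-agreement, single-measures ICC.

    Computed with pingouin's ANOVA-based estimator (ICC2 in the
    Shrout–Fleiss naming); the confidence interval comes from the
    F-distribution. Requires paired measurements on n ≥ 3 targets.
    """
    x = np.asarray(values_reader1, dtype=float)
    y = np.asarray(values_reader2, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("reader vectors must be 1D and equally long")
    n = x.size
    if n < 3:
        raise ValueError("ICC needs at least 3 paired measurements")
    import pingouin as pg

    df = pd.DataFrame({
        "target": np.tile(np.arange(n), 2),
        "rater": np.repeat(["r1", "r2"], n),
        "score": np.concatenate([x, y]),
    })
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = pg.intraclass_corr(df, targets="target", raters="rater",
                                 ratings="score")
    res = res.set_index("Type")
    # pingouin labels the two-way random absolute-agreement single-measures
    # estimator "ICC2" (older releases) or "ICC(A,1)" (McGraw–Wong naming)
    key = "ICC2" if "ICC2" in res.index else "ICC(A,1)"
    row = res.loc[key]
    ci_col = "CI95%" if "CI95%" in res.columns else "CI95"
    lo, hi = row[ci_col]
    return ICCResult(icc=float(row["ICC"]), ci_low=float(lo), ci_high=float(hi), n=n)
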