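"""Generic stain quantification: stained-area %, integrated optical
density, and group-reference normalization of study tables."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

__all__ = [
    "AreaFractionResult",
    "IodResult",
    "stained_area_fraction",
    "integrated_optical_density",
    "normalize_to_reference",
]


@dataclass
class AreaFractionResult:
    roi_name: str
    stained_px: int
    roi_px: int
    fraction_pct: float
    threshold: float


@dataclass
class IodResult:
    roi_name: str
    iod: float        # sum of per-pixel OD over the ROI (unitless x px)
    mean_od: float
    roi_px: int


def stained_area_fraction(stain_channel: np.ndarray, roi_mask: np.ndarray,
                          threshold_rule: float | str = "otsu",
                          roi_name: str = "roi") -> AreaFractionResult:
    """Percentage of ROI pixels whose stain OD exceeds a threshold.

    ``threshold_rule`` is either a fixed OD value or ``"otsu"`` (Otsu's
    method computed on the ROI pixels).
    """
    roi = np.asarray(roi_mask, dtype=bool)
    if not roi.any():
        raise ValueError("ROI mask is empty")
    vals = np.asarray(stain_channel, dtype=float)[roi]
    if isinstance(threshold_rule, str):
        if threshold_rule != "otsu":
            raise ValueError(f"unknown threshold rule {threshold_rule!r}")
        threshold = float(threshold_otsu(vals)) if np.ptp(vals) > 0 else float(vals.max())
    else:
        threshold = float(threshold_rule)
    stained = int(np.count_nonzero(vals > threshold))
    roi_px = int(roi.sum())
    return AreaFractionResult(
        roi_name=roi_name, stained_px=stained, roi_px=roi_px,
        fraction_pct=100.0 * stained / roi_px, threshold=threshold,
    )


def integrated_optical_density(od_channel: np.ndarray, roi_mask: np.ndarray,
                               roi_name: str = "roi") -> IodResult:
    """Sum of per-pixel OD over the ROI (the LFB myelin readout)."""
    roi = np.asarray(roi_mask, dtype=bool)
    if not roi.any():
        raise ValueError("ROI mask is empty")
    vals = np.asarray(od_channel, dtype=float)[roi]
    if not np.all(np.isfinite(vals)):
        raise ValueError("OD channel contains non-finite values in the ROI")
    return IodResult(
        roi_name=roi_name, iod=float(vals.sum()),
        mean_od=float(vals.mean()), roi_px=int(roi.sum()),
    )


def normalize_to_reference(study: pd.DataFrame, measure: str,
                           reference_group: dict, percent: bool = False
                           ) -> pd.DataFrame:
    """Divide a measure by its reference-group mean, per study.

    ``reference_group`` maps column names (genotype/treatment/timepoint
    ...) to the values identifying the reference rows.  Normalization is
    fenced by ``study_id``: each study is normalized to its own reference
    group and groups are never pooled across studies.  With
    ``percent=True`` the reference mean maps to 100 instead of 1.
    """
    out = []
    scale = 100.0 if percent else 1.0
    for study_id, sub in study.groupby("study_id", sort=False):
        sub = sub[sub["measure"] == measure].copy()
        sel = np.ones(len(sub), dtype=bool)
        for col, val in reference_group.items():
            sel &= (sub[col] == val).to_numpy()
        ref = sub.loc[sel, "value"]
        if ref.empty:
            raise ValueError(
                f"reference group {reference_group!r} empty in study {study_id!r}"
            )
        ref_mean = float(ref.mean())
        if ref_mean == 0:
            raise ValueError(f"reference mean is zero in study {study_id!r}")
        sub["value"] = sub["value"] / ref_mean * scale
        sub["units"] = "% of reference" if percent else "fold of reference"
        out.append(sub)
    return pd.concat(out, ignore_index=True)
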