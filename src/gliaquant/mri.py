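"""MRI quantification: magnetization-transfer-ratio maps, mono-exponential
T2 fits of multi-echo ROI signals, and baseline-relative signal ratios.

MTR = (S0 - SMTR) / S0, where S0 and SMTR are the signal intensities of
the acquisitions without and with the MT saturation pulse.  T2 comes from
least-squares fitting S(TE) = S0 * exp(-TE / T2) to the ROI-mean signal
versus echo time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "MtrMap",
    "T2Fit",
    "compute_mtr",
    "estimate_noise_floor",
    "roi_mean_signal",
    "relative_signal",
    "fit_t2",
]


@dataclass
class MtrMap:
    """Per-pixel MTR with a validity mask (S0 above the noise floor).

    Negative MTR values (possible at low SNR) are retained, not clipped;
    clipping would bias ROI means.
    """

    mtr: np.ndarray
    valid: np.ndarray
    noise_floor: float

    def roi_mean(self, roi_mask: np.ndarray) -> float:
        roi = np.asarray(roi_mask, dtype=bool) & self.valid
        if not roi.any():
            raise ValueError("no valid pixel in ROI")
        return float(self.mtr[roi].mean())


@dataclass
class T2Fit:
    t2_ms: float
    s0: float
    residual_norm: float
    converged: bool


def estimate_noise_floor(image: np.ndarray, corner: int = 8, factor: float = 3.0
                         ) -> float:
    """``factor`` x the SD of a background corner patch (default 3 sigma)."""
    patch = np.asarray(image, dtype=float)[:corner, :corner]
    return factor * float(patch.std())


def compute_mtr(s0: np.ndarray, smtr: np.ndarray,
                noise_floor: float | None = None) -> MtrMap:
    """MTR = (S0 - SMTR)/S0 per pixel.

    Pixels with S0 at or below the noise floor are marked invalid (and
    excluded from ROI means) rather than set to zero.  If ``noise_floor``
    is None it is estimated as 3x the SD of a corner background patch.
    """
    s0 = np.asarray(s0, dtype=float)
    smtr = np.asarray(smtr, dtype=float)
    if s0.shape != smtr.shape:
        raise ValueError(f"shape mismatch: S0 {s0.shape} vs SMTR {smtr.shape}")
    if noise_floor is None:
        noise_floor = estimate_noise_floor(s0)
    valid = s0 > noise_floor
    mtr = np.zeros_like(s0)
    np.divide(s0 - smtr, s0, out=mtr, where=valid)
    return MtrMap(mtr=mtr, valid=valid, noise_floor=float(noise_floor))


def roi_mean_signal(image: np.ndarray, roi_mask: np.ndarray) -> float:
    """Arithmetic mean of the image over the ROI pixels."""
    roi = np.asarray(roi_mask, dtype=bool)
    if not roi.any():
        raise ValueError("ROI mask is empty")
    if roi.shape != np.asarray(image).shape:
        raise ValueError("ROI shape does not match the image")
    return float(np.asarray(image, dtype=float)[roi].mean())


def relative_signal(values, baseline_index: int = 0) -> np.ndarray:
    """Per-timepoint signal relative to the baseline timepoint.

    ``values`` is the sequence of ROI-mean signals over timepoints; the
    ratio at the baseline index is 1 by construction.
    """
    vals = np.asarray(values, dtype=float)
    baseline = vals[baseline_index]
    if baseline <= 0:
        raise ValueError("baseline signal must be positive")
    return vals / baseline


def fit_t2(te_ms, signals) -> T2Fit:
    """Mono-exponential T2 fit of ROI-mean signal versus echo time.

    Initializes from a log-linear regression of ln S on TE, then refines by
    nonlinear least squares on S(TE) = S0 exp(-TE/T2).  A non-decaying
    series (fitted T2 <= 0 or optimizer failure) returns converged=False.
    """
    te = np.asarray(te_ms, dtype=float)
    sig = np.asarray(signals, dtype=float)
    if te.size < 3:
        raise ValueError("need at least 3 echoes to fit T2")
    if np.any(np.diff(te) <= 0):
        raise ValueError("echo times must be strictly increasing")
    if np.any(sig <= 0):
        raise ValueError("signals must be positive for initialization")
    slope, intercept = np.polyfit(te, np.log(sig), 1)
    if slope >= 0:
        return T2Fit(t2_ms=float("nan"), s0=float("nan"),
                     residual_norm=float("nan"), converged=False)
    t2_init = -1.0 / slope
    s0_init = float(np.exp(intercept))
    try:
        popt, _ = curve_fit(
            lambda t, s0, t2: s0 * np.exp(-t / t2),
            te, sig, p0=(s0_init, t2_init), maxfev=5000,
        )
    except RuntimeError:
        return T2Fit(t2_ms=float("nan"), s0=float("nan"),
                     residual_norm=float("nan"), converged=False)
    s0_fit, t2_fit = float(popt[0]), float(popt[1])
    resid = sig - s0_fit * np.exp(-te / t2_fit)
    converged = t2_fit > 0 and np.isfinite(t2_fit)
    return T2Fit(t2_ms=t2_fit, s0=s0_fit,
                 residual_norm=float(np.linalg.norm(resid)),
                 converged=converged)
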