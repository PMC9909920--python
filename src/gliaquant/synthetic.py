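"""Ground-truthed synthetic data for every stage of the pipeline.

Three families of generators:

* brightfield IHC scenes — brown DAB-stained ramified microglia (disk soma
  plus random-walk branched processes) over a blue hematoxylin tissue
  background with a white non-tissue margin, composited additively in
  optical-density space and exponentiated to 8-bit RGB, so that color
  deconvolution is exactly invertible at zero noise;
* MRI — magnetization-transfer image pairs (S0 / SMTR) and 16-echo
  spin-echo stacks with per-ROI ground-truth MTR and T2;
* study tables — long-format genotype x treatment x timepoint measurement
  tables with per-animal repeated-measures structure.

Every generator takes an explicit seed and is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .stains import MAX_OD, ODImage, StainVectors, od_to_rgb

__all__ = [
    "IhcSceneParams",
    "GroundTruth",
    "MriSimParams",
    "StudyDesign",
    "GroupEffects",
    "generate_ihc_image",
    "generate_stain_field",
    "generate_mtr_pair",
    "generate_multiecho_stack",
    "generate_study_tables",
]

# 16-echo spin-echo schedule: 11 ms spacing, TE from 11 to 176 ms.
PAPER_TE_LIST_MS = tuple(float(te) for te in range(11, 177, 11))

# In-plane pixel size of the MRI acquisitions, mm.
PAPER_MRI_PIXEL_SIZE_MM = 0.094


# --------------------------------------------------------------------------
# IHC scene generation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class IhcSceneParams:
    """Parameters of a synthetic DAB/hematoxylin microglia scene.

    Geometry is in pixels at a 20x-like scale (soma diameter ~10 px,
    process width 1 px).  ``dab_intensity_soma``/``_process`` and
    ``hematoxylin_background_od`` are optical densities; ``noise_sd`` is
    Gaussian noise in 8-bit intensity units added after rendering.
    """

    image_shape: tuple[int, int] = (512, 512)
    n_cells: int = 15
    soma_radius_range: tuple[float, float] = (4.0, 7.0)
    processes_per_cell: tuple[int, int] = (3, 6)
    process_length_range: tuple[float, float] = (20.0, 60.0)
    branch_probability: float = 0.03
    dab_intensity_soma: float = 0.9
    dab_intensity_process: float = 0.45
    hematoxylin_background_od: float = 0.25
    tissue_fraction: float = 0.9
    noise_sd: float = 2.0
    intensity_jitter: float = 0.0        # per-cell uniform(1-j, 1+j) DAB factor
    min_center_spacing_factor: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.image_shape
        if rows < 64 or cols < 64:
            raise ValueError("image_shape must be at least 64x64")
        if not (0.0 <= self.tissue_fraction <= 1.0):
            raise ValueError("tissue_fraction must lie in [0, 1]")
        if self.n_cells < 0:
            raise ValueError("n_cells must be nonnegative")
        for name in ("soma_radius_range", "processes_per_cell", "process_length_range"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ValueError(f"{name} must be a nonnegative (lo, hi) range")
        if not (0.0 <= self.branch_probability <= 1.0):
            raise ValueError("branch_probability must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not (0.0 <= self.intensity_jitter < 1.0):
            raise ValueError("intensity_jitter must lie in [0, 1)")


@dataclass
class GroundTruth:
    """Generator-side truth for one synthetic IHC scene.

    ``process_polylines[i]`` is the list of (n_points, 2) float arrays of
    (row, col) vertices for cell ``i``; matching ``process_proximal[i]``
    holds per-vertex proximal flags (within ``proximal_radius`` of the soma
    centre).  Lengths are polyline arc lengths (diagonal step = sqrt(2)).
    """

    soma_centers: np.ndarray            # (n_cells, 2) float (row, col)
    soma_radii: np.ndarray              # (n_cells,) float
    soma_mask: np.ndarray               # bool image
    process_polylines: list[list[np.ndarray]]
    process_proximal: list[list[np.ndarray]]
    process_length_per_cell: np.ndarray  # (n_cells,) arc length, px
    proximal_length_per_cell: np.ndarray
    tissue_mask: np.ndarray             # bool image
    proximal_radius: float              # truth radius of the proximal zone

    def __post_init__(self) -> None:
        if np.any(self.soma_mask & ~self.tissue_mask):
            raise ValueError("soma_mask must be contained in tissue_mask")


def _smooth_field(shape: tuple[int, int], rng: np.random.Generator,
                  sigma_frac: float = 0.12) -> np.ndarray:
    """Smoothed Gaussian noise field, standardized; used for blob masks."""
    field_ = rng.standard_normal(shape)
    sigma = sigma_frac * min(shape)
    field_ = ndimage.gaussian_filter(field_, sigma=sigma)
    sd = field_.std()
    if sd > 0:
        field_ = (field_ - field_.mean()) / sd
    return field_


def _fraction_mask(shape, fraction: float, rng: np.random.Generator,
                   sigma_frac: float = 0.12) -> np.ndarray:
    """Smooth random mask covering ``fraction`` of the frame (by quantile cut)."""
    if fraction <= 0.0:
        return np.zeros(shape, dtype=bool)
    if fraction >= 1.0:
        return np.ones(shape, dtype=bool)
    field_ = _smooth_field(shape, rng, sigma_frac)
    cut = np.quantile(field_, 1.0 - fraction)
    return field_ > cut


_STEP_LENGTH = {  # arc length of one 8-connected step
    (0, 1): 1.0, (0, -1): 1.0, (1, 0): 1.0, (-1, 0): 1.0,
    (1, 1): math.sqrt(2), (1, -1): math.sqrt(2),
    (-1, 1): math.sqrt(2), (-1, -1): math.sqrt(2),
}


def _walk_process(start: np.ndarray, angle: float, length_budget: float,
                  tissue: np.ndarray, rng: np.random.Generator,
                  branch_probability: float, depth: int = 0,
                  turn_sd: float = 0.35) -> list[tuple[np.ndarray, float]]:
    """Grow one process as an 8-connected random walk inside the tissue mask.

    Returns a list of (polyline, arc_length) pairs — the main walk plus any
    branches it spawned.  Walks terminate at the tissue border or when the
    length budget is spent.
    """
    rows, cols = tissue.shape
    pos = np.array(start, dtype=int)
    points = [pos.astype(float)]
    arc = 0.0
    results: list[tuple[np.ndarray, float]] = []
    while arc < length_budget:
        angle += rng.normal(0.0, turn_sd)
        step = (int(round(math.sin(angle))), int(round(math.cos(angle))))
        if step == (0, 0):
            step = (0, 1)
        nxt = pos + step
        if not (0 <= nxt[0] < rows and 0 <= nxt[1] < cols) or not tissue[nxt[0], nxt[1]]:
            break
        pos = nxt
        points.append(pos.astype(float))
        arc += _STEP_LENGTH[step]
        if depth < 2 and rng.random() < branch_probability:
            branch_angle = angle + rng.choice([-1.0, 1.0]) * rng.uniform(0.6, 1.2)
            results.extend(
                _walk_process(pos, branch_angle, (length_budget - arc) * 0.7,
                              tissue, rng, branch_probability, depth + 1, turn_sd)
            )
    if len(points) >= 2:
        results.append((np.array(points), arc))
    return results


def _polyline_pixels(polyline: np.ndarray) -> np.ndarray:
    """Integer pixel coordinates visited by an 8-connected polyline."""
    return np.unique(np.rint(polyline).astype(int), axis=0)


def generate_ihc_image(params: IhcSceneParams) -> tuple[np.ndarray, GroundTruth]:
    """Render a synthetic Iba1-like DAB scene and its ground truth.

    Composites hematoxylin tissue background and DAB soma/process
    concentrations in OD space via the H-DAB stain basis, converts to 8-bit
    transmitted-light RGB, then adds Gaussian intensity noise.  Identical
    parameters (including seed) give bit-identical output.
    """
    rng = np.random.default_rng(params.seed)
    shape = params.image_shape
    tissue = _fraction_mask(shape, params.tissue_fraction, rng)
    # Soma must sit fully inside tissue, away from the border.
    r_lo, r_hi = params.soma_radius_range
    margin = int(math.ceil(r_hi)) + 2
    interior = ndimage.binary_erosion(tissue, iterations=margin) if margin else tissue
    candidates = np.argwhere(interior)

    min_spacing = params.min_center_spacing_factor * r_hi
    centers: list[np.ndarray] = []
    radii: list[float] = []
    max_tries = 200 * max(params.n_cells, 1)
    tries = 0
    while len(centers) < params.n_cells:
        if tries >= max_tries or len(candidates) == 0:
            raise RuntimeError(
                "could not place non-overlapping soma: minimum centre spacing "
                f"{min_spacing:.1f}px with {params.n_cells} cells does not fit "
                f"the tissue area; relax n_cells or min_center_spacing_factor"
            )
        tries += 1
        c = candidates[rng.integers(len(candidates))].astype(float)
        if all(np.hypot(*(c - p)) >= min_spacing for p in centers):
            centers.append(c)
            radii.append(rng.uniform(r_lo, r_hi))

    jitter = (
        rng.uniform(1.0 - params.intensity_jitter, 1.0 + params.intensity_jitter,
                    size=len(centers))
        if params.intensity_jitter > 0 else np.ones(len(centers))
    )
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    soma_mask = np.zeros(shape, dtype=bool)
    dab = np.zeros(shape, dtype=float)
    for (c, r), j in zip(zip(centers, radii), jitter):
        disk = (rr - c[0]) ** 2 + (cc - c[1]) ** 2 <= r ** 2
        disk &= tissue
        soma_mask |= disk
        dab[disk] = params.dab_intensity_soma * j

    proximal_radius = 4.0 * float(np.median(radii)) if radii else 0.0
    polylines: list[list[np.ndarray]] = []
    proximal_flags: list[list[np.ndarray]] = []
    total_len = np.zeros(len(centers))
    prox_len = np.zeros(len(centers))
    k_lo, k_hi = params.processes_per_cell
    for i, (c, r) in enumerate(zip(centers, radii)):
        cell_lines: list[np.ndarray] = []
        cell_flags: list[np.ndarray] = []
        n_proc = int(rng.integers(k_lo, k_hi + 1))
        for _ in range(n_proc):
            angle = rng.uniform(0, 2 * math.pi)
            start = np.rint(
                c + (r + 1.0) * np.array([math.sin(angle), math.cos(angle)])
            ).astype(int)
            start = np.clip(start, 0, np.array(shape) - 1)
            if not tissue[start[0], start[1]]:
                continue
            budget = rng.uniform(*params.process_length_range)
            for line, arc in _walk_process(start, angle, budget, tissue, rng,
                                           params.branch_probability):
                pix = _polyline_pixels(line)
                on_soma = soma_mask[pix[:, 0], pix[:, 1]]
                dab[pix[~on_soma, 0], pix[~on_soma, 1]] = np.maximum(
                    dab[pix[~on_soma, 0], pix[~on_soma, 1]],
                    params.dab_intensity_process * jitter[i],
                )
                cell_lines.append(line)
                dist = np.hypot(line[:, 0] - c[0], line[:, 1] - c[1])
                flags = dist <= proximal_radius
                cell_flags.append(flags)
                total_len[i] += arc
                # per-segment arc split by the proximal flag of the far vertex
                seg = np.hypot(*np.diff(line, axis=0).T)
                prox_len[i] += float(seg[flags[1:]].sum())
        polylines.append(cell_lines)
        proximal_flags.append(cell_flags)

    hema = np.where(tissue, params.hematoxylin_background_od, 0.0)
    basis = StainVectors.hdab().matrix
    od = (
        hema[..., None] * basis[0][None, None, :]
        + dab[..., None] * basis[1][None, None, :]
    )
    od = np.clip(od, 0.0, MAX_OD)
    rgb = od_to_rgb(ODImage(od)).astype(float)
    if params.noise_sd > 0:
        rgb = rgb + rng.normal(0.0, params.noise_sd, size=rgb.shape)
    rgb = np.clip(np.rint(rgb), 1, 255).astype(np.uint8)

    truth = GroundTruth(
        soma_centers=np.array(centers).reshape(-1, 2),
        soma_radii=np.array(radii),
        soma_mask=soma_mask,
        process_polylines=polylines,
        process_proximal=proximal_flags,
        process_length_per_cell=total_len,
        proximal_length_per_cell=prox_len,
        tissue_mask=tissue,
        proximal_radius=proximal_radius,
    )
    return rgb, truth


def generate_stain_field(
    area_fraction: float,
    image_shape: tuple[int, int] = (256, 256),
    seed: int = 0,
    stain_od: float = 0.8,
    background_od: float = 0.2,
    tissue_fraction: float = 1.0,
    noise_sd: float = 1.0,
) -> tuple[np.ndarray, float, np.ndarray, np.ndarray]:
    """Random blob field with a known stained-area fraction inside tissue.

    Emulates the generic area-% stains (GFAP, dMBP, SMI312, ...).  Returns
    ``(rgb_image, true_fraction, stain_mask, tissue_mask)`` where
    ``true_fraction`` is the realized stained-pixel fraction of the tissue
    mask, within 0.05 of the request by construction (quantile threshold of
    a smooth random field).
    """
    if not (0.0 <= area_fraction <= 1.0):
        raise ValueError("area_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    tissue = _fraction_mask(image_shape, tissue_fraction, rng)
    if area_fraction <= 0.0:
        stain = np.zeros(image_shape, dtype=bool)
    elif area_fraction >= 1.0:
        stain = tissue.copy()
    else:
        field_ = _smooth_field(image_shape, rng, sigma_frac=0.04)
        vals = field_[tissue]
        cut = np.quantile(vals, 1.0 - area_fraction)
        stain = (field_ > cut) & tissue
    n_tissue = int(tissue.sum())
    true_fraction = float(stain.sum() / n_tissue) if n_tissue else 0.0

    hema = np.where(tissue, background_od, 0.0)
    dab = np.where(stain, stain_od, 0.0)
    basis = StainVectors.hdab().matrix
    od = (
        hema[..., None] * basis[0][None, None, :]
        + dab[..., None] * basis[1][None, None, :]
    )
    od = np.clip(od, 0.0, MAX_OD)
    rgb = od_to_rgb(ODImage(od)).astype(float)
    if noise_sd > 0:
        rgb = rgb + rng.normal(0.0, noise_sd, size=rgb.shape)
    rgb = np.clip(np.rint(rgb), 1, 255).astype(np.uint8)
    return rgb, true_fraction, stain, tissue


# --------------------------------------------------------------------------
# MRI simulation
# --------------------------------------------------------------------------


def _default_rois(shape: tuple[int, int]) -> dict[str, np.ndarray]:
    """Two elliptical white-matter-like ROIs ("cc" and "ec")."""
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    h, w = shape
    cc_roi = ((rr - 0.35 * h) / (0.12 * h)) ** 2 + ((cc - 0.5 * w) / (0.3 * w)) ** 2 <= 1
    ec_roi = ((rr - 0.68 * h) / (0.12 * h)) ** 2 + ((cc - 0.5 * w) / (0.3 * w)) ** 2 <= 1
    return {"cc": cc_roi, "ec": ec_roi}


@dataclass(frozen=True)
class MriSimParams:
    """Parameters of the MRI simulators.

    Defaults reproduce the acquisition geometry the analysis assumes: a
    16-echo spin-echo schedule spaced 11 ms from TE 11 to 176 ms and an
    in-plane pixel size of 0.094 mm.  ``mtr_per_roi`` and ``t2_per_roi_ms``
    are ground-truth values per named ROI; pixels outside every ROI use the
    ``background_*`` values.
    """

    image_shape: tuple[int, int] = (96, 96)
    te_list_ms: tuple[float, ...] = PAPER_TE_LIST_MS
    pixel_size_mm: float = PAPER_MRI_PIXEL_SIZE_MM
    baseline_signal: float = 1000.0
    mtr_per_roi: dict = field(default_factory=lambda: {"cc": 0.32, "ec": 0.30})
    t2_per_roi_ms: dict = field(default_factory=lambda: {"cc": 55.0, "ec": 55.0})
    background_mtr: float = 0.12
    background_t2_ms: float = 80.0
    lesion_signal_multiplier: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        te = np.asarray(self.te_list_ms, dtype=float)
        if te.size < 3 or np.any(np.diff(te) <= 0):
            raise ValueError("te_list_ms must be >=3 strictly increasing echoes")
        for roi, v in self.mtr_per_roi.items():
            if not (0.0 <= v < 1.0):
                raise ValueError(f"MTR for ROI {roi!r} must lie in [0, 1)")
        for roi, v in self.t2_per_roi_ms.items():
            if v <= 0:
                raise ValueError(f"T2 for ROI {roi!r} must be positive")

    def roi_masks(self) -> dict[str, np.ndarray]:
        return _default_rois(self.image_shape)


def generate_mtr_pair(
    params: MriSimParams, mtr_per_roi: dict | None = None
) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """Simulate a FLASH pair without / with MT saturation.

    SMTR = S0 x (1 - MTR(ROI)) + Gaussian noise; pixels outside every ROI
    use ``background_mtr``.  ``mtr_per_roi`` overrides the params' truth,
    e.g. to sweep timepoints.
    """
    mtr_truth = dict(params.mtr_per_roi if mtr_per_roi is None else mtr_per_roi)
    rng = np.random.default_rng(params.seed)
    rois = params.roi_masks()
    s0 = np.full(params.image_shape,
                 params.baseline_signal * params.lesion_signal_multiplier)
    mtr_map = np.full(params.image_shape, params.background_mtr)
    for name, mask in rois.items():
        mtr_map[mask] = mtr_truth[name]
    smtr = s0 * (1.0 - mtr_map)
    if params.noise_sd > 0:
        s0 = s0 + rng.normal(0.0, params.noise_sd, size=s0.shape)
        smtr = smtr + rng.normal(0.0, params.noise_sd, size=smtr.shape)
    return s0, smtr, rois


def generate_multiecho_stack(
    params: MriSimParams, t2_per_roi_ms: dict | None = None
) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """Simulate a 16-echo spin-echo stack, S(TE) = S0 exp(-TE/T2) + noise.

    Returns ``(stack, true_t2_map, roi_masks)`` with the stack ordered by
    increasing TE (first axis).
    """
    t2_truth = dict(params.t2_per_roi_ms if t2_per_roi_ms is None else t2_per_roi_ms)
    rng = np.random.default_rng(params.seed)
    rois = params.roi_masks()
    t2_map = np.full(params.image_shape, params.background_t2_ms)
    for name, mask in rois.items():
        t2_map[mask] = t2_truth[name]
    s0 = params.baseline_signal * params.lesion_signal_multiplier
    te = np.asarray(params.te_list_ms)[:, None, None]
    stack = s0 * np.exp(-te / t2_map[None, :, :])
    if params.noise_sd > 0:
        stack = stack + rng.normal(0.0, params.noise_sd, size=stack.shape)
    return stack, t2_map, rois


# --------------------------------------------------------------------------
# Study tables
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class StudyDesign:
    """Group structure of one study arm: genotypes x treatments x timepoints."""

    genotypes: tuple[str, ...]
    treatments: tuple[str, ...] = ("cuprizone",)
    timepoints: tuple[str, ...] = ("baseline", "week5", "week9")
    n_per_group: int = 7
    study_id: str = "study1"

    def __post_init__(self) -> None:
        if self.n_per_group <= 0:
            raise ValueError("n_per_group must be positive")


@dataclass(frozen=True)
class GroupEffects:
    """Gaussian effect model for one measure.

    value = baseline + shift(genotype, treatment, timepoint)
            + animal intercept N(0, animal_sd) + N(0, noise_sd).
    ``shifts`` maps (genotype, treatment, timepoint) to a mean offset;
    missing cells shift by zero.
    """

    measure: str
    baseline: float = 1.0
    noise_sd: float = 0.25
    animal_sd: float = 0.0
    shifts: dict = field(default_factory=dict)
    units: str = "a.u."


def generate_study_tables(
    design: StudyDesign | list[StudyDesign],
    effects: GroupEffects | list[GroupEffects],
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a long-format study table.

    One row per animal x timepoint x measure, with the same ``animal_id``
    reappearing across timepoints (repeated measures).  Columns:
    study_id, animal_id, genotype, treatment, timepoint, measure, value,
    units.
    """
    designs = design if isinstance(design, list) else [design]
    effect_list = effects if isinstance(effects, list) else [effects]
    rng = np.random.default_rng(seed)
    rows = []
    for dsg in designs:
        animal_no = 0
        for genotype in dsg.genotypes:
            for treatment in dsg.treatments:
                for _ in range(dsg.n_per_group):
                    animal_no += 1
                    animal_id = f"{dsg.study_id}-{genotype}-{treatment}-a{animal_no:03d}"
                    intercepts = {
                        eff.measure: rng.normal(0.0, eff.animal_sd)
                        if eff.animal_sd > 0 else 0.0
                        for eff in effect_list
                    }
                    for timepoint in dsg.timepoints:
                        for eff in effect_list:
                            shift = eff.shifts.get((genotype, treatment, timepoint), 0.0)
                            value = (
                                eff.baseline + shift + intercepts[eff.measure]
                                + rng.normal(0.0, eff.noise_sd)
                            )
                            rows.append(
                                (dsg.study_id, animal_id, genotype, treatment,
                                 timepoint, eff.measure, value, eff.units)
                            )
    return pd.DataFrame(
        rows,
        columns=["study_id", "animal_id", "genotype", "treatment",
                 "timepoint", "measure", "value", "units"],
    )
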