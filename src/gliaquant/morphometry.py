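"""Microglia soma/process morphometry for DAB-stained brightfield sections.

Pipeline over a color-deconvolved DAB concentration image:

1. tissue mask — threshold off the white background, close, fill holes,
   open, drop small objects;
2. soma — adaptive threshold derived from the mean DAB value of the
   "sufficiently dark" pixels (darkest quantile, indicative of soma),
   binarize, size-filter;
3. processes — white top-hat sized to pick 1-px-thin processes, adaptive
   threshold from the same dark-region statistic, size filter, subtract
   soma to keep true processes;
4. skeletonize for length (4-neighbor step = 1, diagonal = sqrt(2));
5. proximal/distal partition — soma dilations give a marker region;
   a circle around each soma centre bounds the proximal zone, overlaps
   resolved by nearest-centre influence zones; distal processes are
   reconstructed from proximal ones only (background fragments are
   ignored) and the circular regions subtracted;
6. per-cell morphometry (area, form factor, skeleton lengths, background-
   corrected optical density) and the two ROI readouts: soma density
   (count per mm^2) and the activation ratio (soma + proximal area over
   non-soma-associated distal process area).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from scipy import ndimage
from skimage import measure, morphology

__all__ = [
    "MorphometryConfig",
    "TissueMask",
    "SomaMask",
    "ProcessMask",
    "MicrogliaRecord",
    "MorphometrySummary",
    "segment_tissue",
    "segment_soma",
    "segment_processes",
    "skeletonize_processes",
    "skeleton_length",
    "partition_proximal_distal",
    "measure_microglia",
    "summarize_roi",
    "analyze_image",
]


@dataclass(frozen=True)
class MorphometryConfig:
    """Tunable parameters of the morphometry pipeline.

    All geometric defaults assume a 20x-like scale (``pixel_size_um`` =
    0.47 um/px).  The adaptive thresholds are ``factor x mean(DAB OD of the
    darkest dark_quantile fraction of tissue pixels)`` — the statistic the
    procedure derives from "sufficiently dark" soma-like regions.
    """

    white_threshold: float = 245.0       # grayscale above this = background
    tissue_min_size_px: int = 500
    tissue_morph_radius: int = 3
    dark_quantile: float = 0.003         # darkest fraction defining the statistic
    soma_factor: float = 0.65            # threshold = stat x factor (soma)
    process_factor: float = 0.3          # threshold = stat x factor (processes)
    soma_min_area_px: int = 30
    soma_max_area_px: int = 1500
    tophat_radius: int = 2               # > process half-width, < soma radius
    soma_subtract_dilation: int = 2      # dilate soma before subtracting, px
    process_min_size_px: int = 5
    n_dilations: int = 3                 # soma dilations for the marker region
    circle_radius_factor: float = 4.0    # x median soma equivalent radius
    annulus_width_px: int = 5            # local-background annulus
    pixel_size_um: float = 0.47
    activation_denominator: str = "distal"   # or "all_nonsoma"

    @classmethod
    def from_yaml(cls, path) -> "MorphometryConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)


@dataclass
class TissueMask:
    mask: np.ndarray
    empty: bool = False

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    def area_mm2(self, pixel_size_um: float) -> float:
        return self.area_px * (pixel_size_um * 1e-3) ** 2


@dataclass
class SomaMask:
    """Labeled soma components with per-soma geometry."""

    labels: np.ndarray                  # int image, 0 = background
    centroids: np.ndarray               # (n, 2) float (row, col)
    areas_px: np.ndarray                # (n,)
    perimeters_px: np.ndarray           # (n,) Crofton perimeter
    threshold: float = float("nan")
    empty: bool = False

    @property
    def n_soma(self) -> int:
        return len(self.areas_px)

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0

    def equivalent_radii(self) -> np.ndarray:
        return np.sqrt(self.areas_px / math.pi)


@dataclass
class ProcessMask:
    mask: np.ndarray                    # binary true-process mask
    thinned: np.ndarray | None = None   # 1-px skeleton
    proximal_labels: np.ndarray | None = None  # per-cell ids on the skeleton
    distal_labels: np.ndarray | None = None
    threshold: float = float("nan")

    @property
    def proximal_mask(self) -> np.ndarray:
        return self.proximal_labels > 0

    @property
    def distal_mask(self) -> np.ndarray:
        return self.distal_labels > 0


@dataclass
class MicrogliaRecord:
    """Per-cell morphometric features."""

    cell_id: int
    soma_area_px: float
    soma_area_um2: float
    soma_form_factor: float
    soma_od: float
    visible_microglia_od: float
    proximal_length_px: float
    proximal_length_um: float
    distal_length_px: float
    distal_length_um: float
    background_fallback: bool = False


@dataclass
class MorphometrySummary:
    """ROI-level readouts: microglia numbers and activation."""

    roi_name: str
    n_soma: int
    roi_area_mm2: float
    soma_density_per_mm2: float
    soma_area_px: int
    proximal_area_px: int
    distal_area_px: int
    activation_ratio: float
    activation_undefined: bool


# --------------------------------------------------------------------------
# Steps (B)-(F)
# --------------------------------------------------------------------------


def segment_tissue(rgb_image: np.ndarray, config: MorphometryConfig | None = None
                   ) -> TissueMask:
    """Segment tissue from the white background (step order: threshold,
    closing, hole filling, opening, small-object removal)."""
    cfg = config or MorphometryConfig()
    gray = np.asarray(rgb_image, dtype=float).mean(axis=-1)
    mask = gray < cfg.white_threshold
    if not mask.any():
        return TissueMask(mask=mask, empty=True)
    selem = morphology.disk(cfg.tissue_morph_radius)
    mask = morphology.closing(mask, selem)
    mask = ndimage.binary_fill_holes(mask)
    mask = morphology.opening(mask, selem)
    mask = _drop_small(mask, cfg.tissue_min_size_px)
    return TissueMask(mask=mask, empty=not mask.any())


def _drop_small(mask: np.ndarray, min_size: int) -> np.ndarray:
    """Remove 8-connected components smaller than ``min_size`` pixels."""
    labels = measure.label(mask, connectivity=2)
    counts = np.bincount(labels.ravel())
    keep = counts >= min_size
    keep[0] = False
    return keep[labels]


def _dark_region_stat(dab_channel: np.ndarray, tissue: np.ndarray,
                      dark_quantile: float) -> float:
    """Mean DAB value over the darkest (= highest-OD) tissue quantile."""
    vals = dab_channel[tissue]
    if vals.size == 0:
        return float("nan")
    cut = np.quantile(vals, 1.0 - dark_quantile)
    dark = vals[vals >= cut]
    if dark.size == 0:
        return float("nan")
    return float(dark.mean())


def segment_soma(dab_channel: np.ndarray, tissue_mask: TissueMask,
                 config: MorphometryConfig | None = None) -> SomaMask:
    """Adaptive soma segmentation from the DAB concentration channel.

    The threshold is the dark-region mean scaled by ``soma_factor``, so it
    tracks staining intensity: doubling the DAB signal leaves the
    segmentation unchanged.
    """
    cfg = config or MorphometryConfig()
    tissue = tissue_mask.mask
    stat = _dark_region_stat(dab_channel, tissue, cfg.dark_quantile)
    empty = SomaMask(
        labels=np.zeros(dab_channel.shape, dtype=int),
        centroids=np.empty((0, 2)), areas_px=np.empty(0),
        perimeters_px=np.empty(0), threshold=stat, empty=True,
    )
    if not np.isfinite(stat) or stat <= 0:
        return empty
    threshold = stat * cfg.soma_factor
    binary = (dab_channel >= threshold) & tissue
    binary = ndimage.binary_fill_holes(binary)
    labels = measure.label(binary, connectivity=2)
    props = measure.regionprops(labels)
    keep = [p for p in props
            if cfg.soma_min_area_px <= p.area <= cfg.soma_max_area_px]
    out = np.zeros_like(labels)
    centroids, areas, perims = [], [], []
    for new_id, p in enumerate(sorted(keep, key=lambda p: p.label), start=1):
        out[labels == p.label] = new_id
        centroids.append(p.centroid)
        areas.append(p.area)
        perims.append(measure.perimeter_crofton(labels == p.label, directions=4))
    if not centroids:
        empty.threshold = threshold
        return empty
    return SomaMask(
        labels=out,
        centroids=np.array(centroids),
        areas_px=np.array(areas, dtype=float),
        perimeters_px=np.array(perims, dtype=float),
        threshold=threshold,
    )


def segment_processes(dab_channel: np.ndarray, soma_mask: SomaMask,
                      tissue_mask: TissueMask,
                      config: MorphometryConfig | None = None) -> ProcessMask:
    """Top-hat + adaptive threshold segmentation of thin processes,
    minus any soma pixels the top-hat also picked."""
    cfg = config or MorphometryConfig()
    selem = morphology.disk(cfg.tophat_radius)
    if min(dab_channel.shape) <= 2 * cfg.tophat_radius:
        raise ValueError("top-hat structuring element larger than the image")
    tophat = morphology.white_tophat(dab_channel, selem)
    stat = _dark_region_stat(dab_channel, tissue_mask.mask, cfg.dark_quantile)
    threshold = stat * cfg.process_factor if np.isfinite(stat) else np.inf
    binary = (tophat >= threshold) & tissue_mask.mask
    binary = _drop_small(binary, cfg.process_min_size_px)
    # the top hat also responds at the soma rim; subtract a slightly
    # dilated soma so only true processes remain
    soma = soma_mask.mask
    if cfg.soma_subtract_dilation > 0:
        soma = ndimage.binary_dilation(soma, np.ones((3, 3), bool),
                                       iterations=cfg.soma_subtract_dilation)
    binary &= ~soma
    return ProcessMask(mask=binary, threshold=threshold)


_HV_SHIFTS = ((0, 1), (1, 0))
_DIAG_SHIFTS = ((1, 1), (1, -1))


def skeleton_length(skeleton: np.ndarray) -> float:
    """Arc length of a 1-px skeleton: each 8-adjacency link counted once,
    1 per horizontal/vertical step and sqrt(2) per diagonal step."""
    sk = skeleton.astype(bool)
    n_hv = sum(
        int(np.count_nonzero(sk[max(dr, 0):sk.shape[0] + min(dr, 0),
                                max(dc, 0):sk.shape[1] + min(dc, 0)]
                             & sk[max(-dr, 0):sk.shape[0] + min(-dr, 0),
                                  max(-dc, 0):sk.shape[1] + min(-dc, 0)]))
        for dr, dc in _HV_SHIFTS
    )
    n_diag = sum(
        int(np.count_nonzero(sk[max(dr, 0):sk.shape[0] + min(dr, 0),
                                max(dc, 0):sk.shape[1] + min(dc, 0)]
                             & sk[max(-dr, 0):sk.shape[0] + min(-dr, 0),
                                  max(-dc, 0):sk.shape[1] + min(-dc, 0)]))
        for dr, dc in _DIAG_SHIFTS
    )
    return n_hv + math.sqrt(2) * n_diag


def skeletonize_processes(process_mask: ProcessMask | np.ndarray
                          ) -> tuple[np.ndarray, float]:
    """Ultimate thinning of the process mask; returns (skeleton, length)."""
    mask = process_mask.mask if isinstance(process_mask, ProcessMask) else process_mask
    thinned = morphology.skeletonize(mask.astype(bool))
    if isinstance(process_mask, ProcessMask):
        process_mask.thinned = thinned
    return thinned, skeleton_length(thinned)


# --------------------------------------------------------------------------
# Steps (G), (I): proximal / distal partition
# --------------------------------------------------------------------------


def _influence_zones(shape: tuple[int, int], centroids: np.ndarray,
                     radius: float) -> np.ndarray:
    """Label image of circular influence zones: pixels within ``radius`` of
    a soma centre, assigned to the nearest centre (ties -> lower cell id)."""
    zones = np.zeros(shape, dtype=int)
    best = np.full(shape, np.inf)
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    for cell_id, (r0, c0) in enumerate(centroids, start=1):
        d2 = (rr - r0) ** 2 + (cc - c0) ** 2
        closer = (d2 <= radius ** 2) & (d2 < best)
        zones[closer] = cell_id
        best = np.minimum(best, np.where(d2 <= radius ** 2, d2, np.inf))
    return zones


def partition_proximal_distal(soma_mask: SomaMask, thinned_mask: np.ndarray,
                              config: MorphometryConfig | None = None
                              ) -> tuple[np.ndarray, np.ndarray, float]:
    """Split the skeleton into proximal and distal process labels.

    Marker = soma dilated ``n_dilations`` times (3x3 element); proximal =
    skeleton components touching the marker, clipped to circular influence
    zones of radius ``circle_radius_factor`` x median soma equivalent
    radius; distal = the rest of those same components (reconstruction from
    proximal seeds, ignoring background fragments that touch no marker)
    minus the circular regions.  Labels carry the owning cell id; distal
    pixels are attributed to the cell owning most of the component's
    proximal pixels.

    Returns ``(proximal_labels, distal_labels, circle_radius)``.
    """
    cfg = config or MorphometryConfig()
    shape = thinned_mask.shape
    prox = np.zeros(shape, dtype=int)
    dist = np.zeros(shape, dtype=int)
    if soma_mask.n_soma == 0:
        return prox, dist, 0.0

    marker = ndimage.binary_dilation(
        soma_mask.mask, structure=np.ones((3, 3), bool),
        iterations=cfg.n_dilations,
    )
    radius = cfg.circle_radius_factor * float(np.median(soma_mask.equivalent_radii()))
    zones = _influence_zones(shape, soma_mask.centroids, radius)

    skel = thinned_mask.astype(bool) & ~soma_mask.mask
    comp = measure.label(skel, connectivity=2)
    touching = np.unique(comp[marker & (comp > 0)])
    for comp_id in touching:
        pix = comp == comp_id
        in_zone = pix & (zones > 0)
        if not in_zone.any():
            continue
        prox[in_zone] = zones[in_zone]
        # distal: remainder of the reconstructed component outside the circles
        owner_ids, counts = np.unique(zones[in_zone], return_counts=True)
        owner = int(owner_ids[np.argmax(counts)])
        outside = pix & (zones == 0)
        dist[outside] = owner
    return prox, dist, radius


# --------------------------------------------------------------------------
# Steps (H), (J), (K): per-cell measurement and ROI summary
# --------------------------------------------------------------------------


def measure_microglia(soma_mask: SomaMask, proximal_labels: np.ndarray,
                      distal_labels: np.ndarray, od_dab: np.ndarray,
                      config: MorphometryConfig | None = None,
                      circle_radius: float | None = None
                      ) -> list[MicrogliaRecord]:
    """Per-cell features: soma area, form factor (4*pi*A/P^2), proximal and
    distal skeleton lengths, and background-corrected optical densities.

    "Visible microglia" = soma + its proximal processes; the local
    background reference is the median DAB OD in an annulus around the
    cell's circular reference region, excluding all visible-microglia
    pixels.  An empty annulus falls back to the tissue-wide median and
    flags the record.
    """
    cfg = config or MorphometryConfig()
    if circle_radius is None:
        circle_radius = (
            cfg.circle_radius_factor * float(np.median(soma_mask.equivalent_radii()))
            if soma_mask.n_soma else 0.0
        )
    um = cfg.pixel_size_um
    visible_all = soma_mask.mask | (proximal_labels > 0)
    tissue_median = float(np.median(od_dab))
    rr, cc = np.mgrid[0:od_dab.shape[0], 0:od_dab.shape[1]]
    records = []
    for i in range(soma_mask.n_soma):
        cell_id = i + 1
        soma_pix = soma_mask.labels == cell_id
        area = float(soma_mask.areas_px[i])
        perim = float(soma_mask.perimeters_px[i])
        form_factor = 4.0 * math.pi * area / perim ** 2 if perim > 0 else 0.0

        prox_pix = proximal_labels == cell_id
        dist_pix = distal_labels == cell_id
        prox_len = skeleton_length(prox_pix)
        dist_len = skeleton_length(dist_pix)

        r0, c0 = soma_mask.centroids[i]
        d = np.hypot(rr - r0, cc - c0)
        annulus = (d > circle_radius) & (d <= circle_radius + cfg.annulus_width_px)
        annulus &= ~visible_all
        fallback = not annulus.any()
        background = tissue_median if fallback else float(np.median(od_dab[annulus]))

        visible = soma_pix | prox_pix
        soma_od = float(od_dab[soma_pix].mean()) - background if area else 0.0
        vis_od = float(od_dab[visible].mean()) - background if visible.any() else 0.0
        records.append(MicrogliaRecord(
            cell_id=cell_id,
            soma_area_px=area,
            soma_area_um2=area * um ** 2,
            soma_form_factor=form_factor,
            soma_od=soma_od,
            visible_microglia_od=vis_od,
            proximal_length_px=prox_len,
            proximal_length_um=prox_len * um,
            distal_length_px=dist_len,
            distal_length_um=dist_len * um,
            background_fallback=fallback,
        ))
    return records


def summarize_roi(records: list[MicrogliaRecord], soma_mask: SomaMask,
                  proximal_labels: np.ndarray, distal_labels: np.ndarray,
                  roi_mask: np.ndarray, roi_name: str = "roi",
                  config: MorphometryConfig | None = None,
                  process_mask: np.ndarray | None = None) -> MorphometrySummary:
    """The two microglia readouts over an ROI.

    * microglia numbers: soma whose centroid falls in the ROI, normalized
      to the ROI area in mm^2;
    * microglia activation: (soma + proximal processes area) normalized to
      the non-soma-associated process area.  The default denominator is
      the distal process area; ``activation_denominator="all_nonsoma"``
      instead uses every process pixel not in a visible-microglia set
      (requires ``process_mask``).
    """
    cfg = config or MorphometryConfig()
    roi = np.asarray(roi_mask, dtype=bool)
    if not roi.any():
        raise ValueError("ROI mask is empty")
    n_soma = sum(
        1 for r0, c0 in soma_mask.centroids
        if roi[int(round(r0)), int(round(c0))]
    )
    area_mm2 = roi.sum() * (cfg.pixel_size_um * 1e-3) ** 2
    soma_px = int((soma_mask.mask & roi).sum())
    prox_px = int(((proximal_labels > 0) & roi).sum())
    if cfg.activation_denominator == "all_nonsoma":
        if process_mask is None:
            raise ValueError("process_mask required for all_nonsoma denominator")
        visible = soma_mask.mask | (proximal_labels > 0)
        denom_px = int((np.asarray(process_mask, bool) & ~visible & roi).sum())
    else:
        denom_px = int(((distal_labels > 0) & roi).sum())
    undefined = denom_px == 0
    ratio = float("nan") if undefined else (soma_px + prox_px) / denom_px
    return MorphometrySummary(
        roi_name=roi_name,
        n_soma=n_soma,
        roi_area_mm2=float(area_mm2),
        soma_density_per_mm2=n_soma / area_mm2 if area_mm2 > 0 else float("nan"),
        soma_area_px=soma_px,
        proximal_area_px=prox_px,
        distal_area_px=denom_px,
        activation_ratio=ratio,
        activation_undefined=undefined,
    )


def analyze_image(rgb_image: np.ndarray, roi_mask: np.ndarray | None = None,
                  config: MorphometryConfig | None = None):
    """Run the full pipeline (steps A-K) on one RGB section image.

    Returns ``(records, summary, masks)`` where ``masks`` is a dict of the
    intermediate tissue/soma/process/proximal/distal images.
    """
    from .stains import deconvolve_stains, rgb_to_od

    cfg = config or MorphometryConfig()
    od = rgb_to_od(rgb_image)
    _, dab, _ = deconvolve_stains(od)
    tissue = segment_tissue(rgb_image, cfg)
    soma = segment_soma(dab, tissue, cfg)
    proc = segment_processes(dab, soma, tissue, cfg)
    thinned, _ = skeletonize_processes(proc)
    prox, dist, radius = partition_proximal_distal(soma, thinned, cfg)
    proc.proximal_labels, proc.distal_labels = prox, dist
    records = measure_microglia(soma, prox, dist, dab, cfg, circle_radius=radius)
    roi = tissue.mask if roi_mask is None else np.asarray(roi_mask, bool)
    summary = summarize_roi(records, soma, prox, dist, roi, config=cfg,
                            process_mask=proc.mask)
    masks = {
        "tissue": tissue, "soma": soma, "process": proc,
        "thinned": thinned, "proximal": prox, "distal": dist,
        "circle_radius": radius,
    }
    return records, summary, masks
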