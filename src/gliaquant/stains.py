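"""Color deconvolution of brightfield IHC images in optical-density space.

Brightfield stains absorb light multiplicatively, so per-channel optical
density OD = -log10(I / I0) is linear in the amount of each stain
(Beer-Lambert).  An RGB pixel's OD vector is then a nonnegative combination
of per-stain unit "color vectors"; solving the 3x3 linear system unmixes
the brown DAB chromogen from the blue hematoxylin counterstain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StainVectors",
    "ODImage",
    "rgb_to_od",
    "od_to_rgb",
    "deconvolve_stains",
]

#: Intensity of a perfectly white (unstained) pixel in an 8-bit image.
DEFAULT_WHITE_POINT = 255.0

#: OD cap such that the reconstructed intensity never rounds below 1,
#: keeping -log10 finite on a round trip (10**-2.41 * 255 ~= 0.99).
MAX_OD = float(np.log10(DEFAULT_WHITE_POINT))

# Condition-number ceiling beyond which a stain matrix is treated as singular.
_MAX_CONDITION = 1e8


@dataclass(frozen=True)
class StainVectors:
    """A 3x3 basis of unit-norm RGB optical-density vectors, one per stain.

    Rows are stains in the order (hematoxylin, DAB, residual); columns are
    the R, G, B optical-density components.
    """

    matrix: np.ndarray
    names: tuple[str, str, str] = ("hematoxylin", "dab", "residual")

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError(f"stain matrix must be 3x3, got {m.shape}")
        norms = np.linalg.norm(m, axis=1)
        if np.any(norms <= 0):
            raise ValueError("stain vectors must be nonzero")
        m = m / norms[:, None]
        cond = np.linalg.cond(m)
        if not np.isfinite(cond) or cond > _MAX_CONDITION:
            raise ValueError(
                f"stain matrix is singular or ill-conditioned (cond={cond:.3g})"
            )
        object.__setattr__(self, "matrix", m)

    @classmethod
    def hdab(cls) -> "StainVectors":
        """Standard published hematoxylin-DAB basis.

        Hematoxylin ~ (0.650, 0.704, 0.286) and DAB ~ (0.269, 0.568, 0.778);
        the residual is their normalized cross product so the basis is
        complete and invertible.
        """
        hema = np.array([0.650, 0.704, 0.286])
        dab = np.array([0.269, 0.568, 0.778])
        res = np.cross(hema, dab)
        res /= np.linalg.norm(res)
        return cls(np.stack([hema, dab, res]))

    @classmethod
    def from_csv(cls, path) -> "StainVectors":
        m = np.loadtxt(path, delimiter=",")
        return cls(m)

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)


@dataclass
class ODImage:
    """Per-pixel optical density per RGB channel plus its white point.

    ``od`` has shape (rows, cols, 3) with values >= 0;
    ``white_point`` is the per-channel incident intensity I0.
    """

    od: np.ndarray
    white_point: np.ndarray = field(
        default_factory=lambda: np.full(3, DEFAULT_WHITE_POINT)
    )

    def __post_init__(self) -> None:
        self.od = np.asarray(self.od, dtype=float)
        self.white_point = np.broadcast_to(
            np.asarray(self.white_point, dtype=float), (3,)
        ).copy()
        if self.od.ndim != 3 or self.od.shape[-1] != 3:
            raise ValueError("od must have shape (rows, cols, 3)")
        if not np.all(np.isfinite(self.od)):
            raise ValueError("optical density must be finite everywhere")

    @property
    def shape(self) -> tuple[int, int]:
        return self.od.shape[:2]


def estimate_white_point(rgb_image: np.ndarray) -> np.ndarray:
    """Per-channel 99th-percentile intensity, a proxy for the clear background."""
    rgb = np.asarray(rgb_image, dtype=float).reshape(-1, 3)
    return np.percentile(rgb, 99, axis=0)


def rgb_to_od(rgb_image: np.ndarray, white_point=DEFAULT_WHITE_POINT) -> ODImage:
    """Convert an 8-bit RGB image to optical density, OD = -log10(I/I0).

    Intensities are clipped to [1, I0] before the log so OD is finite and
    nonnegative; a pixel at the white point maps to OD (0, 0, 0).
    """
    rgb = np.asarray(rgb_image, dtype=float)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError("expected an RGB image with shape (rows, cols, 3)")
    wp = np.broadcast_to(np.asarray(white_point, dtype=float), (3,))
    if np.any(wp <= 0):
        raise ValueError("white point must be positive per channel")
    clipped = np.clip(rgb, 1.0, wp)
    od = -np.log10(clipped / wp)
    return ODImage(od=od, white_point=wp)


def od_to_rgb(od: ODImage, white_point=None) -> np.ndarray:
    """Invert :func:`rgb_to_od` back to an 8-bit RGB image.

    OD 0 maps to the white point; arbitrarily large OD saturates at
    intensity 1 (never 0), the same floor the forward transform clips to.
    """
    if np.any(od.od < 0):
        raise ValueError("optical density must be nonnegative")
    wp = od.white_point if white_point is None else np.broadcast_to(
        np.asarray(white_point, dtype=float), (3,)
    )
    intensity = wp * np.power(10.0, -od.od)
    intensity = np.clip(np.rint(intensity), 1, 255)
    return intensity.astype(np.uint8)


def deconvolve_stains(
    od: ODImage, vectors: StainVectors | None = None, clip: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unmix an OD image into per-stain concentration channels.

    Solves OD = c @ V per pixel, where rows of V are the stain vectors and
    c the stain concentrations.  Returns (hematoxylin, dab, residual)
    channels; with ``clip=True`` (default) negative concentrations —
    numerically possible under noise — are clipped to zero.
    """
    if vectors is None:
        vectors = StainVectors.hdab()
    flat = od.od.reshape(-1, 3)
    conc = flat @ vectors.inverse
    if clip:
        conc = np.maximum(conc, 0.0)
    conc = conc.reshape(od.od.shape)
    return conc[..., 0], conc[..., 1], conc[..., 2]
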