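"""Radial densitometry of in situ hybridization (ISH) images.

A gene's quantified in situ pattern (QISP) is obtained by placing a band-shaped
region of interest (ROI) across the cerebral wall, from the ventricular surface
to the pial surface, splitting the band into 20 equal sub-regions (sROIs, each
5% of the wall), and measuring the mean optical density of each sub-region.
The 20-bin profile is background-corrected against a tissue-free region and
smoothed with a moving average over adjacent bins.

Conventions
-----------
* sROI 1 sits at the ventricular (deep) end of the axis, sROI 20 at the pial
  (superficial) end.  The ventricular endpoint is always listed first in
  :class:`RoiSpec`.
* Image coordinates are 0-based, x to the right, y down; intensities are
  stored as unsigned integers of the stated bit depth.
* Optical density defaults to the linear absorbance proxy
  ``(white - intensity) / white`` in [0, 1]; a ``log10`` transmittance mode
  (``-log10(intensity / white)``) is available for calibrated material.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

N_SROIS = 20

__all__ = [
    "N_SROIS",
    "RoiSpec",
    "QISP",
    "segment_boundaries",
    "place_sroi_grid",
    "measure_optical_density",
    "background_correct",
    "smooth_profile",
    "extract_qisp",
    "white_reference_for",
]


@dataclass(frozen=True)
class RoiSpec:
    """Geometry of the radial sampling band and the background region.

    Parameters
    ----------
    axis
        ``((x_v, y_v), (x_p, y_p))`` — ventricular endpoint first, pial
        endpoint second.  The band runs along this segment.
    band_width_px
        Extent of the band perpendicular to the axis, in pixels.
    background_region
        ``(x, y, width, height)`` rectangle containing no tissue signal.
    """

    axis: tuple[tuple[float, float], tuple[float, float]]
    band_width_px: int
    background_region: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        (x0, y0), (x1, y1) = self.axis
        if (x0, y0) == (x1, y1):
            raise ValueError("ROI axis endpoints must be distinct")
        if self.band_width_px <= 0:
            raise ValueError("band_width_px must be positive")
        if self.background_region[2] <= 0 or self.background_region[3] <= 0:
            raise ValueError("background region must have positive size")

    @property
    def axis_length(self) -> float:
        (x0, y0), (x1, y1) = self.axis
        return float(np.hypot(x1 - x0, y1 - y0))

    def shifted(self, dt: float) -> "RoiSpec":
        """Return a copy with both axis endpoints moved ``dt`` px along the axis."""
        (x0, y0), (x1, y1) = self.axis
        L = self.axis_length
        ux, uy = (x1 - x0) / L, (y1 - y0) / L
        return RoiSpec(
            axis=((x0 + dt * ux, y0 + dt * uy), (x1 + dt * ux, y1 + dt * uy)),
            band_width_px=self.band_width_px,
            background_region=self.background_region,
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")

    def to_dict(self) -> dict:
        return {
            "axis": [list(self.axis[0]), list(self.axis[1])],
            "band_width_px": self.band_width_px,
            "background_region": list(self.background_region),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RoiSpec":
        return cls(
            axis=(tuple(d["axis"][0]), tuple(d["axis"][1])),
            band_width_px=int(d["band_width_px"]),
            background_region=tuple(int(v) for v in d["background_region"]),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "RoiSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class QISP:
    """One gene's 20-bin radial optical-density profile.

    ``corrected[i] == max(raw[i] - background_value, 0)`` and ``smoothed`` is
    the adjacent-bin moving average of ``corrected``.  Index 0 of each array is
    sROI 1 (ventricular end); index 19 is sROI 20 (pial end).
    """

    gene_id: str
    raw: np.ndarray
    corrected: np.ndarray
    smoothed: np.ndarray
    background_value: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("raw", "corrected", "smoothed"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (N_SROIS,):
                raise ValueError(f"{name} must have length {N_SROIS}")
            setattr(self, name, v)

    def profile(self, variant: str = "smoothed") -> np.ndarray:
        if variant not in ("raw", "corrected", "smoothed"):
            raise ValueError(f"unknown profile variant {variant!r}")
        return getattr(self, variant)


def segment_boundaries(length: float, n: int = N_SROIS) -> np.ndarray:
    """Pixel boundaries partitioning an axis of ``length`` px into ``n`` segments.

    Boundary ``k`` is ``round(k * length / n)`` (half-up), so segment sizes
    differ by at most one pixel row for any axis length.  Shared with the
    synthetic renderer so that extraction inverts rendering exactly.
    """
    k = np.arange(n + 1)
    return np.floor(k * (length / n) + 0.5).astype(int)


def place_sroi_grid(
    roi: RoiSpec, image_shape: tuple[int, int]
) -> list[np.ndarray]:
    """Partition the ROI band into 20 contiguous sROI masks.

    Each mask is a boolean array of ``image_shape``.  A pixel belongs to the
    band when its projection ``t`` onto the axis satisfies ``0 <= t < length``
    and its signed perpendicular offset lies in ``[-w/2, w/2)``.  Segment ``k``
    (1-based) covers axis fraction ``[(k-1)/20, k/20)``; the masks are disjoint
    and their union is the band.
    """
    h, w = image_shape
    (x0, y0), (x1, y1) = roi.axis
    L = roi.axis_length
    ux, uy = (x1 - x0) / L, (y1 - y0) / L
    # right-handed normal: for a downward axis this is +x, so the half-open
    # perpendicular window [-w/2, w/2) matches a renderer filling columns
    # [cx - w//2, cx - w//2 + w)
    nx, ny = uy, -ux

    ys, xs = np.mgrid[0:h, 0:w]
    dx, dy = xs - x0, ys - y0
    t = dx * ux + dy * uy
    perp = dx * nx + dy * ny

    half = roi.band_width_px / 2.0
    # reject bands spilling past the raster before building any mask
    corners_x = [x0 + tt * ux + ss * nx for tt in (0.0, L) for ss in (-half, half)]
    corners_y = [y0 + tt * uy + ss * ny for tt in (0.0, L) for ss in (-half, half)]
    if (
        min(corners_x) < -0.5
        or min(corners_y) < -0.5
        or max(corners_x) > w - 0.5
        or max(corners_y) > h - 0.5
    ):
        raise ValueError("ROI band extends outside the image")

    band = (t >= 0) & (t < L) & (perp >= -half) & (perp < half)
    bounds = segment_boundaries(L)
    masks = []
    for k in range(N_SROIS):
        seg = band & (t >= bounds[k]) & (t < bounds[k + 1])
        masks.append(seg)
    # the last boundary equals round(L) which may exceed L for fractional
    # lengths; fold any residual band pixels into the final segment
    residual = band & (t >= bounds[-1])
    masks[-1] |= residual
    if any(not m.any() for m in masks):
        raise ValueError("ROI too short: at least one sROI mask is empty")
    return masks


def white_reference_for(image: np.ndarray) -> float:
    """Maximum representable intensity of the image's integer dtype."""
    if np.issubdtype(image.dtype, np.integer):
        return float(np.iinfo(image.dtype).max)
    return 1.0


def measure_optical_density(
    image: np.ndarray,
    mask: np.ndarray,
    white_reference: float | None = None,
    mode: str = "linear",
) -> float:
    """Mean optical density over ``mask`` pixels.

    ``linear`` (default) returns ``mean((white - I) / white)``, a dimensionless
    absorbance proxy in [0, 1].  ``log10`` returns
    ``mean(-log10(I / white))`` with intensities floored at one count so fully
    dark pixels do not diverge.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    if white_reference is None:
        white_reference = white_reference_for(image)
    vals = np.asarray(image, dtype=float)[mask]
    if mode == "linear":
        return float(np.mean((white_reference - vals) / white_reference))
    if mode == "log10":
        vals = np.maximum(vals, 1.0)
        return float(np.mean(-np.log10(vals / white_reference)))
    raise ValueError(f"unknown density mode {mode!r}")


def background_correct(raw: Sequence[float], background_value: float) -> np.ndarray:
    """Subtract the scalar background density, flooring at zero."""
    if background_value < 0:
        raise ValueError("background_value must be >= 0")
    return np.maximum(np.asarray(raw, dtype=float) - background_value, 0.0)


def smooth_profile(profile: Sequence[float]) -> np.ndarray:
    """Average each sROI with its adjacent sROIs.

    Interior bins use a 3-bin window; the two end bins average with their
    single neighbour only (no padding beyond the wall).
    """
    p = np.asarray(profile, dtype=float)
    if p.shape != (N_SROIS,):
        raise ValueError(f"profile must have length {N_SROIS}")
    out = np.empty_like(p)
    out[0] = p[:2].mean()
    out[-1] = p[-2:].mean()
    for i in range(1, N_SROIS - 1):
        out[i] = p[i - 1 : i + 2].mean()
    return out


def extract_qisp(
    image: np.ndarray,
    roi: RoiSpec,
    gene_id: str,
    mode: str = "linear",
    white_reference: float | None = None,
    image_id: str = "",
) -> QISP:
    """Measure a full QISP from one grayscale image.

    Background density is measured over ``roi.background_region``; raw
    densities are per-sROI means over the band; corrected and smoothed
    variants follow the definitions above.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("image must be a 2-D grayscale raster")
    bx, by, bw, bh = roi.background_region
    if bx < 0 or by < 0 or bx + bw > image.shape[1] or by + bh > image.shape[0]:
        raise ValueError("background region lies outside the image")
    bg_mask = np.zeros(image.shape, dtype=bool)
    bg_mask[by : by + bh, bx : bx + bw] = True
    background = measure_optical_density(image, bg_mask, white_reference, mode)

    masks = place_sroi_grid(roi, image.shape)
    raw = np.array(
        [measure_optical_density(image, m, white_reference, mode) for m in masks]
    )
    corrected = background_correct(raw, max(background, 0.0))
    smoothed = smooth_profile(corrected)
    return QISP(
        gene_id=gene_id,
        raw=raw,
        corrected=corrected,
        smoothed=smoothed,
        background_value=background,
        provenance={"image_id": image_id, "roi": roi.to_dict(), "mode": mode},
    )
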