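"""Scale calibration, color normalization and chroma-key segmentation.

A calibrated photograph contains a square reference patch of known physical
side, used both for pixel-to-mm scaling and for per-channel color
normalization, and a single spike against a uniform blue background.  The
patch is located by chromaticity matching against its declared color (which
is invariant to per-channel linear gain, i.e. to the color casts the
normalization step is meant to correct).  Foreground segmentation is a
chroma key in HSV space with the background hue learned from the frame
borders; the body/awn split is a morphological opening with a structuring
element of physical (mm) radius, so it transfers across image resolutions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_propagation
from scipy.spatial import ConvexHull
from shapely.geometry import MultiPoint
from skimage.color import rgb2hsv
from skimage.measure import find_contours, label, regionprops
from skimage.morphology import dilation, disk, opening

from .synthetic import DEFAULT_PATCH_RGB

_CORNER_OFFSETS = np.array([(-0.5, -0.5), (-0.5, 0.5), (0.5, 0.5), (0.5, -0.5)])


@dataclass
class CalibratedImage:
    """An RGB raster with physical scale and normalization state."""

    pixels: np.ndarray  # (H, W, 3) uint8
    mm_per_px: float
    normalization_applied: bool = False
    protocol: str = "table"

    def __post_init__(self) -> None:
        if self.mm_per_px <= 0:
            raise ValueError("mm_per_px must be positive")
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3 or self.pixels.size == 0:
            raise ValueError("pixels must be a nonempty (H, W, 3) raster")


@dataclass
class SpikeSegmentation:
    """Body mask, awn mask and body contour for one spike.

    The two masks are disjoint by construction (awn = foreground minus
    body); the contour is a closed polygon in (x_px, y_px) coordinates
    tracing the single connected body component.
    """

    body_mask: np.ndarray
    awn_mask: np.ndarray
    body_contour: np.ndarray  # (N, 2) float, columns x_px, y_px
    mm_per_px: float


def locate_patch(
    image: np.ndarray,
    patch_rgb=DEFAULT_PATCH_RGB,
    *,
    chroma_tol: float = 0.04,
    min_area_px: int = 400,
) -> np.ndarray | None:
    """Binary mask of the reference patch, or None if no patch is found.

    Pixels are matched by chromaticity (channel fractions of the RGB sum),
    which is unchanged by per-channel gain, then the largest connected
    matching component above ``min_area_px`` is returned.
    """
    img = np.asarray(image, dtype=float)
    total = img.sum(axis=2)
    ref = np.asarray(patch_rgb, dtype=float)
    ref_chroma = ref / ref.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        chroma = img / total[..., None]
    chroma[~np.isfinite(chroma)] = 0.0
    match = (np.abs(chroma - ref_chroma).max(axis=2) < chroma_tol) & (total > 30.0)
    if not match.any():
        return None
    lab = label(match)
    regions = regionprops(lab)
    best = max(regions, key=lambda r: r.area)
    if best.area < min_area_px:
        return None
    return lab == best.label


def _min_area_rect_sides(mask: np.ndarray) -> tuple[float, float]:
    """Side lengths of the minimum-area rectangle enclosing the mask.

    The rectangle is fit to the pixel *corner* points (centers offset by
    half a pixel), so an axis-aligned n-px square measures exactly n.
    """
    coords = np.argwhere(mask).astype(float)
    hull_pts = coords[ConvexHull(coords).vertices]
    corners = (hull_pts[:, None, :] + _CORNER_OFFSETS[None, :, :]).reshape(-1, 2)
    rect = MultiPoint(corners).minimum_rotated_rectangle
    xy = np.asarray(rect.exterior.coords)[:4]
    d = np.hypot(*np.diff(np.vstack([xy, xy[:1]]), axis=0).T)
    return float(d[0]), float(d[1])


def estimate_scale(image: np.ndarray, patch_side_mm: float, patch_rgb=DEFAULT_PATCH_RGB) -> float:
    """Physical scale (mm per pixel) from the in-frame reference patch.

    The patch side in pixels is the mean of the two side lengths of its
    minimum-area enclosing rectangle; the result is ``patch_side_mm``
    divided by that measurement.
    """
    if patch_side_mm <= 0:
        raise ValueError("patch_side_mm must be positive")
    mask = locate_patch(image, patch_rgb)
    if mask is None:
        raise ValueError("no reference patch detected in the image")
    s1, s2 = _min_area_rect_sides(mask)
    aspect = min(s1, s2) / max(s1, s2)
    if not (0.9 <= aspect <= 1.1):
        raise ValueError(f"reference patch aspect ratio {aspect:.3f} outside [0.9, 1.1]; not a square patch")
    return patch_side_mm / ((s1 + s2) / 2.0)


def normalize_color(image: np.ndarray, patch_reference_rgb, patch_rgb=DEFAULT_PATCH_RGB) -> np.ndarray:
    """Per-channel linear gain so the measured patch mean equals the reference.

    A reference channel of 0 yields a defined gain of 0 (the channel is
    zeroed); a measured patch channel mean of 0 with a nonzero reference is
    a degenerate gain and raises.
    """
    mask = locate_patch(image, patch_rgb)
    if mask is None:
        raise ValueError("no reference patch detected in the image")
    measured = np.asarray(image, dtype=float)[mask].mean(axis=0)
    ref = np.asarray(patch_reference_rgb, dtype=float)
    gains = np.zeros(3)
    for ch in range(3):
        if ref[ch] == 0:
            gains[ch] = 0.0
        elif measured[ch] == 0:
            raise ValueError(f"patch channel {ch} has zero mean; color gain is degenerate")
        else:
            gains[ch] = ref[ch] / measured[ch]
    out = np.clip(np.round(np.asarray(image, dtype=float) * gains), 0, 255)
    return out.astype(np.uint8)


def _circular_hue_distance(h: np.ndarray, h0: float) -> np.ndarray:
    d = np.abs(h - h0)
    return np.minimum(d, 1.0 - d)


def segment_foreground(
    image: CalibratedImage,
    *,
    patch_rgb=DEFAULT_PATCH_RGB,
    hue_tol: float = 0.12,
    sat_floor: float = 0.12,
    val_floor: float = 0.08,
    border_px: int = 10,
    min_fraction: float = 0.001,
    max_fraction: float = 0.60,
) -> np.ndarray:
    """Chroma-key foreground mask of the spike (body plus awns).

    The background hue is learned as the circular mean hue of a
    ``border_px`` frame margin; foreground pixels differ from it by more
    than ``hue_tol`` (hue units, 1 = 360 degrees) and pass saturation/value
    floors.  The reference patch region is excluded, then the largest
    connected component is kept together with any component that touches
    its dilation.
    """
    pixels = image.pixels
    hsv = rgb2hsv(pixels)
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]

    border = np.zeros(pixels.shape[:2], dtype=bool)
    border[:border_px, :] = border[-border_px:, :] = True
    border[:, :border_px] = border[:, -border_px:] = True
    ang = h[border] * 2.0 * np.pi
    bg_hue = (np.arctan2(np.sin(ang).mean(), np.cos(ang).mean()) / (2.0 * np.pi)) % 1.0

    fg = (_circular_hue_distance(h, bg_hue) > hue_tol) & (s > sat_floor) & (v > val_floor)

    patch = locate_patch(pixels, patch_rgb)
    if patch is not None:
        fg &= ~dilation(patch, disk(3))

    fraction = fg.mean()
    if fraction < min_fraction or fraction > max_fraction:
        raise ValueError(
            f"implausible segmentation: foreground covers {100 * fraction:.3f} % of the frame "
            f"(expected {100 * min_fraction:g}-{100 * max_fraction:g} %)"
        )

    lab = label(fg)
    regions = regionprops(lab)
    largest = max(regions, key=lambda r: r.area).label
    main = lab == largest
    touch = dilation(main, disk(4))
    keep_labels = np.unique(lab[touch & (lab > 0)])
    return np.isin(lab, keep_labels)


def trace_contour(mask: np.ndarray) -> np.ndarray:
    """Closed (x_px, y_px) polygon around the largest component of a mask."""
    padded = np.pad(mask, 1)
    contours = find_contours(padded.astype(float), 0.5)
    if not contours:
        raise ValueError("mask has no contour")
    longest = max(contours, key=len) - 1.0  # un-pad; rows, cols
    return longest[:, ::-1].copy()  # -> x (col), y (row)


def split_body_awns(
    foreground: np.ndarray,
    mm_per_px: float,
    *,
    opening_radius_mm: float = 1.0,
) -> SpikeSegmentation:
    """Separate the spike body from the thin awns by morphological opening.

    The structuring element is a disc of radius max(2 px, the pixel
    equivalent of ``opening_radius_mm``); awns, being thinner than the
    disc, are removed by the opening and recovered as foreground minus
    body.  The body is the largest surviving component; its tapering
    base/tip wedges, which the opening also erodes, are reclaimed by
    geodesic propagation through an awn-scale (2 px) opening of the
    foreground.
    """
    if mm_per_px <= 0:
        raise ValueError("mm_per_px must be positive")
    fg = np.asarray(foreground, dtype=bool)
    if not fg.any():
        raise ValueError("foreground mask is empty")
    radius_px = max(2, int(round(opening_radius_mm / mm_per_px)))
    opened = opening(fg, disk(radius_px))
    if not opened.any():
        raise ValueError(
            f"no body found: opening with a {radius_px} px disc removed the whole foreground"
        )
    lab = label(opened)
    regions = regionprops(lab)
    body = lab == max(regions, key=lambda r: r.area).label
    # Reclaim the pointed body ends, which the mm-scale opening erodes: a
    # second opening at awn scale (2 px) removes the thin awns but keeps
    # the tapering wedges; propagate the body through it, then grow the
    # reclaimed part back over the thin boundary ring the fine opening
    # cannot keep.
    fine_r = 2
    if radius_px > fine_r:
        fine = opening(fg, disk(fine_r))
        core = binary_propagation(body, mask=fine | body)
        reclaimed = core & ~body
        if reclaimed.any():
            band = dilation(reclaimed, disk(fine_r)) & fg
            body = body | reclaimed | band
    # If the residual beyond the body is negligible the image has no awns;
    # attribute the leftover wedge tails to the body instead of reporting
    # a spurious awn area.
    residual = fg & ~body
    if residual.sum() < 0.005 * body.sum():
        body = binary_propagation(body, mask=fg)
    awn = fg & ~body
    return SpikeSegmentation(
        body_mask=body,
        awn_mask=awn,
        body_contour=trace_contour(body),
        mm_per_px=mm_per_px,
    )
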