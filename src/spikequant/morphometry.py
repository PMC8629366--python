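"""Two-quadrangle model fitting and shape trait computation.

The spike body outline is approximated by two quadrilaterals sharing the
base (0, 0) and tip (L, 0) on the centerline: the upper chain passes through
(xu1, yu1) and (xu2, yu2), the lower chain through (xb1, -yb1) and
(xb2, -yb2), for nine free parameters in total (the eight interior vertex
coordinates plus the spike length L).  Fitting minimizes the mean absolute
vertical distance between each half-contour profile and its chain, via a
coarse grid over the vertex abscissae followed by Nelder-Mead refinement —
deterministic by construction.

Shape descriptors use the standard morphometric definitions:
circularity = 4*pi*A / P^2 and roundness = 4*A / (pi * major_axis^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.optimize import minimize
from skimage.measure import regionprops

from ._geometry import polyline_length
from .calibration import SpikeSegmentation
from .traits import METADATA_COLUMNS, TRAIT_COLUMNS


@dataclass
class CenterlineFrame:
    """Body geometry resampled in the axis-horizontal frame.

    ``x_mm`` are column positions from the base (x = 0) to the tip
    (x = L); ``upper_mm``/``lower_mm`` are half-width profiles measured
    from the base-tip chord (canonically oriented so the wider side is
    "upper"); ``centerline_mm`` is the curved per-column midline whose arc
    length is the rachis length.
    """

    x_mm: np.ndarray
    upper_mm: np.ndarray
    lower_mm: np.ndarray
    centerline_mm: np.ndarray  # (N, 2)
    L_mm: float
    mm_per_px: float
    rotation_deg: float
    flipped: bool
    swapped: bool


@dataclass
class QuadrangleModel:
    """The nine fitted parameters (mm) plus the fit residual."""

    xu1: float
    yu1: float
    xu2: float
    yu2: float
    xb1: float
    yb1: float
    xb2: float
    yb2: float
    L: float
    residual_mm: float
    status: str = "ok"

    def __post_init__(self) -> None:
        if not (0 < self.xu1 < self.xu2 < self.L and 0 < self.xb1 < self.xb2 < self.L):
            raise ValueError("vertex abscissae must satisfy 0 < x1 < x2 < L on both chains")
        if min(self.yu1, self.yu2, self.yb1, self.yb2) <= 0:
            raise ValueError("half-widths must be positive")
        if self.residual_mm < 0:
            raise ValueError("residual must be non-negative")

    @property
    def free_parameters(self) -> dict[str, float]:
        return {
            "xu1": self.xu1, "yu1": self.yu1, "xu2": self.xu2, "yu2": self.yu2,
            "xb1": self.xb1, "yb1": self.yb1, "xb2": self.xb2, "yb2": self.yb2,
            "L": self.L,
        }


@dataclass
class ShapeTraits:
    """General shape and size descriptors of one spike."""

    perimeter_mm: float
    rachis_length_mm: float
    circularity: float
    roundness: float
    awns_area_mm2: float
    ybm_mm: float


def _principal_angle_deg(mask: np.ndarray) -> tuple[float, float]:
    """Angle (deg) of the mask's principal axis in image coords and the
    sqrt-eigenvalue aspect ratio."""
    coords = np.argwhere(mask).astype(float)  # rows, cols
    xy = coords[:, ::-1]  # x = col, y = row
    cov = np.cov((xy - xy.mean(axis=0)).T)
    evals, evecs = np.linalg.eigh(cov)
    major = evecs[:, np.argmax(evals)]
    aspect = float(np.sqrt(max(evals) / max(min(evals), 1e-12)))
    return float(np.degrees(np.arctan2(major[1], major[0]))), aspect


def compute_centerline(seg: SpikeSegmentation) -> CenterlineFrame:
    """Rotate the body to an axis-horizontal frame and extract its profiles.

    The principal axis of the body mask defines the orientation; the base
    (wider end) is placed at the left.  The centerline is the per-column
    mean of the upper and lower contour ordinates; L is the base-to-tip
    extent along the axis.  Raises if the mask has no well-defined axis
    (aspect ratio < 1.2).
    """
    mask = np.asarray(seg.body_mask, dtype=bool)
    if not mask.any():
        raise ValueError("body mask is empty")
    angle_deg, aspect = _principal_angle_deg(mask)
    if aspect < 1.2:
        raise ValueError(f"mask aspect ratio {aspect:.2f} < 1.2: no well-defined axis")

    # Rotate the subpixel contour polygon analytically (raster rotation
    # would add nearest-neighbour artifacts to the profiles) and scan its
    # upper/lower envelopes per 1-px column bin.  The principal axis of an
    # asymmetric body is slightly tilted against the base-tip line, and a
    # residual tilt shears the profiles (an x-shift proportional to height),
    # so the rotation is refined until the base-tip chord is horizontal.
    raw = np.asarray(seg.body_contour, dtype=float)
    center = raw.mean(axis=0)
    for _ in range(4):
        t = np.deg2rad(-angle_deg)
        rot = np.array([(np.cos(t), -np.sin(t)), (np.sin(t), np.cos(t))])
        pts = (raw - center) @ rot.T

        # densify the boundary so every column bin is hit
        seglen = np.hypot(*np.diff(np.vstack([pts, pts[:1]]), axis=0).T)
        arc = np.concatenate([[0.0], np.cumsum(seglen)])
        dense_arc = np.arange(0.0, arc[-1], 0.25)
        closed = np.vstack([pts, pts[:1]])
        dense = np.column_stack([
            np.interp(dense_arc, arc, closed[:, 0]),
            np.interp(dense_arc, arc, closed[:, 1]),
        ])

        x0, x1 = dense[:, 0].min(), dense[:, 0].max()
        n_cols = max(2, int(np.floor(x1 - x0)))
        bins = np.clip((dense[:, 0] - x0).astype(int), 0, n_cols - 1)
        top = np.full(n_cols, np.inf)
        bottom = np.full(n_cols, -np.inf)
        np.minimum.at(top, bins, dense[:, 1])
        np.maximum.at(bottom, bins, dense[:, 1])
        valid = np.isfinite(top) & np.isfinite(bottom)
        top, bottom = top[valid], bottom[valid]
        n_cols = len(top)

        k = min(3, n_cols)
        mid_raw = (top + bottom) / 2.0
        centers = np.arange(n_cols) + 0.5
        xa, xb = centers[:k].mean(), centers[-k:].mean()
        ya, yb = mid_raw[:k].mean(), mid_raw[-k:].mean()
        chord_slope = (yb - ya) / (xb - xa)
        if abs(chord_slope) < 1e-4:
            break
        angle_deg += float(np.degrees(np.arctan(chord_slope)))

    width = bottom - top
    q = max(1, n_cols // 4)
    flipped = bool(width[-q:].mean() > width[:q].mean())
    if flipped:
        top, bottom, width = top[::-1].copy(), bottom[::-1].copy(), width[::-1].copy()

    mm = seg.mm_per_px
    mid = (top + bottom) / 2.0
    win = max(3, int(round(2.0 / mm)))
    mid_s = uniform_filter1d(mid, size=min(win, n_cols), mode="nearest")

    # Residual chord offset through the base and tip apexes, from the
    # unsmoothed midline of the extreme columns (the smoothed midline is
    # biased there when the upper and lower slopes differ).
    k = min(3, n_cols)
    x_px = np.arange(n_cols) + 0.5
    chord = np.interp(x_px, [x_px[:k].mean(), x_px[-k:].mean()],
                      [mid[:k].mean(), mid[-k:].mean()])
    upper = (chord - top) * mm
    lower = (bottom - chord) * mm

    swapped = bool(lower.mean() > upper.mean())
    if swapped:
        upper, lower = lower, upper

    centerline_mm = np.column_stack([x_px * mm, -mid_s * mm])
    return CenterlineFrame(
        x_mm=x_px * mm,
        upper_mm=upper,
        lower_mm=lower,
        centerline_mm=centerline_mm,
        L_mm=float(x1 - x0) * mm,
        mm_per_px=mm,
        rotation_deg=angle_deg,
        flipped=flipped,
        swapped=swapped,
    )


def _chain_profile(x: np.ndarray, params: np.ndarray, L: float) -> np.ndarray:
    x1, y1, x2, y2 = params
    return np.interp(x, [0.0, x1, x2, L], [0.0, y1, y2, 0.0])


def _fit_half(x: np.ndarray, h: np.ndarray, L: float, grid_fracs: np.ndarray) -> tuple[np.ndarray, float]:
    """Fit one chain (x1, y1, x2, y2) to a half-width profile by grid search
    plus Nelder-Mead refinement on the mean absolute deviation."""

    def objective(p: np.ndarray) -> float:
        x1, y1, x2, y2 = p
        if not (0.0 < x1 < x2 < L) or y1 <= 0 or y2 <= 0:
            return 1e9
        return float(np.mean(np.abs(h - _chain_profile(x, p, L))))

    candidates = []
    for f1 in grid_fracs:
        for f2 in grid_fracs:
            if f2 <= f1:
                continue
            p = np.array([f1 * L, max(np.interp(f1 * L, x, h), 1e-3),
                          f2 * L, max(np.interp(f2 * L, x, h), 1e-3)])
            candidates.append((objective(p), tuple(p)))
    candidates.sort(key=lambda t: t[0])

    # The objective has shallow local minima when an edge of the profile is
    # nearly straight; refine from several grid starts and keep the best.
    best_p, best_val = np.array(candidates[0][1]), candidates[0][0]
    for start_val, start_p in candidates[:6]:
        p, val = np.array(start_p), start_val
        for _ in range(2):  # restart once to polish
            res = minimize(objective, p, method="Nelder-Mead",
                           options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 4000})
            if res.fun <= val:
                p, val = res.x, float(res.fun)
        if val < best_val:
            best_p, best_val = p, val
    return best_p, best_val


def fit_quadrangles(frame: CenterlineFrame, grid_fracs: np.ndarray | None = None) -> QuadrangleModel:
    """Fit the two-quadrangle model to the half-width profiles of a frame.

    Each chain's four free vertex coordinates minimize the mean absolute
    distance to its half-profile.  If the residual exceeds 20 % of the
    maximum half-width the model is returned flagged ``status="poor_fit"``
    with a warning.
    """
    if grid_fracs is None:
        grid_fracs = np.arange(0.1, 0.91, 0.1)
    L = frame.L_mm
    pu, ru = _fit_half(frame.x_mm, frame.upper_mm, L, grid_fracs)
    pb, rb = _fit_half(frame.x_mm, frame.lower_mm, L, grid_fracs)
    residual = float((ru + rb) / 2.0)
    status = "ok"
    max_half = float(max(frame.upper_mm.max(), frame.lower_mm.max()))
    if residual > 0.2 * max_half:
        status = "poor_fit"
        warnings.warn(
            f"quadrangle fit residual {residual:.2f} mm exceeds 20 % of the max half-width {max_half:.2f} mm",
            stacklevel=2,
        )
    return QuadrangleModel(
        xu1=float(pu[0]), yu1=float(pu[1]), xu2=float(pu[2]), yu2=float(pu[3]),
        xb1=float(pb[0]), yb1=float(pb[1]), xb2=float(pb[2]), yb2=float(pb[3]),
        L=L, residual_mm=residual, status=status,
    )


def _closed_contour_length(contour: np.ndarray, smooth_window: int = 7) -> float:
    """Length of a closed contour polygon, lightly smoothed to suppress the
    pixel-staircase overestimate of marching-squares contours."""
    pts = np.asarray(contour, dtype=float)
    if len(pts) < 3:
        return 0.0
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    w = min(smooth_window, len(pts))
    if w >= 3:
        padded = np.vstack([pts[-(w // 2):], pts, pts[: w // 2]])
        kernel = np.ones(w) / w
        pts = np.column_stack([
            np.convolve(padded[:, 0], kernel, mode="valid"),
            np.convolve(padded[:, 1], kernel, mode="valid"),
        ])
    closed = np.vstack([pts, pts[:1]])
    return polyline_length(closed)


def compute_shape_traits(
    seg: SpikeSegmentation,
    frame: CenterlineFrame,
) -> ShapeTraits:
    """Perimeter, rachis length, circularity, roundness, awn area and ybm.

    Perimeter is the (smoothed) body contour length; area is the body mask
    area; the major axis comes from the mask's best-fit ellipse; rachis
    length is the arc length of the curved centerline; ybm is the maximum
    lower half-width in the axis frame.
    """
    body = np.asarray(seg.body_mask, dtype=bool)
    if not body.any():
        raise ValueError("body mask is empty")
    mm = seg.mm_per_px
    area_mm2 = float(body.sum()) * mm**2
    perimeter_mm = _closed_contour_length(seg.body_contour) * mm
    props = regionprops(body.astype(np.uint8))[0]
    major_mm = props.axis_major_length * mm
    circularity = min(1.0, 4.0 * np.pi * area_mm2 / perimeter_mm**2)
    roundness = min(1.0, 4.0 * area_mm2 / (np.pi * major_mm**2))
    return ShapeTraits(
        perimeter_mm=perimeter_mm,
        rachis_length_mm=float(polyline_length(frame.centerline_mm)),
        circularity=float(circularity),
        roundness=float(roundness),
        awns_area_mm2=float(np.asarray(seg.awn_mask, dtype=bool).sum()) * mm**2,
        ybm_mm=float(frame.lower_mm.max()),
    )


def assemble_trait_record(model: QuadrangleModel, traits: ShapeTraits, metadata: dict) -> dict:
    """One trait-table row: the nine analysed traits plus metadata.

    The analysed traits are xu2, ybm, xb2, yu2 (quadrangle measurements),
    perimeter, rachis length, circularity, roundness and awns area.
    """
    record = {
        "xu2_mm": model.xu2,
        "ybm_mm": traits.ybm_mm,
        "xb2_mm": model.xb2,
        "yu2_mm": model.yu2,
        "perimeter_mm": traits.perimeter_mm,
        "rachis_length_mm": traits.rachis_length_mm,
        "circularity": traits.circularity,
        "roundness": traits.roundness,
        "awns_area_mm2": traits.awns_area_mm2,
    }
    for name, value in record.items():
        if value is None or not np.isfinite(value):
            raise ValueError(f"trait {name} is missing or non-finite: {value!r}")
    missing = [k for k in METADATA_COLUMNS if k not in metadata]
    if missing:
        raise ValueError(f"metadata is missing keys: {missing}")
    out = {k: metadata[k] for k in METADATA_COLUMNS}
    out.update(record)
    assert set(TRAIT_COLUMNS) <= set(out)
    return out
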