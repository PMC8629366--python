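"""Synthetic spike imagery and trait tables with known ground truth.

Real spike photographs show a single ear against a uniform blue background
with an in-frame reference patch used for color normalization and pixel-to-mm
scaling.  This module emulates that setup: the spike body is an exact
two-quadrangle polygon (so every geometric parameter is known), awns are thin
random-walk polylines of known total area anchored on the distal third of the
body, and the reference patch is a square of known physical side.  A second
generator produces plant-level trait tables whose per-trait variance differs
between two ploidy groups by a controlled factor, emulating the statistical
structure of a tetraploid/hexaploid comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon

from ._geometry import QUAD_PARAM_NAMES, body_polygon, lower_chain, quad_area, upper_chain
from .traits import TRAIT_COLUMNS

DEFAULT_BACKGROUND_RGB = (30, 60, 160)
DEFAULT_BODY_RGB = (190, 170, 120)
DEFAULT_AWN_RGB = (170, 150, 100)
DEFAULT_PATCH_RGB = (200, 200, 200)
DEFAULT_PATCH_SIDE_MM = 40.0
DEFAULT_CANVAS_PX = (1000, 1600)  # rows, cols
DEFAULT_MM_PER_PX = 0.1

CLASS_PROFILES = ("short_compact", "medium", "long_thin")


@dataclass
class SpikeGroundTruth:
    """Known geometry of one synthetic spike.

    The nine quadrangle parameters are in mm: ``xu1 < xu2`` and
    ``xb1 < xb2`` are positions along the centerline, ``yu*``/``yb*`` are
    positive half-widths above/below it, and ``L`` is the spike length.
    ``body_area_mm2`` is the analytic area of the two quadrilaterals and is
    filled in automatically.  ``realized_*`` fields hold pixel-level areas
    measured after rendering.
    """

    xu1: float
    yu1: float
    xu2: float
    yu2: float
    xb1: float
    yb1: float
    xb2: float
    yb2: float
    L: float
    awns_area_mm2: float = 0.0
    mm_per_px: float = DEFAULT_MM_PER_PX
    body_area_mm2: float = field(default=None)  # type: ignore[assignment]
    protocol: str = "table"
    projection_index: int = 0
    realized_body_area_mm2: float | None = None
    realized_awns_area_mm2: float | None = None

    def __post_init__(self) -> None:
        if self.body_area_mm2 is None:
            self.body_area_mm2 = quad_area(self.quad_params)
        self.validate()

    @property
    def quad_params(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in QUAD_PARAM_NAMES}

    def validate(self) -> None:
        p = self
        if not (0 < p.xu1 < p.xu2 < p.L):
            raise ValueError(f"upper abscissae must satisfy 0 < xu1 < xu2 < L, got {p.xu1}, {p.xu2}, {p.L}")
        if not (0 < p.xb1 < p.xb2 < p.L):
            raise ValueError(f"lower abscissae must satisfy 0 < xb1 < xb2 < L, got {p.xb1}, {p.xb2}, {p.L}")
        if min(p.yu1, p.yu2, p.yb1, p.yb2) <= 0:
            raise ValueError("half-widths yu1, yu2, yb1, yb2 must be positive")
        if p.awns_area_mm2 < 0:
            raise ValueError("awns_area_mm2 must be non-negative")
        if p.mm_per_px <= 0:
            raise ValueError("mm_per_px must be positive")
        if p.projection_index < 0:
            raise ValueError("projection_index must be non-negative")
        if p.protocol not in ("table", "clip"):
            raise ValueError(f"unknown protocol {p.protocol!r}")
        analytic = quad_area(self.quad_params)
        if abs(self.body_area_mm2 - analytic) > 1e-6 * max(analytic, 1.0):
            raise ValueError("body_area_mm2 inconsistent with the quadrangle parameters")


@dataclass
class RenderResult:
    """A rendered synthetic photograph plus its pixel-exact ground truth."""

    image: np.ndarray  # (H, W, 3) uint8
    truth: SpikeGroundTruth
    body_mask: np.ndarray  # bool
    awn_mask: np.ndarray  # bool
    patch_mask: np.ndarray  # bool
    mm_per_px: float
    patch_side_mm: float


# --- ground-truth sampling ---------------------------------------------------

_PROFILE_RANGES = {
    # L range (mm), max half-width range (mm), awn area range (mm^2)
    "short_compact": ((38.0, 57.0), (7.0, 12.0), (10.0, 80.0)),
    "medium": ((62.0, 88.0), (5.5, 9.5), (15.0, 110.0)),
    "long_thin": ((92.0, 125.0), (4.0, 7.5), (20.0, 120.0)),
}


def sample_ground_truth(
    class_profile: str,
    seed: int,
    *,
    mm_per_px: float = DEFAULT_MM_PER_PX,
    protocol: str = "table",
    projection_index: int = 0,
) -> SpikeGroundTruth:
    """Draw a random spike geometry from one of three length classes.

    ``short_compact`` spikes have L < 60 mm and large half-widths,
    ``medium`` 60-90 mm, ``long_thin`` > 90 mm with small half-widths.
    Deterministic for a fixed (class_profile, seed).
    """
    if class_profile not in _PROFILE_RANGES:
        raise ValueError(f"unknown class profile {class_profile!r}; expected one of {CLASS_PROFILES}")
    rng = np.random.default_rng(seed)
    (l_lo, l_hi), (w_lo, w_hi), (a_lo, a_hi) = _PROFILE_RANGES[class_profile]
    L = rng.uniform(l_lo, l_hi)
    wmax = rng.uniform(w_lo, w_hi)

    def draw_chain(y1_range, y2_range):
        # Reject chains whose interior vertices sit nearly on the chord
        # through their neighbours: such outlines are effectively
        # triangles and the vertex position is not identifiable.
        for _ in range(500):
            x1 = L * rng.uniform(0.15, 0.30)
            x2 = L * rng.uniform(0.55, 0.80)
            y1 = wmax * rng.uniform(*y1_range)
            y2 = wmax * rng.uniform(*y2_range)
            bulge1 = y1 - y2 * x1 / x2
            bulge2 = y2 - y1 * (L - x2) / (L - x1)
            if bulge1 >= 0.8 and bulge2 >= 0.8:
                return x1, y1, x2, y2
        raise RuntimeError("could not sample an identifiable chain")

    # Base end is wider than the tip (y1 > y2) and the upper half is wider
    # than the lower one (area margin), fixing a canonical orientation.
    for _ in range(500):
        xu1, yu1, xu2, yu2 = draw_chain((0.90, 1.00), (0.45, 0.70))
        xb1, yb1, xb2, yb2 = draw_chain((0.72, 0.86), (0.40, 0.62))
        area_u = 0.5 * (yu1 * xu2 + yu2 * (L - xu1))
        area_b = 0.5 * (yb1 * xb2 + yb2 * (L - xb1))
        if area_u >= 1.15 * area_b:
            break
    awns = rng.uniform(a_lo, a_hi)
    return SpikeGroundTruth(
        xu1=xu1, yu1=yu1, xu2=xu2, yu2=yu2,
        xb1=xb1, yb1=yb1, xb2=xb2, yb2=yb2, L=L,
        awns_area_mm2=float(awns),
        mm_per_px=mm_per_px,
        protocol=protocol,
        projection_index=projection_index,
    )


# --- image rendering ---------------------------------------------------------

def _patch_corners(origin_rc: tuple[float, float], side_px: float, rotation_deg: float) -> np.ndarray:
    """Corners (row, col) of a square patch rotated about its center.

    Corners sit on pixel-cell boundaries (half-integer offsets), so an
    axis-aligned patch of side n covers exactly n pixels per side.
    """
    r0, c0 = origin_rc
    half = side_px / 2.0
    cr, cc = r0 + half - 0.5, c0 + half - 0.5
    base = np.array([(-half, -half), (-half, half), (half, half), (half, -half)])
    t = np.deg2rad(rotation_deg)
    rot = np.array([(np.cos(t), -np.sin(t)), (np.sin(t), np.cos(t))])
    corners = base @ rot.T + (cr, cc)
    # anchor the (possibly rotated) square's bounding box at the origin
    # cell boundary, preserving the exact n-pixel span when unrotated
    return corners - (corners.min(axis=0) - (r0 - 0.5, c0 - 0.5))


def render_spike_image(
    truth: SpikeGroundTruth,
    background_color: Sequence[int] = DEFAULT_BACKGROUND_RGB,
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    body_color: Sequence[int] = DEFAULT_BODY_RGB,
    awn_color: Sequence[int] = DEFAULT_AWN_RGB,
    patch_color: Sequence[int] = DEFAULT_PATCH_RGB,
    patch_side_mm: float = DEFAULT_PATCH_SIDE_MM,
    patch_rotation_deg: float = 0.0,
    include_patch: bool = True,
    canvas_px: tuple[int, int] = DEFAULT_CANVAS_PX,
    margin_px: int = 40,
) -> RenderResult:
    """Render one calibrated spike photograph.

    The image contains a uniform blue background (with optional Gaussian
    pixel noise), the filled two-quadrangle body, thin random-walk awns whose
    total rendered area matches ``truth.awns_area_mm2`` within 5 %, and a
    square reference patch of known side.  Rendering is bit-deterministic
    for a fixed (truth, seed).
    """
    truth.validate()
    H, W = int(canvas_px[0]), int(canvas_px[1])
    px_per_mm = 1.0 / truth.mm_per_px
    rng = np.random.default_rng(seed)

    img = np.empty((H, W, 3), dtype=float)
    img[...] = np.asarray(background_color, dtype=float)
    patch_mask = np.zeros((H, W), dtype=bool)

    # Reference patch in the top-left corner.
    patch_side_px = patch_side_mm * px_per_mm
    if include_patch:
        corners = _patch_corners((margin_px, margin_px), patch_side_px, patch_rotation_deg)
        if corners.min() < 0 or corners[:, 0].max() >= H or corners[:, 1].max() >= W:
            raise ValueError(
                f"patch_side_mm={patch_side_mm} at {truth.mm_per_px} mm/px does not fit the canvas {canvas_px}"
            )
        rr, cc = draw_polygon(corners[:, 0], corners[:, 1], shape=(H, W))
        patch_mask[rr, cc] = True
        img[patch_mask] = np.asarray(patch_color, dtype=float)
        patch_bottom = int(np.ceil(corners[:, 0].max()))
        patch_right = int(np.ceil(corners[:, 1].max()))
    else:
        patch_bottom = 0
        patch_right = 0

    # Spike body: base towards the left, vertically clear of the patch.
    wmax_px = max(truth.yu1, truth.yu2, truth.yb1, truth.yb2) * px_per_mm
    awn_reach_px = int(round(24.0 * px_per_mm))  # walks are capped at ~22 mm
    base_col = margin_px + 20
    tip_col = base_col + truth.L * px_per_mm
    if tip_col + margin_px + awn_reach_px >= W:
        raise ValueError(f"spike length L={truth.L:.1f} mm does not fit the canvas width {W} px")
    center_row = max(H // 2, patch_bottom + 40 + int(np.ceil(wmax_px)) + 4)
    if center_row + wmax_px + awn_reach_px >= H or center_row - wmax_px - awn_reach_px < 0:
        raise ValueError(
            f"spike half-width {wmax_px * truth.mm_per_px:.1f} mm does not fit the canvas height {H} px"
        )

    verts = body_polygon(truth.quad_params)  # (x, y) in mm, y up
    rows = center_row - verts[:, 1] * px_per_mm
    cols = base_col + verts[:, 0] * px_per_mm
    rr, cc = draw_polygon(rows, cols, shape=(H, W))
    body_mask = np.zeros((H, W), dtype=bool)
    body_mask[rr, cc] = True
    img[body_mask] = np.asarray(body_color, dtype=float)

    # Awns: random-walk polylines from the distal third of the contour,
    # stamped until the requested total area is reached.
    awn_mask = np.zeros((H, W), dtype=bool)
    target_px = truth.awns_area_mm2 * px_per_mm**2
    if target_px > 0:
        blocked = body_mask | patch_mask
        total = 0
        guard = 0
        while total < target_px and guard < 5000:
            guard += 1
            x_mm = rng.uniform(2.0 * truth.L / 3.0, truth.L)
            if x_mm > 0.97 * truth.L:
                side, heading = 0, rng.normal(0.0, 0.15)  # off the tip, roughly +x
            else:
                # brush-like fan: near-perpendicular at the anchor, leaning
                # towards the tip further out, so awns rarely cross
                side = rng.choice((-1, 1))
                t = (x_mm - 2.0 * truth.L / 3.0) / (truth.L / 3.0)
                heading = side * (np.pi / 2 - 1.1 * t) + rng.normal(0.0, 0.12)
            if side >= 0:
                y_mm = upper_chain(np.array([x_mm]), truth.xu1, truth.yu1, truth.xu2, truth.yu2, truth.L)[0]
            else:
                y_mm = -lower_chain(np.array([x_mm]), truth.xb1, truth.yb1, truth.xb2, truth.yb2, truth.L)[0]
            r = center_row - y_mm * px_per_mm
            c = base_col + x_mm * px_per_mm
            width_r = rng.choice((1.1, 1.6))
            n_steps = rng.integers(70, 111)
            for step in range(n_steps):
                # stamp first (the anchor lies on the contour, keeping the
                # awn 8-connected to the body), then advance
                if step > 0:
                    r -= 2.0 * np.sin(heading)
                    c += 2.0 * np.cos(heading)
                    heading += rng.normal(0.0, 0.03)
                if not (2 <= r < H - 2 and 2 <= c < W - 2):
                    break
                if include_patch and r < patch_bottom + 4 and c < patch_right + 4:
                    break
                sr, sc = draw_disk((r, c), width_r, shape=(H, W))
                keep = ~(blocked[sr, sc] | awn_mask[sr, sc])
                total += int(keep.sum())
                awn_mask[sr[keep], sc[keep]] = True
                if total >= target_px:
                    break
    img[awn_mask] = np.asarray(awn_color, dtype=float)

    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, img.shape)
    image = np.clip(np.round(img), 0, 255).astype(np.uint8)

    realized = replace(
        truth,
        realized_body_area_mm2=float(body_mask.sum()) * truth.mm_per_px**2,
        realized_awns_area_mm2=float(awn_mask.sum()) * truth.mm_per_px**2,
    )
    return RenderResult(
        image=image,
        truth=realized,
        body_mask=body_mask,
        awn_mask=awn_mask,
        patch_mask=patch_mask,
        mm_per_px=truth.mm_per_px,
        patch_side_mm=patch_side_mm,
    )


# --- trait-table generation --------------------------------------------------

#: Template trait mean vectors for the two characteristic spike morphologies
#: (order follows TRAIT_COLUMNS).
SPECIES_TEMPLATES = {
    "long_thin": np.array([62.0, 5.5, 60.0, 5.0, 230.0, 105.0, 0.25, 0.20, 95.0]),
    "short_compact": np.array([28.0, 9.0, 27.0, 8.0, 115.0, 42.0, 0.55, 0.50, 40.0]),
    "medium": np.array([45.0, 7.0, 43.0, 6.0, 170.0, 75.0, 0.40, 0.35, 70.0]),
}

#: Default within-species standard deviation per trait.
DEFAULT_BASE_SD = np.array([4.0, 0.8, 4.0, 0.7, 15.0, 7.0, 0.04, 0.04, 14.0])


def sample_species_means(
    template: str | np.ndarray,
    n_species: int,
    rng: np.random.Generator,
    jitter_frac: float = 0.05,
) -> np.ndarray:
    """Draw ``n_species`` mean vectors around a morphology template.

    Species-level jitter is Gaussian with sd = ``jitter_frac`` x template
    value, giving distinct but similar species within a morphology group.
    """
    base = SPECIES_TEMPLATES[template] if isinstance(template, str) else np.asarray(template, dtype=float)
    means = base + rng.normal(0.0, jitter_frac * np.abs(base), size=(int(n_species), base.size))
    return np.abs(means)


@dataclass
class TraitTableSpec:
    """Specification of a synthetic plant-level trait table.

    ``trait_means`` is an (n_species_per_ploidy, 9) array of species mean
    vectors; the same means are used for both ploidy groups (mirrored
    species), so that with ``variance_inflation`` = 1 the two groups are
    exchangeable in distribution.  ``variance_inflation`` (a scalar or a
    9-vector, one entry per trait) multiplies the *variance* of the
    designated ploidy group.
    """

    n_species_per_ploidy: int = 4
    n_plants_per_species: int = 25
    trait_means: np.ndarray | None = None
    base_sd: np.ndarray = field(default_factory=lambda: DEFAULT_BASE_SD.copy())
    variance_inflation: float | np.ndarray = 1.0
    inflated_ploidy: str = "6x"
    seed: int = 0

    def validate(self) -> None:
        if self.n_species_per_ploidy < 0 or self.n_plants_per_species < 0:
            raise ValueError("counts must be non-negative")
        sd = np.asarray(self.base_sd, dtype=float)
        if sd.shape != (9,) or np.any(sd <= 0):
            raise ValueError("base_sd must be 9 positive values")
        infl = np.asarray(self.variance_inflation, dtype=float)
        if infl.ndim not in (0, 1) or (infl.ndim == 1 and infl.shape != (9,)):
            raise ValueError("variance_inflation must be a scalar or a 9-vector")
        if np.any(infl < 1.0):
            raise ValueError("variance_inflation must be >= 1")
        if self.inflated_ploidy not in ("4x", "6x"):
            raise ValueError("inflated_ploidy must be '4x' or '6x'")
        if self.trait_means is not None:
            tm = np.asarray(self.trait_means, dtype=float)
            if tm.shape != (self.n_species_per_ploidy, 9):
                raise ValueError(
                    f"trait_means must have shape ({self.n_species_per_ploidy}, 9), got {tm.shape}"
                )


def generate_trait_table(spec: TraitTableSpec):
    """Generate a plant-level trait table with species and ploidy labels.

    Each plant contributes one row; each trait is drawn independently from a
    normal distribution with the species mean and ``base_sd``, with the sd
    multiplied by sqrt(variance_inflation) for the inflated ploidy group.
    Reproducible under ``spec.seed``.
    """
    import pandas as pd

    spec.validate()
    rng = np.random.default_rng(spec.seed)
    means = (
        np.asarray(spec.trait_means, dtype=float)
        if spec.trait_means is not None
        else sample_species_means("medium", spec.n_species_per_ploidy, rng)
    )
    infl = np.broadcast_to(np.asarray(spec.variance_inflation, dtype=float), (9,))
    base_sd = np.asarray(spec.base_sd, dtype=float)

    frames = []
    for ploidy in ("4x", "6x"):
        sd = base_sd * np.sqrt(infl) if ploidy == spec.inflated_ploidy else base_sd
        for si in range(spec.n_species_per_ploidy):
            n = spec.n_plants_per_species
            species = f"{ploidy}_sp{si + 1:02d}"
            values = rng.normal(means[si], sd, size=(n, 9))
            df = pd.DataFrame(values, columns=TRAIT_COLUMNS)
            df.insert(0, "plant", [f"{species}_p{j + 1:03d}" for j in range(n)])
            df.insert(1, "species", species)
            df.insert(2, "ploidy", ploidy)
            df["protocol"] = "table"
            df["projection"] = 0
            frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["plant", "species", "ploidy", *TRAIT_COLUMNS, "protocol", "projection"])
    return pd.concat(frames, ignore_index=True)
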