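"""End-to-end measurement of a single spike photograph.

Chains the standard stages: scale calibration from the reference patch,
chroma-key foreground segmentation, body/awn separation, centerline
extraction, two-quadrangle model fitting and trait assembly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import (
    CalibratedImage,
    SpikeSegmentation,
    estimate_scale,
    segment_foreground,
    split_body_awns,
)
from .morphometry import (
    CenterlineFrame,
    QuadrangleModel,
    ShapeTraits,
    assemble_trait_record,
    compute_centerline,
    compute_shape_traits,
    fit_quadrangles,
)
from .synthetic import DEFAULT_PATCH_RGB, DEFAULT_PATCH_SIDE_MM


@dataclass
class SpikeMeasurement:
    """All intermediate products of one measured image plus the trait row."""

    record: dict
    segmentation: SpikeSegmentation
    frame: CenterlineFrame
    model: QuadrangleModel
    traits: ShapeTraits
    mm_per_px: float


def measure_spike_image(
    image: np.ndarray,
    metadata: dict,
    *,
    mm_per_px: float | None = None,
    patch_side_mm: float = DEFAULT_PATCH_SIDE_MM,
    patch_rgb=DEFAULT_PATCH_RGB,
    opening_radius_mm: float = 1.0,
) -> SpikeMeasurement:
    """Measure the nine spike traits on one calibrated photograph.

    If ``mm_per_px`` is not given it is estimated from the in-frame
    reference patch of ``patch_side_mm`` physical side.  ``metadata`` must
    carry plant, species, ploidy, protocol and projection.
    """
    if mm_per_px is None:
        mm_per_px = estimate_scale(image, patch_side_mm, patch_rgb)
    cal = CalibratedImage(
        pixels=np.asarray(image),
        mm_per_px=mm_per_px,
        protocol=metadata.get("protocol", "table"),
    )
    fg = segment_foreground(cal, patch_rgb=patch_rgb)
    seg = split_body_awns(fg, mm_per_px, opening_radius_mm=opening_radius_mm)
    frame = compute_centerline(seg)
    model = fit_quadrangles(frame)
    traits = compute_shape_traits(seg, frame)
    record = assemble_trait_record(model, traits, metadata)
    return SpikeMeasurement(
        record=record,
        segmentation=seg,
        frame=frame,
        model=model,
        traits=traits,
        mm_per_px=mm_per_px,
    )
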