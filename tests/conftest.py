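"""Shared fixtures: rendered synthetic spikes and their segmentations."""

from __future__ import annotations

from dataclasses import replace

import pytest

from spikequant.calibration import CalibratedImage, segment_foreground, split_body_awns
from spikequant.morphometry import compute_centerline, fit_quadrangles
from spikequant.synthetic import render_spike_image, sample_ground_truth


@pytest.fixture(scope="session")
def medium_truth():
    return sample_ground_truth("medium", seed=7)


@pytest.fixture(scope="session")
def medium_render(medium_truth):
    """A medium spike with awns, rendered with mild sensor noise."""
    return render_spike_image(medium_truth, noise_sd=4.0, seed=7)


@pytest.fixture(scope="session")
def awnless_render(medium_truth):
    """The same spike geometry with no awns."""
    truth = replace(medium_truth, awns_area_mm2=0.0)
    return render_spike_image(truth, noise_sd=4.0, seed=7)


def segment_render(render):
    cal = CalibratedImage(pixels=render.image, mm_per_px=render.mm_per_px)
    fg = segment_foreground(cal)
    return split_body_awns(fg, render.mm_per_px)


@pytest.fixture(scope="session")
def medium_segmentation(medium_render):
    return segment_render(medium_render)


@pytest.fixture(scope="session")
def awnless_segmentation(awnless_render):
    return segment_render(awnless_render)


@pytest.fixture(scope="session")
def awnless_frame(awnless_segmentation):
    return compute_centerline(awnless_segmentation)


@pytest.fixture(scope="session")
def awnless_model(awnless_frame):
    return fit_quadrangles(awnless_frame)
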