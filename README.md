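# spikequant

Quantitative wheat spike (ear) morphometry from calibrated photographs, and
the cross-ploidy statistics built on it.

Wheat taxonomy leans heavily on spike morphology, and ploidy level
(tetraploid, 4x, vs hexaploid, 6x) is one of its main classifying
characteristics. `spikequant` turns a photograph of a single spike against a
blue background — with an in-frame reference patch for color normalization
and pixel-to-mm scaling — into nine quantitative traits, classifies spikes
by awnedness and length, and runs the species/ploidy-level analysis:
per-trait variance F-tests between ploidy groups, correlation-distance
clustering of species, and t-SNE ordination of images.

## The model

The spike body outline is approximated by **two quadrilaterals sharing a
straight centerline**: with x running from the base (x = 0) to the tip
(x = L), the upper chain passes through the vertices (0, 0), (xu1, yu1),
(xu2, yu2), (L, 0) and the lower chain through (0, 0), (xb1, −yb1),
(xb2, −yb2), (L, 0) — nine free parameters in total (eight interior vertex
coordinates plus the spike length L). The chains are fitted to the measured
half-width profiles by minimizing the mean absolute deviation, with a
coarse grid over the vertex abscissae followed by Nelder–Mead refinement.

The nine analysed traits per image are

| trait | meaning |
|---|---|
| `xu2_mm`, `yu2_mm` | distal upper vertex of the model |
| `xb2_mm` | distal lower vertex abscissa |
| `ybm_mm` | maximum lower half-width |
| `perimeter_mm` | body contour length |
| `rachis_length_mm` | centerline arc length |
| `circularity` | 4πA/P², 1 for a disc |
| `roundness` | 4A/(π·major axis²), ≈ aspect ratio for ellipses |
| `awns_area_mm2` | total awn area |

Classifications: awnless < 30 mm² ≤ moderately awned ≤ 90 mm² < awned;
short < 60 mm ≤ medium ≤ 90 mm < long.

Statistics: traits are z-normalized; variance equality between ploidy
groups is tested per trait with a two-sided variance-ratio F-test (one
image per plant); species are clustered by UPGMA on the 1 − r Pearson
distance between their 9-trait mean vectors; images are ordinated in 2-D
with t-SNE.

A synthetic-data module renders spike images whose body is an exact
two-quadrangle polygon with known parameters, thin random-walk awns of
known total area, and a reference patch of known physical side, so every
pipeline stage is testable without any photograph. It also generates
plant-level trait tables with a controlled variance ratio between ploidy
groups.

## Worked example

```python
import numpy as np
from spikequant import (
    sample_ground_truth, render_spike_image, measure_spike_image,
    classify_length,
)

truth = sample_ground_truth("medium", seed=21)
photo = render_spike_image(truth, noise_sd=4.0, seed=21)
meta = {"plant": "p1", "species": "demo", "ploidy": "6x",
        "protocol": "table", "projection": 0}
m = measure_spike_image(photo.image, meta)
print(f"scale      {m.mm_per_px:.4f} mm/px")
print(f"L          {m.model.L:.1f} mm (truth {truth.L:.1f})")
print(f"perimeter  {m.record['perimeter_mm']:.1f} mm")
print(f"awns area  {m.record['awns_area_mm2']:.1f} mm2")
print(f"class      {classify_length(m.model.L)}")
```

prints

```
scale      0.1000 mm/px
L          81.6 mm (truth 82.3)
perimeter  172.2 mm
awns area  54.4 mm2
class      medium
```

i.e. the scale is recovered from the 40 mm patch, the fitted spike length
is within ~1 % of the generator's ground truth, and an 82 mm spike lands
in the "medium" length class.

There is also a CLI: `spikequant simulate|segment|extract|classify|summarize|analyze`
(see `spikequant --help`).

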