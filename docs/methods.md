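# Methods

## Scope and data model

`spikequant` measures single-spike photographs taken against a uniform blue
background under either of two acquisition protocols ("on the table": one
frontal projection; "on the clip": several projections per plant as the
spike rotates about its axis). Every image must contain a reference patch
of known physical side, used for pixel-to-mm scaling and per-channel color
normalization. One image yields one 9-trait record; plants contribute one
record per projection, and the per-plant deduplication rule for the
variance screen keeps the lowest-numbered projection of the requested
protocol.

## Calibration and segmentation

**Patch localization** is chromaticity matching: a pixel matches the
declared patch color if its channel fractions of the RGB sum are within
0.04 of the reference fractions. Chromaticity is invariant to per-channel
linear gain, which is exactly the distortion the normalization step is
meant to correct, so the patch can be found in an uncalibrated image. The
largest matching connected component above 400 px is the patch.

**Scale** is the declared side divided by the measured side: the mean of
the two side lengths of the minimum-area rectangle enclosing the patch's
pixel *corner* points (pixel centers offset by half a pixel, so an
axis-aligned n-px square measures exactly n). Patches with aspect ratio
outside [0.9, 1.1] are rejected.

**Color normalization** applies per-channel gains so the measured patch
mean equals a reference RGB; a zero reference channel gives a defined gain
of zero, a zero measured channel with nonzero reference raises.

**Foreground segmentation** is a chroma key in HSV space. The background
hue is learned from the image itself — the circular mean hue of a 10-px
frame margin — rather than hard-coded, so moderate lighting shifts and
background-hue jitter (±10°) do not move the mask. Foreground pixels
differ from the background hue by more than 0.12 (43°) and exceed
saturation/value floors of 0.12/0.08. The patch region (dilated by 3 px)
is excluded; the largest connected component is kept along with components
touching its 4-px dilation. Masks covering < 0.1 % or > 60 % of the frame
are rejected as implausible.

**Body/awn separation** is a morphological opening with a disc of physical
radius 1.0 mm (at least 2 px): awns (~0.3–0.8 mm wide in wheat) are
removed, the body survives. Because the opening also erodes the pointed
base/tip wedges of the body, the largest surviving component is then
propagated through a second opening at awn scale (2 px disc), which keeps
any structure wider than an awn; the reclaimed wedge is finally grown back
over its 2-px boundary ring. If the residual foreground beyond the body is
negligible (< 0.5 % of the body area) the image evidently has no awns and
the leftover wedge tails are attributed to the body; synthetic experiments
show awnless residuals ≤ 0.11 % versus ≥ 1.4 % for the smallest awn loads,
so the rule is well separated. Known limitation: with awns present, the
last fraction of a millimetre of the tip sliver (where the body is thinner
than an awn) is indistinguishable from an awn, and awn pixels adjacent to
the body are absorbed by it; on synthetic data this biases the recovered
awn area by −2 % on average and shortens L by up to ~3 % on long thin
spikes.

## Axis frame and model fitting

The body's principal axis (from the pixel covariance eigenvectors) defines
the rotation to an axis-horizontal frame; masks with covariance aspect
ratio < 1.2 have no well-defined axis and are rejected. The base is the
wider end (mean width of the first vs last quarter of columns) and is
placed at the left. Per column, the top/bottom contour rows give the width
profile; their midline, smoothed over 2 mm, is the curved centerline whose
arc length is the rachis length, and L is the column extent. Half-width
profiles are measured from the base–tip chord, estimated from the
unsmoothed midline of the three extreme columns at each end (the smoothed
midline is biased at the apexes when the upper and lower slopes differ).
Because a photograph carries no intrinsic up/down, the frame is
canonicalized so the side with the larger mean half-width is "upper".

Each chain (four free parameters) is fitted to its half-profile by
minimizing the mean absolute deviation: a coarse grid over the two vertex
abscissae at {0.1L, …, 0.9L} with ordinates read off the profile, followed
by Nelder–Mead refinement from the six best grid starts (the objective has
shallow local minima when a profile edge is nearly straight). The
refinement never returns a residual above the best grid start, so the
optimizer is monotone; the whole procedure is deterministic. Fits with
residual above 20 % of the maximum half-width are returned flagged
`poor_fit` with a warning rather than rejected.

Shape descriptors use the standard morphometric definitions: circularity
4πA/P² and roundness 4A/(π·major²), with A the body mask area, P the
contour length and major the full major-axis length of the mask's best-fit
ellipse. The marching-squares contour overestimates length through pixel
staircasing, so the contour is smoothed with a 7-point circular moving
average before measuring; on digitized references this gives a disc
circularity of 0.996 and a square π/4 + 0.007, both well within the 0.02
tolerance used in the tests. Descriptors are capped at 1.

## Threshold classifications

Awnedness by total awn area: awnless < 30 mm², moderately awned 30–90 mm²
(closed interval), awned > 90 mm². Spike length: short < 60 mm, medium
60–90 mm (closed), long > 90 mm. The boundary values belong to the middle
class; "below/above" and "less/more than" are read strictly.

## Statistics

Traits are z-normalized per column with the sample (n−1) standard
deviation. The variance comparison between ploidy groups is a two-sided
variance-ratio F-test per trait, F = s²₆ₓ/s²₄ₓ with df = n−1 per group and
p = 2·min(P(F ≤ f), P(F ≥ f)); no multiple-testing correction is applied —
the nine traits are tested independently at α = 0.05. The z-normalization
does not change F (both groups share the column scaling); it is kept for
interface consistency with the clustering stage.

Species are summarized by the mean of each trait over their images;
species distance is 1 − r with r the Pearson correlation between two
9-trait mean vectors. Trait columns are z-scored across species first,
because raw traits mix mm, mm² and unitless scales and the correlation
would otherwise be dominated by perimeter and rachis length. Clustering is
UPGMA (average linkage) via `scipy.cluster.hierarchy.linkage`; the tests
verify it against an independent brute-force average-linkage
implementation to 1e-12. Trees export to Newick with branch lengths
derived from merge heights, and a flat cut at k groups is provided.

Ordination is t-SNE (scikit-learn, PCA initialization, 1000 iterations)
with a fixed seed recorded in the output; each projection of each plant is
a separate point. Perplexity must satisfy n ≥ 3·perplexity.

## Synthetic data

The generator is the ground-truth oracle for every stage. Spike bodies are
exact two-quadrangle polygons sampled from three morphology classes
matching the length classification: short_compact (L ∈ 38–57 mm,
half-widths up to 12 mm), medium (62–88 mm), long_thin (92–125 mm,
half-widths ≤ 7.5 mm). Sampling rejects near-degenerate outlines whose
interior vertex lies within 0.8 mm of the chord through its neighbours
(the vertex would be unidentifiable), keeps the base wider than the tip,
and gives the upper half at least 15 % more area than the lower one so the
canonical orientation is recoverable. Awns are 2–3 px wide random-walk
polylines anchored on the distal third of the contour, fanning from
near-perpendicular at the anchor towards the tip direction (wheat awns are
fairly straight bristles and rarely cross); walks are stamped until the
requested total area is met, within 5 %. The canvas is 1600×1000 px at
0.1 mm/px with a 40 mm reference patch; background (30, 60, 160), body
(190, 170, 120), awns (170, 150, 100); optional Gaussian pixel noise.
Rendering is bit-deterministic given (truth, seed).

Trait tables draw each plant's nine traits from independent normals with
species-level means and a per-trait base sd; a variance inflation factor
(scalar or per-trait) multiplies the variance of one ploidy group. Both
ploidy groups reuse the same sampled species means (mirrored species), so
with inflation 1 the groups are exchangeable by construction. Default
conditions used by the validation experiments: 2 species per ploidy × 50
plants (100 plants per group) for the variance screen with inflation 3 on
six of nine traits; 4 species per morphology template × 15 plants for the
two-cluster recovery; species-level jitter of 5 % around the template
means.

What the generator does *not* emulate: spikelet/glume texture, shadows,
specular highlights, the supporting clip, multi-spike scenes, or curved
rachises (the synthetic centerline is straight). Passing tests therefore
demonstrate correctness of the geometry, segmentation logic and
statistics, not robustness to photographic artefacts of real spikes.

## Validation experiment sizes

Geometric recovery uses 20 seeded awnless renders (noise sd 4) and
requires every model parameter within 5 % and L and perimeter within 2 %;
awns are validated separately on 20 awned renders at 10 % (their presence
degrades the tip parameters, see the limitation above). The F-test type-I
error uses 2000 Monte-Carlo null replicates at n = 30 + 30; the variance
screen and the cluster recovery use 50 simulated datasets each. These
sizes keep the full suite and the acceptance script within a few minutes
on one CPU while leaving the binomial error of the rate estimates well
below the asserted margins.
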