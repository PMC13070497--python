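# Methods

This note documents the models, algorithms and parameter choices behind
`orgoquant`, the assumptions they rest on, and what the synthetic benchmarks
do and do not demonstrate about real microscopy data.

## Image model and conventions

All quantification happens on 2D planes. Z-stacks are reduced by
maximum-intensity projection per channel; the package never analyzes volumes.
Internally every stack is `(channel, z, row, col)`; coordinates are 0-based
pixel centers, with `(x, y) = (col, row)` whenever a point or polygon is
exported. Physical calibration is a single isotropic pixel size in µm —
anisotropic in-plane calibration is rejected with an explicit error rather
than averaged, because every area below is a pixel count times one scalar.
A file with no calibration metadata requires an explicit override; 1 µm is
never assumed silently.

## Cluster segmentation

The merged organoid cluster is delineated by seeded region growing on the
reference channel: breadth-first growth from an operator-chosen interior
seed, accepting a 4-connected neighbor when its intensity lies within a
tolerance of the running region mean (mean updated after every acceptance,
neighbors offered in row-major order). The criterion uses differences only,
so a constant intensity offset does not change the result, and the fixed
scan order makes it deterministic and checkable against a brute-force
flood-fill oracle. Default tolerance: 35 intensity units on a 16-bit scale,
chosen to separate an organoid interior from background across the noise
levels the generator produces; it is the first parameter to adjust on real
images.

The outer boundary polygon is extracted by Moore-neighbor tracing of the
largest hole-filled component, emitting pixel-center vertices ordered
counter-clockwise. Tracing is done in-house because the marching-squares
contours of standard libraries interpolate at half-pixel offsets, whereas
the area accounting here is defined on pixel centers (a 10×10 block encloses
a 9×9 = 81 px² polygon). Masks too thin to bound area are flagged degenerate
instead of raising.

## Two-ellipse decomposition

A merged confrontation pair has a characteristic "snowman" outline. The
contour is canonicalized (counter-clockwise, arc-length origin at the
topmost-then-leftmost original vertex, resampled to 360 equally spaced
vertices — canonicalization makes the decomposition invariant to the input
polygon's starting vertex and direction), and a signed turning angle is
computed at each vertex over a 5-vertex chord window, smoothed by a circular
moving average of the same width. Vertices that are local turning minima
below −0.05 rad are concavity candidates.

The neck is the candidate pair maximizing

    (combined concavity depth) × (shorter arc between them) / (chord length),

subject to an arc separation of at least max(2·window, n/12) vertices. The
score encodes what a neck *is* — two deep concavities facing each other
across a narrow waist that splits the outline into two substantial arcs —
and is robust to the two failure modes a simpler "deepest pair" or
"farthest-apart pair" rule exhibits on jittered boundaries: an isolated
noise dent (deep, but with no facing partner, so its chord to any other
candidate is long) and local double-wiggles (tiny arc separation). Convex
outlines with fewer than two candidates raise a no-neck error; the
decomposition then falls back to splitting the contour by nearest hint
point, and only if that also fails does the error propagate.

Each arc (trimmed by 3 vertices at the neck, where the two lobes' boundaries
mix) is fitted by the direct least-squares ellipse-specific conic fit.
Fitted axes are normalized so major ≥ minor with rotation in [0, π). The
recorded residual is the RMS *radial* point-to-ellipse distance (measured
along the ray through the center): exactly zero for points on the ellipse —
on noiseless arcs it is ~1e-13 px, i.e. the fit is numerically exact — and a
tight proxy for orthogonal distance near the boundary, without the
convergence limits of iterative orthogonal projections.

Tumor identity goes to the ellipse whose interior holds the larger
GFP-positive pixel fraction when a GFP mask is available, else to the
ellipse containing the tumor hint. In semi-automated use, operator-supplied
ellipses bypass fitting entirely and are used verbatim, recorded as manual.

## Tumor segmentation and metrics

The GFP channel is thresholded inside the cluster only (Otsu on the
intra-cluster intensity pool by default; a fixed threshold is available),
then labeled with 8-connectivity — thin diagonal links such as tumor
microtubes should keep a protrusion attached to the mass, whereas cluster
growth uses 4-connectivity for compact tissue. Components below
`min_object_um2` (default 20 µm², roughly a nuclear cross-section; always
reported with the output) are discarded. The component containing the tumor
anchor — or nearest to it — is the core; everything else is a detached
single cell. "Detached" is literal: not in the core's 8-connected component.
Touching detached cells therefore count once; no instance splitting is
attempted.

With R the rasterized brain-ellipse pixel set, competition = |core∩R|/|R|,
single-cell = |detached∩R|/|R|, total = their exact sum. The denominator is
the full brain ellipse including its overlap with the tumor ellipse: overlap
pixels claimed by the core are precisely what "replacement" means. The
single-cell metric is area-based; the detached-component count (components
with ≥1 pixel in R) is reported alongside for the count interpretation.
Ratios outside their admissible range raise instead of clipping — a
violation signals an upstream geometry or segmentation failure that should
be seen, not hidden. No baseline correction is applied for GFP already
inside R at the first time point; time courses report raw per-time-point
ratios, with non-monotone total invasion flagged but allowed. Replicate
summaries are mean ± SEM with the n−1 SD denominator; treatment effect is
100 × (1 − treated/control) on arm means.

Rasterization evaluates the interior inequality at each pixel center with a
1e-12 relative epsilon, keeping pixels that lie exactly on the boundary
inside regardless of rotation round-off. The pixel count converges to πab
within 1.5% for semi-axes ≥ 15 px; at the default scene scale (a ≈ 78 px)
discretization contributes ≲1% to any ratio.

## Track analysis

Speeds follow the video-recording convention: windows of 40 min (default)
tile each track from its first sample; a step belongs to the window
containing its start time, so a sample landing on a window boundary closes
one window and opens the next. Path length is the sum of Euclidean step
distances — distance traveled, not net displacement — and converts as
path × 60/window. Straightness (net/path) is reported alongside. Windows
with no steps and incomplete trailing windows are skipped and logged. For a
straight track at constant speed the windowed speed equals that speed
exactly at any sampling interval; subsampling can only shorten path length
(triangle inequality). Analysis is planar; a z column is ignored with a
warning. No smoothing is applied.

A boundary reversal is detected at sample j when the position is within
`margin_um` (default 15 µm, about one cell diameter) of the brain-ellipse
boundary, the cell arrived moving outward (its normalized ellipse radius ρ
increased over the previous step), and the motion turns inward within the
next two samples; the event is anchored at the radial peak. The distance to
the boundary is measured along the ray through the ellipse center — exact
on that ray and monotone in ρ, which is all the margin test needs.

Division screening pairs each parent (via `parent_id`) with its daughters
and, for exactly two daughters, reports the angle between their initial
displacement vectors; "opposite directions" means > 90°. Other daughter
counts are flagged, unknown parents raise.

## Synthetic data: what it emulates, what it does not

The scene generator renders the structure the quantification assumes: two
overlapping ellipses (brain lobe ~78×66 px, tumor lobe ~48×42 px on a
256×256 frame at 1 µm/px) with a smooth radial boundary wobble (relative
amplitude 0.02, correlation length 6 px), a darker rim, and a GFP channel
painted before noise. The GFP core at zero replacement is the tumor lobe
*exclusive* of the brain region; the replacement front then grows from the
lobe junction into the brain lobe as a 4-connected geodesic flood, so the
replaced region is always contiguous with the core (mass replacement is
contiguous) and the realized replaced fraction hits the requested value to
within one pixel. Detached cells are placed by rejection sampling in the
unreplaced brain region with exact per-cell pixel quotas summing to the
requested area fraction, kept ≥2 px clear of the core and of each other;
optional sub-filter debris tests the size filter. Noise is Poisson shot
noise on the painted intensity plus Gaussian read noise (SD 8) on a 16-bit
scale (background ~100, GFP signal 3000, brightfield interior 170 /
rim 140 / background 90) — arbitrary but fixed. Ground truth (realized
fractions, counts, masks) is recomputed from the pre-noise masks, never
echoed from the request.

Walks are persistent random walks: turning angles are wrapped-normal with
σ = sqrt(−2 ln p) so the expected step-direction correlation equals the
persistence p (default 0.7); step lengths are gamma-distributed with mean
speed × Δt and CV 0.3 (default speed 23.8 µm/h — the fastest line observed
in the assay; tracks default to one 40-min recording sampled every 2 min,
matching one video session per cell). The brain ellipse is a specular
reflecting boundary; reflection preserves step path length. Divisions are
per-step Poisson events: the parent track ends, and after a stationary
mitotic pause (default 160 min) two daughters leave the division point with
exactly antiparallel headings. Reflection truth is logged at sampling
resolution: one event per boundary-contact episode, placed at the first
radial peak at or after the contact; a contact whose outward-inward turn is
never resolved in the recorded samples (the track ends first) is not an
event, because no detector operating on the samples could place it.

What passing the benchmarks shows: the estimator chain recovers known
replacement/detachment fractions (sweep over 0–0.5 × 0–0.2) with mean
absolute error ~0.01, recovers simulated line speeds within ~2% at the
35–40-cell scale, orders three arms separated by ~2 µm/h correctly in
≥95/100 replicate experiments, and recalls 100% of logged reversals and
divisions. What it does not show: robustness to uneven illumination,
out-of-focus planes, autofluorescence, touching-cell instance errors,
tracking errors from a real tracker, three or more merged organoids, or
tumor lobes whose outline is not approximately elliptical. The generator
deliberately contains no chemotaxis, no microtube rendering and no
photobleaching; it exists to give the estimator a known answer, not to be a
biophysical model.

## Numerical and degenerate-input choices

Region growing re-offers previously rejected pixels when a different
frontier neighbor reaches them (the running mean has moved) — intentional
and mirrored by the test oracle. Geodesic flood and blob placement break
distance ties in row-major order, making scenes pure functions of the seed;
the OME writer pins the file UUID to a content hash so identical seeds give
bit-identical files. Seeds failing their own acceptance criterion still
yield a singleton region. Single-pixel or 1-px-wide clusters produce
degenerate contours that are flagged, not raised; degenerate arcs
(collinear, < 5 points) raise a fit error naming the arc. An empty brain
region raises; an all-background GFP channel yields zero metrics. Batch CLI
processing records per-image failures as rows and continues; every output
row carries a hash of the run configuration, and all CLI randomness flows
from one top-level seed.

## Default problem sizes

The shipped benchmarks use 256×256 px scenes (24 per recovery sweep),
40-track corpora for speed recovery and 100-replicate ordering experiments,
30×400-min high-persistence walks for reversal recall and ~60 simulated
divisions — sizes at which every recovered quantity is stable to well within
its acceptance tolerance while the full suite runs in well under a minute.
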