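# Methods

## The measurement problem

In image-based deformability cytometry, cells driven through constricted
microchannels by a viscoelastic carrier fluid deform into elongated,
front-rounded "bullet" shapes. A high-speed camera records bright-field
frames of a region of interest (ROI) spanning several parallel channels, and
every cell's projected contour is reduced to a small feature set, chiefly the
deformability

    D = 1 − 2·√(π·A) / l

where A is the projected area and l the contour perimeter. D is the
isoperimetric deficit: 0 for a circle, increasing as the contour departs from
circularity, and quadratically sensitive to perimeter estimation error. The
package implements the full chain — synthetic frame generation with exact
geometric ground truth, detection and measurement, density-contour gating,
and the statistical comparisons used for phenotyping — so that every stage
can be validated against known geometry rather than against another image
processor.

## Synthetic cell geometry

Rendered cells come from a star-shaped contour family

    r(θ) = r0 · e(θ; k) · (1 + c3·cos θ·|cos θ|),
    e(θ; k) = 1 / sqrt(k·sin²θ + cos²θ / k)

an area-preserving ellipse elongation (semi-axis ratio k = 1 + c2 along the
flow axis) modulated by a front-bias factor that enlarges the nose and
flattens the rear. The one-parameter sub-family used for deformability
control ties c3 = 0.3·(1 − 1/k), so asymmetry grows with elongation. Over
the admissible range (c2 ∈ [0, 7]) the family is simple (r > 0 everywhere),
quasi-convex (convex-hull area ratio ≤ 1.002), and its deformability rises
strictly monotonically from 0 to ≈ 0.44 — comfortably covering every regime
studied here (population means 0.03–0.16). Monotonicity makes the inverse
problem well-posed: `contour_for_deformability` bisects the knob against a
dense-quadrature oracle (4096-gon shoelace area and polyline perimeter) to
1e-4 in D. Polygon vertices are placed at uniform elliptical anomaly rather
than uniform polar angle, which concentrates them at the high-curvature nose
and makes the quadrature converge to < 1e-5 relative at 1024 vertices.

Populations are sampled with truncated normal distributions: D on
[0, min(0.5, family max)], area on (0, ∞). Truncation bias is audited
analytically and recorded as a manifest warning when it shifts a mean by more
than 10%. Area and deformability decouple exactly because D is
scale-invariant: the shape is solved for D first and then rescaled to the
sampled area.

## Image formation model

The generator emulates the appearance of the reference acquisition rather
than its optics: a bright background (default 180 counts at 8-bit), each cell
darkening it by a uniform interior offset (default 45% of background) plus a
weak darker band (5%) just inside the contour — the "dark rim" of defocused
bright-field cell images. Cell coverage is evaluated on a 4×4 supersampled
grid per pixel using the exact radial profile, so the rendered edge position
is sub-pixel faithful to the ground-truth polygon. The scene is then
motion-blurred along the flow axis by a centered box kernel of length
velocity × exposure / pixel size (2.8 px at the default 0.7 m/s, 2 μs,
0.5 μm/px), blurred by an isotropic Gaussian PSF (σ = 0.7 px, the
diffraction scale of a 20×/0.45 NA objective at this sampling), and corrupted
by Poisson shot noise (via a photon gain of 5 e⁻/count) followed by Gaussian
read noise (SD 2 counts), clipped and quantized.

Two rendering choices matter for measurement accuracy and were fixed by
design, not calibration against targets:

* the rim band lies **inside** the polygon, so the darkness support is
  exactly the stated truth contour;
* the rim is **weak** relative to the interior offset. A strong symmetric
  rim makes any single-iso-level contour biased outward; with a weak rim the
  half-height crossing of the edge stays at the true boundary.

Default imaging geometry is the reference setup: a 1024 × 80 px ROI spanning
10 parallel channels, 1000 (or 10,000) frames/s, 2 μs exposure. Velocity is
a generator input; driving pressure appears only as metadata (the
pressure→velocity relation is an empirical device property not modeled
here).

Two placement drivers exist. `simulate_stream` draws per-channel Poisson
arrivals with lateral jitter (SD 1.5 px) around the channel centerline —
viscoelastic focusing is tight — and supports spiking mixtures down to
1:10,000. `render_population` packs cells densely (default 90% per-channel
occupancy) for parameter-recovery runs and prepends cell-free lead-in frames
emulating the acquisition start before cells reach the deformation zone;
these are the natural background-calibration input when occupancy is high.

## Detection and measurement

Per frame: background subtraction → 3×3 median denoising → absolute
threshold (default 6 × estimated noise SD) → 8-connected components →
sub-pixel contour extraction → features.

The background model defaults to the temporal **median** (robust to
transiting cells up to 50% per-pixel occupancy); the plain mean is available
and is what the packed-protocol driver applies to the cell-free lead-in
frames. Noise SD is estimated per pixel from the median absolute deviation
along time.

Contours are traced marching-squares style (`skimage.measure.find_contours`)
on the lightly smoothed (σ = 0.3 px) background-subtracted image at **half of
each object's own interior contrast** (median over the eroded component
core). For an edge blurred by a symmetric kernel the half-height crossing
coincides with the true edge, so this rule localizes the boundary without
bias and independently of absolute contrast; tracing at the detection
threshold level itself (the configurable alternative) sits near the foot of
the edge ramp and inflates areas by 5–10% at small radii. The traced polygon
is then low-passed in the Fourier-descriptor domain (12 harmonics kept of a
256-point arc-length resampling): pixel-scale tracing zigzag — which inflates
the perimeter and hence D — is almost entirely high-frequency, while the
bullet family itself is represented by 12 harmonics to better than 5e-4 in D.
Shapes with genuine high-frequency content (e.g. polygonal debris) are
outside this design envelope; the low-pass is configurable and can be
disabled.

Features: A and l from the shoelace formula and polyline length of the
sub-pixel contour; D from Eq. above; brightness as the mean original-frame
intensity over pixels whose centers fall inside the contour (holes filled);
aspect ratio as the major/minor axis ratio of the moment-equivalent ellipse,
computed by exact polygon moment integrals (free of pixelation bias — an
ideal 2:1 ellipse contour yields exactly 2.0); area ratio as convex-hull
area over A (≈ 1 for convex cells, larger for concave debris); channel
assignment by nearest channel centerline.

The presence filter rejects candidates by area bounds (default
10–500 μm²), area ratio above 1.05, or proximity to the ROI border
(default 3 px, clipped cells). Velocities are estimated by nearest-neighbor
centroid matching across consecutive frames within a channel and a
displacement gate; ambiguous matches yield no estimate.

### Known measurement biases

Against the generator's exact truth, the pipeline at default settings shows
(400–5000-cell runs across all studied regimes): mean-area bias ≤ +1.1%,
mean-D bias ≤ 0.003 for all populations except the small, strongly deformed
red-cell regime (equivalent radius ≈ 7 px, D ≈ 0.16), where PSF and motion
blur genuinely round the high-curvature nose and depress measured D by
≈ 0.006. This is a physical limit of half-height edge localization at that
scale, not a tuning residue; it is well inside the ±0.01 recovery tolerance
and documented rather than compensated.

## Gating and rare-cell quantification

Populations are summarized in the (area, deformability) plane by a normalized
2-D histogram (default 64 × 64 bins over robust 1st–99th percentile ranges)
or a Gaussian product-kernel KDE with per-axis Scott bandwidths
(h_i = σ_i·n^(−1/6)), evaluated by the standard binned approximation
(histogram on a grid padded by 6 bandwidths, then Gaussian filtering; the
grid integral stays within 1e-3 of unity). The "50% density contour" is the
iso-contour at half the **maximum density value** — a level on the linear
density scale, matching the scatterplot convention — not a 50%
probability-mass region. Contours are traced on a zero-padded grid so
regions touching the edge still close.

A gate is the largest-area such contour of a pure reference population,
stored with provenance (method, level, reference size). Membership counts
boundary points as inside. Because the half-max region of a Gaussian-like
population contains ≈ 50% of its mass, rare-cell quantification is
capture-corrected: the gate's capture fraction is measured once on reference
data, and gated counts (and their Clopper–Pearson 95% intervals) are divided
by it to estimate the spike ratio. With populations separated by ≥ 4 SD in
both axes, contamination from the majority population is negligible and the
corrected interval covers the true spiking ratio at its nominal rate.

## Statistics

Two-group comparisons use the two-tailed Mann-Whitney U test with the
standard policy: exact enumeration when the smaller sample has ≤ 8
observations and no ties, otherwise the normal approximation with midrank tie
correction and continuity correction. Dose-response panels use one-way ANOVA
followed by Tukey's multiple-comparison test (Tukey–Kramer standard errors
for unequal n). Significance stars follow the strict GraphPad-style
thresholds: P < 0.033 (*), < 0.0021 (**), < 0.0002 (***), < 0.0001 (****),
else "ns". Summaries report mean/SD/n of deformability, area, and the
size-to-deformability ratio (mean area / mean D, defined only for positive
mean D), either pooled over single cells or — matching the bar-chart
convention of replicate experiments — as the mean of replicate means; the
mode is labeled in the output because the two can differ.

## Streaming architecture

Real-time operation is emulated by three logical stages — acquisition,
analysis, accumulation — joined by a bounded FIFO buffer. Acquisition runs
on its own thread; analysis drains the buffer through the same per-frame
entry point as batch processing, so a run with no dropped frames is
bit-identical to `process_sequence`. Overflow policy is selectable: `block`
(never drop) or `drop-oldest` (discard the oldest unprocessed frame and count
it). The conservation identity frames_in = frames_processed + frames_dropped
holds in every run. Achieved frame and cell rates are reported as metrics
only; they are host-dependent and never asserted.

## Flow characterization

The carrier fluid's shear-thinning viscosity follows the Carreau model
η(γ̇) = η∞ + (η0 − η∞)[1 + (λ_c γ̇)²]^((n−1)/2), fitted to rheology data by
least squares in log-viscosity space with bound constraints (requires ≥ 6
points over ≥ 2 decades of shear rate). Dimensionless numbers use the
conventions Re = ρUH/η, Wi = λU/H (characteristic shear rate U/H) and
El = Wi/Re, with a default density of 1080 kg/m³.

## What the synthetic data does and does not establish

The generator reproduces the geometry, arrival statistics, channel layout,
blur, and noise character of the reference acquisition, with exact per-cell
truth. It does **not** model cell optics (phase contrast, diffraction
fringes), physical deformation dynamics (no fluid–structure interaction),
intra-cell texture, or focus variation. Passing the recovery suite therefore
demonstrates that the image-analysis chain is unbiased for objects matching
its stated contrast model at realistic noise, blur, and size — not that the
pipeline is robust to every real-microscope artifact. Conversely, because
the truth is exact, any measurement bias observed here is attributable
entirely to the estimator.

## Problem sizes and numerical choices

Parameter-recovery runs use 5,000 cells per population (the per-experiment
cell count of the reference studies) at the default imaging configuration;
each run takes ~30–40 s on one CPU. Rare-cell checks run at 10⁶ records per
replicate, record-level (no rendering). Degenerate inputs are handled
explicitly: single-frame sequences warn and return that frame as background;
zero-variance axes raise a named error in KDE density estimation; degenerate
contours (< 8 vertices or non-positive area) yield rejected records, never
exceptions; saturated frames are skipped with a logged reason. All
randomness flows through `numpy.random.Generator` seeds; fixed seeds give
byte-identical frames, manifests, and tables.
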