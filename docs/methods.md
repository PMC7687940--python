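# Methods

This note documents the models, numerical choices and limitations behind
`fibrekit`. It describes what the code computes and why; every number quoted
here is produced by the package's own tests or scripts.

## Image model and pre-processing

A field of view is three co-registered 2D rasters: SHG (collagen), PL
(cellular fluorescence) and laser transmission. On load, intensities are
rescaled to [0, 1] — integer data by its dtype maximum (so identical
acquisitions compare across files), float data by the channel maximum. The
coordinate convention is row-major, 0-based, pixel centres on integer
coordinates; the default physical pixel size is 471/512 ≈ 0.92 μm, matching a
0.471 mm field sampled at 512×512.

Noise reduction applies a median filter (radius 1 px, for impulsive shot
noise) followed by Gaussian smoothing (σ = 1 px, for white noise), both with
reflect padding. Both default scales are the smallest that act at all; the
operators are the standard choices for those two noise classes, and
`sigma=0, median_radius=0` is an exact identity. When several focal planes of
the same position are available, `plane_consensus` takes the per-pixel median
across planes — a cheap, permutation-invariant stand-in for acquisition-time
plane comparison. It is optional and not part of `compute_record`.

## Structure tensor and texture metrics

Gradients are Gaussian derivatives (σ_d = 1 px), and the tensor components
g_i g_j are averaged over a Gaussian window (σ_w = 1 px), reflect-padded. For
a symmetric 2×2 tensor the anisotropy is computed in closed form,

    n = sqrt((t_xx − t_yy)² + 4 t_xy²) / (t_xx + t_yy),

identical to (λmax − λmin)/(λmax + λmin) but without an eigen-solver call per
pixel; a zero tensor (flat region) maps to 0 by convention — flat regions
count as maximally unordered. Total anisotropy averages the tensor over the
pixel set first; local anisotropy averages each pixel's 3×3-window tensor,
takes the per-pixel anisotropy, then averages the scalars. The 3×3 window is
fixed; the two metrics deliberately bracket "global order" vs "local order":
two orthogonal stripe patches score ≈ 0 total but > 0.8 local (asserted by
test).

Orientation is axial (θ ≡ θ + 180°). The fibre axis is the principal axis
rotated by 90° from the gradient axis, obtained from
tan 2θ = 2 t_xy / (t_yy − t_xx). The angle spectrum uses 180 unweighted
1-degree bins over [0, 180); SDI = mean/max of the bin counts, so a
single-orientation image scores 1/180 and a flat spectrum scores 1. Counts
are unweighted because coherence weighting would couple the SDI to intensity
texture; the mean angle, by contrast, *is* coherence-weighted (low-coherence
pixels carry no reliable orientation) and uses the doubled-angle circular
mean. Intensity entropy uses 256 bins over [0, 1] (8-bit convention), in
bits, with 0·log 0 := 0.

## Fibre network tracer

The tracer concretizes a FIRE-style growth process:

1. **Mask.** SHG > threshold; by default Otsu's threshold on the denoised
   channel, so the operating point adapts to each image.
2. **Nucleation.** Local maxima of the Euclidean distance transform of the
   mask (ridge midpoints), greedily thinned to a minimum spacing of 10 px,
   processed deepest-first with lexicographic (row, col) tie-breaks.
3. **Propagation.** From each seed, chains grow in both senses of the local
   orientation axis in steps of 3 px. At each step the axial ridge direction
   is re-read from the orientation field and sign-aligned with the current
   heading; growth stops when the direction change exceeds 70°, the path
   leaves the mask, or the tip comes within the 5 px edge-length threshold of
   any existing node — in which case it fuses to that node. Fusing to *any*
   node (not only siblings) is what joins touching fibres into one graph.
4. **Seed suppression.** A seed already within the edge threshold of an
   existing node is skipped; its ridge is already covered.

There is no randomness anywhere in extraction; rerunning on the same raster
is bit-identical. Raising the intensity threshold can only shrink the mask
and hence never increases the node count (asserted by test).

Fibre identification starts one walk at every degree-1 node, at each junction
taking the unused edge of least direction change, stopping at the 70°
tolerance or on revisiting a node. Edges are consumed, so a simple path is
traced once, not once per tip. Pure cycles (no degree-1 node) yield no fibres
and are reported separately; they still contribute to network spectra.
Waviness is displacement/length — the convention in which 1 means perfectly
straight — and fibre angle is the end-to-end orientation (the mean edge
orientation was the rejected alternative; end-to-end matches the displacement
that waviness is built from). Network connectivity defaults to algebraic
connectivity (second-smallest Laplacian eigenvalue), computed per connected
component of ≥ 3 nodes and averaged, as is the adjacency max-eigenvalue.

## Segmentation

The pseudo-H&E composite stacks (SHG, PL, trans) per pixel and normalizes to
unit length, removing joint intensity scale exactly (a test asserts
invariance under multiplying all three channels by one constant). Zero
vectors are background and join neither class. Mini-batch K-means with k = 8
clusters the unit vectors (k is deliberately larger than the two classes so
mixed-colour clusters can split); each centroid, renormalized to unit length,
is fibrous iff its red component exceeds the boundary (default 0.5). The
boundary is dataset-dependent by construction; `calibrate_red_boundary` fits
it on a labelled subset by maximizing Jaccard overlap, and the CLI exposes
this as `calibrate-boundary`.

Refinement rasterizes all network edges, dilates by 2 px, and forces those
pixels into the fibre class — the traced SHG network outranks colour
clustering as collagen evidence. Components under 64 px are dropped. Segment
shape is 1 − 2√(πA)/P with P the weighted boundary-step perimeter from
`skimage.measure.regionprops` (diagonal steps weighted √2); on a rasterized
radius-100 disc this estimator yields a shape of ≈ 0.046, within the ±0.05
rasterization tolerance the metric is stated with. Eccentricity is that of
the second-moment-matched ellipse; collinear runs degenerate to 1.

Coverage is segment area over *whole-image* area (so fibre + cell coverage
≤ 1, background permitted); a per-segment bounding-box variant is exposed
separately as `bounding_box_coverage`.

## The 29-metric database

Nine fibre/network metrics plus ten per segment class (fibre texture from
SHG, cell texture from PL) make exactly 29 canonical metrics; fibre density
(fibre-region share of total SHG intensity) is auxiliary, outside the 29 but
in the database and available to the classifier behind
`include_fibre_density`. Per-segment metrics are averaged unweighted across
segments ("each segment one vote"); area weighting is available via config.
Undefined values — e.g. segment-class averages when no segment of that class
survived filtering — are NaN sentinels, written as empty CSV cells, never 0:
a 0 anisotropy is a measurement, an empty cell is an absence.

## Classifier stage

Preprocessing per feature: min-max to [−1, 1], then a rank-based
normal-quantile transform (`QuantileTransformer`); Yeo-Johnson is available
via config for users who prefer a parametric map. Constant features map to
zeros. Inside cross-validation all transform parameters are fitted on the
training folds only — a spy test asserts the fit never sees test rows, and a
canary test plants the label into one fold's test rows and checks accuracy
stays at chance.

LDA uses the eigen solver with automatic (Ledoit-Wolf) shrinkage: with 29
features and folds of a few dozen images the pooled covariance is
ill-conditioned. The stated six splits are read as K = 6 stratified folds,
each image tested exactly once; the CV unit is the image. A group-aware
variant (keeping all images of one case together) is a known gap, noted under
limitations. Binary normal-vs-carcinoma accuracy is reported both ways the
question can be asked: regrouping the four-class model's predictions, and
refitting a dedicated two-class model per fold. RFECV removes, per step, the
feature with the smallest L2 norm of its discriminant coefficients and
records the mean CV score at every feature count down to 1.

ANOVA between two groups uses `scipy.stats.f_oneway`; for two groups F equals
the squared pooled-variance t statistic (asserted against `ttest_ind`). Both
groups constant and equal yields p = 1 rather than NaN.

## Phantom generator

Phantoms state a world, not a fit: fibres are sine-perturbed strokes whose
amplitude is solved (by bisection on the arc-length integral) so that
displacement/arc-length equals the waviness target exactly in the continuum;
zero phase and whole periods keep the endpoints on the chord. Strokes are
rasterized with a soft round profile (width 2 px default ≈ a ~2 μm fibril
bundle at the 0.92 μm default pixel size); cells are Gaussian blobs;
transmission is 1 − 0.5·(SHG + PL), a convenience coupling, not a physical
model. Noise is Gaussian (σ = 0.02) plus Poisson at a nominal 200-photon full
scale — enough to exercise the denoiser without burying structure. Defaults
(20 fibres of 60–140 px, waviness 0.95, 4 blobs of 12–30 px on 256²) give
mid-density fields where both segment classes appear.

The four cohort presets differ strongly and deliberately in fibre count,
length, alignment and blob coverage ("normal": many short disordered fibres,
small blobs → "solid": few long fibres, large merged blobs). They echo the
qualitative contrast between healthy stroma and progressively cellularized
tumour tissue but claim no biological fidelity; a green parameter-recovery
test establishes that the pipeline recovers *constructed* class structure
(93% 6-fold accuracy at 25 images/class, shuffled-label baseline ≈ 27%
against 25% chance), not that it would reach any particular accuracy on real
biopsies. The phantom world also omits: SHG speckle and coherence effects,
fibre thickness variation, collagen inside cellular regions (the cause of the
folded-cell-segment artifact real tissue shows), and case-level correlation
between images.

Cohort seeds derive from one master seed via `numpy.random.SeedSequence`, so
cohorts are reproducible end to end; the determinism tests require
byte-identical databases and reports across reruns.

## Known limitations

- The tracer follows ridges of the orientation field; very short (< ~2-step)
  fibres fall below its resolution, and dense crossings can fuse strokes —
  the traced fibre count on crowded phantoms is close to, but not equal to,
  the drawn count.
- The red-component boundary is a single plane in colour space; imaging
  configurations whose channels differ strongly in gain need recalibration.
- Accuracy is image-level; without case identifiers the classifier cannot
  guard against case-level leakage in real cohorts.
- Metrics are computed at native resolution only; no multi-scale tiling.
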