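# fibrekit

Quantitative analysis of multiphoton tissue images for collagen and cell
morphology. Given paired second-harmonic-generation (SHG), two-photon
photoluminescence (PL) and laser-transmission channels of a tissue field of
view, `fibrekit` extracts the collagen fibre network, segments the field into
fibrous and cellular regions, computes a database of 29 global image metrics,
and classifies tissue diagnosis with linear discriminant analysis (LDA) under
stratified cross-validation. It is aimed at groups doing label-free or
H&E-adjacent nonlinear microscopy of stroma-rich tissue (e.g. mammary tumour
biopsies) who want reproducible, per-region morphometrics instead of visual
scoring.

## What it computes

**Structure-tensor texture.** For an intensity map f(x, y) the structure
tensor T is the window-averaged outer product of the smoothed gradient. Its
eigen-system gives per-pixel fibre orientation (the axis of least intensity
variation) and the anisotropy

    n = (λmax − λmin) / (λmax + λmin) ∈ [0, 1],

0 for isotropic texture, 1 for perfect alignment. *Total* anisotropy applies
this to the mean tensor of a pixel set, n = f(⟨T⟩), so orthogonal orderings
cancel; *local* anisotropy averages the per-pixel anisotropy of each 3×3
window mean, n_local = ⟨f(T)⟩, and is insensitive to overall direction. The
angle-spectrum distribution index (SDI) is mean/max of the folded orientation
histogram (1 = flat, disordered spectrum).

**Fibre network.** A FIRE-style tracer: nucleation points are seeded on ridge
maxima of the thresholded SHG mask and propagate node chains along the local
orientation field; a propagating tip may fuse to *any* existing node within
the edge-length threshold, so touching fibres join into one graph. Individual
fibres start at degree-1 nodes and continue through junctions along the
direction of least bending. Per fibre: length L (summed edge length),
displacement D (end-to-end), waviness D/L ∈ (0, 1] (1 = straight), and
orientation. Per network: mean degree 2|E|/|V|, largest adjacency eigenvalue,
algebraic connectivity, and cross-link density (degree ≥ 3 nodes per fibre).

**Segmentation.** The three channels are stacked into a pseudo-H&E "RGB"
image and normalized per pixel to unit vectors; mini-batch K-means clusters
them and each centroid is called fibrous or cellular by its red (SHG)
component against a calibratable boundary. The traced network then refines
the split, and connected segments get shape 1 − 2√(πA)/P (0 = disc, → 1 =
elongated/folded) and moment eccentricity.

**Statistics.** Per-metric one-way ANOVA between diagnosis groups with
conventional stars, and LDA on all 29 metrics — each feature min-max scaled
to [−1, 1] and Gaussianized (rank-based normal-quantile transform), fitted
under stratified 6-fold CV with preprocessing learned on training folds only.
Reported: multiclass accuracy, binary normal-vs-carcinoma accuracy (both by
regrouping predictions and by a dedicated two-class refit), a 2-component
projection with 1-SD class ellipses, and an optional recursive feature
elimination (RFECV) curve.

## Worked example

```python
import fibrekit as fk

img, truth = fk.make_phantom(fk.PhantomSpec(seed=7))   # 256×256 phantom field
rec = fk.compute_record(img)
for k in ("No. Fibres", "Fibre Waviness", "Fibre Lengths",
          "Fibre Segment Coverage", "Fibre Segment Anisotropy", "Fibre Density"):
    print(f"{k}: {rec[k]:.3f}")
```

prints

```
No. Fibres: 22.000
Fibre Waviness: 0.949
Fibre Lengths: 65.382
Fibre Segment Coverage: 0.104
Fibre Segment Anisotropy: 0.722
Fibre Density: 0.731
```

The phantom was drawn with 20 strokes at waviness target 0.95, so the traced
count (22, crossings can split or fuse strokes), the recovered mean waviness
(0.949) and the mean traced length (65 px against drawn lengths of 60–140 px,
shortened by crossings and thresholding) are all consistent with the known
ground truth; 73% of the SHG intensity falls inside the segmented fibre
region.

The same pipeline from a shell:

```sh
fibrekit synth fields/ -n 25 --seed 1          # 4-class phantom cohort
fibrekit process fields/ metrics.csv --seed 1  # 29-metric database
fibrekit classify metrics.csv report.json --seed 1 --rfecv
```

On that cohort the classifier reports a 6-fold multiclass accuracy around
93% and binary (normal-vs-rest) accuracy of 100%, reflecting the strongly
separated phantom presets rather than any biological claim.

## Acceptance script

`scripts/acceptance.py` recomputes, from scratch through the package, the
analytic limiting values of three core metrics: the total anisotropy of a
parallel-stripe image (fully ordered limit), the waviness of a fibre with
collinear nodes (completely linear limit), and the segment-shape metric of a
rasterized disc (completely circular limit). Run it from the repository root:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
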