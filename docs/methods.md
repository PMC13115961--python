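# Methods

`mirsa` annotates tissue types on mid-infrared (MIR) hyperspectral
images by spatial-autocorrelation (SA) analysis of per-tissue
projection images. This note records the model, the parameter choices,
and the design decisions behind the implementation.

## Preprocessing

Raw cubes hold transmittance per pixel over a wavenumber grid
(instrument convention: 750–4000 cm⁻¹ at 4 cm⁻¹ sampling; the package
accepts any strictly monotonic grid). The chain is:

1. **Background normalization** — division by an optional reference
   spectrum; skipped with a logged notice when none is supplied.
2. **Smoothed second derivative** along the spectral axis
   (Savitzky–Golay, window 9, polynomial order 3 by default). The
   derivative suppresses broad baseline structure and is the standard
   transform in vibrational spectroscopy; results are reported
   unit-less.
3. **Standard normal variate (SNV)** — per-pixel mean-centering and
   scaling to unit standard deviation. Pixels whose derivative spectrum
   has (numerically) zero variance cannot be scaled; they are flagged,
   set to zero and removed from the valid-pixel mask. "Numerically
   zero" means a spectral standard deviation below 1e-8 of the pixel's
   derivative scale, which catches constant and pure-polynomial
   spectra without touching real data.

Tissue masking runs k-means (k = 2) on the raw single-band image at
1552 cm⁻¹ (nearest grid band; matching tolerance is half the median
sampling interval). The lower-transmittance (higher-absorbance)
cluster is tissue by default; polarity is configurable for cubes in
absorbance units.

Coordinates are row-major and 0-based everywhere.

## Discriminant wavenumber selection

For a tissue type of interest (TTOI) the selector:

1. draws a class-balanced pixel subset (500 per tissue type by
   default, capped at the least prevalent type's size),
2. fits a random forest for the binary TTOI-vs-rest task and ranks
   every band by permutation importance,
3. repeats ten times with fresh subsets; every band ranking in the
   top ten at least once becomes a candidate,
4. applies a **specificity error test**: a band survives only if some
   intensity cutoff assigns no tissue type more than 25% of its pixels
   to the wrong side. The cutoff search is a deterministic grid scan
   (512 steps over the band's observed range, so the test is invariant
   to affine rescaling); the error is the worst single-class
   misassignment fraction, counting both TTOI leakage and
   contamination by each other type,
5. tags survivors as positive predictive (ppf; TTOI mean above the
   rest) or negative predictive (npf).

Two implementation choices matter:

* **Importance is scored on held-out pixels.** Neighboring bands of a
  vibrational feature are strongly correlated; on its own training
  pixels a forest reconstructs any single shuffled band from its
  neighbors and every importance collapses to exactly zero. Each
  repeat therefore splits the labeled pixels per class into disjoint
  train/eval halves, trains on a balanced draw from the first and
  scores balanced accuracy on (up to 500 of) the second.
* **Forest size.** 100 trees with scikit-learn defaults otherwise,
  seeded. Selection quality is driven by the top-ten union over ten
  repeats plus the error test, not by forest size; 100 trees keeps a
  full selection run at tens of seconds on one core.

If no candidate passes the error test the selector raises a
no-discriminant-features error naming the tissue type — some tissue
types (e.g. inflammation in the motivating application) genuinely lack
specific bands.

## Projection images

Selected bands are fused into one plane per tissue type:

    P_k = baseline + Σ_i T_k^i − Σ_j T_k^j

with i over ppf bands, j over npf bands and a baseline offset of +10.
Negative values are permitted (SA uses only relative values, and
clipping would distort the intensity distribution); off-mask pixels
are written as 0 so projections zero-pad cleanly when stitched.

## Local Moran's I with conditional permutation

The hotspot statistic at pixel i is the standardized local Moran

    I_i = (z_i / m2) · Σ_j W_ij z_j,   z = x − x̄,   m2 = (1/n) Σ z²,

with queen contiguity (the eight surrounding pixels), off-mask
neighbors removed and remaining weights row-standardized (binary
weights available via `style="binary"`). x̄ and m2 are taken over all
on-mask pixels; pixels with no on-mask neighbor are flagged isolated —
they contribute to the global moments as observations but are excluded
from inference and can never be hotspots.

Significance uses **conditional permutation**: the focal value is held
fixed and its neighborhood redrawn, without replacement, from all
other on-mask observations; with 999 permutations by default,

    p_i = (#{I_perm at least as extreme as I_obs} + 1) / (n_perm + 1),

one-sided in the direction of the observed statistic. A **hotspot** is
a pixel that is significant at α (default 0.01) *and* lies in the
high-high quadrant (z_i > 0 and positive lag); significant low-low
pixels are exposed as coldspots but unused by default. Re-thresholding
at a different α needs no recomputation.

Every pixel owns a counter-based RNG substream (Philox keyed by the
master seed and the pixel's flat grid index), so p-values do not
depend on traversal order and any pixel's permutation stream can be
reproduced in isolation — the tests exploit this to compare against a
loop-level reimplementation permutation by permutation.

A consequence of queen contiguity worth noting: on a ±1 checkerboard
the four same-color diagonal neighbors cancel the four opposite-color
edge neighbors, so interior I_i is exactly 0 (not negative, as it
would be under rook contiguity); alternating stripes give the
expected negative autocorrelation.

## Cohort-wide SA

Per-sample projections are zero-padded to a common tile size and
stitched into a near-square "super image" with a 1-pixel zero gutter
between tiles (queen neighborhoods must not cross sample boundaries).
Zero/off-tissue pixels are omitted, so the global mean, variance and
the permutation pool span every on-tissue pixel of every sample; each
pixel is thus tested against the cohort-wide intensity distribution.
The stitched result is disassembled back into per-sample maps, which
tile-exactly partition the super-image map.

This is what makes homogeneous samples tractable: analyzed alone, a
control without the TTOI still yields ~α·n spurious "hotspots" inside
its own narrow intensity distribution; inside the cohort its values
sit below the cohort mean, cannot enter the high-high quadrant, and
receive (almost) no hotspots.

Because each tile keeps its own pixel-indexed permutation substreams,
identical copies of a sample placed in one cohort share observed
statistics and quadrants exactly, while their pseudo-p values carry
independent permutation noise; maps may differ in the few pixels at
the significance edge.

## Hotspot database and reference-based SA

`build_database` stores, per sample, the cohort-wide Moran result
(full p-grid, for re-thresholding without recomputation), the hotspot
map at α_db, the on-tissue area and the hotspot-to-total-tissue-area
ratio. Reference selection takes the entries with the lowest and the
highest ratio (the low–high combination; ties broken by sample id,
further references alternate inward from the extremes). Two references
is the default.

A new sample is stitched with the two references and SA runs on that
group of three alone — the database's global moments are *not*
injected. The confidence level is swept over α ∈ [0.0005, 0.5] in
steps of 0.0005 (1000 levels); at each level the references' p-grids
are re-thresholded and compared to their database maps by
intersection-over-union, and

    α* = argmax_α (1/m) Σ_i IoU(R_i, R̂_i(α)),

ties resolved to the smallest α. The new sample's map is its p-grid
thresholded at α*. A variant that averages each reference's own best
α is available (`mode="mean_argmax"`). Calibration uses 1999
permutations by default so the pseudo-p granularity (1/2000) matches
the α grid step; with 999 permutations half the grid levels could
never change a map.

Self-consistency behavior: re-calibrating a copy of a database sample
returns α* at or within a few grid steps of α_db and reproduces its
database map with IoU well above 0.9. The residual α* scatter is
genuine — the group of three is a different permutation pool than the
full cohort, and the IoU curve is nearly flat around its maximum.

## Evaluation

Annotations are scored inside evaluation rectangles (three equal
horizontal strips per section in the pipeline's default protocol)
against integer label maps, restricted to on-tissue pixels; unlabeled
truth pixels are not considered. From TP/FP/FN/TN per rectangle:

* standard accuracy (TP+TN)/total — per sample, the mean over its
  rectangles; across samples, median and quartiles (linear
  interpolation);
* balanced accuracy (TPR+TNR)/2 and PPV TP/(TP+FP) — pooled from the
  element-wise *sum* of counts over all rectangles and samples (not
  the mean of per-rectangle values).

Pixels the SA overlay assigned to no tissue count as negative
predictions by default; an exclusion grid can remove them (or
multi-assigned pixels) from the evaluated set. Multi-assigned pixels
count as positive for each tissue evaluated independently.

## Synthetic cohorts

The generator emulates the structure the method assumes, with known
ground truth:

* **Geometry**: thresholded smoothed Gaussian random fields give an
  organic section outline (~85% on-tissue) and a blob partition into
  tumor / stroma / parenchyma (35/35/30% of tissue area). Every
  on-tissue pixel has exactly one true label.
* **Spectra**: a shared transmittance base with broad absorption bands
  (including 1550 cm⁻¹, so raw-intensity masking behaves like real
  data) plus per-tissue Gaussian signature bands (σ = 10 cm⁻¹,
  amplitude 0.08). A band's declared ppf/npf direction refers to the
  analysis domain: a ppf band is planted as a raw transmittance *dip*
  (second derivative positive at center), an npf band as a raw peak.
* **Noise**: iid Gaussian (sd 0.02), a spectrally quadratic and
  spatially smooth baseline drift (amplitude 0.02), and an optional
  per-sample gain/offset batch effect (off by default). These defaults
  put the planted bands at ≈3σ between-class separation after
  preprocessing — strong enough to pass the 25% error test decisively,
  as real discriminant bands do, while leaving visible pixel noise.
* **Controls**: a configurable fraction of samples (default 1/7) is
  homogeneous — a single non-TTOI tissue, emulating non-tumor
  parenchyma controls.
* **Cores**: `punch_cores` crops circular tissue-microarray-style
  cores; a G18-equivalent 825 µm needle on the 25 µm grid gives
  33-pixel cores.

Two default problem sizes are frozen: the full spec (64×64 pixels,
750–1798 cm⁻¹, 263 bands — the fingerprint region) and `compact_spec`
(48×48 pixels, 902–1554 cm⁻¹, 164 bands, signature centers on-grid),
used where a benchmark repeats the workflow many times. Tests and the
acceptance script state which size they use; both share the same SNR
and geometry model.

What the generator does **not** emulate: Mie scattering and dispersion
artifacts, atmospheric lines, detector drift, co-registration error
between stained sections and MIR data, and pathologist label noise.
Passing tests therefore demonstrate the statistical machinery —
selection, projection, permutation inference, calibration, scoring —
under controlled conditions, not robustness to instrument physics.

## Problem sizes and runtime

Single-CPU runtimes that shaped the defaults: one local-Moran run on a
full 64×64 mask with 999 permutations takes ~1.5 s; a 7-sample compact
cohort-wide run ~4 s; a reference calibration (3 stitched samples,
1999 permutations, 1000 α levels) ~3 s; one full feature selection
(10 repeats) ~20 s on the compact cube. The test suite's repeated-run
benchmarks (20 selection runs, 10 held-out calibrations, 50
noise-field replicates) use these sizes.

## Known limitations

* The permutation loop is pure NumPy per pixel; very large sections
  (≥ 512×512) would benefit from batching pixels by neighbor count.
* Calibration assumes the database and the new sample share intensity
  calibration; the batch-effect knob exists to explore violations, but
  no correction is implemented.
* ENVI support covers the package's own band-sequential float32
  dialect, not vendor-specific extensions.
* The CLI's cohort convention (last sorted sample is the "new" one) is
  a convenience for synthetic runs; library users pass explicit
  sample lists.
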