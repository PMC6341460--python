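# Methods

`lungseg` segments hyperdense tumors in 2-D grayscale lung-CT slices by
clustering pixel intensities, with particle-swarm optimizers searching
the space of cluster-center vectors. This note records the models, the
parameter choices, the numerical conventions, and what the synthetic
phantoms do and do not demonstrate.

## Pipeline model

A slice passes through four stages, in order:

1. **Noise removal.** Median, adaptive median, or average filtering.
2. **Contrast enhancement.** Global histogram equalization or CLAHE.
3. **Intensity clustering** into k groups by one of five segmenters:
   k-means, k-median, PSO, inertia-weighted PSO (IWPSO), or
   guaranteed-convergence PSO (GCPSO).
4. **Tumor extraction.** The cluster with the brightest center is
   binarized and cleaned of small islands.

All processing uses float intensities in [0, 1] (inputs are min-max
normalized on load; DICOM rescale slope/intercept is applied first, and
this affine map does not change the normalized image). Coordinates are
0-based (row, col); every stage preserves the raster shape. Constant
input images are accepted with a warning (mapped to all zeros) rather
than rejected, so batch runs survive degenerate slices.

## Filters

Windowed filters use edge replication at the borders, so windows are
always full-sized; zero padding would darken the image rim, which on CT
is exactly where the chest wall sits. The plain median filter defaults
to a 3x3 window. The adaptive median filter is the classical two-stage
scheme: stage A grows the window (3 → smax, default 7) while the window
median is itself an extreme of the window — the signature of an impulse-
dominated neighborhood — and stage B passes the center pixel through
unchanged unless it is an extreme of the final window, in which case the
window median replaces it. The pass-through branch is what preserves
edges and fine structure exactly; on a constant image with up to ~10%
salt-and-pepper corruption, interior pixels are restored exactly.

Histogram equalization maps each intensity to its cumulative histogram
mass over 256 bins; the mapping is monotone, so intensity rank order is
preserved. CLAHE tiles the image (default 8x8), clips each tile
histogram at a fraction of the tile's pixel count (default 0.01),
redistributes the excess, and bilinearly interpolates the per-tile
mappings. The pipeline enhancement default is CLAHE; global
equalization is available. With a single tile and clip 1.0, CLAHE
reduces to global equalization up to quantization.

## Clustering

Pixels are clustered on intensity alone (1-D). k-means minimizes the
within-cluster sum of squares J(v) = Σ_i (x_i − v_{c(i)})² by Lloyd
iteration; k-median recomputes centers as member medians and reports the
sum of absolute deviations. Conventions shared by both:

* initialization: seeded D²-weighted sampling of k distinct intensities
  (first pick by pixel mass, later picks by mass × squared distance to
  the nearest chosen center). Plain uniform sampling of distinct values
  was measured to miss the exhaustive 2-partition optimum on a fraction
  of a percent of few-valued instances even with 10 restarts; the
  D²-weighted variant did not miss in 300 trials.
* 10 restarts by default, lowest objective kept; tol 1e-6 on the
  maximum center shift; max_iter 300.
* assignment ties break to the lowest center index; empty clusters are
  repaired by moving the center to the pixel farthest from its assigned
  center; final centers are sorted ascending and labels renumbered, so
  cluster identities are canonical across runs.
* k defaults to 3: air background, lung parenchyma, dense tissue/tumor.

## Swarm optimizers

Each particle encodes k center intensities in [0, 1]. Fitness is the
cluster-validity ratio

    f(v) = Σ_i  intercluster_i / intracluster ,

with intercluster_i the mean distance from center i to the other
centers, and intracluster the **global** mean absolute deviation of all
pixels from their assigned center (empty clusters contribute 0; the
denominator is floored at 1e-9). The global denominator is a deliberate
design choice: a per-cluster denominator vanishes whenever two centers
straddle a point-mass intensity spike — and clipped, CLAHE-enhanced CT
intensities have exact spikes at 0 and 1 — so maximizing the per-cluster
form degenerates into splitting spikes rather than separating tissue
modes. With the global form the fitness optimum sits at tight,
well-separated centers, though the center of a very small extreme
cluster is pushed slightly beyond its class mean (the intercluster gain
outweighs the tiny intracluster cost); recovery is therefore judged on
the induced segmentation, not raw center proximity.

For speed, fitness is evaluated on the image's 256-bin intensity
histogram (counts as weights), which for a 1-D feature equals per-pixel
evaluation up to the bin width; `exact_fitness=True` switches to
per-pixel evaluation, and both routes agree on phantom centers to
within 0.02.

Velocity updates per iteration, with fresh r1, r2 ~ U(0,1) per particle
and dimension:

* **PSO**: v ← v + c1 r1 (pbest − x) + c2 r2 (gbest − x); the previous
  velocity enters unweighted.
* **IWPSO**: v ← w·v + (same attraction terms); w = 0.7 in constant
  mode, or redrawn once per iteration as 0.5 + U(0,1)/2 in random mode
  (shared by all particles).
* **GCPSO**: all particles update as IWPSO except the current gbest
  holder, which is repositioned to gbest + w·v + ρ·(1 − 2r) — a random
  probe of the ρ-ball around gbest. ρ starts at the bounds width,
  doubles after more than sc = 15 consecutive strict gbest improvements,
  and contracts by 0.5 after more than fc = 5 consecutive failures
  (both factors configurable). An iteration with equal-or-worse gbest
  counts as a failure, preventing ρ inflation on plateaus. The probe
  guarantees the best particle keeps searching instead of stalling at
  gbest with zero velocity — the premature-convergence failure mode of
  plain PSO.

Defaults: 30 particles, 100 iterations, c1 = c2 = 2.0, velocity clamp
v_max = 0.2 (one fifth of the intensity range), positions clipped to
[0, 1], optional stagnation stop after 25 iterations without gbest
improvement. Velocities are clamped to ±v_max for all particles except
the gbest holder's repositioning step, whose implied velocity must be
left unclamped for the probe to land where the rule says (with ρ → 0 and
zero velocity it lands exactly on gbest). pbest updates on strict
improvement only; gbest is the best pbest; both traces are monotone by
construction. All randomness flows from one seeded generator, so a run
is bit-reproducible given its seed.

## Tumor extraction

The cluster with the highest center is taken as tumor (tumors are
hyperdense on CT), connected components smaller than min_area = 30 px
are removed (8-connectivity), and optionally only the largest component
is kept. The rule, threshold and connectivity are configurable; an
index-selected cluster is available for non-default protocols. Raising
min_area never adds foreground pixels.

## Quality metrics

Filter quality compares the noisy image I0 to the filtered If:
SSI = (σ_f/μ_f)·(μ_0/σ_0), the ratio of coefficients of variation
(1 for the identity filter, < 1 means speckle suppression, 0 for total
smoothing); SMPI = (1 + |μ_0 − μ_f|/μ_0)·(σ_f/σ_0), which penalizes
mean shift and is strictly increasing in it at fixed variances. These
are the standard literature definitions of the two indices.

Segmentation quality counts pixelwise TP/TN/FP/FN against a reference
mask and reports TPR, TNR, FPR = 100 − TNR and FNR = 100 − TPR as
percentages (printed to 4 decimals in CSV reports). Accuracy is the
balanced mean (TPR + TNR)/2 — which reconstructs tabulated accuracies
exactly from their rate columns — and raw pixel accuracy
100·(TP + TN)/total is emitted alongside, since the two differ whenever
the tumor occupies a small fraction of the slice. Rates whose
denominator class is absent from the reference are NaN, never silently
zero.

## Synthetic phantoms

A phantom is a piecewise-constant slice: background 0.05, one or two
elliptical lung fields at 0.35, and a tumor disc at 0.85 inside a lung —
three separable intensity modes sized (128x128 default) so the full
pipeline runs in well under a second. Speckle is multiplicative
Gaussian, clip(img·(1 + η), 0, 1) with η ~ N(0, var), the standard
emulation of speckle; the default study condition uses var = 0.05.
Impulse corruption flips an exact count (fraction × pixels, sampled
without replacement) of pixels to 0 or 1 with equal probability, chosen
exact for test determinism.

What the phantoms do not emulate: anatomical texture, Hounsfield
calibration, partial-volume edges, vessels and airways inside the lung
fields, and CT reconstruction artifacts. Passing the phantom suite
demonstrates algorithmic correctness (exact filter behavior, monotone
optimizer bookkeeping, correct metric arithmetic, recovery of separable
intensity classes under noise) — it does not certify clinical accuracy
on real scans, where lung-field restriction and vessel suppression
would matter.

## Problem sizes and verification

The shipped checks use 128x128 phantoms (the package's standard phantom
size), 200 9x9 images for filter-oracle equivalence, 10-instance batches
for clustering optimality, and 10 seeded phantoms for the end-to-end
recovery study; at these sizes the whole suite runs in seconds. The
end-to-end study (adaptive median → CLAHE → GCPSO k=3 →
brightest-cluster extraction, speckle var 0.05) reaches balanced
accuracy ≥ 90 on 10/10 seeds (minimum 92.5, mean ≈ 93.3).

## Known limitations

* Intensity-only features: structures isointense with the tumor
  (contrast-filled vessels, bone windows) would join its cluster;
  there is no spatial regularization beyond component-size filtering.
* The validity fitness biases extreme-cluster centers outward, as
  described above; decision boundaries, not centers, are the reliable
  output.
* Plain PSO can converge prematurely on multimodal fitness landscapes;
  that is the documented motivation for GCPSO, and occasional inferior
  PSO/IWPSO solutions on phantoms are expected behavior, not defects.
* 2-D single-slice processing only; no DICOM series or 3-D volumes.
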