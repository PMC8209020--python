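# Methods

This note documents the models, algorithms and free parameters behind
`fibrometry`, the reasoning behind the design choices that were genuinely
open, and what the synthetic validation does and does not demonstrate.

## Image-analysis chain

### Polarity and normalization

All neighborhood operators assume a *bright* signal. DAB-type chromogens
stain dark on a bright background, so `normalize_and_orient` is the single
place polarity is resolved: intensities are scaled to [0, 1] (8-bit by 255,
16-bit by 65535) and the image is inverted when the stain is dark. In
`auto` mode a dark stain is recognised by a bright majority background
(median > 0.5); this heuristic fails only when stained structures cover
most of the field, in which case the polarity can be forced explicitly. The
operation is idempotent and records the original polarity.

### Illumination flattening

Shading (vignetting, uneven illumination) and diffuse background staining
are removed in one step: a grayscale morphological opening with a disk of
radius `background_scale_px` (default 50 px) erases all structures narrower
than the disk — in particular every fiber — and returns a background
estimate, which is subtracted; the median background level is added back so
the image stays on its original intensity scale and a flat input maps to a
flat output. The opening of a smooth surface is piecewise-flat and the
decomposed disk introduces faceting, so the estimate is smoothed with a
Gaussian at a quarter of the scale. `background_scale_px` must stay well
above the fiber width (≥ 5×, warned otherwise) or the "background" starts
absorbing the fibers themselves.

### Top-hat enhancement

The white top-hat (image minus its opening) with a disk structuring element
of radius `tophat_radius_px` (default 12 px, about twice the expected fiber
width) preserves bright structures narrower than roughly twice the element
radius and suppresses everything wider, including any residual smooth
background. It is pointwise ≤ the input by construction. Border handling
for all neighborhood operators is reflect padding, which avoids border-row
artifacts in the area-fraction estimates.

### Adaptive local-mean threshold

A pixel is foreground iff

    I(x) > mean_{15x15}(I)(x) + offset,

with the local mean computed by a box filter with reflect padding, strict
inequality (ties to background, which makes the constant image
unambiguous), and a fixed window of 15 px. The rule adapts to residual
background variation and is exactly invariant to adding a constant to the
whole image; raising the offset can only shrink the mask.

The **offset constant** is the single biggest free parameter of the whole
chain. Default 0.05 on the [0, 1] scale, calibrated once on the synthetic
presets (noise s.d. 0.05 of dynamic range): small enough to keep the fiber
flanks, large enough that isolated salt noise stays in components far below
the minimum object size. It is logged in every output via the
configuration hash.

### Artifact removal

The original workflow this package systematises relied on interactive
editing to remove non-nervous structures, which is irreproducible. The
deterministic replacement operates on 8-connected components of the raw
mask:

* components smaller than `min_object_px` (default 50 px) are dropped
  (noise specks);
* components with isoperimetric circularity 4πA/P² above
  `circularity_cutoff` (default 0.6) are dropped — compact blobs (cell
  bodies, vessels, adipocytes) score near 1, filaments near 0;
* pixels under an optional user-supplied exclusion mask are dropped first,
  preserving the option of expert input.

`remove_artifacts` never adds foreground pixels. A separate step,
`fill_small_holes` (default cap 40 px), closes enclosed background regions
smaller than a genuine inter-fiber mesh: noise pinholes inside fibers
would otherwise each survive topology-preserving thinning as a spurious
skeleton loop and inflate both length and junction counts. Genuine mesh
openings at realistic fiber spacings are hundreds of px and stay open.

### Skeletonization and branching points

Thinning uses the Zhang–Suen two-subiteration algorithm (scikit-image
implementation): deterministic, 8-connected, preserving the number of
foreground components. Two cleanups follow:

* **staircase removal** — on ragged masks Zhang–Suen occasionally leaves
  2×2 pixel blocks; deletable (simple, non-endpoint) pixels of such blocks
  are removed in raster order, preserving connectivity;
* **spur pruning** (`skeleton_prune_px`, default 5 px) — terminal branches
  of at most that length that end in a junction are boundary-roughness
  artifacts, one per bump, and are deleted together with the junction
  pixel when its remaining neighbors stay connected without it. Open tips
  of genuine fibers are never touched, so a simple path is never
  shortened.

A skeleton pixel is a junction pixel iff it has ≥ 3 skeleton neighbors in
its 8-neighborhood. Junction pixels are first merged by 8-adjacency into
pixel clusters (one representative each: the pixel nearest the cluster
centroid, ties broken lexicographically). Because a single anatomical
bifurcation in a ragged mask often thins into two or three junction pixels
a few pixels apart, the pipeline additionally fuses branching points closer
than `bp_merge_radius_px` (default 5 px ≈ one fiber width); junctions
closer than a fiber width are not anatomically distinguishable anyway.

### The four parameters

For an image of `n_px` pixels at `p` µm/px with foreground count `n_fg`,
skeleton `S` and `B` branching points:

* positive area fraction = 100 · n_fg / n_px (%);
* branching-point density = B / image area (/mm²);
* total length = Σ over unique adjacent skeleton-pixel pairs of
  1 (orthogonal) or √2 (diagonal), times p (reported in mm). This
  estimator is exact on axis-aligned and 45° lines and overestimates
  intermediate orientations by at most ~8 %; a raw pixel-count × p
  alternative is available behind `length_estimator="pixel-count"` for
  sensitivity analysis;
* mean thickness = foreground area (µm²) / total length (µm), so
  thickness × length ≡ area holds identically. A zero-length skeleton
  leaves the thickness *undefined* (NaN, flagged), never zero, and such
  values are excluded from group statistics with a logged count.

All outputs are in physical units (%, /mm², mm, µm); pixel counts never
leak into reports. Coordinates, where reported, are (row, col), 0-based,
origin top-left.

## Statistics

Groups are summarised as mean ± SEM (sample s.d. with n−1 denominator over
√n). The two-sample test statistic is

    t = (mean_a − mean_b) / sqrt(sem_a² + sem_b²),

two-tailed. The Student variant uses pooled df = n_a + n_b − 2 (identical
to the classical pooled test whenever group sizes are equal, and exact for
the summary-statistics mode the published group tables require); the Welch
variant uses the Welch–Satterthwaite df. Raw-value and summary-statistics
modes agree to numerical precision. "Student's t test, two-tailed, pooled"
was chosen as the default because it is the conservative standard when the
test variant is not otherwise specified; both variants are exposed. Zero
pooled variance is handled by convention: p = 1 for equal means, p = 0
(with a warning) otherwise.

The marker ratio divides a dense stain's mean positive area by a sparse
stain's (e.g. a pan-Schwann-cell stain over a sympathetic-fiber stain) and
propagates first-order error
√((sem_a/mean_b)² + (mean_a·sem_b/mean_b²)²).

The statistics module operates on whatever per-unit table it is given
(image, sample or animal) and records n explicitly; choosing the unit of
replication is the caller's responsibility. No multiple-testing correction
is applied (four parameters per comparison); a note is logged if more
comparisons are run.

## Synthetic micrograph generator

### Geometry

Fibers are piecewise-linear random walks: step 4 µm, heading increment
~N(0, `curvature_sd`) per step (default 0.15 rad, giving gently tortuous,
"rhomboid-mesh" fibers), length `fiber_length_um` × U(1±`length_jitter`)
(default 150 µm ± 30 %), truncated at the field border. Each drawn
micrometre of centerline spawns a child branch with probability
`branch_prob`; children attach at a uniformly random point of the current
step, take off at 0.7–1.5 rad to the parent (steep take-off prevents
children from retracing their parents, which would create large correlated
overlap), inherit 0.9× the parent width, and may branch again down to depth
2. Per-fiber widths jitter by `width_jitter` (relative s.d., default 0.15)
around `fiber_width_um`.

Placement uses *relative* coordinates (fractions of the field), so the same
seed at a finer pixel size reproduces the same physical geometry: halving
µm/px leaves ground-truth length and width unchanged and multiplies pixel
counts by ≈4.

### Hitting a target area fraction

When `target_area_fraction_pct` is set, fibers are added until the drawn
stroke area reaches the Boolean-model budget −A·ln(1−p), which yields
coverage p under independent random overlap; the final fiber is truncated
mid-walk, so granularity is one step. Because branches overlap their
parents slightly, the realized coverage is re-measured on the rendered
canvas and the budget extended by the measured deficit (up to 8 rounds, on
one deterministic random stream). Realized coverage lands within a few
percent of the target — comfortably inside the documented ±20 % contract.

### Rendering and ground truth

The noiseless geometry is rasterized at 4× supersampling as round-capped
strokes; the supersampled canvas provides the foreground area (analytic
area of overlapping strokes being intractable, supersampling bounds the
error well below test tolerances) and, block-averaged, an anti-aliased
coverage map. The image is

    background 0.8 × shading × (1 − contrast × coverage) [+ blobs] + noise,

with a smooth multiplicative second-order polynomial shading surface of
relative amplitude `shading_amplitude`, `n_blob_artifacts` dark disks of
5–12 µm radius emulating non-nervous structures, and additive Gaussian
noise (`noise_sd`, fraction of dynamic range). Ground truth is computed
before shading and noise.

Ground truth records, per image: centerline polylines; total drawn length;
area-weighted mean width; rendered foreground area and fraction; the
attachment count `n_branch_points` (one per drawn child); and two derived
junction quantities. In a 2-D projection a crossing of two unrelated
fibers is geometrically indistinguishable from a bifurcation, so the
quantity a perfect junction detector can recover is *attachments +
crossings*, not attachments alone. `n_junctions` therefore adds all
pairwise centerline intersections (excluding a child's intersections with
its own parent near the attachment point, which are the attachment itself),
with intersection points of the same fiber pair closer than the combined
stroke half-widths counted once, mirroring how junctions fuse in the
rendered union. Recovery is evaluated against `n_junctions`.

This crossing model treats fiber pairs independently and is accurate while
junction fusion *across* pairs is rare. The preset branch rates are chosen
inside that validity domain (see below); at substantially higher fiber or
branch densities, local tangles fuse junctions from many pairs and the
model overcounts what any detector could see.

### Presets

Two presets emulate the two fascia regimes: `tlf` (dense aponeurotic
regime: target 9.0 % positive area, 5.8 µm primary fibers, branch rate
0.012/µm) and `gluteal` (sparse epimysial regime: 2.8 %, 4.9 µm,
0.015/µm). Realized area fractions match the targets; realized
area-weighted widths are ~10 % below the primary width because branches
taper. Realized junction densities are ≈ 280 /mm² and ≈ 67 /mm² — the
correct ordering and separation between the regimes, deliberately below the
reported tissue values (≈ 500 and 140 /mm²): pushing branch rates high
enough to match them absolutely drives the networks into crossing-tangle
territory where per-pair junction ground truth is no longer well defined
(and where a fifth of the stroke area is self-overlap). The validation
regime trades absolute branching density for exactness of the reference.

The default pixel size for presets is **1.0 µm/px**. The threshold window
is pinned at 15 px, so the adaptive rule only sees fibers as "local"
structures if they are a few pixels wide; at 1.0 µm/px the 4.9–5.8 µm
fibers span 5–6 px, comfortably inside the window. (At a typical
high-magnification camera resolution of ~0.25 µm/px the same fibers would
span > 20 px, wider than the window, and local-mean thresholding would
hollow out fiber interiors — whatever resolution the original images had,
the printed window size only makes sense with fibers a few pixels wide.)
No scale-dependent conclusion rests on this choice; the resampling test
pins scale invariance of the ground truth, and the morphometry is
calibration-equivariant.

### What the synthetic data does not emulate

Real DAB histology has colored (RGB) stain mixtures, focus gradients,
section-thickness variation, fiber bundles with internal texture,
out-of-plane fibers, and artifact shapes far richer than disks. Passing
the synthetic recovery suite demonstrates that the *measurement chain* is
correct and unbiased within stated tolerances on images with the right
first-order statistics (coverage, width, contrast, noise, shading,
blob clutter); it does not certify segmentation accuracy on real tissue,
where the threshold offset and artifact filters would need calibration
against expert annotation.

## Evaluation conventions and sizes

* Recovery is scored as the cohort-mean relative error per preset (20
  images per preset, 512×512 px at 1 µm/px, noise 0.05, shading 0.2):
  individual images carry irreducible detector-level scatter (a handful of
  junctions either way on a sparse network is tens of percent), while the
  cohort mean exposes bias. Branch-point recovery is scored on networks
  with ≥ 10 true branch points.
* The null (type-I) simulation uses 100 replicate cohorts of 6 + 6 images
  at 256×256 px, both groups drawn from the dense preset, t-tests on
  ground-truth area fraction; the acceptance band for the rejection rate
  at α = 0.05 is [0, 0.12].
* The oracle-equivalence check compares junction counting and
  adjacency-weighted length against O(n²) brute-force enumeration on 10⁵
  random 8×8 masks with ≤ 12 foreground pixels.

## Known limitations

* The length estimator's ≤ 8 % orientation bias is inherited by the
  thickness (area/length) estimate; both are systematic and
  direction-stable, so group *comparisons* are unaffected.
* Junction counts on noisy images carry a residual +5–15 % excess from
  noise-induced bridges between nearby fibers; spur pruning and junction
  merging remove most but not all of it.
* Blob artifacts that touch a fiber survive the circularity filter (they
  merge into an elongated component) and bias area and junction counts
  slightly upward; the exclusion-mask mechanism exists precisely for such
  cases on real data.
* The thinning-based skeleton retreats from clipped fiber ends at the
  image border by about half a fiber width, a ~1 % length deficit at the
  preset field sizes.
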