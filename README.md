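# fibrometry

Quantification of immunostained nerve-fiber networks in 2-D micrographs:
reproducible segmentation, skeleton-based morphometry, and two-group
statistics, validated against a seeded synthetic-micrograph generator with
exact ground truth.

## The problem

Peripheral nerve fibers in stained tissue sections (for example
DAB/S100-stained deep fascia, where Schwann cells mark the nerve network)
appear as dark, branching filaments a few micrometres thick on a bright,
unevenly illuminated background. Comparing innervation between tissues
requires turning such images into numbers. `fibrometry` computes the four
standard morphometric parameters of a stained fiber network:

| parameter | definition | units |
|---|---|---|
| positive area fraction | foreground pixels / total pixels × 100 | % |
| branching-point density | skeleton junctions / image area | /mm² |
| total network length | Σ over adjacent skeleton-pixel pairs of 1 (orthogonal) or √2 (diagonal) pixel spacings | mm |
| mean fiber thickness | foreground area / network length | µm |

and compares them between groups as mean ± SEM with two-tailed two-sample
*t* tests (Student pooled by default, Welch available), either from
per-image values or directly from printed summary statistics. A marker
ratio (for instance the ratio of a pan-nerve stain's area fraction to a
sympathetic-fiber stain's) is also provided with first-order error
propagation.

## The pipeline

Each image passes through a fixed chain:

1. **normalize & orient** — intensities to [0, 1]; dark-signal (DAB-like)
   images are inverted so the stain is bright internally;
2. **flatten illumination** — a grayscale opening at a scale much larger
   than a fiber estimates the smooth background (vignetting, gradients),
   which is subtracted;
3. **top-hat enhancement** — white top-hat with a disk element: keeps
   structures narrower than ~2× the element radius, drives the background
   toward zero;
4. **adaptive local-mean threshold** — a pixel is nerve iff its intensity
   exceeds the mean of its 15 × 15 px neighborhood by more than a fixed
   offset constant;
5. **artifact removal** — deterministic stand-in for manual editing:
   minimum object size, a circularity cutoff that drops compact blobs
   (non-nervous structures) while keeping filaments, an optional
   user-drawn exclusion mask, and filling of pinhole noise;
6. **skeletonization** — Zhang–Suen thinning to a unit-width, 8-connected,
   topology-preserving centerline, with short-spur pruning;
7. **branching points** — skeleton pixels with ≥ 3 skeleton neighbors,
   merged into one point per junction cluster;
8. **summary & statistics** — the four parameters per image, then group
   means ± SEM and *t* tests.

Identical inputs, configuration and seeds give byte-identical outputs, and
every result table embeds the configuration hash.

## Synthetic validation data

The package ships a first-class generator of synthetic stained-fascia
micrographs (`fibrometry.synthetic`): branching random-walk fibers with
controlled width, curvature and branch rate, rendered dark-on-bright at 4×
supersampling, with multiplicative shading, blob artifacts and sensor
noise. Every image comes with exact ground truth (centerlines, length,
width, branch/junction counts, rendered area), so segmentation and
morphometry can be scored quantitatively. Two presets emulate a densely
innervated aponeurotic-fascia regime (~9 % stained area) and a sparse
epimysial regime (~2.8 %).

## Worked example

```python
import fibrometry as fm

spec = fm.preset_spec("tlf", seed=1)          # dense preset, ~9% coverage
image, truth = fm.generate_network(spec)      # 512x512 px at 1 um/px
summary = fm.process_image(image, fm.PipelineConfig())
print(f"positive area:     {summary.positive_area_pct:.2f} %")
print(f"branching points:  {summary.bp_density_per_mm2:.1f} /mm^2")
print(f"network length:    {summary.total_length_mm:.3f} mm")
print(f"mean thickness:    {summary.mean_thickness_um:.2f} um")
```

prints

```
positive area:     8.70 %
branching points:  232.7 /mm^2
network length:    4.773 mm
mean thickness:    4.78 um
```

against ground truth 8.83 %, 4.867 mm and 5.17 µm for this seed — the
stained fraction, skeleton length and area/length thickness recovered from
a noisy, shaded rendering within a few percent. Statistics work directly
from printed summaries too; comparing branching-point densities
500.9 ± 43.1 vs 140.3 ± 31.6 /mm² (n = 6 each):

```python
res = fm.ttest(fm.GroupStats(n=6, mean=500.9, sem=43.1),
               fm.GroupStats(n=6, mean=140.3, sem=31.6))
# t = 6.75, df = 10, p = 5.06e-05
```

## Command line

```sh
fibrometry simulate --out sim/ --seed 7 --n-per-group 10      # synthetic cohort + manifest
fibrometry analyze img1.tif img2.tif --group tlf --out results/
fibrometry compare --manifest sim/manifest.csv --out results/  # two-group report
```

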