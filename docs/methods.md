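# Methods

This note documents the models, conventions, and numerical choices behind
`dcquant`. It is the package's own account of what it computes and what its
synthetic benchmarks do and do not demonstrate.

## What the package measures

In *C. elegans* hermaphrodites the dosage compensation complex halves
transcription from both X chromosomes, compacts the X territory, and holds
it near the nuclear periphery. The package quantifies the three readouts
used to study this system, from image stacks and expression tables:

1. **Territory compaction** — the fraction `v` of the nuclear volume
   occupied by the chromosome territory, from 3D masks of a nuclear stain
   and a chromosome-paint/IF signal, counted in voxels.
2. **Radial position** — the three-zone assay: a mid-nucleus slice is
   partitioned into three concentric, equal-area elliptical zones and the
   fraction of the thresholded signal in each zone is reported
   (central, intermediate, peripheral).
3. **Stain enrichment** — the line-scan ratio `E` (peak / minimum intensity
   along a line through the nucleus crossing the enriched region) and the
   normalized intensity `I` (mean nuclear intensity / mean background
   intensity).
4. **X derepression** — `d = median(log2FC of X-linked genes) −
   median(log2FC of autosomal genes)` between two conditions, with `2^d`
   its fold-change equivalent and a two-sided Wilcoxon rank-sum comparison
   of the two log2FC sets.
5. **Viability statistics** — dead/live contingency comparisons (Fisher's
   exact, chi-square), on/off-auxin survival ratios, and brood viabilities.

## Image pipeline conventions

Axis order is `(z, y, x)`, 0-based, with voxel spacing in µm
(default 0.2 × 0.1 × 0.1: 0.2 µm optical sections, 0.1 µm lateral pixels).
All geometry is computed in pixel units unless stated as µm.

**Rolling-ball background.** Per z-plane, the background surface is a
grayscale opening with a *paraboloid* structuring element whose curvature
`1/(2r)` matches a ball of radius `r` (default 50 px) at the apex — the
sliding-paraboloid variant of the classic rolling-ball filter. Quadratic
structuring functions separate exactly over axes, so the 2D opening is
computed as exact sequential 1D min-plus/max-plus passes (no shrinking, no
approximation); tests verify equality with a brute-force non-separable
opening. Output is clipped at zero. Background subtraction feeds
segmentation and the zone assay; `E` and `I` are computed on raw
intensities (`I` divides the background out by definition, and `E` is a
within-nucleus contrast).

**Segmentation.** Nucleus: global Otsu threshold on the stack histogram,
largest 26-connected component, per-plane hole filling — the automated
stand-in for a hand-drawn 3D mask, justified because dissected-nucleus
fields contain one nucleus by construction. Signal: Otsu restricted to
nuclear voxels, intersected with the nucleus mask (extranuclear staining
never enters any quantification); no largest-component filter, since
territories may fragment. A signal channel flat at zero inside the nucleus
yields an empty mask (flagged, not an error); flat at a positive level, the
whole nucleus. The threshold method is a config option.

**Volume fraction** counts voxels, not µm³; anisotropy scales numerator and
denominator identically, so `v` is spacing-independent.

**Mid-slice choice.** Among the middle third of nucleus-containing planes,
the plane maximizing the normalized intensity variance (variance/mean) of
the signal within the nucleus is selected; ties resolve to the lowest z.
The variance/mean form peaks where the territory cross-section is largest
relative to the nuclear slice, which for ellipsoidal geometry is the
territory's central plane.

**Ellipse fit and QC.** The slice ellipse comes from second-order central
moments (covariance eigenvalues `a²/4`, `b²/4` for a filled ellipse, with a
+1/12 per-axis term for the within-pixel density), rescaled so the ellipse
area equals the mask pixel count. Nuclei are gated on the Jaccard overlap
between mask and fitted ellipse (default ≥ 0.90), a tunable, automated
proxy for "smooth, elliptical" inclusion criteria; failing nuclei keep
their volumetric and intensity metrics but report no zone fractions.

**Zones.** The outer boundary is the fitted ellipse (pixel-center
membership). The two inner boundaries are concentric, co-oriented ellipses
placed at the exact tertiles of the normalized elliptical radius over the
outer-ellipse pixels, so the three pixel counts agree to within one pixel.
For large nuclei the tertile boundaries coincide with the analytic
`√(1/3)`, `√(2/3)` semi-axis scalings; pure pixel-center rasterization of
those analytic boundaries was rejected because lattice count fluctuations
reach 4% for ~20 px semi-axes, violating the equal-area contract the assay
rests on. Zone fractions are thresholded pixel counts by default (the
ROI-overlap convention); an intensity-weighted variant is available via the
`intensities` argument / config flag.

**Line scan.** The line joins the nucleus centroid to the
intensity-weighted centroid of the signal mask, extended both ways to the
nucleus boundary; when no signal is present or the centroids coincide, the
nucleus major axis is used — a deterministic stand-in for an arbitrarily
drawn line, keeping results reproducible. Samples are taken at unit-pixel
steps with bilinear interpolation restricted to nucleus pixels (weights
renormalized): endpoints sit on the boundary without mixing extranuclear
background into boundary samples. `E` applies a window-3 moving average
before the peak/minimum (default on) and floors the minimum at 1e-6 × the
profile maximum. The default background region for `I` is every voxel
outside the nucleus dilated by 3 voxels — a declared convention replacing a
hand-picked background box.

## Synthetic microscopy

The generator emulates a dissected intestinal nucleus (intestinal cells are
32-ploid; the default ellipsoid has semi-axes 2.4 × 5.0 × 4.5 µm on a
32 × 128 × 128 grid, ≥10⁵ nuclear voxels). All geometry is computed in µm
and voxelized by center-point test. The territory is the `f_true`-quantile
sublevel set, over nuclear voxels, of the distance in nucleus-normalized
coordinates from a centre offset along a seeded random mid-plane direction
by `r_true` of the maximal offset `1 − f_true^(1/3)` — an ellipsoidal blob
similar to the nucleus that is a subset of it by construction, touches the
boundary at `r_true = 1`, and realizes `f_true` to within one voxel. An
irregular mode divides the distance field by a smoothed noise field to
perturb the blob boundary. Signal intensities: `nuclear_base` (100) inside
the nucleus, `k_true × nuclear_base` in the territory,
`background_level` (10) outside, an optional linear gradient, and
Poisson–Gaussian camera noise: shot noise at `photons_per_unit`
(default 4 photons per intensity count, a realistic CCD conversion gain)
plus Gaussian read noise of sd `noise_scale` (default 2 counts). The
defaults keep the nuclear baseline above ~400 photons, where a peak/min
statistic such as `E` retains small extreme-value bias; noise-free stacks
(`noise_scale = 0`) are bit-exact renderings. Presets `wt-like`
(`f = 0.125`) and `decondensed-like` (`f = 0.20`) bracket compact and
decondensed territories; they are conveniences, not claims.

What the generator does **not** emulate: optics (PSF, photobleaching),
chromatin texture, multi-nucleus fields, germline nuclei, or irregular
nuclear outlines (except the opt-in irregular territory). Passing recovery
tests therefore demonstrates correctness of the measurement chain on known
geometry, not robustness to real-micrograph artifacts.

## Synthetic expression and viability

Counts follow a two-condition negative binomial design: per-gene baseline
means drawn once from a log-normal (median ≈ 150, log-sd 1), dispersion
α = 0.05 (`var = µ + αµ²`), three replicates per condition, ~20,000 genes
with 2,800 on X (≈14%), and per-sample library factors log-uniform in
[0.7, 1.4] — enough to exercise normalization without dominating it. The
treatment condition multiplies X-linked means by `2^d_true`. The internal
estimator (median-of-ratios size factors, pseudocount-1 log2 ratio of
normalized group means) exists to close the loop on synthetic counts; real
data enter as externally produced log2FC tables, keeping the statistic
decoupled from any differential-expression tool. Medians use the even-n
mean-of-central-pair convention. The Wilcoxon comparison uses mid-ranks for
ties, exact enumeration when the pooled size is ≤ 12 with no ties, and a
tie- and continuity-corrected normal approximation otherwise; the
approximation is within 0.02 of exact enumeration whenever both samples
have ≥ 5 observations (it is not engaged below that in routine use). A
minimum-mean expression filter is available but off by default: the
statistic is computed on all genes with finite log2FC.

Viability simulation is a two-stage binomial (embryonic death, then larval
death among hatchlings), one draw per genotype. Fisher's two-sided p uses
the point-probability rule (the convention of mainstream implementations);
chi-square is Pearson without continuity correction (Yates behind a flag);
replicate counts are summed before testing. Chromosome profiles drop genes
with `p ≥ 0.05` when p-values are present, then bin by start coordinate
(default 500 kb, presentational only) over WBcel235 chromosome lengths.

## Problem sizes and determinism

Recovery benchmarks use 10–20 nuclei or simulation seeds per condition,
100 seeds for null calibration, and full enumeration for the small-sample
oracles (all 2×2 tables with total ≤ 40; all no-tie rank splits with pooled
n ≤ 12) — sizes at which every check completes in minutes on one CPU while
keeping Monte-Carlo error well inside the asserted tolerances. All
generators and the pipeline are deterministic given (params, seed); the
acceptance script derives independent sub-seed streams from a single
`--seed` via `SeedSequence`.

## Known limitations

- Thresholding is global Otsu; dim or unevenly stained real nuclei may need
  a different method (the option exists, but only `otsu` and `mean` ship).
- The ellipticity gate is a Jaccard score against a moment-fitted ellipse;
  it does not detect smooth-but-lobed outlines at high overlap thresholds.
- The line-scan fallback (major axis) is deterministic where the original
  procedure drew an arbitrary line; distributions of `E` in unenriched
  nuclei therefore have zero placement variance.
- `segment_signal` assumes a bimodal in-nucleus histogram; weak enrichment
  (`k_true` close to 1) degrades the territory mask before it degrades `E`.
- The NB simulator draws genes independently; correlated programs
  (co-regulated operons, batch effects) are out of scope.
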