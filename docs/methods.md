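# Methods

## The quantification model

Single-molecule FISH and RNAscope probes tile each target transcript with
many fluorophores, so the total fluorescence bound to one transcript is
approximately fixed and the **integrated intensity** over a cell scales
linearly with its transcript count, even when individual diffraction-limited
spots are too crowded to resolve.  The pipeline therefore reports a
*relative* per-cell measure — the sum of noise-subtracted, nucleus-masked
pixel intensities — rather than an absolute spot count.  No calibration to
absolute molecule numbers is attempted, and no per-cell normalization to an
internal transcript-negative baseline is performed.

The workflow is a fixed seven-step sequence, deterministic given the two
input stacks and the configuration:

1. maximum-intensity projection (MIP) of the nuclear-stain z-stack;
2. binning of the MIP intensity range into `n_bins` (default 100)
   equal-width bins whose upper edges are the candidate thresholds;
3. nucleus mask: strictly above the central bin's threshold (for an even
   bin count, the range midpoint); its connected components are the cells;
4. background mask: among all below-threshold candidate masks, the one whose
   blobs have the smallest area-weighted mean solidity, refined by
   morphological opening (disk radius 5) with removal of blobs under 50 px²,
   erosion (disk radius 10), and infill of interior holes up to 1500 px²;
   its blobs anchor the grouping of cells into ommatidia;
5. per slice of the FISH stack: subtraction of the mean intensity sampled
   under the background mask (floored at zero), then multiplication by the
   nucleus mask;
6. optional 2-D Gaussian smoothing (sigma 0.8 px, reflective borders);
7. per-cell integrated intensity per slice, summarized per cell as
   mean ± sd over ALL slices, the CENTRAL80 slices (symmetric 10 % trim
   from each end, floor/ceil at the edges), or the MAX slice (the slice
   whose whole-frame processed total is largest; a per-cell-max variant is
   available behind `per_cell_max`).

Masking from the MIP — rather than per slice — is deliberate: one mask is
consistent across the whole stack, so per-slice segmentation jitter cannot
masquerade as axial expression structure.

### Numerical conventions

* Pixel coordinates are 0-based `(row, col)`, origin top-left.  Intensities
  are raw arbitrary units; integer inputs are promoted to float64 without
  rescaling.
* The nucleus mask uses strict `>`, background candidates strict `<`;
  pixels exactly at a threshold belong to neither mask.
* Solidity is blob area divided by the number of lattice points inside or on
  the convex hull of the blob's pixel centers (computed by a scanline over
  the hull of the component's boundary pixels).  This makes the solidity of
  any convex rasterized shape exactly 1 and keeps the quantity testable
  against an independent point-in-hull oracle to 1e-9.  Collinear blobs
  (lines, single pixels) are defined to have solidity 1.
* Connectivity defaults to 8-connected foreground; hole infill treats the
  complement as 4-connected (the proper dual), and holes are complement
  components not touching the image border.
* Weighted-solidity ties and plateau ties break toward the lower threshold.
* Negative values after noise subtraction are floored at zero.  This
  prevents negative "transcript" signal but biases a pure-noise cell's
  integral upward by about `area · sd / sqrt(2π)` per slice; the knockout
  analyses below account for that floor.
* Erosion during background-mask refinement can fragment ragged blobs, so
  blobs under the minimum surviving area are removed a second time after
  it, and anchors smaller than `anchor_min_area_fraction` (default 0.25) of
  the largest background blob are dropped before assignment — ommatidium
  cores are uniformly large, so sub-scale blobs are debris.

### Cell-to-ommatidium assignment

Distances from each background-blob centroid to every nucleus centroid are
sorted ascending.  The near/far split is the first local maximum of the
forward differences that dominates the typical spacing — it must exceed
`gap_factor` (default 3) times the median of the *other* differences, and
must be non-negligible relative to the distance scale (pure floating-point
fuzz between exactly equal distances is not a gap).  The leave-one-out
median makes a lone dominant gap (two nuclei at distances 1 and 50)
detectable, which a plain median would veto.  The near count is capped at 7
because the eighth photoreceptor nucleus does not appear in the imaging
planes this workflow targets.  A nucleus claimed by several anchors goes to
the nearest (ties to the earlier, row-major-ordered, letter label); nuclei
claimed by nobody are reported and excluded.  Cells are numbered 1..k
counter-clockwise (`atan2(-(row-row₀), col-col₀)`), starting from the
smallest non-negative angle from image east; only the CCW order, not the
start, is meaningful.

### The conventional spot-counting baseline

The baseline filters each slice with a negated, zero-sum 8×8
Laplacian-of-Gaussian kernel (sigma 0.8 px, symmetric-reflection borders),
counts connected components above each of 100 thresholds spanning
`(0, max]`, and selects the reference intensity at the minimum
|forward difference| of the count curve — the flattest point of the
non-zero plateau.  When driven by `run_spotcount`, the selected position
must additionally sit inside a run of at least `plateau_min_run` (default
20) consecutive equal counts.  The rationale is an order-statistics one: on
pure noise the count curve's equal-count runs come from gaps between the
top order statistics of the filtered noise, whose Gumbel spacing gives runs
of roughly 5 bins, while a true spot plateau spans most of the threshold
range (~80 bins at the default SNR).  Requiring 20 % of the range therefore
rejects noise-only slices (reported as 0 spots with a warning) without
touching genuine plateaus.  Direct calls to `select_plateau_threshold`
default to `min_run=1`, the plain argmin contract.

The baseline exists as a foil: it is accurate on sparse, high-SNR spots and
fragile on crowded or noisy data, which motivates the integrated-intensity
route (which omits Laplacian filtering entirely).

## The synthetic specimen generator

The generator emulates the whole-mount compound-eye retina preparations the
workflow was designed for.  Defaults (one choice, used everywhere):

| parameter | default | meaning |
|---|---|---|
| frame, slices | 512×512 px, 10 | acquisition geometry |
| ommatidia | 9 on a 3×3 grid, spacing 120 px (jitter sd 2) | cluster field |
| nuclei | 7 per cluster on a ring of radius 40 px (radial jitter sd 1.5, angular sd 3°), radius 10 px | photoreceptor nuclei |
| nuclear channel | field 60, nuclei 200, dark cluster core 0, edge blur sigma 1.5, noise sd 0.3 | high-SNR DAPI-like scene |
| FISH channel | background mean 8, sd 1.5, sd growth 3 %/slice | probe channel noise with depth-dependent SNR decay |
| spots | amplitude 400, PSF sigma 1.2 px, 20 per expressing cell | bright RNAscope-like transcripts |
| expression pattern | 6 of 7 ring cells express; the 7th never does | transcript-negative cell per cluster |

Spots are placed uniformly inside their parent nucleus disc on a uniformly
chosen slice, so per-cell ground truth is unambiguous; noise is Gaussian
floored at zero (a Poisson option exists).  The dark cluster core stops at
ring radius + 1.5 nucleus radii so neighboring cores stay separated by a
bright inter-ommatidial lane; the bright lane is what lets the refined
background mask individuate one anchor per ommatidium.  The spot amplitude
is bright relative to background noise (peak SNR ≈ 270) — the regime of
branched-amplification chemistry — chosen so that the transcript-free
residual left by the noise-subtraction floor stays a few percent of the
wild-type signal, as in the original validation specimens.

What the generator does **not** emulate: 3-D PSFs and optical sectioning
(spots live on a single slice), autofluorescent texture, chromatic offsets
between channels, segmentation-hostile nuclear shapes, or the mirror
symmetry of ommatidial chirality across the eye midline.  Passing the
synthetic validation therefore demonstrates the correctness and linearity
of the *algorithm*, not robustness to every real-microscopy artifact.

## Synthetic validation experiments

`ccrit.validation` re-creates the validation design with the planted spot
count standing in for the qRT-PCR reference:

* **Linearity** — expression levels {0, 0.25, 0.5, 0.7, 1.0} × 3 replicate
  specimens at default scale; mean cell intensity regressed on planted
  spots per cell.
* **Knockout null** — the level-0 specimens' mean intensity as a fraction
  of the level-1 mean, plus the fraction of their slices on which the
  baseline spot counter reports zero.
* **Genotype discrimination** — level 0.7 vs 1.0 under five independent
  seeds; the 0.7 specimen should score lower in every seed.
* **Assignment accuracy** — fraction of nuclei assigned to their
  generating ommatidium over ten seeds of the default layout.
* **Spot recovery** — exact recovery of 20 well-separated high-SNR planted
  spots per slice, two stacks of ten slices.

Problem sizes (15 + 10 + 10 full-scale specimens, plus two spot fields) keep
the whole battery at a few minutes on one core while still exercising every
stage at acquisition-scale geometry.  All randomness derives from one seed
via a splitting hash kept below 2³¹.

## Known limitations

* The weighted-solidity background selection can, on some noise
  realizations, prefer a threshold inside a flat noisy band, yielding a
  speckle-like mask; the refinement stages plus the anchor-size filter
  absorb this, but a pathological scene with many equally sized dark
  regions could still confuse anchor selection.
* `CENTRAL80` on stacks of fewer than two slices falls back to ALL with a
  warning; sample sd of a single value is reported as 0.
* The baseline spot counter has no spot-quality score; its plateau-width
  guard trades a small chance of rejecting a genuine but narrow plateau for
  robust zero reporting on empty specimens.
* Transcript-negative cells are located only by their (lack of) signal;
  identifying *which* numbered cell is the negative one is out of scope.
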