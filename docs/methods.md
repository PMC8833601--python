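# Methods

## The analysis model

The pipeline treats a slide as a planar point pattern of segmented cells,
each carrying a tissue category (tumor / liver parenchyma / peritumoral
stroma), a compartment (epithelial / stromal) and boolean marker states.
All geometry is computed in µm; areas are reported in mm².

**Interfaces are defined by cell populations, not drawn curves.** The
distance of a cell to "the interface" is the distance to the nearest cell
of the reference tissue set. This matches how cell-resolved data are
actually analyzed: no segmentation of a boundary polyline is required,
and the measure degrades gracefully with segmentation noise. The cost is
a small positive bias of order the cell spacing in the reference tissue
(see *Numerical behavior* below).

**Two reference schemes.** Measure A takes liver parenchyma as the
reference and analyzes stroma + tumor cells; Measure B takes liver +
stroma as the reference and analyzes tumor cells only. B's reference set
contains A's, so Measure-B distances are never larger for the same cell;
equality holds exactly when the nearest reference cell is hepatic. The
two schemes bracket the ambiguity of whether a fibrotic capsule belongs
to host or tumor.

**Zones, hulls, densities.** Distances are binned into half-open zones
[lo, hi) — by default 0–100, 100–200, 200–400, 400–600 µm; distances at
or beyond the last edge are outside the zoned band. Zone area is the
convex hull of *all* analysis-tissue cells in the zone (not only the
subset of interest), so within a zone every subset shares one
denominator; a per-subset hull is available behind the `hull_scope`
switch for sensitivity analysis. Hulls need ≥3 non-collinear points;
degenerate hulls yield NA density, and NA propagates to statistics as
pairwise-complete deletion. A zone with a defined hull but zero subset
cells has density 0, which is information, not missingness.

**Regions.** PERIPHERY is the interface band: liver cells within 100 µm
of the nearest non-liver cell, every peritumoral stroma cell (the whole
capsule), and tumor cells within 100 µm of the nearest non-tumor cell.
The "first row of tumor cells" is operationalized as that 100 µm tumor
fringe — literal cell rows are not well defined in point data. The
invasive margin (IM) is tumor tissue with Measure-B distance < 800 µm
not already peripheral; CENTRAL is the rest of the tumor. Precedence
PERIPHERY > IM > CENTRAL makes the three regions a partition of the
tumor-cell population.

**Composite metrics** are computed from counts pooled over a region
(one value per sample and region), not by averaging per-zone ratios:
CD8/(CD8+CD4) and CD8_epi/(CD8_epi+CD8_stromal). Both are scale-free and
in [0, 1]; a zero denominator gives NA.

## Statistics

*Mann–Whitney U* is computed from mid-ranks. For pooled samples of ≤ 12
tie-free observations the p-value is exact, by enumerating all
C(n1+n2, n1) rank assignments; otherwise a normal approximation with the
standard tie-correction in the variance and a 0.5 continuity correction
is used. *Wilcoxon signed-rank* uses Pratt's treatment of zero
differences — zeros are ranked along with everything else, then dropped
from the signed sums — with mid-ranks for tied magnitudes; exact
enumeration over 2^m sign patterns applies for ≤ 12 tie-free non-zero
differences. The normal-approximation variance Σr²/4 over non-zero ranks
absorbs both the zero- and tie-corrections. Two-sided alternatives are
the default. No multiple-testing adjustment is applied by default;
Benjamini–Hochberg is available on the batch interface. Ward clustering
is agglomerative minimum-variance linkage on Euclidean distances with
column-median imputation; it is provided as part of the statistical
toolkit but feeds no headline output.

A deliberate reading: "Mann–Whitney with Pratt correction for ties" is
not a standard procedure (Pratt's method concerns zeros in the paired
test). We implement the defensible pair — tie-corrected U test, Pratt
zeros in the signed-rank test — and record the choice in each result's
method string.

## The synthetic-slide generator

The generator exists to give the pipeline inputs with known ground
truth. A slide is a 1.86 × 1.39 mm rectangle (the acquisition-region
size of the imaging platform) stratified along x: a 400 µm liver band;
then, for dHGP, a 250 µm capsule of stroma cells, or, for ndHGP, a direct
interface with reactive-stroma patches covering 30% of the interface
length to a depth of 150 µm; tumor tissue fills the remainder. Cohorts
default to 13 dHGP + 9 ndHGP samples.

Cells are drawn from Poisson processes (inhomogeneous ones by thinning a
homogeneous proposal at the peak intensity). Lymphocyte classes are laid
down with intensity λ(d) = base + λ₀·e^(−d/τ), d the depth from the
liver interface, and carry exact marker patterns (e.g. the memory-CD4
class is CD4⁺CD45RO⁺ and nothing else), so analysis subsets are realized
by construction and expected zone densities have the closed form
base + λ₀τ(e^(−a/τ) − e^(−b/τ))/(b−a) over a band [a, b).

Choices that matter:

* **Structural floor.** Every band receives marker-negative cells at
  5000 cells/mm². This is within the realistic range of nuclear
  segmentations of solid tissue, and it doubles as the resolution of the
  cell-defined interface: the measured distance to the nearest reference
  cell exceeds the geometric depth by roughly half the reference-cell
  spacing plus a lateral term (≈ 4–9 µm at this floor). Cohort-level
  Monte-Carlo sweeps (type-I error, detection rates) use a reduced floor
  of 1200 cells/mm²: those checks concern test calibration and effect
  direction, which are insensitive to interface resolution, and the
  reduction keeps repeated-cohort sweeps to minutes.
* **Effect structure.** The "paper-like" scenario concentrates CD8 and
  CD20 in the outer capsule of dHGP slides (λ₀ = 700/400 per mm², τ =
  120/100 µm), enriches the CD4 family and CD45RO in ndHGP stroma and
  tumor (λ₀ up to 500/mm², τ = 200 µm), and sets the CD8 epithelial
  fraction to 0.45 (dHGP) vs 0.15 (ndHGP). The "null" scenario uses flat,
  group-identical intensities, so only geometry differs between groups
  and every group contrast has a true null distribution. Absolute levels
  are order-of-magnitude choices — the source data for this design exist
  only as figure-level summaries — so synthetic effect sizes are the
  generator's own, and detection-rate results quantify the pipeline, not
  the biology.
* **Between-sample variability.** Each sample draws a lognormal
  multiplier (σ = 0.4) per class intensity and a logit-normal jitter
  (σ = 0.3) on epithelial fractions. Without this, between-sample
  variance would be pure Poisson noise and group tests would be
  unrealistically powerful.
* **Geometry.** The interface is flat and axis-parallel. Real lesions
  are curved, but every downstream quantity is distance-based, and the
  flat geometry is what makes band integrals exact ground truth.

## Numerical behavior, tolerances, degenerate inputs

* Nearest-neighbor queries use a KD-tree; the contract (and the test) is
  exact equality with an all-pairs scan, not approximate search.
* Hull areas of N uniform points in a zone under-cover the zone by
  O(log N / N); with the default floor this is a few percent, and it
  partially cancels the interface-resolution bias above. Density
  recovery is validated to within three standard errors over seeded
  replicates, which these residual biases respect.
* Zone boundaries are half-open; a distance exactly at an inner edge
  belongs to the deeper zone, one at the last edge leaves the band.
* Mask exclusion uses the strict polygon interior; boundary cells stay.
* Excluded cells participate in nothing: no reference set, no analysis
  set, no hull, no count.
* All randomness flows from explicit integer seeds; cohort slides use
  per-slide streams keyed by (seed, sample index). Reruns are
  bit-identical, including TSV output ordering (stable sort on the key).

## What passing tests do and do not show

The validation demonstrates that the implementation is internally
correct (oracle equality, conservation, calibration against closed
forms, exactness and type-I control of the tests) and that the designed
group contrasts are recovered at the generator's effect sizes. It does
not calibrate absolute densities to any real cohort, does not model
segmentation error, staining variability, curved interfaces, necrosis or
holes in tissue, and makes no claim about prognosis. Conclusions about
real slides require real per-cell tables, for which the exclusion-mask
and intensity-threshold hooks exist.
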