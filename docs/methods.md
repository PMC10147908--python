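# Methods

## The model

`melanotype` treats a stained tissue compartment as a finite mixture of
melanocyte cell types. Each type t is characterized by Gaussian feature
components — nucleus area (µm²), nucleus circularity (4πA/P², unitless),
nuclear BAP-1 OD, cytoplasmic BAP-1 OD, and, where expressed, membrane
IGF-1R and cytoplasmic IDO/TIGIT ODs — with means and SDs stored in the
archetype table, and each compartment c by mixing proportions π(t|c):
normal choroid 82/18 normal/spindle A, nevus 47/53, primary tumor 45/23/32
epithelioid/spindle A/spindle B, metastasis 69/31 epithelioid/spindle B.
Region-resolved proportions inside primary tumors enrich epithelioid and
spindle B cells at the base and apex and spindle A cells centrally; only
the direction of that enrichment is established, so the magnitudes
(0.50/0.145/0.355 at base and apex, 0.35/0.40/0.25 centrally, averaging
exactly to the compartment-level proportions over equal thirds) are a
package choice exposed in configuration.

Optical density is Beer–Lambert: OD = −log10(I/I0), linear in stain
concentration. RGB images are decomposed onto unit hematoxylin and red
chromogen absorbance vectors by least squares with non-negativity clipping.
Per-slide calibration maps a raw mean OD x to (x − neg)/(pos − neg) where
neg/pos are reference-cell ODs; the calibrated scale is anchored at 0/1 but
values above 1 (cells darker than the positive reference) are preserved.

## Synthetic data

`synthetic_data` is the test bed for every downstream stage.

* **Feature tables.** Types are drawn i.i.d. from π(·|c); each feature is
  drawn from the type's Gaussian and *clipped* to its physical domain
  (area ≥ 1 µm², circularity in [0.05, 1], ODs ≥ 0). Clipping rather than
  resampling keeps type proportions exact, at the cost of point masses at
  the domain edges — a quarter of metastatic cells sit at exactly zero
  nuclear BAP-1 OD, which matters for clustering (below). Features not
  carried by the archetype table are derived from the ellipse with the
  sampled area and circularity: the axis ratio is obtained by inverting
  the Ramanujan perimeter approximation (tabulated and interpolated, error
  < 1e-3 in circularity), calipers are the ellipse axes, eccentricity is
  √(1−(b/a)²), the nucleus:cell ratio uses a 3.5 µm expanded ellipse; all
  derived features carry configurable relative noise (default 2%,
  eccentricity ±0.01, ratio 5%). Hematoxylin OD defaults to N(0.45, 0.20)
  clipped at 0; markers a type does not express get half-normal background
  of scale 0.02.
* **Scenes.** Cells are placed by rejection sampling (never overlapping,
  including their 3.5 µm cytoplasm rings) as rotated ellipses; nucleus
  pixels absorb hematoxylin plus chromogen at the nuclear-marker OD, the
  cytoplasm ring absorbs the cytoplasmic-marker OD; the image is
  I0·10^(−A) per channel with additive Gaussian pixel noise (default SD 2
  counts) and 8-bit quantization. Pixel size defaults to 0.25 µm/px.
* **What it does not emulate.** Within-type feature correlations (only
  marginal moments are published, so components are independent), chromatin
  texture and nucleoli, overlapping cells, uneven illumination, and
  tissue-level artifacts. Passing tests therefore demonstrate algorithmic
  correctness under the stated statistical model, not performance on real
  slides.

## Segmentation

Detection parameters follow the published setup: background radius 8 µm,
smoothing sigma 2 µm, nucleus area limits 10–200 µm², cell expansion
3.5 µm. The operator chain is classical and deterministic: morphological
opening (disk of the background radius) as background subtraction, Gaussian
smoothing, Otsu threshold (with a small OD floor; a fixed threshold can be
configured), watershed from h-maxima of the smoothed distance transform
(maxima depth scaled to the minimum nucleus radius so ridge bumps along
elongated nuclei do not oversplit), and the area filter. Because the 2 µm
smoothing kernel is comparable to a nucleus radius, a single global
threshold on the smoothed image systematically distorts sizes; each object
boundary is therefore refined on the unsmoothed background-subtracted OD at
half its plateau (95th percentile) within its watershed basin. On rendered
scenes of in-range, well-separated nuclei this recovers every ground-truth
nucleus at IoU ≈ 1.0, areas within ±10% and circularities within ±0.05.
Cells are nuclei expanded by 3.5 µm under scikit-image's nearest-label
expansion (a Voronoi constraint: cells never overlap); cytoplasm is
cell∖nucleus and the membrane is the 1-px cell boundary band.

## Two-step clustering

Continuous features only, standardized to zero mean and unit variance by
default (the log-likelihood distance is scale-invariant, so
standardization only affects the silhouette and reported centroids).

1. **Pre-clustering.** Records are inserted sequentially into a flat list
   of leaf entries (count, per-feature sum, sum of squares). A record joins
   its nearest entry if the log-likelihood distance is below the current
   threshold, else opens a new entry; at more than 512 entries the
   threshold rises to the median nearest-neighbour merge distance and all
   entries are re-inserted. The pass is bypassed (one record = one
   summary) at N ≤ 5,000. Insertion order matters, so the input is
   shuffled once with the run seed, which is recorded in the model.
2. **Agglomeration.** Greedy merging by minimal d(i,j), computable from
   sufficient statistics alone; verified to equal a brute-force
   re-implementation exactly. BIC(J) is recorded for J = 1..6.
3. **Automatic k.** Stage 1 takes the largest J whose BIC improvement
   ratio ΔBIC(J)/ΔBIC(2) stays ≥ 0.04; stage 2 computes
   R2(J) = d_min(C_J)/d_min(C_{J+1}) for J = 2..J1 and selects the J with
   the largest R2, or the larger of the top two J when their ratios are
   within a factor 1.15. The constants 0.04 and 1.15 are the documented
   defaults of the original two-step procedure.
4. **Assignment and quality.** Records are hard-assigned to the nearest
   cluster under the singleton-to-cluster distance; the silhouette is
   centroid-based, s(i) = (b−a)/max(a,b) with a the distance to the own
   centroid and b to the nearest other centroid, averaged (NaN for k = 1).
   The feature-subset search fits every non-empty subset (with
   pre-clustering above 2,000 records to keep 1,023 fits tractable) and
   returns the subset with the highest model silhouette, ties toward fewer
   features.

**Known behavior of the automatic rule.** On well-separated components the
selector recovers the generating k reliably (the primary-tumor mixture at
n = 50,000 gives k = 3 in 20/20 seeds). On strongly overlapping or
non-Gaussian data it overpartitions, as has long been reported for the
original tool: a single spherical Gaussian is split into 2–6 clusters
(BIC keeps improving and the distance-ratio refinement cannot return 1),
and the metastasis mixture — whose zero-clipped nuclear BAP-1 spike is a
genuine third mode — yields k = 2 in only ~55% of seeds, the largest
distance-ratio jump sitting at J = 2 in 16/20 seeds but the larger-J tie
rule resolving near-ties upward. Similarly, because a one-dimensional
split always looks cohesive, single features dominate the model-silhouette
ranking in the subset search whenever a feature's marginal is bimodal.
These are properties of the documented procedure, reproduced deliberately
rather than patched; the tie rule and thresholds are exposed in code for
experimentation.

## Cell typing and statistics

Cluster centroids (raw units) are matched one-to-one to archetype mean
vectors by Hungarian assignment on Euclidean distance standardized by
pooled across-type SDs, using only features shared with the archetype
table; unmatched archetypes are reported absent. Per-cell nuclear BAP-1
status uses a calibrated-OD cutoff of 0.5 (no numeric per-cell threshold
is published; the cutoff is configurable and halfway between the reference
cells). Lesion-level BAP-1 status applies the ≥ 33% immunoreactive-cell
rule; with cell coordinates the fraction is computed in the n = 3 most
intensely stained high-power-field windows (default 0.95 mm², emulating
field selection under the microscope), otherwise lesion-wide.

The statistical battery mirrors the analysis protocol: two-group
comparisons gate on Shapiro–Wilk normality of both samples (p > 0.05 → t
test, else Mann–Whitney U; exact U for tie-free n ≤ 20, asymptotic with
continuity and tie correction otherwise; Shapiro–Wilk subsamples to 5,000
with a recorded seed because the test is unstable at very large n), three
or more groups use tie-corrected Kruskal–Wallis, categorical tables use
Pearson χ² without continuity correction, and feature-vs-OD associations
use OLS with a two-sided slope test. No multiple-testing correction is
applied, matching the analysis it reproduces. All numerical engines are
scipy; tests verify them against hand-written formula oracles.

## Problem sizes and numerical choices

Simulations use n = 50,000 cells per compartment run (20 seeds) for the
primary-tumor and metastasis recovery studies, n = 20,000 for the nevus
study, and a 1/100-scale full cohort (12,455 cells: 573/183/10,281/1,418
per compartment) for pooled-moment checks — sizes chosen so each study
runs in minutes on one CPU while keeping Monte-Carlo error well inside
the stated tolerances. Variance estimates are clipped at 0 against
round-off; merged-statistic distances agree with raw-member distances to
1e-9; the rasterized-shape tolerance for eccentricity/circularity tests
is 0.02 at the default pixel size (second moments include the 1/12
per-pixel variance so thin shapes stay strictly inside [0, 1)). Perimeters
are polygonal lengths of the subpixel marching-squares contour of the
lightly smoothed (σ = 1 px) mask; the raw staircase contour would inflate
perimeters ~5–8% and depress circularity accordingly.

## Limitations

Independent per-feature Gaussians understate real within-type structure;
clipped-at-zero ODs create edge point masses that both the generator and
real calibrated measurements share; the automatic cluster-count rule is
unstable on overlapping mixtures (above); the per-cell BAP-1 cutoff and
the region-proportion magnitudes are package choices, so the 99/46/2%
positive fractions and printed silhouettes of the real cohort are not
reproduction targets; and the renderer's scenes are far simpler than
tissue, so segmentation results bound algorithmic, not histological,
performance.
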