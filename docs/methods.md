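# Methods

This note records the models, numerical choices and known limits of the
package. Nothing here is an empirical claim beyond what the test suite
and `scripts/acceptance.py` compute.

## Approximate BML volumetry

A bone-marrow lesion is summarised by its three maximal orthogonal
diameters (cm): anterior–posterior and superior–inferior measured on
sagittal slices, medial–lateral on coronal slices, each taken as the
greatest extent across all slices showing the lesion. The approximate
volume is their product. This deliberately over-estimates the true
(segmented) volume — a box circumscribes the lesion — but is fast,
requires no proprietary software, and is monotone in lesion size, which
is what correlation analyses need. A finding qualifies as a lesion only
if it appears on at least two sagittal or at least two coronal slices.

Regional volumes are sums over the lesions in a region (index femur,
index tibia, non-index femur, non-index tibia; the index compartment is
the more diseased tibiofemoral side). A region with no lesions at one
timepoint contributes 0 cm³ to the longitudinal change, so incident and
resolved lesions enter with their full volume.

Peak lesion signal is normalised by normal bone-marrow signal sampled
in the posterior non-index femur (a region reliably lesion-free) to
remove acquisition-to-acquisition intensity drift; the regional peak is
the maximum over lesions, and is *absent* (not zero) for lesion-free
regions.

### Smallest detectable difference

Test–retest reliability data give, per lesion, the difference between
two independent readings of the volume change:
`D = (F₁ − B₁) − (F₂ − B₂)`. These differences are small-sample and
skewed, so the SDD uses the distribution-free CI of the median: for
sample size n, the interval between the order statistics at ranks
`(l, n+1−l)`, with `l` the largest rank whose Binomial(n, ½) lower tail
stays at or below α/2. This is conservative (exact coverage ≥ 95%; for
n = 16 the ranks are 4 and 13 with coverage 97.9%) and needs n ≥ 6 at
the 95% level. The SDD threshold is the larger absolute endpoint —
conservative again, since classification should not call noise change.
A bootstrap percentile CI of the median (default 1000 resamples, seeded
PCG64) is provided as the cross-check method; on simulated reliability
sets the two intervals agree to within their own widths.

Change classification is strict outside the threshold and inclusive
inside: `ΔV < −T` regression, `ΔV > +T` progression, otherwise no
change. `T` defaults to 3.2 cm³ (the reference reliability analysis)
but any SDD estimate overrides it. Display percentages round half away
from zero to whole percent.

## Cartilage morphometry

Inputs are per-slice binary cartilage masks with isotropic in-plane
pixel size `s` (mm) and slice spacing (slice thickness + gap, mm).
Conventions: row/col coordinates, origin top-left, pixel-centre
geometry, 0-based; foreground components are 8-connected; the boundary
is the set of foreground pixels with a 4-connected background neighbour
(grid edges count as background); components under 5 px are dropped and
logged. The skeleton is topology-preserving thinning (scikit-image); a
component that thins away entirely is replaced by its
distance-transform maximum so the skeleton is never empty.

### Thickness

Per slice, pooled over components:

```
thickness = 2 · (Σᵢ dᵢ / N + ½) · s
```

with `dᵢ` the Euclidean distance (exact distance transform) from
boundary pixel `i` to the nearest skeleton pixel and `N` the pooled
boundary count. The factor 2 turns the mean centerline-to-surface
half-thickness into full thickness. The half-pixel term is a
digitization-bias correction: boundary and skeleton distances are
centre-to-centre, but the physical surface lies half a pixel outside
the boundary pixel centre, so the raw mean underestimates the
half-thickness by `s/2` (for a t-px band the raw formula converges to
`(t−1)·s`, not `t·s`). With the correction, band phantoms of 6–14 px
recover true thickness within ~2%; the residual error comes from band
ends and skeleton end-shortening and shrinks as the plate lengthens.
Anisotropic in-plane spacing is rejected: the formula has a single
pixel size.

Known bias: on strongly curved plates (annulus sectors with radius
comparable to a few multiples of the thickness) the estimator reads
10–15% low, because boundary pixels on the inner arc sit closer to the
skeleton than the radial thickness. The recovery guarantees in the test
suite therefore apply to straight-band geometry.

### Full-thickness lesion span

For each annotated pair of components flanking a defect (annotations
are authoritative; an automatic mode pairs consecutive components along
the principal axis whose skeleton-to-skeleton gap exceeds 2 px, for
phantoms and screening), a least-squares quadratic is fitted to the
pooled skeleton pixel centres. The fit runs in a frame whose x-axis is
the first principal axis of the points (sign-canonicalised, so the fit
is independent of operand order); this keeps the curve single-valued
for sheet-like cartilage at any orientation. The curve is sampled
between the extreme skeleton projections at arc steps ≤ 0.25 px
(halving the step moves lengths by < 0.5%); a sample overlaps cartilage
iff its containing pixel is foreground in either flanking component,
with transition segments counted half. The lesion length is the arc
length of the longest non-overlap run strictly between cartilage
samples; the overlap length is the in-cartilage arc length.

Pixel density is (flanking pixel count)/(overlap length, mm). The
lesion re-enters the thickness mean as `n_lesion = length · density`
virtual boundary points at exactly 0 mm:

```
thickness_incl = 2 · (Σᵢ dᵢ + N/2) / (N + n_lesion) · s
```

which reduces to the plain thickness at zero lesion length and halves
it when `n_lesion = N`. With multiple annotated pairs per slice,
lengths and virtual pixels accumulate per pair.

Resolution limit: lesion lengths are recovered within ±1 px + 5% on
collinear bands (gaps 4–30 px) and within 10% on annulus sectors when
the true arc is ≳ 10 px. Below that, ±1 px rasterization granularity
alone exceeds a 10% relative band — a floor any pixel-grid method
shares.

### Plate aggregation

Plate thickness is the unweighted mean of per-slice lesion-inclusive
thicknesses (slices with no cartilage are excluded and logged;
weighting by cartilage amount is a defensible alternative, unweighted
was chosen to keep each slice's reading equal). Lesion area is
Σ(lesion length)·slice spacing; subchondral bone area is Σ(overlap
length)·spacing, with the skeleton arc length (8-adjacency polyline
length) standing in as the bone-interface proxy on lesion-free slices,
where no spanning curve exists. The lesion-area percentage
`100·lesion/(lesion+bone)` is then invariant to the spacing itself.
Cartilage volume is the foreground voxel count times the voxel volume.

## Statistics

* **Spearman rho** is the Pearson correlation of average-ranked data
  (scipy); undefined for constant input.
* **Fisher-z CI**: `tanh(atanh(r) ± z₍α/2₎/√(n−3))`, with the exact
  normal quantile (1.959964…, not 1.96) — needed to match reference
  intervals at two decimals.
* **p-values**: the exact permutation distribution for n ≤ 9 (full
  enumeration), otherwise the t approximation
  `t = r·√((n−2)/(1−r²))` on n−2 df; the method is recorded on each
  result.
* **Batteries** drop missing values pairwise (each pair keeps its own
  n), skip pairs with n < 4 (logged), and flag significance at
  `family_alpha/m` (Bonferroni; 0.05/24 ≈ 0.002).

## Synthetic data

* **Phantoms** emulate segmented cartilage plates: axis-aligned bands
  or rasterized annulus sectors (pixel foreground iff its centre lies
  in the continuous shape), replicated across slices, with
  full-thickness gaps of known width. Ground truth carries thickness,
  per-gap length (mid-thickness arc for sectors) and exact voxel
  volume. They do not emulate segmentation errors, partial-volume
  boundaries, anisotropic pixels or through-slice curvature, so passing
  recovery tests demonstrates correctness of the geometry pipeline, not
  robustness to manual-segmentation noise.
* **Test–retest sets** draw log-normal true baselines (median 4 cm³),
  Gaussian true changes, and add independent N(0, error_sd) noise to
  each of the four readings; the difference-of-changes then has SD
  2·error_sd. Defaults (n = 16, error_sd = 3 cm³) reproduce the scale
  of a 16-lesion reliability set with difference SD ≈ 6 cm³.
* **Cohorts** use a Gaussian copula with latent Pearson correlation
  `2·sin(π·ρ_s/6)` — the exact normal-scores relation — so the
  population Spearman correlation equals the target; marginals are
  log-normal BML volume (median 8.8 cm³) and Beta-distributed lesion
  area scaled to 0–100% (mean 24.8, SD 17.8), applied by inverse CDF,
  which leaves ranks untouched. Change columns are independent noise.

All generators are pure functions of spec + seed (byte-identical
reruns).

## Problem sizes

The validation suite uses single-slice phantoms up to ~100×100 px,
2,000-replicate Monte-Carlo loops for coverage and family-wise error
(n = 16–40 per replicate), and n = 2000 for cohort rank-correlation
recovery — sizes at which binomial Monte-Carlo error (≈ 0.5% on a 95%
coverage estimate) is small against the margins being tested, while the
full suite runs in a few minutes.

## Limitations

* Linear BML dimensions are manual inputs by design; no lesion
  detection or DICOM reading.
* The thickness estimator assumes sheet-like, mildly curved plates;
  strong curvature biases it low (see above).
* Automatic gap detection orders components along one principal axis
  and cannot handle nested or branching defect topologies; expert
  annotations are the supported path for real data.
* The per-plate mean is unweighted across slices; plates whose
  cartilage amount varies strongly across slices will weight sparse
  slices as much as dense ones.
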