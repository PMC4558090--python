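# Methods

This note documents the models, algorithms and design choices behind
`mammodense`, in the spirit of the methods documentation of packages like
statsmodels or scanpy: what is computed, under which assumptions, and which
choices were genuinely open.

## Segmentation: moment-preserving thresholding

The dense/lucent split uses a single global gray-level threshold on the
256-bin histogram of masked pixels.  Writing the normalized histogram as a
distribution over gray levels z with moments m₁ = E[z], m₂ = E[z²],
m₃ = E[z³], the two-level image that preserves all three moments has levels
z₀ < z₁ given by the roots of z² + c₁z + c₀ = 0 with

    c₀ = (m₁m₃ − m₂²) / (m₂ − m₁²),   c₁ = (m₁m₂ − m₃) / (m₂ − m₁²),

and below-threshold fraction p₀ = (z₁ − m₁)/(z₁ − z₀).  The threshold is
the p₀-tile: the smallest gray level whose cumulative fraction reaches p₀
(a 10⁻⁹ tolerance on the comparison keeps exactly attained tiles, e.g. the
symmetric-bimodal p₀ = ½ case, in the lower class).  This is the two-point
Gauss-quadrature construction, so z₀, z₁ are real and distinct whenever the
histogram has positive variance; any degenerate input (single gray level,
zero variance) raises an explicit error rather than silently returning a
mid-scale value, because silent fallbacks mask upstream bugs.

Pixels strictly above the threshold are dense; ties are non-dense, matching
the below-or-equal semantics of p₀.  Deeper-than-8-bit input (e.g. DICOM)
is min–max normalized to 8 bits over masked pixels first — the method needs
a fixed 256-bin domain, and how the original acquisition reduced bit depth
is unknowable downstream, so a documented linear rescaling is used.

Area metrics are exact pixel counts scaled by the squared pixel spacing:
dense + lucent = breast holds exactly by construction, and overall PD is
the dense fraction in percent.

## Regional grid and zones

After mirroring right-laterality images (so the chest wall is always on the
left and "anterior" is a consistent grid side) and cropping to the mask's
bounding box, the box is tiled into 6 columns × 8 rows.  When the box is
not divisible by 6 or 8, remainder pixels go to the last column/row —
deterministic, and "equally sized" holds to within one pixel.  Cell
coordinates are 1-based (column, row) with column 1 posterior.  Two exact
partition identities are enforced by tests: per-cell pixel counts sum to
the totals, and overall PD equals the breast-pixel-weighted mean of
regional PDs.

Zones are column bands: posterior = columns 1–2, middle = 3–4, anterior =
5–6.  The band assignment is a configuration default (the zone map is
overridable per cell) since equal-width bands are the simplest consistent
reading of a three-zone split of a six-column grid.  Zonal PD is the
unweighted mean over the zone's nonempty cells; a zone with no tissue is
reported missing (NaN), never zero.  Cells without tissue carry regional
PD 0 in the 48-vector used for Moran's I (keeping N = 48) but are excluded
from zonal means; a "drop" policy that removes them and renormalizes N is
available.

## Moran's I

    I = (N/S₀) · Σᵢ Σⱼ wᵢⱼ (xᵢ−x̄)(xⱼ−x̄) / Σᵢ (xᵢ−x̄)²

over the N = 48 regional PDs.  The default weights are wᵢⱼ = 1/dᵢⱼ² for
**all** pairs of cell midpoints, with d measured in physical cell
dimensions.  "Inverse squared distance between adjacent sub-regions" is
ambiguous between all-pairs and neighbors-only weighting; all-pairs is the
default here because a 1/d² kernel is vacuous if only unit-distance
neighbors receive weight, and rook contiguity (binary edge-sharing
weights) is provided as the alternative reading.  A lattice-unit variant
ignores the cell aspect ratio.  I is invariant to positive rescaling of W
and to affine transforms of the values (both property-tested); the rook
checkerboard gives I = −1 exactly, and the permutation expectation is
−1/(N−1).

The permutation null shuffles the value vector uniformly (n_perm ≥ 100),
reporting the null mean and sd and a two-sided empirical p with the +1
inclusion of the observed arrangement.

Degenerate inputs (constant values) make I undefined and raise; images
whose 48-vector is constant (fully dense or fully lucent breasts) carry a
missing Moran value through the cohort tables.

## Synthetic generator

The generator emulates a longitudinal screening cohort:

* **Mask** — a half-ellipse flush with the chest-wall edge with a
  triangular pectoral cut, axes scaled by √breast_scale so mask area is
  linear in `breast_scale`.  At the default 480×360 px frame and
  0.033 cm/px spacing the full-scale mask is ≈ 114 cm², in the range of
  cropped MLO views of real breasts.
* **Dense field** — white noise smoothed by a Gaussian kernel of sd
  `corr_length`, standardized inside the mask, plus an optional linear
  anterior ramp of `anterior_weight` field-sd per breast length, cut at
  the quantile that marks exactly round(PD·|mask|) pixels dense.  PD is
  therefore exact to one pixel, and autocorrelation increases monotonically
  with `corr_length` (tested over 30 seeds).
* **Rendering** — dense pixels at gray 200, lucent at 60, Gaussian blur
  (sd 1 px) at tissue boundaries, additive noise (sd 5), black background.
* **Cohort** — per subject a left-entry and left-exit image (same mask,
  independent field realizations) and a right-exit image that exactly
  mirrors the left exit.  Exit parameters shift by `ExitShift`
  (default +2.5 PD points and ×0.85 correlation length, emulating the
  observed longitudinal pattern of similar density but weakened
  autocorrelation).  Density strata default to
  {15 %: 0.24, 30 %: 0.32, 50 %: 0.30, 65 %: 0.14} with 3-pp subject
  jitter, and breast size is negatively coupled to density
  (scale = 1.05 − 0.007·PD + noise), reproducing the smaller-denser-breast
  association.  All randomness flows from one seed through per-subject,
  per-image `SeedSequence` spawns, so subject k's images are identical
  whatever the cohort size.

Default free parameters and why:

| parameter | default | rationale |
|---|---|---|
| `corr_length` | 24 px (≈ 0.8 cm) | no quantitative texture scale is published for screening cohorts; 0.8 cm puts fibroglandular clusters at about half a grid cell, which yields clearly positive regional Moran's I as observed in real breasts |
| `anterior_weight` | 1.6 sd / breast | makes anterior zonal PD ≈ 2× posterior, the magnitude seen in sparser real breasts where glands cluster behind the nipple; negative values reverse the ramp |
| `noise_sd` | 5 gray levels | visible speckle that still leaves the bimodal histogram intact |
| `pixel_spacing_cm` | 0.033 | a processed/downsampled resolution placing breast areas near 100 cm² |

What the generator does **not** emulate: real parenchymal texture
(power-law spectra, ducts, vessels), compression and acquisition physics,
lesions and calcifications, BI-RADS-like categorical structure, or the
positive density–autocorrelation coupling seen in clinic cohorts.  Passing
tests therefore demonstrate correctness of the measurement pipeline and
calibration of the statistics under controlled spatial structure — not
clinical validity on real mammograms.

## Cohort statistics

Subjects are grouped by left-exit overall PD into fixed 20-point bins
([0,20) … [60,100]); left-closed/right-open with the last bin closed makes
boundary values unambiguous.  (A quantile split would equalize group sizes;
fixed-width bins follow the conventional density strata and produce the
unequal group sizes typical of screening cohorts.)  Tables report
mean ± sd per group and overall.

* **Zonal**: Friedman test across the three zones within subjects; when
  significant at 0.05, unadjusted pairwise Wilcoxon signed-rank post hocs
  (a Holm/Bonferroni option exists but is off by default, since the
  unadjusted pairs are the conventional presentation).  Degenerate all-tied
  data reports p = 1 (no signal); groups below n = 3 are flagged
  not-computed.
* **Longitudinal / symmetry**: paired Wilcoxon signed-rank on entry-vs-exit
  Moran's I and on left-vs-right PD and I.  scipy's method="auto" uses the
  exact distribution for small samples without ties and the normal
  approximation otherwise.  All-zero differences (e.g. exactly mirrored
  breasts) are reported not-computed rather than p = 1.
* **Correlations**: Spearman rank correlations of breast area ~ overall PD
  and overall PD ~ Moran's I per timepoint.

### Type-I calibration

`null_rejection_rates` simulates cohorts from the null generator (no
anterior ramp, no entry-exit shift; entry and exit are independent
realizations of the same field) and reports the rejection rate of the
zonal Friedman and longitudinal Wilcoxon tests at α = 0.05.  The
calibration runs on ground-truth dense maps (not rendered images) to
isolate the tests' calibration from segmentation noise, at a 240×180 px
frame with corr_length 12 — half the default resolution at the same
texture-to-cell ratio, which leaves the 48-cell statistics unchanged while
keeping hundreds of cohorts cheap to simulate.  Cohorts of 20 subjects are
used because the exact signed-rank test's discrete achievable level is
0.048 at n = 20 (vs 0.042 at n = 12), keeping the empirical rate close to
nominal.

## Numerical and degenerate-input choices

* Histogram p₀-tile comparison tolerance 10⁻⁹ (see above).
* Quantile cut of the continuous field uses `argpartition` on the masked
  values: exactly k pixels dense, ties broken by array order (measure-zero
  for continuous fields).
* Empty masks, zero-variance histograms/value vectors, unknown laterality
  and out-of-range PDs all raise explicit `ValueError`s; the batch pipeline
  is fail-soft per image (failures logged with subject/slot identity, run
  continues).
* DICOM pixel spacing is read as mm and converted to cm; metadata takes
  precedence over configuration.

## Known limitations

* The moments threshold assumes a roughly bimodal masked histogram; heavily
  quantized or near-constant images are rejected rather than guessed at.
* The 6×8 grid and zone bands are fixed conventions; anatomically adaptive
  regions are out of scope.
* Moran's I under the physical all-pairs 1/d² weighting has a compressed
  dynamic range (a pure linear gradient reaches I ≈ 0.48, vs 0.80 under
  rook weights), so absolute I values are not comparable across weighting
  schemes — only within one scheme.
* Synthetic images are stylized (see above); no claim of photorealism.
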