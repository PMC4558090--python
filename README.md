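# mammodense

Spatial analysis of mammographic breast density (MBD) for researchers
studying how radio-dense fibroglandular tissue is distributed within the
breast — and how that distribution changes over time or differs between
populations.

Mammographic percent density (PD, the fraction of breast area that is
radio-dense) is one of the strongest image-based risk factors for breast
cancer, but a single whole-breast number hides *where* the dense tissue
sits. `mammodense` quantifies the spatial layout:

1. **Segmentation** — the breast (inside a user-supplied or synthetic mask
   excluding background and pectoral muscle) is dichotomized into dense and
   lucent tissue with the automatic *moment-preserving* ("Moments") global
   threshold: the binarized image preserves the first three gray-level
   moments m₁, m₂, m₃ of the masked histogram, and the threshold is the
   p₀-tile of the histogram where p₀ is the moment-matched below-threshold
   fraction.  Pixel-spacing calibration turns counts into cm².
2. **Regional grid** — the cropped breast is split into 48 equally sized
   rectangles (6 columns × 8 rows; column 1 at the chest wall), each with a
   regional PD; columns aggregate into posterior / middle / anterior zones.
3. **Spatial autocorrelation** — Moran's I over the 48 regional PDs,

   I = (N/S₀) · Σᵢⱼ wᵢⱼ (xᵢ−x̄)(xⱼ−x̄) / Σᵢ (xᵢ−x̄)²,

   with inverse-squared-distance weights wᵢⱼ = 1/dᵢⱼ² between cell
   midpoints (rook-contiguity and lattice-unit variants included), plus a
   permutation null for significance.
4. **Cohort comparisons** — density-group binning, mean ± sd summary
   tables, Friedman + Wilcoxon signed-rank zone comparisons, paired
   entry-vs-exit and left-vs-right tests, and Spearman correlations.

Because clinical mammograms are rarely shareable, the package ships a
**synthetic mammogram generator** (Gaussian-random-field dense tissue with
controllable PD, texture scale and anterior gradient inside breast-shaped
masks) so the entire pipeline is testable end-to-end against known ground
truth.

## Worked example

```python
import mammodense as md

params = md.SyntheticParams(target_pd=35.0, seed=0)   # 480x360 px, 0.033 cm/px
mask   = md.generate_breast_mask(params)
truth  = md.generate_density_field(mask, params.target_pd, params.corr_length,
                                   params.anterior_weight, seed=0)
image  = md.render_mammogram(truth, params, seed=1)

analysis = md.analyze_image(image, mask)   # orient, crop, segment, grid, Moran
seg = analysis.segmentation
print(f"threshold   : {seg.threshold}")
print(f"breast area : {seg.breast_area_cm2:.1f} cm^2")
print(f"overall PD  : {seg.overall_pd:.2f} %  (truth {truth.true_overall_pd:.2f} %)")
z = analysis.zones
print(f"zonal PD    : posterior {z.posterior:.1f} %, middle {z.middle:.1f} %, "
      f"anterior {z.anterior:.1f} %")
print(f"Moran's I   : {analysis.moran.I:.3f}  "
      f"(random expectation {analysis.moran.expected_i:.4f})")
```

prints

```
threshold   : 123
breast area : 113.8 cm^2
overall PD  : 35.04 %  (truth 35.00 %)
zonal PD    : posterior 17.1 %, middle 49.5 %, anterior 35.4 %
Moran's I   : 0.125  (random expectation -0.0213)
```

The automatic threshold (gray level 123) recovers the generator's 35 % true
density to 0.04 percentage points; the positive Moran's I (well above the
−1/47 random-arrangement expectation) reflects the clustered dense tissue,
and the anterior-weighted generator shifts density away from the chest wall
(posterior 17 % vs 35–50 % elsewhere).

For whole cohorts, use the CLI:

```bash
mammodense simulate --n-subjects 20 --seed 1 --out cohort/
cat > config.yaml <<EOF
manifest: cohort/manifest.csv
output_dir: results/
EOF
mammodense run-all --config config.yaml
```

which writes per-image metrics, the long-format regional PD table, and the
cohort summary/test tables (density groups, zonal Friedman/Wilcoxon,
entry-vs-exit and left-vs-right comparisons, Spearman correlations) as CSV.

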