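# oamq — quantitative knee-OA MRI morphometry

Tools for two imaging biomarkers of knee osteoarthritis and the
statistics that connect them:

1. **Approximate bone-marrow-lesion (BML) volume.** A BML is an
   ill-defined high-signal region in subchondral bone on fluid-sensitive
   MRI. Instead of slice-by-slice segmentation, each lesion is summarised
   by its three maximal orthogonal diameters — anterior–posterior (AP)
   and superior–inferior (SI) on sagittal images, medial–lateral (ML) on
   coronal images — and its approximate volume is the product
   `V ≈ AP · ML · SI` (cm³). Volumes are summed per knee region
   (index/non-index femur and tibia), and longitudinal change
   `ΔV = V_followup − V_baseline` is classified as *regression*
   (`ΔV < −SDD`), *progression* (`ΔV > +SDD`) or *no change* against a
   smallest detectable difference (SDD) derived from test–retest data:
   the larger absolute endpoint of the distribution-free 95% CI of the
   median difference-of-changes (a 1000-resample bootstrap percentile CI
   is available as a cross-check).
2. **Skeleton-based cartilage morphometry.** From binary cartilage masks,
   per-slice mean thickness is `2·(Σᵢ dᵢ/N + ½)·s`, where `dᵢ` is the
   Euclidean distance from boundary pixel `i` to the morphological
   skeleton of its connected component, `N` the boundary pixel count and
   `s` the pixel size (mm). Where two cartilage segments flank a
   full-thickness lesion (cartilage completely absent), a second-order
   polynomial fitted to the pooled skeletons spans the defect; the arc
   length of the curve outside cartilage is the lesion length, folded
   back into the thickness mean as zero-thickness virtual pixels and
   accumulated across slices into the lesion area as a percentage of
   subchondral bone.
3. **Statistics.** Spearman rank correlations with Fisher-z
   (`atanh`) 95% confidence intervals, Bonferroni-corrected correlation
   batteries, and conservative order-statistic median CIs.

Because clinical-trial MRI of this kind is not publicly deposited, the
package ships a synthetic-data module (`oamq.synthetic`) that generates
cartilage phantoms with known thickness/gap ground truth, test–retest
measurement sets with controlled noise, and bivariate cohorts with a
target Spearman correlation — everything needed to validate the pipeline
end to end.

## Worked example

Generate a test–retest reliability set and derive the SDD:

```sh
oamq simulate retest --seed 1 --out work
oamq sdd --retest work/retest.csv
```

```
median change difference 1.3 cm^3, 95% CI (-4.43, 3.61), SDD threshold 4.43 cm^3 [median_order_statistic]
```

With 16 lesions the 95% order-statistic CI of the median spans the 4th
to 13th order statistics of the difference-of-changes; the SDD is the
larger absolute endpoint, i.e. a regional volume change must exceed
4.43 cm³ (at this simulated reading noise, SD 3 cm³ per reading) before
it is called real change rather than measurement error.

Measure a cartilage phantom with a full-thickness defect:

```sh
printf 'shape: band\nthickness_px: 8\nlength_px: 70\ngaps: [[30, 10]]\npixel_spacing_mm: 0.5\n' > work/band.yaml
oamq simulate phantom --seed 1 --spec work/band.yaml --out work
oamq morpho --mask work/phantom.nii.gz --auto-gaps --out work/morpho.csv
```

```
plate thickness 2.452 mm, lesion area 15.6% of subchondral bone, cartilage volume 468.0 mm^3
```

The true band is 8 px × 0.5 mm = 4.0 mm thick with a 10 px = 5.0 mm
gap; the lesion-inclusive thickness (2.45 mm) is pulled down from the
lesion-free estimate (3.96 mm) because the recovered 4.98 mm defect
enters the mean as 0 mm cartilage.

The numbered scripts under `analysis/` run the full study on simulated
inputs: `01_simulate_inputs.py` generates phantoms, the reliability set
and a 44-knee cohort; `02_phantom_recovery.py` sweeps thickness and
gap recovery (worst error 4.7% across bands 6–14 px and gaps 4–30 px);
`03_sdd_reliability.py` derives the SDD both ways and shows it tracking
injected noise; `04_correlation_battery.py` runs the Bonferroni-corrected
Spearman battery (the built-in 0.63-correlation pair is detected at
r = +0.61, CI +0.39 to +0.77, p < 0.002; null pairs are not). Outputs
land in `results/`.

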