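# dcehabitat

Automatic analysis of dynamic contrast-enhanced MRI (DCE-MRI) of the
prostate: the package takes a 4D T1-weighted series (12 frames at 30 s)
plus contours of the prostate, the peripheral zone (PZ) and a gluteus
maximus (GM) muscle sample, and produces a segmentation of the
well-perfused (tumor-suspicious) habitat, six semi-quantitative kinetic
features of its contrast curve, and a per-voxel 1–10 aggressiveness map.
It is aimed at researchers in quantitative prostate imaging who want a
reproducible, unsupervised alternative to hand-drawn tumor ROIs.

## Method

1. **Motion correction.** Each frame is aligned to its (corrected)
   predecessor by an in-plane affine transform (shift, rotation,
   isotropic scale) maximizing the mutual information of the intensities
   inside the prostate contour dilated by 18.75 mm (15 pixels in-plane).
   A correction is applied only when the sum of squared differences (SSD)
   in that region decreases.
2. **Pattern recognition.** The baseline-corrected signal–time curves of
   all prostate voxels form a non-negative matrix *D* (voxels × frames)
   factorized as *D* ≈ *W* × *S* with *k* = 3 non-negative temporal
   patterns. The *well-perfused* pattern *S*<sub>wp</sub> is the one with
   the largest AUC over the first 90 s; its weight map *W*<sub>wp</sub>
   images the suspicious perfusion.
3. **Segmentation.** ROI<sub>wp</sub> = voxels whose well-perfused weight
   exceeds β = 60 % of their total weight (Otsu thresholding is the
   alternative), cleaned of connected components < 0.05 cc. ROIs below
   0.5 cc are rejected; the rest are assigned to PZ when > 10 % of the
   ROI overlaps the PZ contour, else to the transition zone (TZ). Zone
   voxels outside the ROI become normal-appearing tissue (NAT) masks.
4. **Kinetic features.** The de-noised ROI curve *S*<sub>ROI</sub> =
   mean(*W* rows) × *S* and the muscle curve *S*<sub>GM</sub> are fitted
   to a bi-exponential enhancement model
   *S*(*t*) = *s*₀ + *A*(e<sup>−k₂(t−t₀)</sup> − e<sup>−k₁(t−t₀)</sup>)
   and to a late linear model (270–330 s). Six features are computed:
   early/late AUC (60–120 s, 240–330 s), wash-in (*s*<sub>m</sub>−*s*₀)/τ,
   early/late area under the fitted curve, and wash-out (−late slope) —
   each also as a ratio to the muscle value.
5. **Map of aggressiveness.** With *F* a chosen feature value and
   ω = mean(*W*<sub>wp</sub> | ROI<sub>wp</sub>), every voxel's weight is
   scaled by *F*/ω, so the map averages exactly to *F* inside the ROI; a
   cohort-derived scale (5th/95th percentile bounds, ten uniform bins)
   turns the continuous values into 1–10 scores.

A synthetic phantom module generates pelvic DCE series with ground-truth
anatomy, grade-programmable lesions, Gaussian/Rician noise and injectable
inter-frame motion, so every stage is testable without patient data.

## Worked example

```bash
python examples/03_nmf_segmentation.py
```

prints, for the default one-lesion phantom at baseline SNR 20:

```
relative reconstruction residual: 0.0444
pattern 0: AUC(0-90 s) =  13.70  <- well-perfused
pattern 1: AUC(0-90 s) =   3.59
pattern 2: AUC(0-90 s) =   9.33
ROI_wp: 0.68 cc, zone PZ, rejected=False
Dice overlap with the true lesion: 0.810
```

Pattern 0 wins the early-AUC selection, the 60 % purity rule segments a
0.68 cc PZ habitat, and its Dice overlap with the programmed 1.0 cc
lesion is 0.81. `examples/04_features_map.py` continues the same case to
the feature table and the 1–10 map (median score 10 inside the ROI, 1 in
normal-appearing PZ); the other examples cover the phantom itself, motion
correction, and cohort statistics.

The same pipeline is scriptable from the shell:

```bash
dcehabitat phantom --snr 20 --seed 1 --out ph/
dcehabitat run-all ph/series.nii.gz --prostate ph/masks/prostate.nii.gz \
    --pz ph/masks/PZ.nii.gz --muscle ph/masks/GM.nii.gz --out run/
```

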