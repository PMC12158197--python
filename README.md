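# vegcover

Fractional vegetation cover (FVC) from consumer-grade UAV visible-light
imagery. The package is for ecologists and agronomists who fly low-cost RGB
drones over crops, trees or shrubland and need per-scene canopy cover without
multispectral sensors or radiometric calibration.

## Method

For each pixel with digital numbers *(ρr, ρg, ρb)* the package computes four
visible-band vegetation indices:

| index | formula | range | vegetation side |
|-------|---------|-------|-----------------|
| EXG   | 2ρg − ρr − ρb | [−510, 510] | high |
| VDVI  | (2ρg − ρr − ρb)/(2ρg + ρr + ρb) | [−1, 1] | high |
| RGRI  | ρr/ρg | ≥ 0 | low |
| RGBVI | (ρg² − ρr·ρb)/(ρg² + ρr·ρb) | [−1, 1] | high |

Live canopy reflects green and absorbs red/blue, so vegetation and bare soil
form a high–low bimodal distribution in each index. The segmentation
threshold is read off the **intersection of the class-conditional
histograms**: labelled vegetation and soil pixels are binned on one shared
grid, and within the interval between the two class modes the bin edge that
misclassifies the fewest labelled pixels is selected (vegetation iff
VI ≥ t, or VI ≤ t for RGRI). Coverage is then
F = 100 · n_veg / n_valid over the thresholded mask.

A linear support-vector pixel classifier trained on the same labels provides
the reference ("approximate true") mask; the accuracy battery reports the
confusion matrix, user's/producer's accuracy, Cohen's Kappa
κ = (p_o − p_e)/(1 − p_e), the signed relative extraction error
100·(F_thr − F_ref)/F_ref, the absolute error |F_thr − F_ref| in percentage
points, per-index error SDs, a multi-resolution (ground-sample-distance)
analysis and a ±5% threshold-sensitivity check. A synthetic scene generator
with exact truth masks (blob geometry, colour noise, shadow and mixed
boundary pixels) makes every stage testable without flight data.

## Worked example

`examples/03_full_pipeline.py` generates a 128×128 scene with 60 % true
cover and moderate colour noise, then runs the full chain —
classifier → histograms → threshold → segmentation → coverage:

```text
selected threshold      : 0.21 (VDVI)
threshold coverage      : 60.01%
classifier coverage     : 59.99%
true (generator) cover  : 60.00%
extraction error        : 0.03%  (absolute 0.02 points)
kappa vs classifier mask: 0.9996
```

The VDVI threshold 0.21 sits between the soil mode (≈ 0.01) and the canopy
mode (≈ 0.45); both coverage estimates land within a few hundredths of a
percentage point of the generator's truth, and the near-unit Kappa says the
threshold mask and the classifier mask agree almost pixel-for-pixel. The
other scripts in `examples/` each demonstrate one capability (indices,
threshold selection, resolution analysis, sensitivity, accuracy
statistics).

There is also a thin CLI (`vegcover index|train|classify|threshold|segment|`
`coverage|validate|pipeline|resolution|sensitivity|simulate`) over the same
functions for shell use; `vegcover simulate --help` etc. show the options.

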