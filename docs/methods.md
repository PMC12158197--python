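# Methods

## Scope and model

`vegcover` estimates fractional vegetation cover (FVC) — the percentage of
ground area covered by the vertical projection of canopy — from 3-band 8-bit
UAV orthomosaics. The model is deliberately simple: vegetation and bare soil
occupy distinct regions of the visible-band vegetation-index axis, so a
scene decomposes into a high–low bimodal class-conditional distribution and
one scalar threshold separates the classes. All arithmetic is done on raw
digital numbers; no radiometric or atmospheric calibration is applied, on
the assumption that imagery comes from a single sensor under stable
illumination and that binary vegetation/soil discrimination is insensitive
to absolute radiometry.

## Vegetation indices

Four indices are implemented exactly as defined (EXG, VDVI, RGRI, RGBVI;
formulas in the README). Properties the implementation guarantees and the
tests assert:

- VDVI and RGBVI lie in [−1, 1], EXG in [−510, 510] for 8-bit input, RGRI ≥ 0;
- EXG is homogeneous of degree 1 under a global brightness scaling, the
  other three are scale-invariant — which is why shadows (a multiplicative
  darkening) barely move the normalised indices;
- EXG and VDVI increase strictly in green, RGRI decreases;
- polarity is attached to every index raster: vegetation is *above* the
  threshold for EXG/VDVI/RGBVI and *below* it for RGRI.

Zero-denominator pixels (VDVI: 2g+r+b = 0; RGRI: g = 0; RGBVI: g²+rb = 0)
are flagged invalid rather than clamped. EXG has no denominator, but by
default all-zero (black, typically nodata-fill) pixels are flagged invalid
there too so the four index masks agree; the flag can be turned off.
RGBVI additionally accepts an optional linear scale factor: reported RGBVI
thresholds in the field are sometimes quoted on a scaled axis incompatible
with the normalised [−1, 1] definition, and the factor lets users reproduce
such conventions explicitly rather than guessing a hidden scaling.

## Threshold selection

Labelled vegetation and soil values are binned on one shared grid starting
at `floor(min/width)·width` over the pooled range. Default bin widths are
1.0 for EXG (integer DN arithmetic) and 0.01 for VDVI/RGRI/RGBVI, matching
the precision at which thresholds for these indices are conventionally
quoted. An optional zero-padded centred moving average (odd window) can
smooth both histograms identically; raw counts are always retained, the
default is no smoothing. Note that zero-padding does not conserve class
totals when a class has mass in the outermost `window//2` bins; totals are
conserved exactly whenever the margins are empty, which is the regime in
which smoothing is sensible anyway.

Selection proceeds in three steps:

1. locate each class's mode bin (on the smoothed counts when smoothing is
   on); identical histograms raise a no-separability error, coincident
   modes a degenerate-separation error carrying both mode indices;
2. scan the bins strictly between the modes for the dominance transition —
   the intersection interval runs from the first bin no longer dominated by
   the near class to the last bin not yet dominated by the far class;
3. among all bin-edge candidates strictly between the modes, select the one
   minimising the total number of misclassified labelled pixels under the
   polarity rule. Ties break toward the soil mode (misclassifying as little
   vegetation as possible). If zero error is attainable the classes are
   separated by a gap, and the midpoint of the zero-error edge run is
   reported instead of an arbitrary edge.

Counting on the histogram is exact for bin-edge thresholds under numpy's
half-open `[low, high)` bins: a value equal to an edge falls in the bin
starting there, which matches the closed-on-the-vegetation-side decision
rule `VI ≥ t` for veg-high polarity. For veg-low polarity the mass of the
bin starting at the threshold is treated as above-threshold; the
exact-equality mass cannot be recovered from a histogram, and for
continuous-valued data it is null. The misclassification-minimum rule (as
opposed to "first crossing") makes the choice deterministic and auditable,
and the tests verify it against an exhaustive search over every bin edge.

## Reference classification

The reference mask comes from a two-class support-vector classifier
(scikit-learn `SVC`), linear kernel, C = 1.0 by default — the smallest
defensible configuration for a margin classifier when nothing more is known
about the feature geometry; kernel, C and γ are exposed in
`ClassifierConfig`. Features are the raw (r, g, b) triple by default, or a
single vegetation index for like-for-like comparison with the threshold
rule (this single-index mode is also what the multi-resolution analysis
uses). Any estimator with `fit`/`predict` over pixel-feature rows can be
substituted. No spatial regularisation or morphology is applied to masks;
classification is strictly per pixel.

## Error statistics

With F_thr the threshold coverage and F_ref the classifier coverage (the
"approximate true value" — it is itself a model output, not ground truth,
and the reports keep that caveat):

- extraction error (signed, relative, %): 100·(F_thr − F_ref)/F_ref;
- absolute error (percentage points): |F_thr − F_ref|;
- per-index spread: sample SD (n − 1 denominator) of the absolute errors
  across vegetation types.

These definitions were fixed by checking them against published tables of
coverage pairs and their printed error columns: the signed column is
relative percent, the absolute column is percentage points, and the SD
column is the sample SD of the absolute errors. A few printed cells differ
from recomputation by ±0.01 (rounding of unrounded upstream intermediates
at two decimals); the package rounds only at serialisation and treats those
cells as unreproducible from printed values.

The multi-resolution analysis fixes one index and one threshold (determined
on the finest scene unless supplied), trains the classifier per resolution
in single-index feature mode, and uses the *mean* of the per-resolution
classifier coverages as the common reference, since no single resolution is
privileged. Labels are defined on the finest grid and mapped to coarser
grids by the GSD ratio (integer scaling, deduplicated). The sensitivity
check evaluates overall accuracy against the labelled pixels at t·(1 ± p/100)
and reports the largest absolute change; perturbed thresholds outside the
observed index range are clipped with a warning.

Cohen's Kappa uses p_e from the row/column marginals; a degenerate marginal
(p_e = 1) raises rather than returning NaN. The test suite cross-checks
Kappa against scikit-learn's independent implementation on random matrices.

## Synthetic scenes

The generator emulates the statistical structure the threshold method
relies on, not radiative-transfer realism:

- **geometry**: a Gaussian-smoothed white-noise field (blob scale 8 px by
  default) thresholded at the exact order statistic for the target cover,
  so patches have extended boundaries and the realised coverage equals the
  target up to one pixel's worth of rounding;
- **colour**: truncated (clipped to [0, 255]) Gaussians around class means
  (60, 160, 60) for canopy and (150, 120, 90) for soil, per-band SD 10 —
  a moderately noisy, well-separated sunlit scene;
- **shadow**: a fraction (default 0.05) of vegetation pixels darkened
  multiplicatively by 0.4, still labelled vegetation — shadows preserve
  chromaticity, so the scale-invariant indices are nearly unaffected while
  EXG is not, mirroring why normalised indices are preferred;
- **mixed pixels**: pixels within a band (default 1 px) of the class
  boundary get a linear colour blend weighted by distance, truth label
  unchanged;
- block-average downsampling with majority-vote truth (vegetation wins
  ties) emulates flying the same scene at coarser ground sample distance.

What the scenes do **not** emulate: within-class spectral gradients
(phenology, soil moisture), correlated texture, specular highlights,
georeferencing artefacts, and between-species spectral overlap. Passing the
synthetic battery therefore demonstrates the correctness and stability of
the machinery — exact coverage recovery in the noiseless limit, ≤ 2.5-point
recovery under moderate noise, threshold placement at the analytic
equal-density crossing — not field accuracy on arbitrary real scenes.

## Numerical and design choices

- All statistics in float64; rounding to two decimals only at CSV/JSON
  serialisation.
- Candidate thresholds are bin edges (plus the gap midpoint in the
  separable case), never bin centres.
- Pixel coordinates are 0-based, row-major, origin top-left; every label
  CSV carries a header comment stating the convention.
- Raster I/O uses `tifffile` (TIFF with the GSD stored in the resolution
  tags) and Pillow (PNG); masks are uint8 with 1 = vegetation, 0 = soil,
  255 = nodata; VI rasters are float32 with NaN nodata.
- All file writes are atomic (temp file + rename); a failed stage never
  leaves a partial artifact, and the run log records the config hash, seed
  and input checksums.
- Problem sizes in the tests and the acceptance script (scenes of 128²–512²
  pixels, 20-scene recovery sweeps, 10⁵-sample histogram recovery) were
  chosen as the smallest sizes at which the estimators' sampling noise is
  comfortably below the tolerances being checked.

## Known limitations

- The intersection rule assumes a bimodal scene; heavily mixed or
  continuously vegetated scenes violate the premise and raise degeneracy
  errors rather than returning a meaningless threshold.
- The classifier reference is circular to the extent that both methods see
  the same colour space; agreement between them bounds consistency, not
  truth. The synthetic scenes, where exact truth exists, close that gap in
  testing only.
- Multiple-scene mosaics, terrain correction and area weighting are out of
  scope; coverage is a per-scene pixel fraction.
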