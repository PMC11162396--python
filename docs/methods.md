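# Methods

This note documents the models, defaults and numerical choices behind
`cryodist`, and what the synthetic validation does and does not
establish.

## The measurement chain being modelled

A tissue block containing a fluorescently labelled drug depot is
embedded in a blackened medium, sectioned at a fixed slice thickness,
and the *remaining block face* is photographed after every cut in a
fluorescence channel and a reflection channel. The stack is resampled to
an analysis voxel grid, the fluorescent region is segmented above a
fixed intensity threshold while excluding autofluorescent tissue, and
the segmented volume is reported as the fluorescent drug volume — a
proxy for, not an estimate of, the injected volume. The pipeline
defaults mirror that setup: 48 µm slices, 13.66 µm pixel pitch, a
27.4 × 27.4 × 35.0 µm analysis grid (voxel volume 26 276.6 µm³), a
segmentation threshold of 2000 counts on a 16-bit scale, and a
0.9527 g/mL suspension density for residual-dose conversion.

## Phantom generator

The phantom is a fine isotropic grid (default 20 µm spacing; the
pipeline config enforces spacing ≤ half the coarsest acquisition
interval) holding a fluorophore concentration field, a tissue mask and a
depot mask. Ground truth is defined by brute force: depot volume =
voxel count × voxel volume.

* **Tissue**: a centred box (default 15 × 15 mm cross-section) inside an
  embedding margin. Autofluorescence is a correlated Gaussian random
  field (mean 300, SD 80 counts, correlation length 150 µm) — smooth
  enough to look like tissue texture, far enough below the 2000-count
  threshold that exclusion rules, not luck, must handle its upper tail
  after bleed-through amplification. The embedding medium is nearly dark
  (50 counts), emulating ink-blackened embedding.
* **Depots**: spheres, axis-aligned ellipsoids, unions of spheres
  ("multilobe", papule-like) and unions of capsules ("track_set",
  fractured needle-track-like). Default brightness 2200 counts per grid
  sample (rationale below).
* **Determinism**: all randomness flows from explicit integer seeds;
  identical inputs give bit-identical fields and stacks.

## Acquisition simulator

One fluorescence and one reflection image per section;
`n = ceil(depth / slice_thickness)` faces at depths `k·slice_thickness`.

* **Bleed-through (axial response)**: the instrument's true axial PSF is
  unknown, so the simulator uses the simplest one-parameter stand-in: the
  image at a cut face is the sum over grid samples at and below the face
  weighted by `exp(-depth/λ)`, with unit weight at the face. `λ = 0`
  reproduces ideal surface-only imaging exactly. An *unnormalized* sum
  (rather than a weighted average) was chosen deliberately: every
  pixel's intensity is then non-decreasing in λ, so bleed-through only
  ever adds apparent signal — masks grow nested and the apparent volume
  grows monotonically, which is the qualitative behaviour the optical
  caveat describes and which the validation suite asserts strictly.
  A weighted average would instead trade signal between faces inside and
  above the depot with no guaranteed direction. The price is that
  absolute intensities depend on the simulation grid spacing (the sum is
  per sample); defaults are stated at the 20 µm default grid. Default
  λ = 25 µm: detection depths in blackened block-face preparations are a
  few tens of µm, well under the 48 µm slice pitch.
* **Brightness**: depot concentration defaults to 2200 counts/sample so
  that after the default bleed-through amplification (×≈1.8 at 20 µm
  grid) the depot plateau sits ≈2× the 2000-count threshold above
  background — the regime a "pragmatically chosen" fixed threshold
  presupposes, with the threshold near the half-amplitude level that
  minimizes blur-induced boundary bias. This is a design choice of the
  stated synthetic world, made once, not a tuned constant.
* **In-plane PSF**: isotropic Gaussian, default σ = 1 pixel (13.66 µm).
* **Noise**: Poisson shot noise with a gain (default 2) plus additive
  Gaussian read noise (default SD 20), then clipping and quantization to
  the configured bit depth (default 16). Default SNR for a depot is
  ≈40–80, comfortably above the ≥10 regime the recovery suite assumes.
* **Reflection channel**: tissue mask at the cut face mapped between a
  dark background (200) and a bright tissue level (20 000), same noise
  model — enough contrast for automatic (Otsu) border reconstruction.

## Reconstruction

Resampling runs in physical coordinates (µm), never index scaling,
because the in-plane (13.66 → 27.4) and axial (48 → 35.0) factors
differ. The `linear` method uses bilinear point sampling in-plane and an
**area-weighted linear kernel along z**: each output value is the exact
mean of the piecewise-linear z-interpolant over the output voxel's 35 µm
axial window, computed from the interpolant's antiderivative. Since
consecutive windows tile depth, the z-integral of an interior feature is
conserved exactly at any section phase — plain point-sampled trilinear
interpolation shows phase-dependent intensity errors up to ±11% for a
single bright section, which would corrupt volume accounting.
Constancy and min/max bounds are preserved (to floating-point
round-off). `nearest` is pure nearest-neighbour for mask-like data and
gives exact identity resampling at the source spacing. Edges clamp to
the boundary sample. Output is floating point; thresholds compare
against it directly.

## Segmentation

"Excluding autofluorescent tissue as much as possible" is not an
algorithm, so it is operationalized as three separately testable rules:
(i) candidates must lie inside the reflection-derived tissue mask
(largest 26-connected component of the Otsu split, holes filled);
(ii) components smaller than `min_component_voxels` (default 8 voxels
≈ 0.0002 µL) are dropped; (iii) optionally, candidates brighter than a
given percentile of tissue reflection are removed. Fixed conventions,
declared for reproducibility: strict `value > threshold`,
26-connectivity, threshold applied post-resampling on the resampled
intensity scale. The exclusion ledger always balances:
candidates = kept + excluded.

## Quantification

* Volume: voxel count × voxel volume, µL; per-component volumes sum to
  the total exactly.
* Shape: principal extents from the inertia-aligned bounding box (padded
  by the voxel footprint so a single voxel reports the voxel size);
  maximum depth of any segmented voxel; sphericity
  Ψ = π^(1/3)(6V)^(2/3)/A with A from a marching-cubes mesh — voxel-face
  area counting overestimates A by tens of percent for round bodies and
  was rejected; fragmentation = component count.
* Residual dose: V_res[µL] = 1000·m[g]/ρ with ρ = 0.9527 g/mL
  (conversion factor 1/ρ = 1.0496 mL/g, reported to 4 decimals);
  fractions above 100% of the injected dose are flagged, not rejected.
* Group statistics: per-group mean and sample SD (n−1; groups of three
  are the norm here), pooled mean across all samples (equal to the
  unweighted mean of group means for equal n), and half-up integer
  rounding for display (248.5 → 249) matching table precision.

## What the synthetic validation establishes — and what it does not

The recovery suite (20 sphere/ellipsoid phantoms, 0.2–2 µL, default
pipeline) recovers volumes with a median relative error of a few
percent, systematically positive: bleed-through and the fixed threshold
inflate the apparent volume, and the inflation grows strictly with the
attenuation length — the optical caveat made quantitative. Green tests
therefore establish that the *measurement chain* is implemented
consistently: geometry, resampling, thresholding, component analysis and
unit conversions do what they claim on a world whose ground truth is
known.

They do not establish accuracy on real tissue. The phantom's
autofluorescence is a stationary Gaussian texture, not structured
collagen; optical properties are uniform and tissue-independent, whereas
keloid and normal skin scatter differently; the axial response is an
assumed exponential, not the instrument's measured PSF; and no
registration error, sectioning artefacts or surface smearing are
simulated. Absolute fluorescent volumes remain comparative measures, as
in the real study.

## Degenerate inputs and tie-breaks

Otsu on a constant volume raises a dedicated error directing to the
fixed method; an empty tissue mask is an error, an empty fluorescence
segmentation is a valid zero-volume result; shape metrics on an empty
mask raise; a crop or depot outside its bounds raises a geometry error;
residual fractions > 100% flag measurement error. Thresholds use strict
inequality; nearest-neighbour z-lookup rounds half up via `rint`.

## Known limitations

Simulated intensities are arbitrary counts (exposure is a unitless
scale); no spectral model beyond two abstract channels; no deconvolution
or inter-slice registration (block-face geometry is registered by
construction); group statistics are descriptive only — the emulated
study performs no inferential testing.
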