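# cryodist

Quantifying the 3D biodistribution of an intralesionally injected drug —
how much ended up in the tissue, in what shape, and how much never made
it in — from serial block-face fluorescence imaging of tissue blocks.

The motivating application is corticosteroid (triamcinolone acetonide,
TAC) injection into keloid scars: a fluorescently labelled 100 µL dose is
injected ex vivo by needle or needle-free jet injector, the block is
frozen, sectioned at 48 µm, and after every cut the remaining bulk is
photographed in a fluorescence channel (595/620 nm) and a reflection
channel (549 nm) that delineates the tissue border. The resulting
anisotropic image stack is resampled to a 27.4 × 27.4 × 35.0 µm voxel
grid, the fluorescent drug region is segmented above an intensity
threshold of 2000 counts while excluding autofluorescent tissue, and the
segmented volume — the *fluorescent drug volume*, a proxy for the
injected dose — plus 3D shape descriptors are reported per sample and
summarized per technique.

Because block-face imaging sees a short distance *into* the block,
subsurface fluorescence bleeds into every image and inflates the apparent
volume. No study data are redistributable, so the package ships a phantom
generator that simulates the whole acquisition with a known ground-truth
depot; every pipeline stage is validated by recovery experiments against
that truth, including a quantitative version of the bleed-through bias.

## What's inside

| module | role |
| --- | --- |
| `cryodist.phantom` | synthetic tissue blocks (autofluorescent texture, embedding medium) with sphere / ellipsoid / multilobe / needle-track depots; block-face acquisition simulator (depth-weighted bleed-through, Gaussian PSF, Poisson + Gaussian noise, quantization) |
| `cryodist.stack_io` | TIFF series + JSON sidecar storage of section stacks; cropping |
| `cryodist.reconstruct` | physical-coordinate resampling of the anisotropic stack (13.66 µm in-plane / 48 µm axial) onto the analysis voxel grid |
| `cryodist.segment` | tissue border from the reflection channel (Otsu or fixed); threshold segmentation with autofluorescence-exclusion rules; 26-connected components |
| `cryodist.quantify` | fluorescent volume (µL), principal extents / max depth / sphericity / fragmentation, gauze-mass → residual-volume conversion, group mean ± SD tables |
| `cryodist.pipeline` | one validated config driving simulate → reconstruct → segment → quantify, with config-hash provenance and replicate helpers |

Key quantities, in the field's usual notation: a segmentation mask M on a
voxel grid with voxel volume v gives the fluorescent volume
V = |M| · v (reported in µL, 1 µL = 10⁹ µm³); sphericity is
Ψ = π^(1/3) (6V)^(2/3) / A with A the marching-cubes surface area;
residual dose converts gauze mass gain m (g) to volume via the suspension
density ρ = 0.9527 g/mL, V_res = m/ρ (equivalently a factor of
1.0496 mL/g).

## Worked example

`examples/` contains one narrative script per capability. Running
`python examples/01_simulate_phantom.py` followed by
`python examples/02_reconstruct_and_segment.py` prints:

```
ground-truth depot volume : 0.9986 µL
sections emitted          : 50 (= ceil(2400 µm depth / 48 µm slices))
image size                : (323, 323) px at 13.66 µm pitch
...
analysis volume            : (68, 161, 161) voxels of 26276.6 µm³
tissue Otsu threshold      : 3979 counts
fluorescent components     : 1
fluorescent volume         : 1.0344 µL
```

A 1 µL spherical depot (radius 620.35 µm, chosen so 4/3·π·r³ = 10⁹ µm³)
was simulated, imaged, reconstructed and recovered as a single segmented
component of 1.03 µL — the ~3% excess is the systematic inflation caused
by optical bleed-through and the fixed threshold, which
`examples/03_shape_metrics.py` through `05_full_pipeline.py` and the test
suite explore further (shape contrast between compact boluses and needle
tracks, residual-dose arithmetic, triplicate reproducibility).

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's end-to-end measurement from scratch — generates
the default 1 µL sphere phantom under the given seed, simulates the
acquisition, reconstructs, segments and quantifies it — prints the
recovered vs true volume, and writes the results JSON to `--out`.
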