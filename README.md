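# monorelief

Closed-form monocular relief reconstruction for biological image analysis.
Given a single photograph and a hand-drawn region-of-interest mask,
`monorelief` recovers an implied (relative, non-metric) height map of the
surface in three steps:

1. **Intrinsic image decomposition** — split the image `I = R × S` into a
   monochromatic shading map `S` and per-channel reflectance `R` by solving
   a Retinex-regularised sparse least-squares problem in log colour-space
   (Retinex gradient term, texture-patch term, and a scale term pinning the
   brightest pixels).
2. **Normal estimation** — estimate the illumination azimuth from the
   dominant shading gradient (incident elevation fixed at 45°), then
   recover per-pixel unit normals from the Lambertian relation
   `S = ⟨D, N⟩` with normal-smoothness and reflectance-edge constraints,
   again as a sparse least-squares problem.
3. **Height integration** — convert normals to the height gradient
   `∇H = −(Nx/Nz, Ny/Nz)`, integrate it over the ROI by least squares with
   one border pixel anchored at zero, subtract the best-fit plane, and
   min-max normalise for display.

A synthetic Lambertian scene generator (`monorelief.synthetic`) provides
ground-truth height/reflectance/light bundles — curled sheets, hemispheres,
Mondrian patches, spots, stripes, eyespots — so every stage is validated
against known answers, including the "false depth" effect where flat
high-contrast patterns reconstruct as nonzero relief.

## CLI

```sh
# generate a ground-truth synthetic scene
monorelief synth curled_leaf_like --seed 0 --size 128 --out scene/

# reconstruct a photo (or the synthetic rendering) within an ROI mask
monorelief reconstruct scene/rendered.png --mask scene/mask.png \
    --out result/ --no-srgb-linearize

# score the pipeline against a scene's ground truth
monorelief evaluate scene/
```

`reconstruct` writes `R.png`, `S.png`, `N.png` (normal map, RGB = x/y/z
components), `H.png` (height, 0 = black far, 255 = white near), `H.tif`
(float32 height) and `report.json` (config hash, seed, input hashes,
residuals — enough to reproduce the run exactly). `--export-mesh` adds an
ASCII PLY surface mesh. Runs are fully deterministic.

A complete default configuration is shipped at `configs/default.toml`;
pass a modified copy via `reconstruct --config`. Camera images are assumed
sRGB-encoded and are linearised before analysis unless
`--no-srgb-linearize` is given (synthetic scenes are already linear).

## Layout

- `src/monorelief/raster_io.py` — image/mask I/O, log colour-space, normal
  and height map display encodings, PLY export
- `src/monorelief/intrinsic.py` — Retinex/texture/scale decomposition
- `src/monorelief/normals.py` — light-direction estimation, Lambertian
  normal solver
- `src/monorelief/height.py` — gradient integration, plane detrending
- `src/monorelief/synthetic.py` — ground-truth scene generation
- `src/monorelief/pipeline.py`, `cli.py` — orchestration, recipes, CLI
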