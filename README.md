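# ctmorph

3D micro-CT plant-tissue morphometry: synthetic tissue phantoms with voxel-exact
ground truth, cell segmentation of control and contrast-enhanced volumes,
per-cell 3D measurements with VOI-level summaries, and rigid + anisotropic-scale
registration with XOR change quantification.

The package analyzes greyscale voxel volumes (multi-page TIFF, 8- or 12/16-bit,
isotropic voxel size in µm) through the stage chain

```
classify intensities → despeckle/open → watershed separation → border kill
→ debris filter (diameter / sphericity) → edge-constrained volume recovery
→ per-cell morphometry → VOI summary
```

Because no real scan data ships with the package, the `phantom` module
generates parenchyma-like tissue volumes (Voronoi tessellation of Poisson-disc
seeds, carved intercellular air channels, optional bright cell boundaries,
flooded airspace, vasculature tubes and stone-cell clusters) with exact
ground-truth labels, so every stage is testable end to end.

## CLI

One entry point, `ctmorph`, with five subcommands:

```sh
# synthetic volume + ground truth (porosity presets: apple 0.20, pear 0.10, tomato 0.05)
ctmorph phantom --out out/ph --shape 128 128 128 --preset pear --contrast \
    --noise-sd 8 --seed 1

# greyscale volume -> label TIFF + cell table CSV
ctmorph segment out/ph/greyscale.tif --out out/seg --mode enhanced --preset pear

# label volume -> cell table + VOI summary
ctmorph measure out/seg/labels.tif --out out/meas

# register two volumes and quantify the XOR difference
ctmorph compare fixed.tif moving.tif --out out/cmp

# full pipeline from a YAML config
ctmorph run --config run.yaml --seed 1
```

A minimal `run.yaml`:

```yaml
mode: enhanced
preset: pear
seed: 1
phantom:
  shape: [128, 128, 128]
  voxel_size: 2.5
  target_porosity: 0.10
  noise_sd: 8.0
  random_seed: 1
```

Tissue presets bundle the analysis settings: VOI edge (apple/pear 2400 µm,
tomato 2000 µm) and debris filters (apple: 40–200 µm diameter and
sphericity > 0.75; pear: no lower bound, < 200 µm, sphericity > 0.75;
tomato: > 100 µm, sphericity > 0.75). VOIs below the minimum representative
volume of 1.3 mm³ are rejected.

## Library layout

| module | contents |
| --- | --- |
| `ctmorph.core` | `VolumeImage` (data + voxel size + bit depth), axis convention (z, y, x) |
| `ctmorph.phantom` | `PhantomSpec`, `generate_tissue`, `add_imaging_noise`, `add_inclusions` |
| `ctmorph.volume_io` | TIFF stack / slice-directory I/O, 12→8-bit rescale, cell-table CSV |
| `ctmorph.segmentation` | multi-Otsu classes, 3D Sobel, cleanup, watershed, border kill, filters, volume recovery, dense-structure extraction |
| `ctmorph.morphometry` | equivalent diameter, mesh surface area, sphericity, anisotropy, `measure_labels`, VOI summaries, SEM, percent increase |
| `ctmorph.registration` | principal-axes pre-alignment, rigid + aniso-scale NCC registration, XOR fraction, corrected cell difference |
| `ctmorph.pipeline` | `RunConfig` / YAML, presets, replicate runs, group t tests |

## Conventions

- Arrays are indexed `(z, y, x)`, 0-based; voxels are isotropic, sizes in µm.
- Label volumes are integer arrays, 0 = background.
- All randomness is seed-controlled; segmentation itself is deterministic.
- 12-bit volumes live in 16-bit containers; the 8-bit rescale maps the
  observed min/max linearly with round-half-away-from-zero.
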