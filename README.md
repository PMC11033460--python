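# ugls

Uncertainty-guided two-stage image segmentation. A coarse segmentation from
a small U-Net-style network is converted, per object, into

* a **potential boundary region (PBR)** — the annular band
  `dilate(P, SE_r) \ erode(P, SE_r)` around the coarse boundary, built with a
  circular structuring element of radius `r`,
* a **boundary uncertainty map (BUM)** — the PBR smoothed by a normalized
  Gaussian (sigma `r`, truncated to an `r x r` window), peaking on the band
  centerline,
* a **background-excluded image (BEI)** — the elementwise product `PBR x I`.

These channels are concatenated (modes `bum`, `ori+bum`, `bei+bum`) and fed
to a second, identically configured network for fine segmentation, which
sharpens object boundaries. The package includes synthetic fundus
(disc/cup) and chest (left/right lung) phantoms so the whole pipeline runs
end to end on a laptop CPU with no external data, plus Dice/MCC/sensitivity/
Hausdorff evaluation with brute-force oracle cross-checks in the test suite.

The segmentation backbone is a hand-written NumPy encoder–decoder (two 3x3
convolutions with instance norm and ReLU per level, max-pool down,
nearest-upsample + conv up, skip concatenation, per-object sigmoid) trained
with RMSprop on `1 − mean Dice`; no deep-learning framework is required.

## CLI

```sh
# 60 lung phantoms, 64x64, split into train/val/test thirds
ugls synthesize --kind lungs --n 60 --size 64 --seed 1 -o data/

# everything in one go: coarse stage, bundles, fine stage, metric CSVs
ugls run-all -i data/ -o out/ --r-m 9 --input-mode bei+bum --seed 1

# or stage by stage
ugls train-coarse -i data/ -o out/coarse --seed 1
ugls make-bundles -i data/ -m out/coarse/coarse.npz -o out/bundles --r-m 9
ugls train-fine   -i data/ -b out/bundles -o out/fine --input-mode bei+bum
ugls evaluate     -i data/ -m out/fine/fine.npz -b out/bundles -o out/eval
```

Training flags: `--lr` (default 0.001), `--batch-size` (8), `--epochs`
(100), `--patience` (20), `--threshold` (0.5), `--base-filters`, `--depth`,
`--r-m`, `--r-g` (defaults to `--r-m`; shared radii work best), `--seed`,
`--no-augment`, or a YAML `--config` file (flags win). Radii are quoted at
256x256 resolution in the source protocol; `ugls.training.scale_radius`
maps them to other image sizes (e.g. 35 → 9 at 64x64).

Every training/evaluation command writes a resolved-config snapshot
(`config.yaml`, including the seed) and logs to `run.log` in its output
directory. Datasets use a plain directory layout (`images/*.png` 16-bit,
`masks/<object>/*.png` 0/255, `split.json`); BUMs/BEIs are 32-bit float
TIFF.

## Package layout

| module | contents |
| --- | --- |
| `ugls.imaging` | masks, circular structuring elements, dilate/erode, PBR/BUM/BEI |
| `ugls.metrics` | Dice cost, confusion, MCC, sensitivity, boundary Hausdorff, aggregation |
| `ugls.backbone` | NumPy U-Net (forward/backward), RMSprop, binarize, checkpoints |
| `ugls.training` | augmentation, early-stopped training loop, subset rotation, two-stage pipeline |
| `ugls.preprocessing` | normalization, reference-patch extraction, resizing |
| `ugls.synthetic` | fundus/lung phantoms, coarse-mask perturber, dataset generator |
| `ugls.datasets` | directory layout, PNG/TIFF readers and writers |
| `ugls.cli` | `ugls` command group |
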