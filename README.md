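# cestlab

An end-to-end laboratory for denoising synthetic CEST-MRI data:

* **Phantom generation** — randomized layered-geometry 2D label maps with
  per-region multi-pool (2–5 pool) exchange parameters drawn from published
  simulation ranges (`cestlab.phantom_geometry`).
* **Bloch–McConnell simulation** — pulsed Gaussian saturation, matrix-
  exponential propagation, voxel-wise Z-spectra rendered into H×W×offsets
  volumes (`cestlab.bm_simulator`).
* **Noise model** — Gaussian noise added to the real/imaginary k-space
  channels with a unitary FFT, magnitude reconstruction, random 50→41 offset
  cropping, and robust (Haar-MAD) sigma estimation (`cestlab.noise`).
* **Analytical denoisers** — spectral PCA with *median*, *Nelson* and
  *Malinowski* component-selection criteria, non-local means, and a two-pass
  (hard-threshold + Wiener) BM3D with a 3D DCT (`cestlab.denoise_classic`).
* **Neural denoisers** — UNet and ResUNet autoencoders in noise-estimation
  (`*-NE-yes`: predict the noise, subtract) and direct (`*-NE-no`) modes,
  trained with Adam + ReduceLROnPlateau and per-epoch noise/crop
  augmentation. Implemented in pure NumPy with hand-written backprop so no
  deep-learning framework is required (`cestlab.denoise_nn`).
* **Metrics & benchmark** — pooled PSNR (MAX=1), spectral-minimum B0
  self-correction, MTR_asym maps with per-ROI statistics, and a
  sigma-sweep benchmark harness (`cestlab.metrics`, `cestlab.bench`).

## CLI

```bash
cestlab generate phantom.nii --seed 1 --grid 128 --dyn 50
cestlab noisify phantom.nii noisy.nii --sigma 0.1 --seed 7
cestlab denoise noisy.nii out.nii --method "PCA-Median"
cestlab denoise noisy.nii out.nii --method "NLM BW_21_SW_5"
cestlab denoise noisy.nii out.nii --method "BM3D WS_11_BS_4"
cestlab train --config train.yaml --out model.npz
cestlab denoise noisy.nii out.nii --method resunet --checkpoint model.npz
cestlab evaluate phantom.nii out.nii
cestlab benchmark --preset smoke --out bench.csv
```

Volumes are written as NIfTI (`.nii`) with a JSON sidecar carrying the
offset axis (ppm), M0 reference, mask and provenance metadata. Any integer
label-map NIfTI (e.g. an anatomical atlas slice) can be passed to
`generate --label-map` to use as evaluation geometry.

Training configs are YAML:

```yaml
model: {arch: resunet, noise_estimation: true, depth: 4, in_channels: 41, base_channels: 64}
train: {epochs: 30, batch_size: 40, lr: 0.01, weight_decay: 1.0e-6, sigma_range: [0.0, 0.2], seed: 0}
data:  {n_phantoms: 10000, grid: 128, dyn: 50}
```

The defaults above are the full-scale recipe and are impractical on a
laptop CPU; the test suite uses small smoke-scale variants of the same
pipeline.

## Notes

* PCA component-selection formulas are reconstructions of the criteria the
  benchmark names (they are not uniquely fixed by their common names); the
  committed rules are documented in `cestlab.denoise_classic`.
* BM3D is a faithful but compact two-pass implementation tuned for the
  small images used here, not a performance-optimised port.
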