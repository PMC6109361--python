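# mfsr — multi-scale fusion networks for MR image super-resolution

`mfsr` re-implements a slice-wise deep-learning pipeline for structural MR
image super-resolution built around *multi-scale fusion units*: blocks with a
main convolution path (conv + ReLU) and one or more sub-paths whose outputs
are summed in a fusion layer. Networks stack a few of these units plus a
single-kernel reconstruction convolution and are trained end-to-end with a
Euclidean loss on 33×33 LR/HR patch pairs under the pre-upsampling
convention (the low-resolution input is bicubically interpolated onto the
high-resolution grid before entering the network).

Everything runs on CPU with NumPy — the networks involved are tiny (≈25k
parameters), so no deep-learning framework is required.

## What's inside

| module | role |
| --- | --- |
| `mfsr.phantom` | synthetic multi-tissue brain phantoms (nested ellipses, bias field, optional noise) with masks, plus the edge-residual-energy analysis |
| `mfsr.degrade` | degradation model `L = DSH + e` (blur, integer downsampling, bicubic re-upsampling), masked patch-pair extraction, HDF5 patch container |
| `mfsr.network` | declarative network specs in `s_k/n_k` table notation, seeded Gaussian init, fully convolutional forward + analytic backward |
| `mfsr.training` | Euclidean-loss momentum SGD with seeded batch order, validation-PSNR traces, convergence-index analysis |
| `mfsr.metrics` | masked RMSE / SNR / PSNR / SSIM with the conventions that reproduce published bicubic benchmarks (R = 255 on 0–255 rescaled intensities) |
| `mfsr.experiments` | named architecture variants, paired-seed sweeps, fusion-vs-plain-CNN convergence comparison, feature-map montages |
| `mfsr.io`, `mfsr.pipeline`, `mfsr.cli` | NIfTI I/O, end-to-end orchestration, subcommand CLI |

## CLI

```bash
mfsr phantom out/phantom.nii.gz --seed 1 --subjects 1       # generate a phantom + mask
mfsr degrade out/phantom.nii.gz out/lr.nii.gz --scale 3     # blur + downsample + bicubic
mfsr train   out/phantom.nii.gz out/run --scale 3 --budget 2000 --lr 1e-4
mfsr reconstruct out/lr.nii.gz out/run/checkpoint.npz out/sr.nii.gz --scale 3
mfsr evaluate out/phantom.nii.gz out/sr.nii.gz --scale 3 --out out/metrics.csv
mfsr ablate  out/sweep --variants MFCN_BL,MFCN_BL_relu_fusion --budget 500
mfsr featuremaps out/run/checkpoint.npz out/phantom.nii.gz out/maps
```

Exit codes: 0 success, 2 configuration error, 3 data error, 4 training
divergence. Network specs are YAML files mirroring the table notation:

```yaml
units:
  - main: 9/32
    subpaths: [["1/32"]]
  - main: 3/64
    subpaths: [["1/64"]]
recon: 5/1
```

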