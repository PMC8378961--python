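# mcrn

Single-image super-resolution with a multichannel residual attention
network: dilated multichannel residual feature extraction, iterative
up/down back-projection with error feedback, channel attention, and
subpixel reconstruction — plus the training recipe (L1 loss, Adam,
lr 1e-4), evaluation metrics (PSNR, SSIM, information entropy, average
gradient) and a synthetic short-axis cardiac phantom generator so the whole
pipeline runs at desk scale without any downloads.

Everything is pure numpy/scipy: the package ships a minimal reverse-mode
autodiff engine (`mcrn.nn`) with exactly the primitives the network needs
(convolution, transposed convolution, dilated convolution, PReLU, sigmoid,
pixel shuffle), pinned by finite-difference gradient checks.

## Library layout

| module         | contents                                                             |
|----------------|----------------------------------------------------------------------|
| `mcrn.data`    | `ImageGray`, phantom generator, bicubic resize (Catmull-Rom a=-0.5), 16x augmentation, LR/HR patch pairs, PNG/NIfTI I/O |
| `mcrn.nn`      | numpy autodiff: `Tensor`, `conv2d`, `conv_transpose2d`, `prelu`, `pixel_shuffle`, ... |
| `mcrn.model`   | network blocks (`init_features`, `dilated_multichannel_block`, `up_block`, `down_block`, `channel_attention`, `reconstruct`, `mcrn_forward`), checkpoints |
| `mcrn.metrics` | `psnr`, `ssim`, `shannon_entropy`, `average_gradient`, `evaluate_pair` |
| `mcrn.train`   | `TrainConfig`, `Adam`, `train_model` (deterministic + resumable), `evaluate_model` (vs. bicubic baseline) |
| `mcrn.cli`     | the `mcrn` command line                                              |

## CLI

```sh
# synthetic phantom corpus
mcrn phantom --n 20 --size 128 --seed 7 --out corpus/

# train (desk preset: 16 channels, 2 up/down stages, CPU-friendly)
mcrn train --data corpus/ --out run/ --preset desk --scale 2 --seed 1

# super-resolve one image
mcrn sr --ckpt run/model.npz --in lr.png --out sr.png

# score reconstructed images against references
mcrn eval --ref hr_dir/ --test sr_dir/ --scale 2 --json report.json
```

Configuration precedence is CLI flag > `--config` file (YAML/JSON) > built-in
defaults; unknown config keys are rejected by name. Every artifact-producing
run writes `run.json` (resolved config + seed + version) next to its outputs.
Exit codes: 2 usage, 3 config, 4 I/O, 5 shape.

## Notes

- Images are canonicalized to float in [0, 1]; 8/16-bit quantization happens
  only at I/O and metric boundaries.
- Metrics follow the common SR benchmark protocol: 8-bit grayscale, border
  shave = scale factor, SSIM with an 11x11 Gaussian window (sigma 1.5).
  PSNR is the standard 10*log10(L^2/MSE).
- Training is bit-deterministic for a fixed seed, and checkpoints carry
  optimizer moments plus the sampler RNG state, so a resumed run reproduces
  the uninterrupted one exactly.
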