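# saxseg

Left-ventricle / myocardium segmentation from short-axis cardiac MR slices
with a compact 15-layer fully convolutional network (FCN), implemented in
pure NumPy (forward, backprop, and the SGDM/Adam/RMSProp solvers).

The pipeline:

1. **Data** — either convert 3D NIfTI volumes (EMIDEC-style layout, label
   codes 0–4) into per-slice 8-bit PNGs, or generate synthetic phantom
   slices (a bright disk cavity inside an annular myocardium on a noisy
   background) so everything is testable offline. Conversion applies the
   min/max 8-bit normalization `round(255 * (x - min)/(max - min))` (a
   {0,1,2} label matrix becomes {0,128,255}), remaps the 5 label codes to
   3 classes (`{0→0, 1→1, 2→2, 3→2, 4→2}`), and resizes to 256×192
   (bilinear for images, nearest-neighbor for masks).
2. **Class weights** — inverse-frequency weights `w_c = 1/(C·f_c)` computed
   on the training split, so `w_c·f_c = 1/C` for every present class and
   the dominant background class stops swamping the loss.
3. **Network** — encoder (3×3 conv 16 → BN → ReLU → 2×2/2 max pool →
   3×3 conv 32 → BN → ReLU → 3×3 conv 64 → BN → ReLU), decoder (4×4
   stride-2 transpose conv 16 → 3×3 conv C → softmax → pixel
   classification). 40,210 learnables at C=2; fully convolutional, so the
   parameter count is independent of input size.
4. **Training** — weighted cross-entropy (normalized by the applied
   weights), mini-batch solvers `sgdm`/`adam`/`rmsprop`, per-iteration
   accuracy/loss history, and a hyper-parameter sweep over
   solver × learning-rate × epochs × mini-batch.
5. **Metrics** — accumulated confusion matrix; per-class and aggregate
   Dice, Jaccard, sensitivity, specificity, PPV, NPV; global/mean
   accuracy, mean and weighted IoU; mean boundary-F1 (BF) score with a
   default tolerance of 0.75 % of the image diagonal.

## CLI

```bash
# synthetic dataset (images/, masks/, manifest.csv)
saxseg phantom --n 100 --seed 0 --out runs/demo

# or convert NIfTI volumes instead
saxseg convert --in /path/to/emidec --out runs/demo

# weights -> training -> evaluation -> prediction
saxseg weights  --out runs/demo
saxseg train    --out runs/demo --solver adam --lr 0.001 --epochs 30 --mini-batch 4
saxseg evaluate --out runs/demo
saxseg predict  --out runs/demo --image runs/demo/data/images/case000_s000.png

# solver/LR grid in one table
saxseg sweep --out runs/demo --solvers adam,sgdm,rmsprop --lrs 0.01,0.001
```

Every command also accepts `--config cfg.yaml` (a serialized `RunConfig`);
each stage appends a line to `manifest.jsonl` with the config hash and its
outputs, and re-running from the saved config reproduces the run exactly.

## Layout

```
src/saxseg/
  phantom.py      synthetic labeled slices + dataset splitting
  conversion.py   NIfTI -> PNG, normalization, label remap, resizing
  weighting.py    inverse-frequency class weights
  nn/             layers (im2col conv, BN, pooling, transpose conv),
                  network spec/builder, solvers
  training.py     weighted cross-entropy, training loop, sweep
  metrics.py      confusion matrix, overlap metrics, BF score
  pipeline.py     staged runs with manifests
  cli.py          click commands
```
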