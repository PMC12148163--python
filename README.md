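# scrnet

A pure-NumPy toolkit for a family of **lightweight underwater object
detectors** and the accounting that justifies calling them lightweight.

Benthic surveys (sea urchins, sea cucumbers, starfish, scallops) increasingly
run detection on small embedded platforms where every parameter and every
FLOP counts. This package implements a YOLOv8n-layout anchor-free detector
and three drop-in lightweight substitutions:

* **SPPE** — a spatial-pyramid-pooling block built on an ELAN aggregation
  stream: the left ELAN branch is removed, the first 3×3 convolution is
  replaced by a 5×5 max pool, every activation is ReLU, and the internal
  width is tiny. It replaces SPPF at the end of the backbone (switch `S`).
* **RGE** — a reparameterizable ghost-ELAN feature extractor that replaces
  every C2f block: the bottlenecks are dropped in favour of one RepConv
  stream (3×3 + 1×1 + identity branches at training time, a single fused 3×3
  at inference) plus cheap depthwise 3×3 convolutions that generate duplicate
  feature maps (switch `R`).
* **CFFP** — a cross-scale feature-fusion neck: 1×1 laterals hold all three
  backbone scales at 64 channels, channel-preserving 1×1 refinements precede
  each upsampling, and the bottom-up path fuses with plain 1×1 convolutions
  (switch `C`).

The switches compose: `CRS` (all three) is the full lightweight network.

Beyond the architecture the package provides, all in NumPy (no deep-learning
framework required):

* a small reverse-mode autodiff engine (`scrnet.autodiff`) sufficient to
  *train* these detectors on CPU;
* exact parameter/FLOP profiling by symbolic shape propagation, with an
  independent operator-hook counter as a cross-check (`scrnet.analyzer`);
* train→deploy structural reparameterization with numerical equivalence
  verification (`scrnet.reparam`);
* a deterministic synthetic underwater-scene generator with YOLO-format
  labels, augmentations and degradation transforms — hazing, blur, low
  contrast, imbalanced light (`scrnet.data_synth`);
* detection metrics: greedy IoU matching, PR curves, AP/mAP@0.5, NMS
  (`scrnet.metrics`);
* task-aligned assignment, the composite BCE/CIoU/DFL loss and an SGD
  overfit smoke test (`scrnet.train_smoke`);
* the budget-calibration search that pinned the blocks' free widths
  (`scrnet.calibration`).

## Worked example

```python
from scrnet import build_variant, profile_model, reduction

table = {}
for v in ("baseline", "S", "R", "C", "CS", "CR", "CRS"):
    model = build_variant(v, num_classes=4, input_size=640)
    table[v] = profile_model(model, 640)
    p = table[v]
    print(f"{v:9s} {p.total_params:9,d} params  {p.total_params_M:5.2f} M  "
          f"{p.total_flops_G:4.1f} G")
print("reduction:", reduction(table["baseline"], table["CRS"]))
```

prints

```
baseline  3,011,628 params   3.01 M   8.1 G
S         2,854,140 params   2.85 M   8.0 G
R         2,232,425 params   2.23 M   6.1 G
C         2,068,652 params   2.07 M   7.3 G
CS        1,911,164 params   1.91 M   7.2 G
CR        1,500,094 params   1.50 M   5.2 G
CRS       1,342,606 params   1.34 M   5.1 G
reduction: (55.5, 37.0)
```

i.e. the full lightweight model carries 55.5 % fewer parameters and 37.0 %
fewer FLOPs than the baseline at a 640×640 input with 4 classes. The
`M`/`G` figures are exact integer sums over every convolution (weights,
biases where present, BatchNorm affine terms) converted to Mega/Giga units
and rounded to table precision.

A complete small experiment from the shell:

```bash
scrnet generate --n 50 --seed 7 --img 160 --out data      # synthetic scenes
scrnet train-smoke --variant CRS --n-images 8 --steps 300 --img 64 --ckpt w.npz
scrnet fuse --in w.npz --out w_fused.npz --verify          # reparameterize
scrnet eval --ckpt w_fused.npz --data data/data.yaml       # mAP@0.5
scrnet analyze --variant CRS --per-layer                   # budget breakdown
```

`train-smoke` reports the per-step loss and the train-set mAP@0.5 of the
overfitted model (≥ 0.9 within 300 steps on 8 images); `fuse --verify`
prints the max-abs deviation between the multi-branch and the fused model
per output map (≤ 1e-4 in float32, typically ~1e-7).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

rebuilds each detector variant at 4 classes, recomputes its parameter and
FLOP totals from scratch by shape propagation over the actual weight arrays
(cross-checked against an operator-hook count taken during a real forward
pass), and writes the headline budget figures as JSON. Parameter and FLOP
totals are deterministic quantities: the seed only feeds weight
initialisation and does not affect them.

## Layout

```
src/scrnet/
  autodiff.py     reverse-mode AD over NumPy (conv/BN/pool/...)
  blocks.py       Conv-BN-act, SPPF, SPPE, RepConv, C2f, RGE, detect head
  assembly.py     variant graphs (baseline, S, R, C, CS, CR, CRS)
  reparam.py      BN folding, branch fusion, equivalence verification
  analyzer.py     parameter/FLOP profiles and reduction percentages
  calibration.py  the budget-calibration search for the free widths
  data_synth.py   synthetic scenes, YOLO labels, splits, degradations
  metrics.py      IoU, NMS, matching, PR/AP, mAP@0.5
  train_smoke.py  assignment, loss, SGD, overfit smoke
  config.py       YAML configs and .npz checkpoints
  cli.py          the `scrnet` command
```
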