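# fpnseg

Binary segmentation of brain tumors in 2D MRI slices with a **U-Net/FPN
hybrid**: the contracting path of a U-Net serves as the bottom-up pathway of
a feature pyramid network, and an FPN-style top-down decoder with lateral
1×1 connections, nearest-neighbor merges and multi-level fusion produces the
probability map.  The package is aimed at researchers who want a compact,
fully inspectable implementation of this architecture family — every
gradient is computed by a small numpy autodiff engine that ships with the
package and is finite-difference checked — together with the full
surrounding pipeline: preprocessing, nine-operation augmentation, Dice-loss
training with early stopping, overlap metrics, and a synthetic phantom
generator so that everything runs end to end on one CPU without any
download.

## Model

For predicted pixel set *A* and reference set *B*, training minimizes the
smoothed Dice loss

```
L_dice = 1 − (2·|A∩B| + ξ) / (|A| + |B| + ξ),    ξ = 100
```

(soft relaxation: |A∩B| = Σ p·g).  Evaluation reports

```
DSC = 2|A∩B| / (|A|+|B|),   Jac/IoU = |A∩B| / (|A|+|B|−|A∩B|),
Acc = (TP+TN) / (TP+TN+FP+FN)
```

The hybrid network: four encoder downsamplings (widths 64→1024), lateral
1×1 convolutions to 128 channels, top-down nearest-neighbor merges, two 3×3
convolutions per merged level, concatenation of the four levels into a
512-channel tensor, a 3×3 conv + BN + ReLU fusion, a 1×1 head and a
bilinear upsample to input resolution with sigmoid output.  A matching
classical U-Net is included as the comparison baseline.

## Worked example

```python
import numpy as np
from fpnseg import (PhantomConfig, generate_dataset, preprocess_records,
                    split_dataset, ImprovedFPN, ModelConfig, TrainingConfig,
                    AugmentationConfig, train, evaluate)

records, _ = generate_dataset(
    200, PhantomConfig(image_size=(64, 64), tumor_probability=1.0, seed=1), seed=1)
split = split_dataset(preprocess_records(records), seed=1)   # sizes (140, 40, 20)

model = ImprovedFPN(ModelConfig.small(seed=1))               # CPU-scale widths
_, history = train(model, split,
                   TrainingConfig(seed=1, learning_rate=1e-3, max_epochs=30),
                   AugmentationConfig())                     # study augmentations
report = evaluate(model, split.test)
print(report.summary("improved_fpn"))
```

prints (a few minutes on one CPU):

```
improved_fpn: DSC 0.9184  Jaccard 0.8538  accuracy 0.9881  (n=20)
```

i.e. on 20 held-out phantoms the predicted masks overlap the true tumor
masks with a mean per-image Dice coefficient of 0.92 and Jaccard of 0.85;
pixel accuracy is near 1 because background dominates every slice.

The `examples/` directory contains one short script per capability
(metrics, phantom generation, augmentation, training comparison), and the
`fpnseg` console command exposes the same pipeline as subcommands
(`make-synthetic`, `preprocess`, `train`, `evaluate`, `predict`, `compare`,
`score`).

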