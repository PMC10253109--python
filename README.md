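# granulonet

A granular-computing convolutional classifier for breast-lesion images
— ultrasound scans (normal / benign / malignant) and histopathology
patches (IDC-negative / IDC-positive) — built for the small-corpus
regime where standard deep networks overfit.

The pipeline combines four data-efficiency devices:

1. **Granular computing** — each image is cut into g x g tiles
   ("granules", default 32 x 32 → a 7 x 7 grid on 224 x 224 input), a
   feature vector is extracted per tile, and the per-tile feature norms
   re-weight the image so salient regions are highlighted before
   training (or are mean/max-pooled into one descriptor per image).
2. **Learnable activation functions** — `LAF(x) = a · F(W·x) + b` with
   `a`, `b`, `W` trained by backpropagation; `F = max(0, ·)` after
   convolutions, `F = logistic` in dense layers. Initialized at
   (1, 0, 1), i.e. exactly ReLU / sigmoid.
3. **A wide-and-deep architecture** — six inception-style *X-modules*
   (three parallel residual *R-blocks* with 1 x 1 channel reducers plus
   a max-pool branch, concatenated), two stride-2 downsample modules,
   two auxiliary classifiers for deep supervision, spatial attention on
   the input and attentive pooling before the classifier head. Three
   variants differ in the R-block filter sizes: `R3_R3_R3`, `R5_R5_R5`
   and `R3_R5_R35` (3x3 / 5x5 / 3x5 branches).
4. **Attention** — softmax-normalized spatial weight maps (summing to 1
   over the image) multiply the input and pool the final features.

Evaluation reports a confusion matrix and accuracy / precision / recall
/ F1 (macro or weighted). The whole stack — including a compact NumPy
reverse-mode autodiff engine with im2col convolutions, batch
normalization and Adam — is pure Python + NumPy/SciPy and runs on a CPU
with no downloads; synthetic ultrasound- and histopathology-style
generators make every stage testable end to end.

## Worked example

Train the small profile (64 x 64 input, base width 16, ~269k
parameters) on a synthetic binary ultrasound task — speckle images with
vs. without a darker lesion — and evaluate on held-out images:

```python
import granulonet as gn

train_ds = gn.generate_dataset(gn.SyntheticSpec(
    style="ultrasound", n_per_class=100, image_size=(64, 64),
    n_classes=2, separability=1.0, seed=11))
test_ds = gn.generate_dataset(gn.SyntheticSpec(
    style="ultrasound", n_per_class=30, image_size=(64, 64),
    n_classes=2, separability=1.0, seed=1011))

model = gn.build_model(gn.ModelConfig.small(n_classes=2, seed=11,
                                            input_shape=(64, 64, 1)))
model, history = gn.train(model, train_ds, None, gn.TrainConfig.small(seed=11))
cm, report = gn.evaluate(model, test_ds)
print(history.frame.tail(3).to_string(index=False))
print(cm.to_frame())
print(f"accuracy={report.accuracy:.3f}  f1={report.f1:.3f}")
```

Output (a few minutes on one CPU core):

```
 epoch  train_loss  train_acc  val_loss  val_acc
    10    0.025889   0.994444  0.007357      1.0
    11    0.008408   1.000000  0.006921      1.0
    12    0.008632   1.000000  0.006570      1.0
                 predicted_normal  predicted_abnormal
actual_normal                  30                   0
actual_abnormal                 0                  30
accuracy=1.000  f1=1.000
```

The training history shows the loss converging within a dozen epochs;
the confusion matrix counts test images by actual class (rows) and
predicted class (columns) — here all 60 held-out phantoms are classified
correctly, which is expected at full class separability. Lowering
`separability` toward 0 removes the lesion contrast and accuracy falls
to chance (~0.5).

The published-style metrics operations work standalone; for the fixed
binary test matrix [[33, 4], [1, 30]] shipped as a worked-example
fixture:

```python
rep = gn.metrics_from_confusion(gn.worked_example_confusion())
print(round(rep.accuracy, 2), round(rep.f1, 2), gn.worked_example_confusion().misclassified)
# 0.93 0.93 5
```

## Command line

```bash
granulonet generate --style ultrasound --n 50 --classes 2 \
    --separability 0.8 --seed 7 --out data/
granulonet granulate data/manifest.csv --mode vector --out feats.csv
granulonet train data/manifest.csv run/ --variant R3_R5_R35 --seed 0
granulonet evaluate run/checkpoint.npz data/manifest.csv report.json
```

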