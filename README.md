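# protods

Prototypical-network classification of hyperspectral instances under severe
class imbalance, with instance-wise spectral contrastive pretraining and
Dice-loss fine-tuning.

## The problem

Near-infrared (NIR, ~900–1700 nm) hyperspectral imaging can detect food
adulteration — authentic products substituted or cut with cheaper look-alike
varieties (aged citrus peel, coffee beans, medicinal herbs) — without
destroying the sample.  Each sample is an H×W×B reflectance cube; after
calibration against dark/white references and masking of background pixels,
every *effective* pixel contributes one D-band spectrum `x ∈ R^D`.  In
practice the counterfeit or rare class is scarce: a training set may hold
hundreds of authentic instances and single-digit counterfeits, and
conventional classifiers then collapse onto the majority class.

## The method

Training runs in two steps over an embedding network `f: R^D → R^M`
(four BatchNorm → Linear → LeakyReLU blocks, M = 256):

1. **Instance-wise spectral contrastive pretraining** (no labels).  Pixel
   spectra from the same physical instance are positives, spectra from other
   instances are negatives; the InfoNCE loss with B = 16 negatives,
   temperature τ = 1 and similarity `s = −‖a−b‖²` teaches the embedding to
   discard illumination and noise nuisance before any label is seen.
2. **Episodic fine-tuning with Dice + cross-entropy.**  Per epoch, a random
   support subset of each class supplies prototypes
   `c_k = mean of class-k support embeddings`; all training pixels are
   queries classified by `p(y=k|x) ∝ exp(−‖f(x) − c_k‖²)`, and the loss is
   `CE + Dice`, where the per-class soft Dice term
   `1 − 2Σp_i y_i / (Σp_i² + Σy_i²)` is one minus the Dice–Sørensen
   coefficient — algebraically the class F1 for hard predictions.  Ignoring
   true negatives, it stops the majority class from dominating the gradient.

At test time all pixel embeddings of one instance are averaged (set pooling)
into a single vector, which is classified against prototypes recomputed from
the whole training set with the final network.

The package includes the full preprocessing chain (min–max calibration,
1000–1600 nm band retention, effective-pixel masking at mean reflectance
\> 0.1), ENVI and `.npz` cube I/O, a seeded synthetic-cube generator with
controlled class imbalance, the imbalance evaluation protocol
(prevalence-immune metrics, minority-count ladder n ∈ {1,5,10,15,20}),
ablation harness, pixel probability maps, and a PCA/Gaussian-ellipse
class-separability diagnostic.

## Worked example

```python
import numpy as np
from protods import (SignatureModel, SimConfig, simulate_dataset, dataset_to_records,
                     NetworkConfig, SSLConfig, FinetuneConfig, train_protods,
                     evaluate_model)

model = SignatureModel(n_classes=2, n_bands=64)          # smooth NIR signatures
cfg = SimConfig(seed=1, n_majority=100, n_minority=(5,),  # 100 vs 5 training instances
                n_test_per_class=25, height=7, width=7)
dataset = simulate_dataset(model, cfg)
train, test, band_idx = dataset_to_records(dataset)       # calibrate, crop, mask

protods_model, history = train_protods(
    train,
    NetworkConfig(input_dim=band_idx.size),
    SSLConfig(epochs=60, seed=1),        # step 1: contrastive pretraining
    FinetuneConfig(epochs=50, seed=1),   # step 2: Dice + CE fine-tuning
)
report = evaluate_model(protods_model, test)
print(f"B.Acc={report.balanced_accuracy:.3f}  M.F1={report.macro_f1:.3f}  "
      f"M.AUROC={report.macro_auroc:.3f}  M.AP={report.macro_ap:.3f}")
```

Output (a few minutes on one CPU core):

```
B.Acc=0.860  M.F1=0.857  M.AUROC=0.930  M.AP=0.891
```

Despite training on only 5 minority instances against 100 majority ones, the
balanced accuracy — the mean of the two per-class recalls, immune to the
20:1 prevalence — is 0.86: the model recalls 72% of held-out minority
instances (confusion matrix `[[25, 0], [7, 18]]`) instead of collapsing onto
the majority class.  The pretraining loss trace in
`history["ssl_trace"]` fell from 60.9 to 25.0 over 60 epochs.

A command-line interface mirrors the library
(`protods simulate | preprocess | pretrain | train | predict | evaluate |
ablate | probmap | separability`); see `protods --help`.

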