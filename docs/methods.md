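# Methods

## Problem setting

Near-infrared hyperspectral imaging is used to screen granular biological
products (dried citrus peel, coffee beans, medicinal herbs) for adulteration:
an authentic majority product mixed with a visually similar but cheaper
substitute.  Each physical sample is imaged as an H×W×B reflectance cube;
after calibration and masking, the sample is represented not by one averaged
spectrum but by the full set of its effective per-pixel spectra.  The
practical difficulty is class imbalance — counterfeit or rare-grade samples
may number in the single digits while the authentic class has hundreds — and
conventional discriminative training then collapses onto the majority class.

## Pipeline

**Calibration.** Raw counts are min–max rescaled between a dark-current cube
and a white-reference cube, `R = (I − I_dark) / (I_white − I_dark)`.  The
calibration errors out (rather than producing infinities) wherever
`white − dark ≤ 0`, naming the offending pixel/band.

**Band retention.** Only bands with centres in the closed interval
[1000, 1600] nm are kept; the spectral extremes of InGaAs sensors carry low
signal-to-noise.  On a uniform 256-band grid spanning 900–1700 nm this
leaves D = 192 bands, which is the embedding network's input width.  The
interval is closed at both ends; the band grid is treated as band centres
and never resampled.

**Effective-pixel masking.** A pixel is kept iff its mean reflectance over
the *retained* bands is strictly greater than 0.1.  Post-crop averaging was
chosen (over pre-crop) so the masking statistic is computed on exactly the
spectra the model will see.  Exact-threshold pixels are excluded.  An
instance whose pixels are all masked away raises an error instead of being
dropped, so dataset bookkeeping stays exact.

## Model

The embedding `f: R^D → R^M` is four identical blocks of
BatchNorm → Linear → LeakyReLU (negative slope 0.01, configurable).  Placing
batch normalization *before* each linear layer rescales the raw reflectance
on entry, which stabilizes training on NIR data.  The first linear maps
D → 256 and the rest preserve width, so M = 256.  Training mode uses batch
statistics; all reported inference uses running statistics, making an
embedding independent of its batch.

A class prototype is the arithmetic mean of the class's support embeddings,
and classification is a softmax over negative prototype distances.  The
distance is squared Euclidean by default — the standard prototypical-network
choice, under which the posterior is the Bayes rule of equal-covariance
Gaussian class conditionals — with plain Euclidean available as a switch.
At test time the pixel embeddings of one instance are averaged (set pooling)
into a single vector before classification, so the decision is invariant to
how many pixels an instance happens to contribute.  Prediction ties break
toward the lowest class id.

## Step 1: instance-wise spectral contrastive pretraining

Labels are ignored.  For each sampled instance, one pixel spectrum is the
query, a distinct pixel of the same instance is the positive key, and B = 16
pixels drawn from other instances are negatives; the InfoNCE loss with
temperature τ = 1 and similarity s = −‖a−b‖² pulls same-instance spectra
together.  Same-instance pixels differ only by illumination scale and noise,
so the learned embedding discards that nuisance variation before any label
is seen — the property that later protects the minority class from being
overwhelmed.

Two conventions were genuinely open and are exposed as configuration:
negatives may optionally include the query's own instance
(`negatives_include_own_instance`, off by default because same-instance
negatives contradict the pretext hypothesis), and the positive key may pool
several same-instance pixels (`positive_pool_size`, default 1).  There is no
projection head; the loss acts on the final embedding.  One query per
instance per step, 16 instances per step; an epoch is one shuffled pass over
all training instances.  Optimization is Adam at 1e-4; the reference budget
is 200 epochs.

## Step 2: fine-tuning with Dice + cross-entropy

Each epoch is a prototypical episode: half of each class's instances
(minimum one — a singleton minority is always its own support) are drawn as
support; their pixel embeddings, capped at 256 per class per episode for
bounded step cost, form the prototypes.  All training pixels then act as
queries in shuffled mini-batches of 256, each mini-batch performing one Adam
update (lr 1e-4) of the combined objective

    L = λ_CE · CE(p, y) + λ_D · Dice(p, y),      λ_CE = λ_D = 1,

with the soft Dice loss per class `1 − 2Σᵢ p_ic y_ic / (Σᵢ p_ic² + Σᵢ y_ic²)`
averaged over classes.  One minus the class term is the Dice–Sørensen
coefficient, which for hard predictions equals the class F1 exactly
(`2TP/(2TP+FP+FN)`); because it never counts true negatives, the majority
class cannot dominate the gradient.  Pixels inherit their instance's label
during training; set pooling is applied only at test time.  Batch-norm
running statistics continue updating during fine-tuning.

Numerical choices: a class absent from a mini-batch is computed as written
when its denominator is positive and defined as 0 when the denominator is
exactly 0; gradient columns whose denominator would underflow when squared
(below 1e-150, i.e. all probabilities saturated) are zeroed — their
contribution is vanishing, and propagating the underflow would poison the
parameters with NaNs.  True-class probabilities are clamped at 1e-12 before
the log.  Gradients throughout (network, both losses, the prototype path)
are hand-derived and pinned by finite-difference tests.

After fine-tuning, deployment prototypes are recomputed from **all**
training pixels with the final network in inference mode.

Ablation flags reproduce four variants: the full method, without Dice
(`use_dice=False`), without pretraining (`use_ssl_init=False`), and the
vanilla prototypical network (both off).

## Evaluation protocol

Metrics are prevalence-immune: balanced accuracy (mean per-class recall;
equal to (sensitivity+specificity)/2 in the binary case), macro F1, macro
one-vs-rest AUROC and average precision (midrank tie handling, via
scikit-learn), and per-class sensitivity/specificity (one-vs-rest; no scalar
aggregate is invented for the multiclass case).  Metrics are computed at the
instance level, after set pooling, matching the test-time procedure.

The imbalance ladder holds the majority class fixed and sets the
least-represented minority's *training* count to n ∈ {1, 5, 10, 15, 20};
other minority classes scale as `round_half_up(n · orig_k / orig_least)`.
For the age-graded four-class configuration with original counts
1267/197/104/40 this yields minority training counts (5,3,1), (25,13,5) and
(99,52,20) at n = 1, 5, 20.  The test split is stratified, carved out first
from the seed alone, and therefore identical across all n.  The training
side of the split uses half-up rounding: with 197 instances at 50/50 this
gives 99 training candidates, exactly accommodating the n = 20 rung (floor
would leave 98 and make the ladder infeasible).

Separability diagnostic: embeddings are projected to two principal
components, each class is fitted with a mean+covariance Gaussian, and the
pairwise Intersection-over-Union of the 95% confidence ellipses (chi-square
radius, 2 df) is computed on a shared rasterized grid (default 200×200;
refinement changes the value by < 0.01).  Singular covariances are
ridge-regularized with a warning.  Grid rasterization was chosen over
analytic ellipse–ellipse intersection for robustness.

## Synthetic data generator

No public datasets accompany the method, so the generator emulates the
statistical structure the method relies on, per class c a smooth signature
(baseline 0.45 plus three Gaussian bumps, amplitude ≤ 0.18, widths
40–160 nm, clipped into (0.1, 1.0)), with a minimum pairwise L2 separation
(default 0.5, resampled until met).  Each instance draws a lognormal
illumination factor (σ = 0.15), each pixel a further lognormal jitter
(σ = 0.05) — multiplicative, so shadowed pixels keep their spectral shape,
which is exactly the structure the contrastive pretext task exploits — plus
iid Gaussian band noise (σ = 0.02).  A shadow fraction (default 10%) of
pixels is rescaled to mean reflectance ≈ 0.06, below the effective-pixel
threshold.  Reflectance clips at 1.2, since min–max calibrated data can
mildly exceed 1.  In raw mode the generator emits dark/white/raw triplets
satisfying `calibrate(raw) == reflectance` to 1e-9.

What it does **not** model: spatial texture and pixel correlations,
wavelength-dependent noise, detector nonlinearity, scattering physics.
Passing tests therefore demonstrate the pipeline's correctness and the
method's imbalance behaviour under the assumed spectral structure, not
performance on real instruments.

## Problem sizes in the bundled experiments

The canonical experiments (`protods.experiments`) use scaled-down cubes the
package chooses for fast iteration: 64-band signatures (D = 48 after
cropping), 7×7-pixel instances, 50–60 pretraining epochs.  The structure
experiment pretrains on 40 unlabeled instances; the imbalance experiment
trains on 100 majority / 5 minority instances with a balanced 25+25 test
set, over 5 seeds, comparing the full method against the vanilla
prototypical network.  At reference scale the defaults are those given
above (200/50 epochs, D = 192).

## Known limitations

* No SMOTE or class-reweighting integration; the method argues they are
  unnecessary, and combining them is future work.
* Regression (soft-label) extension not implemented.
* Watershed ROI segmentation is out of scope; cubes are assumed pre-cropped
  to one instance.
* Training is single-threaded numpy; adequate at the bundled problem sizes,
  not tuned for very large cubes.
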