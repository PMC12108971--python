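# Methods

## Problem and model

The package predicts the risk of vertical root fracture (VRF) after root
canal therapy from 17 clinical items describing one tooth: 10 categorical
items (sex, five yes/no history items, tooth position, post type, abutment
status, prior apical surgery — 30 options in total) and 7 numerical items
(age, remaining wall count, time to prosthetic installation, wear and
periodontal scores, two thicknesses in mm).  The outcome is binary;
fractured is the positive class.

The core classifier is a three-stage fusion network (TSFNN):

1. **Numerical stage** — the 7 numerical items are min-max normalized and
   fed to a dense branch (7 → 16 ReLU).
2. **Categorical stage** — the 10 items are globally ordinal-encoded
   (consecutive codes 1..30 across all options of all items, so no two
   items share a code) and passed through an *embedding layer*: a
   one-hidden-layer network (10 scaled codes → 20 ReLU → 1 sigmoid) is
   pre-trained on the fracture label and its output node is removed,
   leaving a dense 20-dimensional representation.  The embedded vector
   feeds a dense branch (20 → 16 ReLU).
3. **Fusion stage** — the two branch outputs are concatenated (32) and
   passed through a fusion sub-network (32 → 16 ReLU → 1 sigmoid).

Batch normalization, when enabled (the default), is applied after each
hidden linear transform and before its activation in both branches and the
fusion stage: activations are normalized by mini-batch mean and standard
deviation with learned scale/shift; inference uses exponential running
statistics (momentum 0.9, ε = 1e-5), so prediction is a pure function of
the trained weights.

Baselines sharing the same preprocessing: a plain ANN (all 17 normalized
inputs → 32 → 1), the numerical branch alone (`nnn`), the categorical
branch alone (`cnn` — "categorical", not convolutional), and a two-way
network (`two_way`) that concatenates the two branch outputs directly into
the output node with no fusion sub-network.  Default widths give the
two-way network (32 hidden nodes) and the fusion network (48) deliberately
comparable capacity so their comparison isolates the fusion stage.

## Normalization modes

The printed normalization formula, y = x/(max − min), maps onto [0, 1]
only when min = 0, while the stated target range is 0 to 1.  The default
is therefore the standard form y = (x − min)/(max − min); the literal form
is available as `mode="paper_literal"` and equals the standard form plus
the constant min/(max − min) (tested).  Degenerate items (max = min inside
a training fold) map to 0 rather than raising; at apply time, standard-mode
values outside the fitted range are clamped to [0, 1].

## Training

Binary cross-entropy in logit space, Adam (lr 1e-3), mini-batches of 16,
300 epochs by default; ReLU hidden activations, sigmoid output, He-scaled
Gaussian init.  None of these are prescribed by the source method
description; all are recorded in `ModelSpec` so every run is reproducible.
A probability exactly equal to the decision threshold (default 0.5) is
called positive.  Optional inverse-frequency class weights exist but are
off by default.  The embedding is pre-trained first and then frozen inside
the downstream network (a `fine_tune_embedding` flag grafts it in as a
trainable layer instead); a `staged_training` flag alternatively pre-trains
each branch as a standalone classifier, freezes both, and trains only the
fusion head.  Neither alternative is asserted to be "the" original
procedure; the default (embedding pre-trained, rest end-to-end) is the
one explicit construction.

## Evaluation protocol

Leave-one-out cross-validation: with n records the harness runs n folds;
fold i refits *everything* — min-max parameters, the embedding, the
network — on the other n−1 records (`fit_scope="fold"`, the no-leakage
default; `"global"` fits preprocessing once on all records, since the
original fitting scope is not stated).  Per-fold seeds derive
deterministically from (master seed, fold index) via `SeedSequence`.  The
n single predictions are pooled into one confusion matrix from which
Accuracy = (TP+TN)/total, Precision = TP/(TP+FP), Recall = TP/(TP+FN) and
F1 = 2/(1/P + 1/R) are computed once.  For accuracy, pooling is identical
to averaging per-fold 0/1 accuracies; for precision/recall it is the only
well-defined aggregation when each fold holds one test sample.
Zero-denominator metrics are NaN, never silently 0.  A fold whose training
set becomes single-class is skipped with a warning and reported.

## Synthetic data

The study's clinical records are private, so all experiments run on
synthetic data emulating the study conditions: 97 positive / 48 negative
records by default, the exact 17-item schema, and configurable planted
effects.  Numerical items are class-conditional Gaussians with fixed
plausible base distributions (age ≈ N(55, 12²) on [20, 85] years; wall
counts on 0–4; days to prosthetic installation ≈ N(60, 40²) clipped at 0;
wear/periodontal scores on 0–3; canal wall ≈ N(1.5, 0.5²) mm; pericervical
dentin ≈ N(2.0, 0.6²) mm); integer-valued items are rounded.  Effects are
per-item mean shifts in within-class SD units.  Categorical items are
drawn from per-class option-probability vectors.  These constants are
fixture choices; no claim is made that they match the private data's joint
distribution, so passing tests demonstrate correct mechanics and
qualitative behaviour, not clinical performance.

Three named conditions:

* `null_spec` — all effects zero (label independent of every item), used
  for the chance-level check against the majority proportion 97/145 ≈ 0.669;
* `study_spec` — moderate mixed-type signal (thinner walls/dentin, fewer
  remaining walls, higher age, shifted post-type/pain/retreatment odds in
  fractured teeth).  The frozen fixture shipped at
  `tsfnn/data/study_fixture.csv` is `study_spec` at pinned seed 1450 and is
  byte-identical to regeneration (tested);
* `interaction_spec` — the label depends mainly on an exclusive-or of two
  designated options (tooth position "Mandibular molars" × post type
  "Casting post", satisfied with probability 0.9 in positives, 0.1 in
  negatives) plus a weak thickness effect.  The pair assignment keeps each
  item's own class-conditional marginal flat (tested), so the signal is
  invisible to any model linear in the ordinal codes and exercises the
  embedding and fusion stages specifically.

A `make_separable_fixture` helper plants disjoint class-conditional ranges
on canal wall thickness for training sanity checks.

## Problem sizes used in tests and the acceptance script

Full-length training (300 epochs) is used for single-model examples.  The
LOOCV-heavy checks (fold accounting, chance-level null across all five
architectures, ablation directions) use 100-epoch training (embedding
included) — loss curves on the 145-record fixtures are flat well before
that point — and the fold-accounting check uses 3 epochs, since fold
counts are independent of training length.

## Known limitations

* Reported headline metrics of the original study were computed on the
  private clinical data and are not reproducible here; only the protocol,
  the architectures and the qualitative ablation directions are.
* With n = 145 and fold-local, label-supervised embedding pre-training,
  all architectures overfit their training folds; deeper variants can
  generalize worse than shallower ones.  In particular, on the
  planted-interaction family — where the signal lives entirely inside the
  categorical branch plus an additive numeric shift — the fusion
  sub-network has no cross-type structure to exploit, and the two-way
  baseline's shallower head consistently generalizes somewhat better in
  pooled LOOCV accuracy (the dedicated direction test documents this as an
  expected-failure-in-fact: it asserts the fusion ≥ two-way direction and
  currently fails on this synthetic family).  Advantages of the fusion
  stage reported on real clinical data presumably rest on cross-type
  dependence that this generator, by design, does not plant.
* No missing-data handling, no hyperparameter search, no ROC/AUC, no
  significance procedures (an optional bootstrap CI flag is the only
  extension), matching the scope of the original protocol.
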