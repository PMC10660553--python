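# Methods

## The optimizer

The core is the Artificial Gorilla Troops Optimizer, a box-constrained
population metaheuristic. A troop of `Nmax` solutions evolves for `Tmax`
iterations; each iteration runs an exploration sweep and an exploitation
sweep over all members, and each candidate replaces its incumbent only when
strictly better (ties keep the incumbent, which prevents drift on flat
fitness landscapes). The silverback — the lowest-cost member — is
re-identified lazily after every acceptance.

Coefficients are drawn per update: `C = (cos(2·r4) + 1)(1 − t/Tmax)` decays
to zero at the final iteration, `L = C·l` with `l ~ U(−1, 1)`,
`Q = 2·r5 − 1 ∈ [−1, 1]` is the impact force, and `A = β·E` is the conflict
vector, where `E` is a per-dimension standard-normal draw half the time and
a single shared normal draw otherwise. In the follow-the-silverback move the
troop magnitude is `M = (|mean(pop)|^g)^(1/g)` with `g = 2^L`, computed over
the current population (exploration acceptances included). Exploitation
follows the silverback when `C ≥ w` and competes otherwise.

Branch selection in exploration uses two independent uniform draws: one for
the migration check (`< p`), and — when migration is not taken — a second
one deciding between the peer-following and known-position mechanisms, so
the branch probabilities are `(p, (1−p)/2, (1−p)/2)`.

Defaults `Nmax = 10`, `Tmax = 25`, `p = 0.03`, `β = 3`, `w = 0.8`. Bound
violations are restored by clipping — the simplest contract, chosen over
reflection or re-sampling. Everything draws from a single
`numpy.random.Generator` seeded per run, and the per-operation draw order is
documented in `gto_core` and pinned by replay tests, so runs are exactly
reproducible.

## Decoding

Discrete cells decode by the ceiling range-index rule
`index = ⌈value × n_options⌉`, 1-based, clamped to 1 at value 0 (the rule is
monotone and surjective onto the option list; each option owns a width-`1/n`
interval of `[0, 1]`). Continuous cells decode linearly,
`lo + value·(hi − lo)` — the discrete rule's natural continuum limit.

The 15-cell image-classifier space is: loss (6 options), batch size
{4..48 step 4}, dropout `[0, 0.6]`, transfer-learn ratio {1..100}%,
optimizer (11 options), scaler (5 options), the augmentation on/off flag
(No/Yes), then rotation {0..45}°, width/height shift, shear and zoom
`[0, 0.25]`, two flip flags, and brightness. Brightness is a single cell but
denotes a multiplier *range*: the cell decodes the lower end over
`[0.5, 2.0]` and the upper end is capped at `lower + 0.5` (a one-cell
encoding cannot express two free endpoints; the rule is documented here and
kept fixed). When the augmentation flag decodes to "No", the eight sub-cells
are forced to inert values and marked unused — they stay in the vector
(constant 15-dimensional search space) but cannot influence fitness, and the
fitness memoization key is the decoded configuration, so vectors differing
only in unused cells share one evaluation.

Feature masks decode by thresholding at 0.5 (inclusive). An all-drop vector
keeps the single largest cell (ties toward the lowest index): a zero-feature
classifier is undefined, and the argmax fallback is the smallest perturbation
of the decoded intent.

## Pre-processing

Question marks (unanswered screening items) become 0 before label encoding,
and categorical columns that carried missing markers reserve code 0 for
"missing", coding real categories lexicographically from 1; complete columns
code from 0. The five column scalers implement, verbatim: `x/max(x)`;
`(x − μ)/σ` with the population σ (no Bessel correction, as the formula has
none); `(x − min)/(max − min)`; `x/|max(x)|`; and `(x − Q1)/(Q3 − Q1)`. The
robust scaler deliberately centers on the **first quartile** rather than the
conventional median — that is the formula this framework defines, and the
implementation follows it rather than silently "fixing" it. Quartiles use
linear interpolation (configurable). Degenerate denominators are guarded:
kinds 2/3/5 return zeros on constant input, kinds 1/4 the sign pattern.
In cross-validation, scalers are fit on training folds only and applied to
held-out folds — leakage prevention the fitness protocol depends on. For
images the scaler is fit globally over the training pixels (per-column
scaling is the tabular mode).

Images resize bilinearly to 128×128×3 (grayscale replicated). Augmentation
applies, in order: rotation uniform in ± the decoded maximum, width/height
shifts as uniform fractions of the image size, shear, zoom, deterministic
flips when their flags are "Yes", and a brightness multiplier drawn from the
decoded range with output clamped to [0, 1].

## Fitness definitions

*Feature selection*: decode the mask, restrict the table, and for each point
of the model's hyperparameter grid (decision tree / extra tree: criterion ×
splitter; LightGBM: learning rate ∈ {0.01, 0.1, 1.0} at 300 estimators) run
stratified 5-fold CV with fold-fit scalers; fitness is
`1 − best mean CV accuracy` plus a `1e−6 · k/D` term that breaks
equal-accuracy ties toward smaller subsets. The fold split is seeded once
per problem so fitness values are comparable across candidates, and fitness
is memoized on the decoded mask (identical masks recur constantly in a
thresholded encoding; the cache changes cost, never values). The final
report re-evaluates the winning mask under the same protocol and assembles
the metric suite from the out-of-fold predictions, with the rank-based AUC
computed from out-of-fold class probabilities.

*Image hyperparameter search*: decode the 15-cell configuration, train on
the stratified 80% split for 5 epochs, and use the held-out loss (the
decoded loss function evaluated on the 20% split) as fitness; held-out
accuracy, AUC, Dice/IoU, Youden and cosine similarity are recorded
alongside. A trainer failure maps to `+inf` fitness so the search continues.
The transfer-learn ratio is interpreted as the percentage of backbone layers
made trainable, rounded to the nearest layer.

The trainer is a contract, not a framework binding: the six pretrained CNN
backbone names (DenseNet169/201, MobileNet, MobileNetV2, MobileNetV3
Small/Large) are accepted and require the caller to supply a trainer. The
built-in `tiny-test` backbone is a small numpy softmax network — one frozen
random dense layer with ReLU as the "backbone", a trainable softmax head,
genuine implementations of the six losses (gradients propagated through the
softmax Jacobian) and of the eleven optimizer names mapped onto their update
families (SGD ± Nesterov, the Adam family with NAdam/AdaMax/AMSGrad
variants, RMSProp plain/centered, AdaGrad, AdaDelta, and FTRL in its
accumulator form, which without regularization reduces to per-coordinate
AdaGrad). With the single-layer backbone the learn ratio unfreezes it at
≥ 50%. The point of this trainer is to exercise every decoded
hyperparameter deterministically on a CPU, not to model CNN behaviour.

## Synthetic fixtures

The screening generator emits the full 21-attribute schema (A1..A10, age,
gender, ethnicity, jaundice, family-PDD, residence, screening-app use,
result, age description, relation, class). Items are i.i.d. Bernoulli(0.5)
by default, `result` is their sum, and `class = YES iff result ≥ 7` — the
AQ-10-style screening cut. At these defaults YES prevalence is the binomial
tail `P(Bin(10, 0.5) ≥ 7) = 0.172`. Demographics are independent noise drawn
from fixed vocabularies (an optional mode appends extra noise columns), and
"?" markers are injected only into demographic cells. The label rule means
(a) the label is recomputable from the items alone, so perfect CV accuracy
is attainable and feature selection has a clean optimum, and (b) the
`result` column is individually sufficient — runs typically converge to it,
which is the intended demonstration that most columns are dispensable.
What this emulates — and what it does not: real screening data has
correlated items, noisy labels and informative demographics; passing tests
here show the wrapper machinery is correct, not that selection would be this
clean on clinical data.

The image generator writes two-class PNG trees where a bright square cue
sits in the upper-left (class 0) or lower-right (class 1) quadrant over
Gaussian pixel noise (an alternative mode varies an ellipse's aspect ratio).
The classes are linearly separable by construction — a single-pixel probe
suffices at zero noise — so a correct training pipeline must exceed 90%
held-out accuracy easily, and failures indicate plumbing bugs rather than
hard learning problems. Default: 50 images per class at 128 px, noise σ
0.05.

## Evaluation protocol notes

Tabular runs are scored by 5-fold stratified CV throughout (fitness and
final report); image runs are scored on the held-out 20% split. The
positive class is the lexicographically last label ("YES"; the second
directory name for image trees) unless overridden. The report's "ROC" row
is the rank-based AUC, which for hard predictions equals balanced accuracy.
Percentages are formatted half-up to two decimals only at report time;
internal values keep full precision. The "overlap index" row is tabulated as
Dice; the conventional overlap coefficient is exposed separately as
`overlap_coefficient`.

Problem sizes used by the test suite and the acceptance script — 1,100-row
tables for full feature-selection runs (smaller tables for unit tests), 100
images at 128 px with a population of 4 and 3 iterations for the image smoke
run — are the package's chosen desk-scale study conditions; GPU-scale
fine-tuning of real pretrained backbones on external image sets is out of
scope by design.

## Known limitations

- The tiny-test trainer's determinism holds on CPU with a fixed seed;
  user-supplied trainers own their reproducibility.
- The robust scaler follows the first-quartile formula above; callers who
  want median-centered robust scaling should standardise upstream.
- Elapsed-time comparisons (before vs after selection) are wall-clock
  measurements and inherently noisy; the package reports best-of-repeats
  in its acceptance checks.
- Multi-class problems are out of scope; metrics are binary one-vs-rest.
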