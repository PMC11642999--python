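# Methods

## The open-set model

`mosqopen` treats a trained closed-set classifier as a black box that maps a
sample to an M-vector of activations (logits), one component per known
class. Open-set behaviour is grafted on afterwards from three ingredients
estimated on training activations only:

1. **Mean Activation Vector (MAV).** The per-class arithmetic mean of the
   training activation vectors. By default every vector of the class
   contributes (`mav_source="all_samples"`); `"correct_only"` restricts to
   vectors whose own argmax points at the true class, the convention of the
   original OpenMax literature. The two coincide for well-trained models,
   and differ only when the underlying classifier misclassifies part of its
   own training set.
2. **Distance tail.** Euclidean distances between the class's training
   vectors and its MAV summarize typicality. Only the η largest distances
   are modelled: extreme-value theory says the tail of "how far can a
   genuine member sit from its centre" is what matters for deciding whether
   a new distance is implausibly large, and the bulk of the distance
   distribution is deliberately ignored.
3. **Weibull fit.** A Weibull CDF
   `F(d) = 1 − exp(−((d − μ)/γ)^b)` is fitted to the tail. The location μ
   is fixed first; shape b and scale γ are maximum-likelihood estimates.

Rejection then comes in two flavours, both first-class:

* `score_threshold`: per-class recalibrated scores `r_c = 1 − F_c(d_c)`;
  reject when `max_c r_c < ε`, otherwise predict the argmax class.
* `openmax`: rank classes by activation; for ranks j = 1…β down-weight
  activation c = rank(j) by `θ_c = 1 − ((β − j)/β)·F_c(d_c)`; collect the
  removed mass `Σ_c a_c(1 − θ_c)` as a synthetic unknown activation;
  softmax over the M+1 augmented activations; reject when the unknown entry
  wins or the winning probability is below ε.

The two rules answer slightly different questions (a per-class typicality
veto versus a redistributed posterior), and published descriptions of
OpenMax-based pipelines are frequently ambiguous about which one a reported
threshold applies to. Both are exposed, every report states the mode used,
and neither is claimed to be "the" canonical one.

### A note on the recalibration weight

A literal reading of some printed descriptions of the OpenMax loop puts a
raw exponential of the distance ratio, `exp(((d − μ)/λ)^κ)`, in place of the
Weibull CDF in the θ update. That quantity is unbounded — it explodes for
any sample moderately far from a MAV and drives θ far outside [0, 1] — so it
cannot be a probability weight; the bounded CDF form is what the rest of the
recalibration mathematics (the `1 − CDF` score definition in particular)
requires. The toolkit implements the CDF form and keeps the literal
exponential available behind `openmax_probabilities(...,
literal_exponential=True)` purely as a diagnostic; a test demonstrates its
divergence.

## Parameters

| Parameter | Default | Meaning and rationale |
|---|---|---|
| η (`tail_size`) | `min(20, N_c)` | Number of largest distances fitted. 20 is the conventional meta-recognition tail size: large enough to estimate two Weibull parameters, small enough to stay in the tail. |
| β (`beta`) | `M` (all classes) | How many top-ranked activations are down-weighted. No principled universal value exists; modifying all classes is the neutral choice and the knob is exposed. Note that with the `(β − j)/β` ladder, rank j = β receives zero modification, so β = 1 coincides with β = 0. |
| ε (`threshold`) | 0.1 | Rejection cutoff, on `max r_c` or on the winning OpenMax probability depending on mode. The sweep default (0.5, 0.4, 0.3, 0.2, 0.1) brackets the useful range; accuracy on an extended test set typically rises as ε falls toward 0.1. |
| `location_mode` | `tail_min` | Where the Weibull support starts. `tail_min` fixes μ = (1 − 10⁻⁶)·min(tail), i.e. the fit models exceedances over the tail's onset — the libMR/meta-recognition convention. A `zero` mode (μ = 0) is available, but a zero-location Weibull on distances bounded well away from zero is misspecified: it inflates the shape parameter and places CDF mass across the bulk of the within-class distance distribution, which measurably erodes known-class retention at practical ε. `tail_min` is therefore the package default. |
| `mav_source` | `all_samples` | See above. |
| Dedup `max_hamming` | 5 of 64 bits | Common perceptual-hash practice for "near-duplicate"; 0 restricts to exact hash collisions. |
| Split ratios | 0.8 / 0.8 | Outer train/test then inner train/validation, i.e. 64/16/20 overall — exact whenever a class size is divisible by 25. |
| Augmentation | ±20° rotation, ±0.20 shifts, ±0.20 rad shear, zoom [0.8, 1.2], horizontal flip, nearest fill | Perturbs pose without destroying fine anatomy (wing position, antennae) that species identification depends on. Magnitude units follow the common image-augmentation convention: shifts are fractions of width/height, shear is an angle in radians, zoom is multiplicative. |

## Synthetic data: what it emulates, and what it does not

The activation generator draws class c from an isotropic Gaussian centred at
`separation·spread·e_c` (a scaled one-hot direction), so any two class means
are `separation·spread·√2` apart and `separation` is a single separability
dial. This mimics the logit geometry of a well-trained classifier — tight,
well-separated class clusters — not the feature statistics of any particular
network. Out-of-distribution samples come in three flavours:
`shifted_cluster` (default) places a coherent Gaussian cluster on the
all-ones line, exactly equidistant from every class mean and at least as far
from each class as the classes are from each other — the analogue of a
coherent foreign insect class rather than white noise; `uniform_box` fills
the known activations' bounding box; `low_margin` sits between pairs of
class means. The toy image corpus renders one deterministic geometric
template per class plus Gaussian pixel noise, with per-class counts
defaulting to a realistically imbalanced profile (9–500 images per class,
1749 total over ten classes).

Consequently, a passing synthetic suite shows that the open-set machinery is
implemented correctly and behaves as designed *when its assumptions hold*
(separable clusters, coherent unknowns). It does not certify performance on
real activations, whose clusters are anisotropic, whose unknowns may overlap
known classes, and whose tails may be heavier than Gaussian. The reference
conditions used throughout the tests and the acceptance script — ten
classes, separation 6, spread 1, 50 training samples per class, an extended
test set of 100 known plus 100 unknown samples — were chosen so that a
nearest-centroid classifier is ≥ 99% accurate, which pins any open-set
losses on the rejection machinery rather than on inseparable fixtures.

## Numerical choices

* **Weibull MLE.** With location fixed, the scale is profiled out and the
  shape solves `1/k + mean(log x) − Σx^k log x / Σx^k = 0`, which is
  strictly decreasing in k. The solver brackets a sign change, then iterates
  Newton steps clamped to the bracket (bisection fallback), tolerance 1e-10,
  at most 200 iterations, starting from the moment estimate
  `k₀ = π/(√6·sd(log x))`. Powers are computed on data scaled by its maximum
  so `x^k` cannot overflow. Degenerate tails (all values equal, or
  non-positive after translation) raise rather than returning junk.
* **Softmax.** Always max-stabilized; probability vectors sum to 1 within
  1e-9 by construction.
* **Tie-breaks.** Everywhere the lowest vocabulary index wins: argmax over
  scores, over OpenMax probabilities, and the descending activation ranking
  (stable sort). The vocabulary is the sorted training-label order unless
  given explicitly.
* **Perceptual hashes.** dhash area-averages the luma image to 8×9 and
  emits one bit per horizontally adjacent pair (left > right), row-major,
  MSB first; ahash thresholds an 8×8 average at its mean. Area averaging is
  exact fractional-overlap integration (not interpolation). Comparisons
  treat cells within 1e-8 as equal so float round-off cannot flip bits of
  analytically tied cells — a constant image hashes to exactly 0 under
  dhash.
* **Split rounding.** Per class, the test count is `floor(0.2·n + 0.5)`
  (round half up), then the same rule on the remainder for validation. This
  makes the 64/16/20 identity exact for class sizes divisible by 25.
* **Augmentation geometry.** Pixel centres sit at integer coordinates;
  transforms act about the image centre `((H−1)/2, (W−1)/2)`; the forward
  matrix is `Rotation @ Shear @ Zoom @ Flip` in (row, col) coordinates;
  resampling is nearest-neighbour with out-of-frame samples clamped to the
  nearest edge pixel. Random draws occur in a fixed order (rotation, x
  shift, y shift, shear, zoom, flip coin) so a draw seed fully determines
  the transform.
* **Serialization.** Models round-trip through a single JSON document with
  repr-precision floats, so two builds from identical inputs are
  byte-identical and a reloaded model reproduces every score exactly.
* **Pipeline seeding.** A single root seed derives per-stage seeds as
  `(root + crc32(stage_name)) mod 2³¹`, so the randomness of one stage is
  independent of which other stages run.

## Split-then-balance versus balance-then-split

Two orderings of the corpus-engineering stages are defensible and the
toolkit ships both. The default splits first and balances only the training
partition, which prevents augmented near-copies of one photograph from
landing on both sides of the train/test boundary (the leakage argument).
The `balance_first` mode balances the whole corpus to the target count and
then splits, which reproduces the arithmetic in which a 20% test partition
of a ten-class corpus balanced to 500/class contains exactly 1000 images.
The two cannot be reconciled into one ordering; the run manifest records
which was used.

## Evaluation conventions

Precision, recall and F1 use the zero-denominator → 0 convention. Macro
averages run over labels with support or predictions, and include the
unknown label whenever it has either — an open-set evaluation over ten known
classes therefore averages over eleven labels. Balanced accuracy is the
mean recall over labels with support. MCC uses the generalized multiclass
covariance form. ROC curves are one-vs-rest at every unique score with
trapezoidal AUC; PR curves are step-wise with no interpolation, AUPRC the
step sum (identical to average precision); the micro average pools all
(sample, label) decisions. The sweep's "f1" column is micro-F1, which
equals accuracy for single-label decisions and is reported explicitly so
the coincidence is visible rather than mysterious. Labels whose truth
column is single-class get flagged `undefined` and are excluded from macro
curve averages.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data at
the reference conditions above: model fits on 500 training vectors (10×50),
evaluation on 200 extended-test samples, Weibull recovery on 1000 draws per
seed across 20 seeds, oracle equivalence on 100+ random instances across
M ∈ {2, 3, 10}, and image-stage checks on corpora of a few dozen 24×24–32×32
PNGs. The full suite completes in well under a minute on one CPU.

## Known limitations

* The Gaussian-cluster generator is a stand-in for real logit geometry, not
  a claim about any particular network's activations.
* Duplicate detection inherits the robustness limits of 64-bit perceptual
  hashes: large rotations or crops defeat it by design.
* β's rank ladder `(β − j)/β` leaves the β-th ranked class unmodified (and
  makes β = 1 a no-op); this matches the transcribed procedure and is kept
  as-is rather than silently corrected to the `(β − j + 1)/β` variant found
  elsewhere in the open-set literature.
* The toolkit does not train or fine-tune feature extractors, implement
  alternative open-set methods (energy scores, MetaMax), or render plots;
  curve and sweep exports are tables for the caller's plotting tool.
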