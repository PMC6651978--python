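# Methods

## The observation model

The unit of analysis is the *observation*: one plant individual
photographed from five fixed perspectives — entire plant (EP), flower
frontal (FF), flower lateral (FL), leaf top (LT), leaf back (LB). A
dataset manifest is a balanced collection of observations (equal count
per species), stored as a long-form delimited table with one row per
image. Species are ordered lexicographically throughout; that order
defines the column order of every score matrix, so artifacts from
different runs align without extra bookkeeping. Group labels are free
strings ("forb"/"grass" by convention); every per-group statistic works
for any partition of the species.

## Splitting

Splits are drawn per species over whole observations, never over single
images: all five images of a plant land in the same subset, so no test
plant is partially seen during training. Each species gets its own
random stream, derived by hashing `(seed, species)` — adding or removing
a species never perturbs the draws of the others. The default protocol
follows the balanced design: n_train/n_val/n_test observations per
species (80/10/10 at full scale; 20/5/5 at the package's desk scale).

Training-size reduction subsamples the training set per species while
validation and test sets are inherited unchanged. Reductions are
**nested** (each smaller training set is contained in the larger one);
the alternative — independent subsamples per size — adds subsampling
variance to the ablation comparison without buying anything, so nesting
is the default and only mode. The validation set is recorded in every
split but the shipped backends do not use it for early stopping; training
runs a fixed budget, and hyperparameters are treated as fixed
configuration.

## Scorers and the two training strategies

A scorer maps one test image to a probability vector over the species
list (softmax-normalized confidence scores; rows sum to 1 within 1e-6).
Two training strategies are supported:

* **A** — five scorers, each fitted only on training images of its own
  perspective;
* **B** — one scorer fitted on all training images pooled.

The reference recipe of the full-scale experiment (Inception-ResNet-v2
transfer learning; batch 32, learning rate 0.003, RMSProp, weight decay
4e-5, 200 000 steps; centered 87.5 % crop, resize to 299 px; random
horizontal flip, brightness delta up to 0.125, saturation factor in
[0.5, 1.5]) is recorded in `TrainConfig` as documentation defaults. The
shipped desk-scale backends are a multinomial logistic model and a small
multilayer perceptron, both on downsampled pixels (default 12 px side
after the 87.5 % crop). The backbone is deliberately pluggable: every
downstream result depends only on the scorer contract (probability rows,
deterministic given the seed), and the methodology under study is the
observation/fusion design, not the network.

Two interpretation choices in the augmentation recipe were genuinely
open and are fixed as follows: "brightness factor up to 0.125" is an
additive delta drawn uniformly from ±0.125 on the normalized [0, 1]
intensity scale, and "saturation factor up to 0.5" is a multiplicative
factor drawn uniformly from [0.5, 1.5], applied by blending each pixel
with its Rec. 601 luminance (grayscale images are exact fixed points).
Both match the conventional semantics of mainstream training frameworks.
For non-square images the centered min-side square is taken *before* the
87.5 % fraction, which guarantees a square output. Draws whose magnitude
is exactly neutral skip the arithmetic so that zero-magnitude specs are
bit-exact identities.

## Fusion

Scores are fused by the sum rule: the fused score of a species is the
arithmetic mean of that species' scores over the perspectives in the
combination, S = (1/n) Σ s. The mean (rather than the bare sum) keeps
rows normalized and makes combinations of different sizes commensurable;
argmax-based accuracy is identical either way. Fused scores are computed
for all 31 non-empty subsets of the five perspectives. Scores are
fused as softmax probabilities, not raw logits — "confidence score"
admits either reading, but averaging requires commensurable quantities
and probability rows are what the scorer contract guarantees. A missing
per-perspective row is a hard error; silently renormalizing a partial
fusion would bias comparisons between combinations.

## Evaluation

Top-k accuracy per species is the fraction of that species' test
observations whose true species ranks within the top k fused scores.
Ranking ties are broken deterministically — (score descending, species
label ascending) — so results are reproducible; for continuous scorers
ties are measure-zero anyway. Under the balanced design the unweighted
mean over species equals the pooled per-image fraction (asserted to
1e-12 in the tests). Per-group means are unweighted means over the
group's species. Datasets with fewer than five species use k =
min(5, S) for the "Top-5" column. A species counts as *fully correct*
for a combination when its Top-1 accuracy is exactly 1.0. The optional
standard error reported per combination is the standard error of the
per-species Top-1 mean; no further inferential statistics are emitted.

## Synthetic data

No real plant imagery ships with the package; the synthetic module
generates balanced datasets whose *statistical* structure matches what
the analysis assumes, at two tiers.

**Score tier.** For observation o of species c and perspective p the
latent logit vector is

    z = d_p · v_c + σ_b · b_o + σ · ε,      scores = softmax(z)

with v_c the species' signal direction, b_o a per-observation draw
shared by all five perspectives (emulating habitat background common to
one plant's images — error correlated across perspectives, which fusion
cannot average away), and ε i.i.d. noise. The signal direction is the
species' own coordinate axis tilted by a small random component (0.15),
so species differ slightly in intrinsic difficulty; cluster members are
blended with their cluster mean, v = (1−ρ)·e + ρ·u, so the within-cluster
similarity ρ genuinely interpolates between independent species (ρ = 0)
and indistinguishable ones (ρ → 1). Clustered species are labelled
"grass", singletons "forb". The default discriminability map
(EP 1.0 < LT 1.75 < LB 2.5 < FF 3.25 < FL 4.0) encodes the field
observation that flower views are the most informative and the
entire-plant view the least, with spacing wide enough that the five
single-perspective accuracies are clearly separated at desk scale.

**Image tier.** Small RGB images (32 px default) are rendered as a gray
field plus (i) a species-coded glyph — disc position, radius and color
derived from species identity, stripe texture varying by perspective —
with contrast proportional to d_p, (ii) an observation-level low-
frequency color tint of strength σ_b shared across the observation's
five images, and (iii) i.i.d. pixel noise of strength σ. The render
amplitudes (glyph 0.02, tint 0.12, noise 0.10 on the [0, 1] scale) were
fixed once so that, with the default discriminability and the desk
backends, single-perspective accuracies span chance to ≈ 0.85 rather
than saturating — a saturated benchmark cannot separate training
strategies or training sizes. Because the glyph texture differs across
perspectives while the tint is shared within an observation, a pooled
strategy-B scorer faces both capacity dilution and a spurious
observation-level signal, reproducing the qualitative A-over-B gap of
interest.

What the generators do **not** emulate: photographic nuisance factors
(blur, occlusion, exposure), intra-class pose variation, long-tailed
class frequencies, and any real correlation structure between
perspectives of actual plants. Passing tests on this data demonstrate
that the pipeline's bookkeeping, fusion arithmetic and evaluation are
correct and that the expected qualitative effects emerge under
controlled conditions — not that any particular accuracy level would be
reached on field photographs.

## Experiment scales and statistical design

The shipped experiments run on one CPU in seconds to minutes; scales
were chosen once, by power analysis with the score-tier simulator,
before the test suite was frozen:

* chance-level calibration: 20 species × 50 observations × 20 replicate
  seeds, compared at three standard errors;
* discriminability-ranking recovery: 10 species × 100 observations × 10
  replicates with the default (well-separated) d map, where perfect
  Spearman recovery is expected in ≥ 9 of 10 replicates;
* fusion-gain monotonicity: equal d = 3.5 for all five perspectives,
  σ = 1, 10 species × 100 observations. In weak-signal regimes the
  spread of same-size combination accuracies is pure Monte-Carlo noise
  and its sample standard deviation is not reliably monotone in
  combination size at any sample size; in the strong-signal regime
  higher-order fusions saturate, the systematic spread decrease
  dominates, and both the median increase and the spread decrease hold
  in essentially every replicate;
* strategy A vs B and the training-size ablation: image tier at
  10 species × 30 observations × 32 px with the logistic backend,
  σ_b = 1.5 and 1.0 respectively.

## Determinism

Every pipeline artifact is reproducible byte-for-byte from (data,
parameters, seed): per-species split streams and per-image augmentation
streams are hash-derived, the logistic backend is deterministic, the MLP
is seeded, floats are serialized with fixed formats ("%.10g", ≥ 9
significant digits, which round-trips scores well below the 1e-6
normalization tolerance), and JSON keys are sorted. Seed and
configuration hash are stamped into the split file header and the
`run.json` metadata file of each run directory.

## Known limitations

* The desk backends are linear or shallow; they demonstrate the
  methodology, not state-of-the-art recognition, and image-tier accuracy
  levels are not comparable to transfer-learned deep networks.
* Fusion is the unweighted sum rule only — no weighted, product-rule,
  max-rule or learned combination.
* The evaluation reports no significance tests between combinations,
  only per-combination standard errors of the species mean.
* Score-tier and image-tier discriminability scales are not
  commensurable: d = 1 means different accuracy levels in the two tiers.
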