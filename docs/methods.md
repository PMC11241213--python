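# Methods

## Search model

All five engines optimize over binary feature masks **x** ∈ {0,1}ⁿ.
Internally each candidate carries a real position vector **p** ∈
[−B, B]ⁿ with B = 6; the mask is drawn through the sigmoid transfer
function σ(p_i) = 1/(1+e^(−p_i)). Two binarization rules are provided:

- `sigmoid_stochastic` (default): bit i is 1 with probability σ(p_i).
- `sigmoid_threshold`: bit i is 1 iff σ(p_i) > 0.5 (an exact 0.5 maps
  to 0; the strict inequality is the fixed tie rule that keeps runs
  bitwise reproducible).

The bound B = 6 keeps selection probabilities inside
[σ(−6), σ(6)] ≈ [0.0025, 0.9975], so no bit ever freezes irreversibly
and positions cannot diverge.

### Fisher-mantis engine (reference variant)

The mantis metaheuristic is specified in the literature only by its
linear state-decay schedule and by prose hunt/abandon semantics; the
concrete update used here is therefore defined by this repository as the
reference variant. Per iteration *it* (0-based), for every member with
position **p**:

1. **Attack** — pull toward the best-known solution:
   `p ← p + r ⊙ (e(x*) − p)`, with r ~ U(0,1)ⁿ elementwise and
   e(x*) = (2x* − 1)·B the saturated encoding of the best-ever mask x*.
2. **Ambush/retreat** — exploration perturbation:
   `p ← p + m_t · ε`, ε ~ N(0, I), with amplitude

   `m_t = m − m · it / MaxIt`

   decaying linearly from the initial state scale m (default 1.0) to
   exactly 0 at it = MaxIt, where the move degenerates to a pure pull.

Positions are clipped to [−B, B], masks re-drawn, fitnesses
re-evaluated, and the best-ever candidate updated monotonically.

Anchoring attractors at the saturated encoding of the best *mask*
(rather than at the raw position that happened to sample it) is the
usual construction in binary swarm optimizers: it drives selection
probabilities toward 0/1 as the population agrees, which is what makes
the engines close out OneMax-style problems instead of hovering at
σ ≈ 0.5. The same device is used for the PSO personal/global attractors
and the GWO leaders.

### Baselines

- **GA** — generational, on the masks directly: with probability 0.9 a
  member's mask is replaced by a uniform crossover of two size-2
  tournament winners, then bits flip with rate 1/n; elitism reinstates
  the best-ever mask only if variation lost it (so zero-rate variation
  leaves the population multiset untouched). Position kept as ±1
  encoding of the mask.
- **PSO** — inertia-weight velocity update (w = 0.7, c1 = c2 = 1.5,
  |v| ≤ 4) toward the encoded personal-best and global-best masks;
  position integrates velocity and is binarized as above.
- **ACO** — per-bit pheromone τ ∈ [0.01, 0.99], initialized 0.5; each
  ant samples its mask from Bernoulli(τ); after the colony evaluates,
  τ ← (1−ρ)τ + ρ·x* with evaporation ρ = 0.1.
- **GWO** — encircling around the three best wolves with the customary
  a: 2 → 0 linear decay (a = a₀(1 − (it+1)/MaxIt), exactly 0 at the
  final iteration, collapsing the pack onto the leaders).

All hyperparameters are textbook defaults, overridable via
`OptimizerConfig.params`, and echoed into every run report.

### Determinism and invariants

One `numpy` generator seeded from `OptimizerConfig.seed` drives every
draw in fixed member order, so runs are bitwise reproducible. For every
algorithm and seed: the best-so-far trajectory is monotone; population
size, dimension and the {0,1} mask domain are conserved; the history
vector has length `max_iter + 1` (including the uniform-[−1,1]
initialization). An optional `patience` stops selection after that many
iterations without improvement (pipeline default 20; direct
`run_optimizer` calls default to no early stopping, preserving the exact
iteration count).

## Wrapper fitness

`fitness(x) = CVacc(x) − α·|x|/n`, with CVacc the stratified k-fold
(default 5) cross-validated accuracy of the configured classifier on the
masked columns. Folds are shuffled with the fitness seed; features are
z-scored inside each training fold only. α defaults to 0.01 and must be
< 1 so the accuracy term always dominates; α = 0 gives pure CV accuracy.
All-zero masks are invalid; the engines repair them by setting one
uniformly random bit rather than assigning a sentinel penalty, keeping
every evaluated fitness finite. Masks are cached by byte pattern inside
one selection run, so the evaluation budget counts *distinct* masks.

Classifier bank (scikit-learn behind the package's interfaces): KNN (k = 5,
Euclidean, ties resolved by stable neighbor order), SVM (RBF, C = 1),
decision tree, "ensemble" = 100 bagged decision trees, Gaussian naive
Bayes.

Final metrics are never taken from the selection objective: the table is
split (stratified, default 70/30) before selection, the optimizer sees
only the training partition, and the report carries held-out
sensitivity/specificity/accuracy/PPV/NPV/F1 (percent) and ROC/AUC. A
metric with a zero denominator is flagged `None`, never imputed. The
all-features baseline fitness is always recorded alongside the selected
mask so a worse-than-baseline selection is visible in the report.

## Imaging front end

Augmentation samples rotation ∈ [−15°, 15°], shift ∈ [−20%, 20%] of
each dimension, scale ∈ [0.8, 1.2] (all uniform), then a uniformly
placed crop to 700×700 (defaults sized for 768×768 source images) and
independent coin-flip horizontal/vertical mirrors. Operators apply in
the fixed order rotate → scale → shift → crop → flips, composed into a
single bilinear warp with reflect padding, so one interpolation pass
runs per output and no black corners leak class-correlated artifacts
into features. Geometric ops preserve the canvas; the crop is validated
against the canvas size and failures name the offending spec field. A
degenerate spec (zero rotation/shift, unit scale, full-size crop, flips
off) is an exact pixel identity. When augmented images enter the
pipeline, the train/test split is made at the *source image* level so
augmented copies of one image never straddle the split.

Feature extraction is pluggable. `toy_projection` (default, fully
offline) resizes the grayscale image to 64×64, computes the 8×8 grid of
block means plus per-block variance and Sobel edge density (192 raw
descriptors), and applies a fixed Gaussian random projection (seeded by
`projection_seed`, scaled 1/√d_in) to the requested embedding dimension
(default 64). `googlenet` / `resnet50` load pretrained torchvision
backbones with the classifier head removed, 224×224 inputs and canonical
ImageNet normalization, yielding 1024-/2048-d pooled embeddings; if
torch is unavailable the error says to use `toy_projection`. An optional
per-channel histogram-equalization hook exists and is off by default.

## Synthetic generators

`gen_feature_table` plants `n_informative` randomly placed columns whose
class-conditional means differ by `effect_size · noise_sd`
(identity covariance by default; an optional equicorrelation parameter
adds a shared latent factor to stress redundancy handling); all other
columns are pure noise. Random placement prevents position-dependent
selection bugs from passing tests. `gen_images` scatters dark elliptical
blobs over a noisy bright pink-tinted background, with per-class blob
density and radius — a cartoon of cellularity differences between
carcinoma and normal mucosa. Both generators are pure functions of their
spec, seed included.

What the generators do *not* emulate: staining variation, spatial
texture correlation, tissue architecture, batch effects, or the
covariance structure of real CNN embeddings. Passing tests therefore
demonstrate correctness of the search, scoring and reporting machinery
— not clinical performance on histopathology slides.

## Problem sizes and numerical choices

The test and acceptance workloads use deliberately modest sizes chosen
to exercise each property at full strength: OneMax at n = 20 (20 seeds,
200 iterations), exhaustive-equivalence on 8-feature tables (255 masks
enumerable exactly), planted recovery at 500×256 with 16 informative
columns and effect 1.5 (weak enough that selection has to work for it),
and the image pipeline at 50 synthetic 96×96 images with a 32-d toy
embedding. Oracle agreements (metric arithmetic, Mann–Whitney AUC) are
asserted to 1e−9; exhaustive-equivalence to 1e−12; the decay schedule's
second differences to a few machine epsilons relative to m.

Other fixed choices: report JSON uses sorted keys so reruns are
byte-comparable (timestamps live in one removable key); CSV feature
tables round-trip floats through the shortest-repr formatting; the
positive class is always label 1 = cancer; F1 is computed from PPV and
TPR in percent space (algebraically identical to proportion space).

## Known limitations

- The mantis update couples the linear decay schedule above with
  repository-defined hunt/ambush operators; other implementations under
  the same name may differ in the perturbation law.
- Wrapper selection with small α keeps weakly penalized noise features
  when the classifier is already near ceiling; recovery is enrichment
  (Jaccard above a size-matched null), not exact support recovery.
- Stochastic engines are not guaranteed to match exhaustive enumeration
  on every random landscape at a fixed budget; the equivalence property
  holds at the documented budget and seeds and is reported as a match
  rate by the acceptance script.
- `grid_search` re-runs selection per grid point; its cost is the
  product of the grid with the selection budget.
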