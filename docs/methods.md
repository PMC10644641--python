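# Methods

## Model

`gexgan` trains a conditional Wasserstein GAN with gradient penalty whose
critic sees three aligned views of the training matrix.  Given a
samples × genes training matrix X₁ (log-transformed, per-gene z-scored),
two K-nearest-neighbour graphs are built over the samples — one under
Euclidean distance, one under cosine distance — each symmetrized by union
(an edge exists if either endpoint selects the other) with ties in
neighbour rank broken toward the lower sample index for determinism.  One
parameter-free linear graph convolution

    X₂ = D̃_E^(−1/2) (A_E + I) D̃_E^(−1/2) X₁,
    X₃ = D̃_C^(−1/2) (A_C + I) D̃_C^(−1/2) X₁

smooths every sample toward its neighbours (identity activation, no learned
weights, a single layer).  The smoothed views act as enriched training
samples: they present the critic with locally averaged variants of the real
data, which regularizes the feedback reaching the generator when the
training set is small.  The views exist only at training time; evaluation
and generation never touch them.

The generator maps `[z, y]` — a 128-dimensional standard-normal noise
vector concatenated with a one-hot encoding of the joint (tissue,
condition) class — through two 256-unit ReLU hidden layers to an unbounded
expression vector (no output activation, since z-scored expression is
unbounded on both sides).  The critic maps `[x, y]` through the same
architecture to a scalar score.  The three critics are fully weight-tied:
one parameter collection is evaluated on all three views, so the
multi-view structure enters the optimization only through the per-view
loss terms.  A consequence worth noting: the generator-dependent term
−E[D(G(Z|Y)|Y)] is identical across views, so the aggregate generator loss
is (1 + λ_g·n_aux/2) times the single-view term, with n_aux the number of
enabled auxiliary views.

Per view the critic maximizes E[D(Xᵢ|Y)] − E[D(G(Z|Y)|Y)] while the
gradient penalty λ·E[(‖∇_x̂ D(x̂ᵢ|Y)‖₂ − 1)²] enters the minimized critic
loss with positive sign (standard WGAN-GP practice).  The interpolate x̂ᵢ
is a per-sample uniform mixture of the view's real batch and the generated
batch; the penalty norm is taken over the expression coordinates only —
the label block is conditioning information, not part of the transport
space.  Auxiliary views are weighted λ_d/2 in the critic loss and λ_g/2 in
the generator loss.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `lambda_gp` | 10 | gradient-penalty strength (dimensionless) |
| `lambda_g` | 0.2 | auxiliary-view weight in the generator loss |
| `lambda_d` | 0.02 | auxiliary-view weight in the critic loss |
| `learning_rate` | 5·10⁻⁴ | RMSProp step size, both networks |
| `hidden_sizes` | (256, 256) | ReLU hidden layers, both networks |
| `noise_dim` | 128 | generator noise dimension |
| `knn_k` | 5 | neighbours per sample in both graphs |
| `n_critic` | 5 | critic updates per generator update |
| `batch_size` | 32 | minibatch rows |
| `max_epochs` | 500 | maximum training iterations |
| `patience` | 20 | consecutive non-improving evaluations before stop |

The λ's, learning rate, architecture, iteration cap and patience are the
published training recipe for this model family; `noise_dim`, `knn_k`,
`n_critic` and `batch_size` are unstated there and fixed at the values
above (WGAN-GP and KNN-graph conventions).  All randomness derives from a
single integer seed via independent child streams (initialization,
shuffling, noise, interpolation, validation), so a run is exactly
reproducible.

## Training schedule and early stopping

One **iteration** is the canonical WGAN-GP cycle: `n_critic` critic
minibatch updates (batches drawn from a without-replacement cycle over the
training split, reshuffled when exhausted, last short batch kept) followed
by one generator update.  An epoch-based schedule (one critic pass over
the data per validation) was considered and rejected: at the package's
working scale (~100 training samples, 4 minibatches per pass) it gives the
generator fewer than one update per validation and demonstrably leaves the
class-conditional means unconverged within the iteration budget.

After every iteration the model generates a batch matching the validation
set's size and labels from freshly drawn (deterministically seeded) noise,
and the gene-correlation `dist` between validation data and that batch is
recorded.  Training stops at `max_epochs` iterations or when the score has
failed to strictly exceed the **previous** evaluation's value for
`patience` consecutive evaluations; the returned model carries the
parameters of the best-scoring iteration.  Comparing each evaluation to
its predecessor (rather than to the running best) matters at desk scale:
with ~200 gene pairs the score's sampling noise makes the running maximum
an inflated, rarely beaten target, and a best-so-far rule halts training
long before the generator has matched the class-conditional means.  A
genuine plateau or decline still terminates the run.  If the generated
batch is correlation-degenerate (e.g. a collapsed generator emitting a
constant gene), the score is recorded as −1 rather than raising.

## Differentiation without an autodiff framework

The networks are small ReLU MLPs, so all derivatives are computed in
numpy.  The critic loss needs one non-standard derivative: the parameter
gradient of the penalty, which itself contains the input gradient
∇_x D(x).  For ReLU networks the activation masks are locally constant
almost everywhere, so ∇_x D is a product of masked weight matrices;
differentiating it again reduces to one forward-style Jacobian-vector
pass, and the penalty contributes exactly zero gradient to the biases —
the same result reverse-mode autodiff produces for ReLU nets.  Both the
first-order backprop and this double-backprop are verified against central
finite differences in the unit tests, and twenty full optimization steps
of the λ_g = λ_d = 0 reduction match an independently written single-critic
conditional WGAN-GP loop to ~1e-7 relative.

RMSProp follows v ← 0.99·v + 0.01·g², θ ← θ − lr·g/(√v + 10⁻⁸).

## Evaluation

* `dist(D^X, D^Z)` standardizes the upper triangles of the two gene–gene
  Pearson matrices by their means and population standard deviations, sums
  the products, and divides by the number of pairs n(n−1)/2 — i.e. the
  population Pearson correlation of the two triangles, so identical
  structure scores exactly 1.  The normalization is required for the
  statistic to live in [−1, 1] independent of gene count; the population
  (divide-by-n) form is used throughout, including inside the Pearson
  entries.
* TSTR: a classifier (random forest, 200 trees; 5-NN; or a 2×128 ReLU MLP)
  is fitted on the generated samples' normal/cancer labels and evaluated on
  held-out real samples; confusion-matrix metrics (accuracy, precision,
  recall, F1, MCC, with "cancer" the positive class) are averaged over 10
  seeded repeats.  Metrics with zero denominators are reported as missing,
  never as 0.
* Key-gene comparison: Pearson submatrices over a named gene list from
  real and generated data, with their element-wise maximum absolute
  difference.

Generated evaluation sets are always sized to the real comparison set per
class.  Gene-correlation matrices computed during training and evaluation
tolerate zero-variance columns by reporting 0 for the affected pairs; the
strict API raises and names the offending gene.

## Synthetic cohorts

`make_synthetic_cohort` draws each (tissue, condition) class from a
multivariate normal **on the normalized scale** (the space the GAN and all
metrics operate in): block-diagonal gene–gene correlation with a common
within-block value, within-class SD `noise_sd`, baseline mean 0, and a
`+effect_size·noise_sd` shift on the leading `de_gene_fraction` of genes
for the cancer condition.  The default specification — 20 genes in four
5-gene blocks at correlation 0.8, two classes of 100 samples, a 3-SD shift
on 5 genes — is small enough to train in under a minute yet structured
enough that recovery is meaningful: the correlation blocks are what `dist`
detects, and the condition shift is what TSTR detects.  Because the
shifted genes form one equicorrelated block, the analytic Bayes accuracy
of the two-class problem is Φ(d/2) with d² = e²·p/(1+(p−1)ρ) ≈ Φ(1.63) ≈
0.95, which bounds what any TSTR classifier can reach.

What the generator deliberately does not emulate: raw-count noise
(negative binomial dispersion, zero inflation), batch effects, and
library-size variation.  Passing tests therefore demonstrate that the
implementation recovers known low-dimensional Gaussian structure, not that
it handles the full noise anatomy of real RNA-seq — on real data the
log/z-score preprocessing in `gexgan.preprocess` absorbs part, but not
all, of that gap.

## Canonical experiment

`gexgan.benchmark.run_recovery_experiment` (what `scripts/acceptance.py`
runs): draw the default cohort, split it 50/50 per class, enrich and train
on one half with default hyperparameters, and measure on the held-out half
the best validation `dist` (versus an untrained copy of the same
initialization), the TSTR random-forest metrics on a generated set sized
and labelled like the held-out half, and the worst class-conditional
gene-mean error in SD units.  The 50/50 split (rather than a 10/90 one)
keeps 100 training samples, enough for the KNN graphs and minibatch
schedule to be meaningful at 20 genes.  Typical seeded results: trained
`dist` 0.95–0.97 against an untrained baseline near 0, TSTR accuracy
0.89–0.97, worst mean error 0.3–0.5 SD.

## Known limitations

* Fully tied critic weights are one reading of multi-critic "weight
  sharing"; a shared trunk with per-view heads is a plausible alternative
  the package does not implement.
* The joint (tissue, condition) one-hot label scales poorly past a few
  hundred classes.
* Training cost is quadratic in hidden width on CPU; the numpy
  implementation is sized for thousands of genes at most.
* Early stopping monitors correlation structure only; mean fit arrives
  later in training and is monitored only through the final evaluation.
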