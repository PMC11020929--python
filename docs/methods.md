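# Methods

This note documents the models, procedures and design choices behind
`curricnet`: what is simulated, with which parameters, and what the
desk-scale results do and do not show.

## The two-task curriculum

The study object is a two-task curriculum on composed digit scenes:

* **Task 1 (supporting)** — recognize a single digit scattered on a white
  84×84 canvas (the 28×28 glyph is padded, never resized, so the network
  must become position-invariant).
* **Task 2a (main, parity)** — report whether the sum of the *two* digits in
  a scene is odd or even. Equivalently the XOR of the component parities.
* **Task 2b (main, magnitude)** — report the sum X of the two digits through
  a 20-unit magnitude code, `l_i = 1 iff i ≤ X`.

Task 2a's error signal is *orthogonal* to single-digit identity: in a
parity-balanced scene set, each digit appears equally often in odd- and
even-sum scenes, so the expected main-task gradient with respect to any
digit-selective feature is zero until an XOR transformation already exists
upstream. The prediction is that Task 2a is unlearnable from scratch but
becomes learnable after Task 1 pretraining, whereas Task 2b — whose labels
correlate with each digit's presence — needs no curriculum.

## Network

A deliberately small CNN, shared trunk with two heads:

    conv 3×3 ×64 — ReLU — avgpool 2×2
    conv 3×3 ×32 — ReLU — avgpool 2×2
    [optional third conv ×32 — ReLU — avgpool]
    flatten — dense 10                    ← Task-1 loss (softmax cross-entropy)
    softmax — dense 2 — ReLU — dense 2    ← Task-2a loss (softmax cross-entropy)
    (magnitude variant: softmax — dense 20, sigmoid, mean-absolute-error loss)

The 10-unit layer is an *output* layer for Task 1, and the Task-2 head
consumes its softmax probabilities: for a two-digit scene this is a
"two-hot" digit code, which is what makes the XOR readable by the tiny
head. (A `head_input="relu"` option feeds rectified logits instead; in
pilots that variant left parity near chance even from near-saturated digit
representations.)

Adam, constant learning rate 1e-3 (variant 5e-4), batch 32, no
regularization anywhere, weights never frozen. Each head owns its optimizer
state; both losses backpropagate through the shared trunk. Initialization
is Glorot-uniform from the run seed, with a +0.1 bias on the 2-unit hidden
layer: with probability-scale inputs a zero-bias ReLU pair starts dead for
a sizable fraction of seeds, severing the whole main-task gradient path
(runs then sit at exactly 50% forever — one of the XOR head's bad basins).
The network is intentionally below ceiling on the main task; that is what
makes curriculum differences visible.

Numerical choices: convolutions use zero ("same") padding; pooling is
2×2/stride 2 with odd trailing rows dropped; classification logits are the
dense layers' pre-activations; the magnitude head applies a logistic per
output and predicts the sum as the count of outputs above 0.5, evaluated as
the mean squared error of that predicted sum (the training loss stays MAE —
the two roles are deliberately separated). Inputs are complemented
(`1 − x`) before the first convolution so the white background maps to zero
drive; with raw white-background input every unit receives a large constant
term that slowed learning about threefold in pilots. Everything is float32;
the engine is pure NumPy with BLAS-backed convolutions, so a run is
bit-reproducible for a fixed seed on a given platform.

## Curricula

Training material is cut into slices of `slice_size` exemplars sampled
without replacement. Regimes:

* **static** — one pooled subset of `n · slice_size`, presented for 3 epochs;
* **continual** — `n` disjoint slices, 3 epochs each, visited once in order
  (exemplar-incremental learning);
* **reversed** — the main task is trained first, then the supporting task;
* **class_incremental** — supporting-task slices introduce two previously
  unseen digit classes per stage (5 stages).

The main-task phase always uses the sequential disjoint-slice procedure
(identical across pretraining regimes, for comparability), except the
magnitude variant, which pools its main-task set (static), matching its
simplified learnability design. Held-out performance is evaluated after
every slice (configurable; the fastest configurations evaluate only at the
end), and training-slice performance is accumulated from the final epoch's
minibatch predictions.

Replicate runs differ only in the network seed:
`seed_k = base_seed + 10007·k`.

## Switching metrics

Four families of signals a learner could monitor to decide when to leave the
supporting task, evaluated against the hindsight criterion:

* **optimal switching window** — the set of pretraining amounts whose mean
  final main-task performance reaches the top decile of the observed means
  (lower-interpolation 90th percentile, so the cut is an observed value and
  the window always contains the argmax); its smallest element is the
  optimal switching moment.
* **performance threshold** — first pretraining slice whose held-out
  supporting-task accuracy crosses a threshold.
* **initial competence** — main-task held-out performance after its first
  training slice.
* **prediction gain** — first differences of performance across slices.
* **Fisher Information** — diagonal empirical Fisher of the weights:
  per weight, the mean over sample items of the squared gradient of the
  output log-likelihood with labels drawn from the model's own predictive
  distribution (categorical for softmax heads, per-unit Bernoulli for the
  magnitude head); the reported scalar is the mean over all weights, making
  it invariant to weight ordering and sample partitioning. FI can be
  computed under either task's loss, on the current slice or on candidate
  next-step slices (on copies of the state, never mutating the run).
  The estimator is validated against the closed form `mean(p(1−p)x²)` of a
  one-weight Bernoulli-logistic model and against a per-example
  squared-gradient loop.

Pairwise comparisons of FI across pretraining amounts use Welch's t-test
with no multiplicity correction (the comparison table reports raw pairwise
p-values); correlations are Pearson with two-sided p-values. The report
machinery never assumes a metric carries signal: degenerate or absent
inputs are reported as such.

## Synthetic glyph corpus

Real handwritten-digit data is not downloaded; the corpus generator emulates
its statistical structure: 10 glyph classes at 28×28 in [0,1], dark ink on a
white background, balanced classes, and per-"writer" style variation.
Templates are hand-designed seven-segment-style digits with 3 px strokes and
a large footprint, so class differences are low-frequency and survive two
rounds of average pooling — the property of handwriting that makes digit
classes separable to a small CNN. (An earlier 2 px design left several
class pairs differing by less than one pooled pixel and capped held-out
digit accuracy near 0.58.) Each writer is a fixed style drawn once:
rotation ±15°, shear ±0.15, translation ±2 px, stroke dilation ∈ {none, 2 px},
plus per-image Gaussian pixel noise (σ = 0.05, clipped to [0,1]). Writers
are assigned round-robin within class.

What the generator does *not* emulate: genuine stroke topology variation
between exemplars of one writer (images of one (class, writer) pair differ
only in pixel noise), curved strokes, slant correlated with writer identity
across classes, or label noise. Passing tests therefore show that the
*pipeline and phenomena* behave as designed on a corpus with MNIST-like
coarse statistics — not that any result would transfer quantitatively to
real handwriting.

Scenes paste one or two glyphs at uniform positions with disjoint 28×28
bounding boxes (rejection sampling; paste is pixel-wise minimum so ink wins
over background exactly). Two-digit scene classes cycle through shuffled
blocks of the 100 *ordered* digit pairs: every block is exactly
parity-balanced (chance on Task 2a is exactly 50%), each digit is equally
represented, and all 55 unordered pair classes appear in any 550 scenes.

An IDX-container reader/writer lets users substitute real data (with an
`invert` flag for the usual light-on-dark polarity); nothing else depends
on it.

## Desk-scale study conditions

The full-scale experiment (30 000-exemplar pools, slices of 1250, up to 24
slices per task, 8–12 replicates) is far beyond a single CPU. The packaged
scenarios run a scaled-down version whose qualitative structure is the same;
these sizes are the package's study conditions, fixed once:

| scenario | pretraining n (slices, regime) | main slices | slice | replicates | test set |
|---|---|---|---|---|---|
| no_pretrain_chance | 0, continual | 8 | 400 | 4 | 1000 |
| curriculum_benefit | 8, static | 8 | 400 | 1 | 600 |
| reversed_order | 1 after, continual | 8 | 400 | 1 | 600 |
| overtraining_detriment | 1/3/8, continual | 8 | 400 | 4 | 1000 |
| magnitude_no_pretrain | 0/2/4, static | 3 (static) | 400 | 2 | 600 |
| class_incremental_forgetting | 5, class-incremental | 8 | 400 | 2 | 1000 |

Corpus: 9000 glyphs (900 per class, 50 writers), split 75/25 into train and
evaluation pools; 3 epochs per slice (or per pooled static subset); batch
32; Adam 1e-3. Every scenario validates a gradient-step ceiling so the
whole suite stays desk-sized. The benefit scenario pools its pretraining
(static) because disjoint 400-exemplar slices starve position-invariant
digit learning at this scale; replicate counts are the minimum that makes
each scenario's statistic well-defined within a single-CPU test budget.
The `overtraining_detriment` grid is provided and constructible but its
full-size contrast is not exercised in the test suite; the continual
overtraining effect rests on error accumulation over long exemplar-
incremental sequences that this desk scale cannot reach honestly.

## What the desk scale can and cannot show

The orthogonality phenomena reproduce cleanly at desk scale: with zero or
reversed pretraining the parity task sits at chance however long it is
trained, and the magnitude task behaves the same with and without
pretraining. The *size* of the curriculum benefit does not transfer: under
the fixed 3-epochs-per-subset procedure, held-out digit accuracy saturates
near 0.73–0.75 whether the pool holds 6400 or 9600 digits; at that
competence both digits of a two-glyph scene are jointly readable from the
10-unit code in under a fifth of scenes, an oracle classifier on that code
tops out near 0.57 parity accuracy, and the 2-unit head recovers a few
points above chance (+0 to +6 across seeds). The full-scale benefit rests
on a digit competence that only the full 30 000-exemplar budget reaches.
The benefit scenario therefore measures a real but small lift; treat its
magnitude as a floor, not an estimate of the full-scale effect.

The magnitude task has an analogous caveat in the other direction: MAE
training moves each linear output toward its per-unit median at a fixed
Adam-step rate, so calibration alone needs on the order of a thousand
updates — more than the desk-scale main phase contains. The desk scenario
verifies the *equality* claim (pretraining neither helps nor hurts
beyond between-run spread, because the error signal is not orthogonal to
the digits), while absolute sum error remains in the calibration regime.

## Known limitations

* The 2-unit XOR head retains bad basins even with the live-start bias;
  replicate variation in the curriculum scenarios partly reflects that,
  which is why grids are replicated at all.
* Fisher Information traces are optional (off by default in the fast
  scenarios) because per-example gradients double a slice's cost.
* The t-SNE step calls scikit-learn (2 components, perplexity 40, 300
  iterations, random init, no prior dimensionality reduction); its internals
  are out of scope.
* Images of one (class, writer) pair differ only by pixel noise; real
  handwriting varies in stroke topology within a writer.
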