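# Methods

## Scope and data model

`bulklabel` models the object-labeling workflow of embedding-guided bulk
annotation: a *project* holds ROI images with instance segmentation masks
(positive integer id per object, 0 = background), one derived
`ObjectInstance` per id (centroid = arithmetic mean of the id's pixel
coordinates, area, half-open bbox), and exactly one fixed-size patch per
object. Coordinates are 0-based `(row, col)`; centroids are rounded
half-away-from-zero before cropping; patches extending past the image are
zero-filled (black), which keeps border objects visually explicit during
review. Everything — images, objects, labels, the full event history, and
model checkpoints — lives in one SQLite file, so a project is a single
portable artifact. A new confirmed label overwrites the previous one but
appends a new event, so the history remains auditable.

Labels are integer class ids `1..K` or special string labels (default
`"unsure"`); specials are stored and exported but never enter supervised
training or, by default, concordance.

## Synthetic study data

The generator emulates the shape of real inputs — pre-cropped ROIs plus
instance masks plus a known class per object — without attempting
photorealistic histology. Objects are axis-aligned ellipses placed by
rejection sampling (1000 attempts per object, then a hard `PackingError`;
never silent truncation), with disjoint footprints. Each class has a base
hue on the color wheel and a sinusoidal texture frequency; a single
`separability ∈ [0,1]` interpolates all class parameters toward a common
mean, so one scalar controls task difficulty. Texture is mean-centered per
footprint, making the mean fill color exactly the class color at zero
noise. Pixel-level Gaussian noise (`noise_sd`, default 0.05 on a [0,1]
scale) is independent of separability.

Default conditions, used by the test suite and the acceptance script: 10
images of 128×128 px, 30 objects each (300 total), K = 3, separability 0.9,
radii 5–9 px, 32-px patches. This is a desk-scale stand-in for a
nuclei-style use case: easy enough for a tiny encoder to learn in seconds,
but not solvable perfectly from raw pixels (raw-pixel 10-NN purity is
~0.78 because object shape and position dominate pixel distance). What
passing on this data shows is that the *mechanism* works — contrastive
features separate appearance classes, fine-tuning sharpens them, bulk
labeling is faster than unaided labeling; it does not certify performance
on real stains, staining variability, segmentation errors, or class
imbalance, none of which the generator models.

`corrupt_labels` models annotator error: each row flips to a uniformly
random *different* class with probability `error_rate`.

## Representation learning

The encoder is a small residual multi-layer perceptron over the flattened
patch: input projection to `hidden_dim` (default 128), `n_blocks` residual
ReLU blocks (default 1), linear map to `feature_dim` (default 64); a
two-layer projection head (to `projection_dim`, default 32) feeds the
contrastive loss, and a linear classification head (K outputs, near-zero
init so an untrained model predicts ~1/K) feeds the supervised term.
Convolutional backbones were deliberately not used: the package's training
loop is pure NumPy with explicit backpropagation, chosen so that training is
bit-reproducible, dependency-light and fast on one CPU at the supported
problem sizes; an MLP keeps the hand-written gradients simple, and `BACKENDS`
leaves room for alternative self-supervised back ends. The `encoder_size`
input resolution defaults to the patch size; the tests pool 32-px patches to
16 px, which preserves the color/texture signal the synthetic classes carry
while shrinking the input 4×.

Augmentation per view: random resized crop (area scale 0.6–1.0),
horizontal/vertical flips, per-channel color jitter (±0.15), Gaussian noise
(σ = 0.02), then resize to `encoder_size`. Setting all strengths to zero
makes augmentation the identity, which the tests exploit.

NT-Xent: cosine similarities of the L2-normalized projections divided by
τ (default 0.5); each view's loss is the softmax cross-entropy of its
positive among the other 2N−1 views, averaged over 2N views. The analytic
gradient (through the normalization) is verified against finite differences
and the loss against an independent scalar double-loop in the tests.
Fine-tuning adds `λ · cross-entropy` (λ default 1.0) over the labeled views
in each batch; with no labels the supervised branch is skipped entirely, so
an empty-label fine-tune is exactly a self-supervised continuation.

Optimization: Adam (lr 1e-3, cosine decay within each call), batch 64,
20 pre-training / 8–10 fine-tuning epochs by default. The data-order and
augmentation RNG is seeded from `(config seed, optimizer step)`, so a
fine-tune continuation is reproducible but distinct from a fresh run.
Model state (weights + Adam moments + step) serializes bit-exactly via NPZ.

## Embedding, retrieval, purity

UMAP (n_neighbors 15, min_dist 0.1, fixed `random_state`) is the production
2-D projection; PCA (full SVD) is the deterministic fallback on which all
geometric unit tests run, since UMAP's numerics make bit-exact cross-run
assertions fragile. The embedding is recomputed from scratch at every
iteration. Retrieval is exact brute-force nearest-neighbor in feature
space, ties broken by object id. `knn_purity(X, labels, k)` — mean fraction
of each labeled point's k nearest labeled neighbors sharing its label — is
the package's proxy for class separation; it is invariant under rigid
transforms and requires ≥ k+1 labeled points.

## Session engine and the simulated annotator

All session time is simulated: annotator actions cost
`seconds_per_action` (bulk lasso + class key, default 8 s) or
`seconds_per_single_label` (default 2 s), and each `run_iteration` appends
one training and one embedding compute interval of configurable simulated
duration (defaults 60 s and 15 s, a deliberately modest stand-in for
GPU-scale training). Wall-clock timing would make every efficiency metric
nondeterministic; simulated costs make them exact and configurable. Human
time = session span − compute intervals.

Policies:

- `one_at_a_time` — the unaided baseline: random order, fixed cost per
  label, no model.
- `peripheral_bulk` — repeatedly picks the unlabeled point farthest from
  the embedding centroid (the periphery holds the most cleanly clustered
  objects), selects its `bulk_size` (40) nearest unlabeled neighbors in 2-D
  as a lasso surrogate, and labels the selection with its majority true
  class; fine-tune/re-embed every 5 bulk events; finally a grid-review pass
  corrects members of mixed selections one at a time (`review_edit`
  events), emulating tile-level label review. At `error_rate 0` this makes
  final concordance with truth exact.
- `interface_refine` — labels the lowest-confidence unlabeled objects one
  at a time (the class interfaces), retraining every 50 labels.

An action is taken only if it finishes within the budget, so a budget below
one action yields an empty event list. All assignment decisions (majority
votes, single labels, corrections) are corrupted independently at
`error_rate`.

## Metrics

`lps = n / t` with `t > 0`. `n_labels` counts *distinct* objects holding a
final confirmed label — relabels do not double-count (a session log loaded
from CSV lacks object identities and falls back to summed event sizes).
Windowed LPS uses a 900 s window advancing by 300 s from the session start,
last window clipped; a window's denominator excludes compute time inside
it, keeping windowed rates human-time rates, and fully-compute windows are
skipped. θ is computed against human-time LPS. Report formatting follows
the conventional precisions (LPS 3 d.p., θ 2 d.p., concordance integer
percent).

## Numerical and design choices

- Ties: retrieval and the annotator's argmin/argmax break ties by object
  id / stable order, for cross-platform determinism.
- Lasso on-edge points are *inside* (boundary-inclusive covering), matching
  user expectation for inclusive selection.
- NT-Xent guards: norms clipped at 1e-12; ≥ 2 pairs required (a single pair
  has no negatives).
- Degenerate inputs: empty masks import cleanly as zero objects; patches
  larger than the image are legal (all-padding corners); PCA on 1-D feature
  spaces pads a zero column.
- Problem sizes throughout tests and the acceptance script (300 objects,
  16-px encoder input, ≤ 20 epochs) were chosen so a full run completes in
  well under a minute on one CPU while leaving clear margins on every
  asserted direction-of-effect.

## Known limitations

- The annotator model has no fatigue, learning, or visual-search time; its
  review pass consults the ground truth directly, which is optimistic about
  how completely a human reviewer spots mislabeled grid patches.
- The MLP backbone is not translation-invariant; it relies on objects being
  centered by construction. Real pipelines with sloppy segmentation
  centroids would favor a convolutional backbone behind the same interface.
- Absolute LPS values and speed-ups depend directly on the simulated cost
  parameters; only directions and ratios under *identical* costs are
  meaningful. The package asserts direction (bulk > unaided), not any
  particular magnitude.
- UMAP determinism holds for a fixed seed, library version and thread
  count, not across versions.
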