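# Methods

## Models

Both model families are recurrent message-passing networks for
graph-level prediction. Each node `n` of a molecular graph holds a state
vector `x_n` of dimension `d_x`, initialized i.i.d. uniform on
`[-init_scale, +init_scale]` per coordinate (zero-centered; `init_scale`
defaults to 0.1 and is seeded, so a forward pass is a pure function of
the batch and the configuration). States are updated synchronously for a
fixed `K` iterations (no convergence test; `K = 6` by default). The
update input of node `n` concatenates its previous state, its label, and
the *sum* over neighbors of the concatenated message components; because
summation and concatenation commute blockwise, the aggregate is computed
as a sparse adjacency product per component. The empty sum (isolated
node) is the zero vector.

The standard model's message is `(x_m, l_m, e_mn)` — the neighbor label
is part of the message. The composite model's message is `(x_m, e_mn)`:
each node of type `i = T(n)` is updated by a dedicated single-hidden-layer
MLP `f_{w,i}`, and the neighbor's type information reaches `n` through the
neighbor's state, which its own typed updater produced. The
`include_neighbor_label` flag on the standard model makes this composition
difference explicit; the single-type equivalence test disables it so the
two families coincide exactly when weights are copied.

All state updaters of a composite model share the output dimension
`d_x`, so nodes of different types exchange messages without adapters. A
single output network serves both families: a sigmoid-headed MLP applied
to `(x_n^K, l_n)` per node and averaged over all nodes of a graph. Mean
readout (rather than sum) keeps the output scale independent of graph
size and preserves permutation invariance.

Types come from an 8-group partition of the elements: C, N, O, P and S
have singleton groups; everything else is pooled as metals, metalloids or
halogens by standard periodic-table classification (Se and Po counted
with the metalloids, At with the halogens). Hydrogen and the noble gases
have no group — heavy-atom molecular graphs do not contain them — and are
rejected with an explicit error. The table ships as package data and can
be replaced via `ElementGrouping.from_json`. For the standard model the
group is one-hot encoded (8 columns) into the node label; for the
composite model the label deliberately does *not* encode the species.

## Networks and optimization

Every network has exactly one hidden layer; deeper variants are out of
scope. The hidden layer and the state-updater output layer share one
activation (relu / tanh / selu, a searched hyperparameter); the output
network ends in a logistic sigmoid, for classification directly and for
regression after min-max normalization of the training targets to
[0, 1] (evaluation happens on the original scale after the inverse
transform; a constant target column is an error). Weights are
Glorot-uniform, fully determined by (spec, seed).

Gradients are exact reverse-mode derivatives of the unrolled `K`-step
recurrence, implemented directly in numpy (state initialization is a
constant with respect to the parameters). Losses are masked: multi-task
binary targets may have missing entries (NaN), which contribute neither
value nor gradient; the loss is the mean BCE (or MSE) over observed
entries. Probabilities are clipped at 1e-7 inside the loss only.
Optimization is Adam with textbook β₁ = 0.9, β₂ = 0.999, ε = 1e-8; only
the initial learning rate is searched. Early stopping monitors validation
loss after every epoch with patience 10: any non-strict-decrease counts
against patience, and the best-epoch weights are restored at the end.
Training is full-batch by default; a mini-batch size can be configured
(with full-batch gradient descent one epoch is a single Adam step, which
interacts poorly with epoch-based patience — see the calibration note
below).

## Metrics and model selection

AUROC (rank / Mann–Whitney formulation, ties half credit), average
precision (precision at each positive's rank), and RMSE delegate to
scikit-learn, wrapped with per-task missing-label exclusion; multi-task
scores average the evaluable tasks (both classes present for AUROC, at
least one positive for AP) and warn about dropped tasks. The metric per
benchmark dataset is fixed: AUROC for HIV / Tox-21 / BACE / BBBP /
ClinTox / Sider, AP for MUV, RMSE for FreeSolv.

The hyperparameter grid crosses 4 learning rates × 4 state-updater hidden
sizes × 4 output hidden sizes × 5 state dimensions × 3 activations = 960
configurations per model kind. `run_sweep` trains each with early
stopping, scores the validation split with the dataset's metric, selects
the optimum (ties broken by enumeration order), and evaluates only the
selected configuration on the test split. Per-config seeds are
`base_seed + index` (mod 2³¹) so sweeps resume and parallelize
reproducibly; configurations that diverge are recorded as failed and
excluded from selection.

## Synthetic data

The generator emulates the *shape* of molecular benchmark data — not its
chemistry: connected graphs (random spanning tree plus uniformly added
edges up to a target density) of 5–15 nodes by default, node types drawn
from a carbon-dominated group mix (55 % C, 12 % N, 14 % O, …), optional
constant bond-indicator edge labels, and graph-level targets that are
pure functions of the typed structure so tests can recompute them:

* `type-fraction` — binary; 1 iff the fraction of nodes of a chosen group
  exceeds a threshold (default: oxygen fraction > 0.15, roughly balanced
  under the default mix). Label noise flips labels with probability
  `noise_level`.
* `type-weighted-sum` — regression; the sum over nodes of a per-group
  weight, plus Gaussian noise of sd `noise_level`.
* `type-pair-sum` — regression; the sum over bonds of a symmetric
  per-type-pair interaction weight (a fixed 8×8 matrix), plus Gaussian
  noise.

Valence limits, aromaticity and real bond features are deliberately not
modeled: the models under test respond to typed-graph structure only, so
passing tests demonstrate correct learning on type-dependent structural
signal, not chemical accuracy or transfer to real assay data. Splits are
80/10/10 by graph, seeded.

## Desk-scale model comparison (calibration note)

The headline qualitative claim — the composite model matches or beats the
standard model — is checked at desk scale on a synthetic regression task
with 600 graphs, noise sd 0.3, five seeded replicates, and one fixed
small configuration for both models (`d_x = 5`, hidden sizes 20/20, tanh,
learning rate 1e-2, mini-batches of 32, ≤ 300 epochs, patience 10). Two
calibration choices matter and were made deliberately:

* **The planted rule is `type-pair-sum`, not `type-weighted-sum`.** A
  target that is linear in type counts can be read directly off the
  species one-hot that homogenization places in the standard model's node
  labels — both in every message and in the output network — so on that
  rule the two families are at statistical parity by construction. The
  pair-interaction rule makes the target depend on how the types of
  *bonded* atoms interact, which is precisely the signal that per-type
  state updaters specialize on; the composite advantage there is robust
  across disjoint seed sets.
* **Mini-batches of 32 rather than full batch.** With full-batch training
  an epoch is one Adam step, so patience 10 halts both models after a few
  dozen gradient updates — far short of convergence, and hardest on the
  composite model, which has eight updaters to coordinate.

Problem sizes throughout the suite (graph counts, node ranges, epochs)
are chosen so the full test run completes in about a minute on one CPU
while still exercising every code path at realistic shapes; the
comparison experiment above is the one deliberately larger computation.

## Numerical and degenerate-input conventions

* Edges are undirected bonds stored internally as two directed arcs;
  self-loops and duplicate undirected edges are rejected at construction.
* Batches are disjoint unions with block-diagonal adjacency; per-graph
  outputs are bit-identical whether a graph is alone or co-batched (the
  invariance tests pin this).
* selu's negative branch clamps the exponent argument to avoid spurious
  overflow in the unselected branch of the vectorized form.
* AUROC on a single-class task is undefined: an error for single-task
  input, a warned drop from the multi-task mean.
* `K = 0` is legal and returns the initial states; `init_scale = 0` gives
  deterministic all-zero initial states.
* All randomness (initial states, weight init, data generation, batch
  shuffling) flows through `numpy.random.default_rng` with explicit
  seeds; identical (data, config, seed) reproduces training records and
  final weights exactly.

## Known limitations

* No SMILES/SDF parsing or chemistry perception; inputs are typed graphs
  in the package's JSON dialect or benchmark raw-CSV layout.
* Node- and edge-focused output heads are not implemented (graph-level
  prediction only).
* The benchmark adapter reads the on-disk raw CSV layout only; it has
  been validated against hand-built miniature fixtures, not against full
  benchmark downloads, and full-scale benchmark results are outside the
  test surface.
* Training is CPU numpy; it is intended for desk-scale experiments, not
  for the multi-day full-grid sweeps of the large benchmarks.
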