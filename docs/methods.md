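# Methods

## Model

A reaction is a small set of molecular components (typically amine, aryl
bromide and product for a C–N coupling) plus optional categorical
components, mapped to a real-valued outcome. Each molecular component is
parsed with RDKit into a directed graph: atoms are nodes, every bond
contributes the two directed edges (v→w, w→v), and both directions share
one bond-feature row. Atom features are one-hot blocks for element (11
common elements + other), degree (0–5), formal charge (−2…+2), chirality
tag, attached-H count (0–4) and hybridization, plus an aromaticity flag and
the atomic mass scaled by 0.01 (F_a = 43). Bond features are type
(single/double/triple/aromatic), stereochemistry, conjugation and ring
flags (F_b = 14). Hydrogens are implicit; salts keep the largest fragment
with a warning. The molecule is renumbered into its canonical-SMILES atom
order at parse time and the edge list sorted, so every SMILES form of a
molecule yields a component-wise identical graph — a requirement because
the readout is order-sensitive.

The encoder is a communicative message-passing network. Initial states are
h⁰(v) = ReLU(W_vx x_v) and h⁰(e_{v,w}) = ReLU(W_ex [x_v; x_e]). Each of K
iterations computes, in order:

1. node message m^k(v): aggregation of incoming edge states
   h^{k−1}(e_{u,v}) — summation by default (`mean` and `max` are config
   options);
2. node update (the communicative function): h^k(v) =
   ReLU(W_comm [h^{k−1}(v); m^k(v)] + b). We use the simplest form
   consistent with "a learned transform of the concatenated pair": a single
   linear layer + ReLU;
3. edge message m^k(e_{v,w}) = h^k(v) − h^{k−1}(e′). By default e′ is the
   reverse edge e_{w,v} (`edge_message: reverse`), the established
   communicative-MPNN choice that stops a directed edge from echoing its own
   state back along the bond; `edge_message: self` subtracts the edge's own
   previous state instead and is exposed for comparison;
4. edge update h^k(e_{v,w}) = ReLU(h⁰(e_{v,w}) + W·m^k(e_{v,w})) — note the
   skip from the *initial* edge state, which anchors edge states to the bond
   identity at every depth.

After K steps a final communicative layer fuses [m(v); h^K(v); x_v] into the
node embedding h(v). A gated recurrent unit consumes the node embeddings in
canonical atom order from a zero initial state; the **terminal hidden
state** is the molecule vector (an alternative would be pooling the per-node
GRU outputs; the terminal state is simpler and performed equivalently in
smoke experiments). Width d is 300 by default, adjustable.

Reaction vector: component vectors are summed (width d; invariant to
component order) or concatenated in the schema's fixed role order — amine,
bromide, product — giving width d·n. One-hot blocks for categorical
components are appended **after** aggregation in both modes, because summing
an indicator into a learned 300-dimensional space is ill-typed. The head is
one ReLU hidden layer (width d) plus a linear unit.

## Training protocol

Outcomes are z-score normalized, x̂ = (x − μ)/σ, with μ, σ estimated from
the training portion only (no leakage; asserted by recomputation in tests)
and inverted before metrics. Loss is MSE on the normalized outcome,
optimized by Adam (learning rate 1e-3, batch 32, max 100 epochs by
default). 20 % of the training portion is held out as a validation set;
training stops after `patience` (default 10) epochs without validation
improvement and the best-validation checkpoint is returned. k-fold
cross-validation partitions the data into k disjoint test sets (80:20
train/test per fold at k = 5); per-fold metrics are reported as mean ±
standard deviation.

R² is the squared Pearson correlation between predictions and observations
(the yield-prediction literature's convention); the coefficient of
determination is computed alongside (`Metrics.r2_cod`) since the two differ
for miscalibrated predictions.

All randomness flows from one master seed fanned out (split / initialization
/ shuffling); two runs with the same seed are byte-identical, including the
serialized metrics JSON.

## Numerical implementation

The network is implemented in float64 NumPy on a small reverse-mode
autodiff core (`rxnyield._autodiff`) providing exactly the ops the model
needs (matmul, elementwise nonlinearities, concatenation, row
gather/scatter, segment reductions over the edge list). Every op's gradient
is verified against central finite differences in the test suite, and the
full encoder is checked elementwise (atol 1e-6) against a naive loop-based
reference implementation on small graphs, for all aggregation and
edge-message variants. Molecules are packed into one batched index space
per minibatch and deduplicated, so each unique structure is encoded once
per step. Parameters are Xavier-uniform initialized from a seeded
generator. `segment_max` routes gradients to the first maximizing row;
ties are measure-zero under continuous parameters. Empty aggregation
buckets (atoms with no incoming edges) receive the zero message.

## Synthetic screens

The generator emulates a plate-based amination screen: 12 amines and 12
bromides built from benzene/pyridine cores carrying H, Me, OMe, F, CF₃ or
CN substituents at ortho/meta/para positions, half benzenoid and half
pyridyl per role, so the four substrate-class quadrants G1–G4 all occur.
The product SMILES is a template join of the two substrates (diarylamine).
Each substrate receives a latent effect drawn once from a seeded normal
(sd = 1); the noiseless outcome is

    y₀ = sigmoid(base + e_amine + e_bromide + 0.5·e_amine·e_bromide)^skew

with skew = 3 by default, which piles outcomes up at low values (≈ 60 % of
reactions below 0.2 at the defaults) as real screens do. Measurement noise
is Gaussian (sd 0.05 by default) truncated at ±2 sd, and outcomes are
clipped to [0, 1]. The noiseless value and the substrate effect table are
persisted, making recovery measurable.

What passing on synthetic data does **not** show: the generator's outcome
is a smooth low-rank function of substrate identity with a single additive
noise scale; real plate data add spectral-integration artifacts, discarded
wells, condition (catalyst/base/solvent) effects and structure–activity
cliffs. Synthetic results certify the pipeline's correctness and its
ability to recover latent substituent structure, not field performance.

## Problem sizes and defaults

Training checks use the sizes the checks are stated at: 20 noiseless
reactions for the memorization check (R² ≥ 0.99) and a 500-reaction screen
with noise sd 0.05 under 5-fold CV for the recovery check (mean test
R² ≥ 0.8). For those runs the hidden size is 64 and depth 3 with at most
60 epochs (patience 8): molecule-level representation quality is flat in
vector size over a wide range, so the smaller width is the package's
standard choice for screen-scale datasets, while `ModelConfig` defaults to
the 300-wide encoder. Depth K = 3 is the customary message-passing radius
for small organic molecules (captures up to 3-bond environments).

## HTE data reduction

ratio_UV = (A_product × c)/A_IS × 100 % with c = 0.0625 equivalents of the
internal standard by default. Internally ratios are fractions in [0, 1];
percent is an I/O convention. Values above 1 (over-unity response ratios,
e.g. chromophore differences) are retained with a warning, never clipped.
Substrates are classified Ph vs Py by a SMARTS match on the six-membered
aromatic ring directly bearing the NH₂ or Br; fused or multi-ring systems
classify by that ring alone. Group summaries report counts and the fraction
of reactions at or above a ratio threshold (default 0.5); the heatmap
matrix uses 'A'-prefixed amine columns and 'B'-prefixed bromide rows with
NaN marking absent (failed/discarded) combinations.

## Known limitations

- The GRU readout makes molecule vectors depend on the canonical atom
  order; canonicalization makes this deterministic but it is still an
  arbitrary sequence, not a permutation-invariant pooling.
- One-hot categorical components cannot extrapolate to unseen categories
  (an explicit error at prediction time, by design).
- The NumPy training loop is single-threaded and sized for
  10²–10⁴-reaction datasets, not for large-scale pretraining.
- Pearson-based R² is insensitive to calibration; consult MAE/RMSE (and
  `r2_cod`) when predictions may be biased.
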