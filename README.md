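# rxnyield

Graph-based prediction of chemical reaction outcomes, with the data-reduction
utilities used by plate-scale high-throughput experimentation (HTE) screens.

## The problem

When chemists screen a coupling reaction — say a palladium-catalysed C–N
(Buchwald–Hartwig) amination across dozens of amines and aryl bromides —
they need a model that predicts the outcome (yield, selectivity, or a UV
response ratio) of combinations they have not run. `rxnyield` learns a
task-specific representation of each reaction directly from the 2D
structures of its components, with no precomputed fingerprints or quantum
descriptors.

## The model

Each reaction component is parsed into a **directed molecular graph**
G(V, E): every bond contributes two opposed directed edges, each carrying a
hidden state. A communicative message-passing encoder runs K iterations:

- **node update** — the incoming edge states are aggregated into a message
  m^k(v), and h^k(v) = ReLU(W_comm · [h^{k−1}(v); m^k(v)] + b);
- **edge update** — m^k(e_{v,w}) = h^k(v) − h^{k−1}(e_{w,v}) (the reverse
  edge is subtracted to suppress self-echo; a `self` variant is available),
  then h^k(e_{v,w}) = ReLU(h^0(e_{v,w}) + W · m^k(e_{v,w}));
- **readout** — after a final fusion of message, node state and raw atom
  features, a gated recurrent unit consumes the node embeddings in
  canonical atom order; its terminal state is the molecule vector
  (d = 300 by default).

Component vectors are combined into one **reaction vector** either by
elementwise summation (width d, order-free) or concatenation in a fixed
role order (width d·n, e.g. 900 for amine + bromide + product at d = 300).
Non-graph components (bases, catalysts named categorically) are appended as
one-hot blocks. A dense head (one ReLU hidden layer + linear unit)
regresses the z-score-normalized outcome; metrics (R² as squared Pearson
correlation, MAE, RMSE) are computed in original units over k-fold
cross-validation without replacement.

The network, including a small reverse-mode autodiff core, is implemented
in NumPy and trained with Adam and early stopping; everything is
deterministic under a fixed seed.

For HTE plates, the package also computes the internal-standard UV ratio

    ratio_UV = (A_product × c) / A_IS × 100 %,   c = 0.0625 eq.

and assigns each reaction to a substrate-class quadrant (G1 = Ph-NH₂ ×
Ph-Br, G2 = Ph-NH₂ × Py-Br, G3 = Py-NH₂ × Ph-Br, G4 = Py-NH₂ × Py-Br) with
per-group summaries and an amine × bromide heatmap matrix.

## Worked example

```python
import numpy as np
from rxnyield import (GeneratorConfig, generate, ReactionSchema,
                      ModelConfig, cross_validate, OptimizerConfig)

data, truth = generate(GeneratorConfig(n=500, seed=7, noise_sd=0.05))
schema = ReactionSchema(
    component_columns=["amine_smiles", "bromide_smiles", "product_smiles"],
    outcome_column="ratio_uv",
)
res = cross_validate(
    data, schema,
    config=ModelConfig(hidden_size=64, depth=3, reaction_mode="concat"),
    k=5, seed=0,
    optimizer=OptimizerConfig(max_epochs=60, patience=8),
)
print(res.summary())
```

prints (about 2–3 minutes on one CPU):

```
5-fold cross-validation
========================================
fold   R2      MAE      RMSE
   0   0.915   0.0358   0.0456
   1   0.838   0.0363   0.0484
   2   0.903   0.0355   0.0478
   3   0.880   0.0366   0.0489
   4   0.866   0.0351   0.0446
mean   0.881 ± 0.027   0.036 ± 0.001   0.047 ± 0.002
```

Mean test R² ≈ 0.88 means the model recovers most of the latent
substituent-effect structure of the synthetic screen; MAE ≈ 0.036 is the
average error on the unit-range UV-ratio outcome, below the scale of the
injected measurement noise (0.05), i.e. close to the attainable floor.

The same pipeline is available from the shell:

```bash
rxnyield generate --n 500 --seed 7 --out-dir screen
rxnyield cv --data screen/dataset.csv --k 5 --seed 0 --out-dir cv_out
rxnyield hte-reduce --data plate.csv --out-dir hte_out
```

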