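"""Reaction-level representation: aggregate component vectors and regress.

A multi-component reaction (e.g. amine + aryl bromide -> product) is encoded
by running the molecule encoder on every graph component and combining the
component vectors into one reaction vector, either by elementwise summation
(length d, order-free) or by concatenation in a fixed role order (length
d x n_components, order-sensitive). Components that have no sensible graph
structure (inorganic bases, catalysts identified only by name) enter as
one-hot indicator blocks appended after the aggregated graph block in both
modes. A small dense head (one ReLU hidden layer + linear output) maps the
reaction vector to the normalized outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._autodiff import Tensor, concat, matmul, relu

AGG_MODES = ("sum", "concat")


@dataclass
class ReactionSchema:
    """Column layout of a reaction table.

    component_columns: ordered SMILES columns (role order is fixed for the
    whole dataset and governs concatenation order, e.g. amine, bromide,
    product). categorical_columns: non-graph components encoded one-hot.
    outcome_column: the numeric regression target.
    """

    component_columns: list[str]
    outcome_column: str
    categorical_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.component_columns:
            raise ValueError("schema needs at least one graph component column")


@dataclass
class ReactionRecord:
    """One reaction: component SMILES, categorical ids, observed outcome."""

    components: list[str]
    outcome: float
    categoricals: list[str] = field(default_factory=list)
    group: str | None = None


def records_from_dataframe(
    df: pd.DataFrame, schema: ReactionSchema, require_outcome: bool = True
) -> list[ReactionRecord]:
    missing = [
        c
        for c in schema.component_columns + schema.categorical_columns
        if c not in df.columns
    ]
    if require_outcome and schema.outcome_column not in df.columns:
        missing.append(schema.outcome_column)
    if missing:
        raise KeyError(f"dataset is missing schema columns: {missing}")
    records = []
    for _, row in df.iterrows():
        records.append(
            ReactionRecord(
                components=[str(row[c]) for c in schema.component_columns],
                categoricals=[str(row[c]) for c in schema.categorical_columns],
                outcome=(
                    float(row[schema.outcome_column]) if require_outcome else np.nan
                ),
                group=(str(row["group"]) if "group" in df.columns else None),
            )
        )
    return records


class CategoricalVocabulary:
    """One-hot vocabularies for the non-graph component columns."""

    def __init__(self, columns: list[str]):
        self.columns = columns
        self.values: dict[str, list[str]] = {}

    def fit(self, records: list[ReactionRecord]) -> "CategoricalVocabulary":
        for j, col in enumerate(self.columns):
            self.values[col] = sorted({r.categoricals[j] for r in records})
        return self

    @property
    def total_width(self) -> int:
        return sum(len(v) for v in self.values.values())

    def encode(self, record: ReactionRecord) -> np.ndarray:
        blocks = [
            encode_onehot(record.categoricals[j], self.values[col])
            for j, col in enumerate(self.columns)
        ]
        return np.concatenate(blocks) if blocks else np.zeros(0)


def encode_onehot(category: str, vocabulary: list[str]) -> np.ndarray:
    """Indicator vector over `vocabulary` with a single 1 at `category`."""
    try:
        idx = vocabulary.index(category)
    except ValueError:
        raise KeyError(
            f"unknown category {category!r}; known values: {vocabulary}"
        ) from None
    vec = np.zeros(len(vocabulary))
    vec[idx] = 1.0
    return vec


def aggregate_reaction(
    molecule_vectors: list[Tensor] | Tensor,
    mode: str,
    onehot_block: np.ndarray | None = None,
) -> Tensor:
    """Combine per-component molecule vectors into one reaction vector.

    molecule_vectors may be a list of (n, d) tensors (one per component role,
    rows are reactions) or a single tensor for one-component reactions.
    ``sum`` adds them elementwise (component-order invariant, width d);
    ``concat`` concatenates in role order (width d x n_components). Any
    one-hot block for categorical components is appended afterwards.
    """
    if isinstance(molecule_vectors, Tensor):
        molecule_vectors = [molecule_vectors]
    if not molecule_vectors:
        raise ValueError("no molecule vectors to aggregate")
    if mode not in AGG_MODES:
        raise ValueError(f"mode must be one of {AGG_MODES}")
    widths = {v.shape[-1] for v in molecule_vectors}
    if len(widths) != 1:
        raise ValueError(f"mixed molecule vector widths: {sorted(widths)}")
    if mode == "sum":
        out = molecule_vectors[0]
        for v in molecule_vectors[1:]:
            out = out + v
    else:
        out = concat(molecule_vectors, axis=-1)
    if onehot_block is not None and onehot_block.shape[-1] > 0:
        out = concat([out, Tensor(onehot_block)], axis=-1)
    return out


def reaction_vector_width(
    d: int, n_components: int, mode: str, onehot_width: int = 0
) -> int:
    """Length law of the reaction vector."""
    if mode == "sum":
        return d + onehot_width
    return d * n_components + onehot_width


def init_head_params(
    input_width: int, hidden_width: int, rng: np.random.Generator
) -> dict[str, Tensor]:
    """Dense regression head: one ReLU hidden layer + linear output unit."""

    def xavier(fan_in, fan_out):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=(fan_in, fan_out))

    return {
        "head/W1": Tensor(xavier(input_width, hidden_width)),
        "head/b1": Tensor(np.zeros(hidden_width)),
        "head/W2": Tensor(xavier(hidden_width, 1)),
        "head/b2": Tensor(np.zeros(1)),
    }


def predict_outcome(reaction_vectors: Tensor, params: dict[str, Tensor]) -> Tensor:
    """Normalized outcome predictions, shape (n,)."""
    hidden = relu(matmul(reaction_vectors, params["head/W1"]) + params["head/b1"])
    out = matmul(hidden, params["head/W2"]) + params["head/b2"]
    return out.reshape(-1)


def split_reaction_smiles(rxn_smiles: str) -> tuple[list[str], list[str]]:
    """Split a 'reactant.reactant>>product' reaction SMILES into sides."""
    parts = rxn_smiles.split(">")
    if len(parts) not in (2, 3):
        raise ValueError(f"not a reaction SMILES: {rxn_smiles!r}")
    reactants = [s for s in parts[0].split(".") if s]
    products = [s for s in parts[-1].split(".") if s]
    return reactants, products
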