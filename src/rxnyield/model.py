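"""Model / Results surface for reaction outcome regression.

:class:`ReactionModel` is constructed from data (a list of
:class:`~rxnyield.reaction.ReactionRecord` or a DataFrame plus a
:class:`~rxnyield.reaction.ReactionSchema`); ``fit()`` trains the
message-passing encoder and dense head jointly and returns a
:class:`ReactionResults` carrying the learned parameters, the outcome
scaler, the training log and prediction/evaluation methods.
:func:`cross_validate` repeats the fit over a k-fold plan and aggregates
per-fold test metrics as mean +/- standard deviation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from ._autodiff import Tensor, gather_rows
from .encoder import (
    EncoderConfig,
    batch_graphs,
    encode_batch,
    init_encoder_params,
    load_params,
    save_params,
)
from .molgraph import MolGraph, build_graph
from .reaction import (
    CategoricalVocabulary,
    ReactionRecord,
    ReactionSchema,
    aggregate_reaction,
    init_head_params,
    predict_outcome,
    reaction_vector_width,
    records_from_dataframe,
)
from .training import (
    Adam,
    FoldPlan,
    Metrics,
    OptimizerConfig,
    OutcomeScaler,
    early_stopped_loop,
    evaluate,
    make_folds,
    mse_loss,
    summarize_metrics,
    train_val_test_split,
)


@dataclass
class ModelConfig:
    """Architecture settings: encoder hyperparameters plus the reaction-level
    aggregation mode (``sum`` -> elementwise summation, width d;
    ``concat`` -> concatenation in role order, width d x n_components)."""

    hidden_size: int = 300
    depth: int = 3
    aggregation: str = "sum"  # node-message aggregation inside the encoder
    edge_message: str = "reverse"
    reaction_mode: str = "concat"  # sum | concat of component vectors

    def encoder_config(self, seed: int = 0) -> EncoderConfig:
        return EncoderConfig(
            hidden_size=self.hidden_size,
            depth=self.depth,
            aggregation=self.aggregation,
            edge_message=self.edge_message,
            seed=seed,
        )


class ReactionModel:
    """Multi-component reaction outcome regression model.

    Parameters
    ----------
    records : list of ReactionRecord
    schema : ReactionSchema describing component roles and the outcome.
    config : ModelConfig, architecture settings.
    """

    def __init__(
        self,
        records: list[ReactionRecord],
        schema: ReactionSchema,
        config: ModelConfig | None = None,
    ):
        if not records:
            raise ValueError("no reaction records")
        n_comp = len(schema.component_columns)
        for r in records:
            if len(r.components) != n_comp:
                raise ValueError(
                    "record component count does not match schema "
                    f"({len(r.components)} vs {n_comp})"
                )
        self.records = records
        self.schema = schema
        self.config = config or ModelConfig()
        self._graph_cache: dict[str, MolGraph] = {}

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        schema: ReactionSchema,
        config: ModelConfig | None = None,
    ) -> "ReactionModel":
        return cls(records_from_dataframe(df, schema), schema, config)

    # -- internals ------------------------------------------------------
    def _graph(self, smiles: str) -> MolGraph:
        g = self._graph_cache.get(smiles)
        if g is None:
            g = build_graph(smiles)
            self._graph_cache[smiles] = g
        return g

    def _forward(
        self,
        records: list[ReactionRecord],
        params: dict[str, Tensor],
        vocab: CategoricalVocabulary,
        enc_config: EncoderConfig,
    ) -> Tensor:
        """Normalized outcome predictions for `records` (differentiable)."""
        position: dict[str, int] = {}
        graphs: list[MolGraph] = []
        for r in records:
            for s in r.components:
                if s not in position:
                    position[s] = len(graphs)
                    graphs.append(self._graph(s))
        batch = batch_graphs(graphs)
        mol_vecs = encode_batch(batch, params, enc_config)
        component_vecs = [
            gather_rows(
                mol_vecs, np.array([position[r.components[j]] for r in records])
            )
            for j in range(len(self.schema.component_columns))
        ]
        onehot = (
            np.stack([vocab.encode(r) for r in records])
            if vocab.columns
            else None
        )
        rxn_vec = aggregate_reaction(component_vecs, self.config.reaction_mode, onehot)
        return predict_outcome(rxn_vec, params)

    # -- fitting ----------------------------------------------------------
    def fit(
        self,
        seed: int = 0,
        optimizer: OptimizerConfig | None = None,
        val_fraction: float = 0.2,
        train_indices: np.ndarray | None = None,
        val_indices: np.ndarray | None = None,
    ) -> "ReactionResults":
        """Train encoder + head jointly with Adam on the MSE of normalized
        outcomes, early-stopping on a held-out validation share of the
        training portion; returns the best-validation checkpoint."""
        optimizer = optimizer or OptimizerConfig()
        master = np.random.default_rng(seed)
        split_seed, init_seed, shuffle_seed = master.integers(0, 2**31 - 1, size=3)

        n = len(self.records)
        if train_indices is None:
            perm = np.random.default_rng(split_seed).permutation(n)
            n_val = int(round(n * val_fraction))
            val_indices = np.sort(perm[:n_val])
            train_indices = np.sort(perm[n_val:])
        elif val_indices is None:
            perm = np.random.default_rng(split_seed).permutation(len(train_indices))
            n_val = int(round(len(train_indices) * val_fraction))
            train_indices = np.asarray(train_indices)
            val_indices = np.sort(train_indices[perm[:n_val]])
            train_indices = np.sort(train_indices[perm[n_val:]])
        train_indices = np.asarray(train_indices, dtype=np.intp)
        val_indices = np.asarray(val_indices, dtype=np.intp)

        train_records = [self.records[i] for i in train_indices]
        val_records = [self.records[i] for i in val_indices]

        # Normalization and categorical vocabularies: training portion only.
        scaler = OutcomeScaler.fit(np.array([r.outcome for r in train_records]))
        vocab = CategoricalVocabulary(self.schema.categorical_columns).fit(
            train_records
        )

        enc_config = self.config.encoder_config(seed=int(init_seed))
        rng_init = np.random.default_rng(int(init_seed))
        params = init_encoder_params(enc_config, rng_init)
        width = reaction_vector_width(
            self.config.hidden_size,
            len(self.schema.component_columns),
            self.config.reaction_mode,
            vocab.total_width,
        )
        params.update(
            init_head_params(width, self.config.hidden_size, rng_init)
        )

        adam = Adam(params, optimizer)
        y_train = scaler.transform(np.array([r.outcome for r in train_records]))
        y_val = scaler.transform(np.array([r.outcome for r in val_records]))

        def step_fn(batch_idx: np.ndarray) -> float:
            adam.zero_grad()
            recs = [train_records[i] for i in batch_idx]
            pred = self._forward(recs, params, vocab, enc_config)
            loss = mse_loss(pred, y_train[batch_idx])
            loss.backward()
            adam.step()
            return float(loss.data)

        def val_fn() -> float:
            if not val_records:
                return float("nan")
            preds = []
            for start in range(0, len(val_records), optimizer.batch_size):
                recs = val_records[start : start + optimizer.batch_size]
                preds.append(
                    self._forward(recs, params, vocab, enc_config).data
                )
            err = np.concatenate(preds) - y_val
            return float((err**2).mean())

        if not val_records:
            # fall back to early stopping on training loss
            last_train = [np.inf]

            orig_step = step_fn

            def step_fn(batch_idx: np.ndarray) -> float:  # noqa: F811
                loss = orig_step(batch_idx)
                last_train[0] = loss
                return loss

            def val_fn() -> float:  # noqa: F811
                return last_train[0]

        log = early_stopped_loop(
            n_train=len(train_records),
            step_fn=step_fn,
            val_fn=val_fn,
            snapshot_fn=lambda: {k: v.data.copy() for k, v in params.items()},
            restore_fn=lambda snap: [
                params[k].__setattr__("data", v) for k, v in snap.items()
            ],
            config=optimizer,
            rng=np.random.default_rng(int(shuffle_seed)),
        )

        return ReactionResults(
            model=self,
            params=params,
            scaler=scaler,
            vocab=vocab,
            encoder_config=enc_config,
            optimizer_config=optimizer,
            log=log,
            train_indices=train_indices,
            val_indices=val_indices,
            seed=seed,
        )


@dataclass
class ReactionResults:
    """Fitted reaction model: learned parameters plus everything needed to
    predict on new reactions and report training diagnostics."""

    model: ReactionModel
    params: dict[str, Tensor]
    scaler: OutcomeScaler
    vocab: CategoricalVocabulary
    encoder_config: EncoderConfig
    optimizer_config: OptimizerConfig
    log: list[dict[str, float]]
    train_indices: np.ndarray
    val_indices: np.ndarray
    seed: int

    @property
    def n_parameters(self) -> int:
        return int(sum(v.data.size for v in self.params.values()))

    def predict_records(self, records: list[ReactionRecord]) -> np.ndarray:
        """Predicted outcomes in original units."""
        preds = []
        bs = self.optimizer_config.batch_size
        for start in range(0, len(records), bs):
            recs = records[start : start + bs]
            preds.append(
                self.model._forward(
                    recs, self.params, self.vocab, self.encoder_config
                ).data
            )
        return self.scaler.inverse_transform(np.concatenate(preds))

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        records = records_from_dataframe(df, self.model.schema, require_outcome=False)
        return self.predict_records(records)

    def evaluate_records(self, records: list[ReactionRecord]) -> Metrics:
        preds = self.predict_records(records)
        obs = np.array([r.outcome for r in records])
        return evaluate(preds, obs)

    def evaluate(self, df: pd.DataFrame) -> Metrics:
        return self.evaluate_records(
            records_from_dataframe(df, self.model.schema)
        )

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Reaction outcome regression (message-passing graph encoder)",
            "=" * 60,
            f"components: {', '.join(self.model.schema.component_columns)}",
            f"outcome:    {self.model.schema.outcome_column}",
            f"hidden size d={cfg.hidden_size}  depth K={cfg.depth}  "
            f"reaction mode={cfg.reaction_mode}",
            f"node aggregation={cfg.aggregation}  edge message={cfg.edge_message}",
            f"parameters: {self.n_parameters}",
            f"train/val sizes: {len(self.train_indices)}/{len(self.val_indices)}",
            f"epochs run: {len(self.log)}  (seed={self.seed})",
        ]
        if self.log:
            best = min(self.log, key=lambda e: e["val_loss"])
            lines.append(
                f"best val MSE (normalized): {best['val_loss']:.6f} "
                f"at epoch {int(best['epoch'])}"
            )
        if len(self.val_indices):
            m = self.evaluate_records(
                [self.model.records[i] for i in self.val_indices]
            )
            lines.append(
                f"validation: R2={m.r2:.3f}  MAE={m.mae:.4g}  RMSE={m.rmse:.4g}"
            )
        return "\n".join(lines)

    def save(self, path) -> None:
        meta = {
            "model_config": asdict(self.model.config),
            "scaler": {"mu": self.scaler.mu, "sigma": self.scaler.sigma},
            "vocab": self.vocab.values,
            "schema": {
                "component_columns": self.model.schema.component_columns,
                "outcome_column": self.model.schema.outcome_column,
                "categorical_columns": self.model.schema.categorical_columns,
            },
            "seed": self.seed,
            "encoder_seed": self.encoder_config.seed,
        }
        save_params(path, self.params, meta)

    @classmethod
    def load(cls, path) -> "ReactionResults":
        params, meta = load_params(path)
        schema = ReactionSchema(**meta["schema"])
        config = ModelConfig(**meta["model_config"])
        # A loaded results object predicts; it does not resume training.
        model = ReactionModel.__new__(ReactionModel)
        model.records = []
        model.schema = schema
        model.config = config
        model._graph_cache = {}
        vocab = CategoricalVocabulary(schema.categorical_columns)
        vocab.values = meta["vocab"]
        return cls(
            model=model,
            params=params,
            scaler=OutcomeScaler(**meta["scaler"]),
            vocab=vocab,
            encoder_config=config.encoder_config(seed=meta.get("encoder_seed", 0)),
            optimizer_config=OptimizerConfig(),
            log=[],
            train_indices=np.zeros(0, dtype=np.intp),
            val_indices=np.zeros(0, dtype=np.intp),
            seed=meta.get("seed", 0),
        )


@dataclass
class CVResults:
    """Per-fold test metrics and pooled out-of-fold predictions."""

    fold_metrics: list[Metrics]
    fold_plan: FoldPlan
    predictions: pd.DataFrame  # columns: fold, index, observed, predicted

    @property
    def summary_stats(self) -> dict[str, dict[str, float]]:
        return summarize_metrics(self.fold_metrics)

    def summary(self) -> str:
        s = self.summary_stats
        lines = [
            f"{self.fold_plan.k}-fold cross-validation",
            "=" * 40,
            "fold   R2      MAE      RMSE",
        ]
        for i, m in enumerate(self.fold_metrics):
            lines.append(f"{i:>4}   {m.r2:.3f}   {m.mae:.4f}   {m.rmse:.4f}")
        lines.append(
            "mean   "
            + "   ".join(
                f"{s[k]['mean']:.3f} ± {s[k]['std']:.3f}" for k in ("r2", "mae", "rmse")
            )
        )
        return "\n".join(lines)

    def to_json(self) -> str:
        return json.dumps(
            {
                "k": self.fold_plan.k,
                "seed": self.fold_plan.seed,
                "folds": [m.as_dict() for m in self.fold_metrics],
                "summary": self.summary_stats,
            },
            sort_keys=True,
            indent=2,
        )


def cross_validate(
    records: list[ReactionRecord] | pd.DataFrame,
    schema: ReactionSchema,
    config: ModelConfig | None = None,
    k: int = 5,
    seed: int = 0,
    optimizer: OptimizerConfig | None = None,
    val_fraction: float = 0.2,
) -> CVResults:
    """k-fold CV without replacement: each fold trains on the remainder
    (with a validation share for early stopping) and is scored on its test
    partition in original outcome units."""
    if isinstance(records, pd.DataFrame):
        records = records_from_dataframe(records, schema)
    plan = make_folds(len(records), k=k, val_fraction=val_fraction, seed=seed)
    model = ReactionModel(records, schema, config)
    metrics: list[Metrics] = []
    rows = []
    for fold_id, (train_idx, val_idx, test_idx) in enumerate(plan.folds):
        res = model.fit(
            seed=seed + fold_id,
            optimizer=optimizer,
            train_indices=train_idx,
            val_indices=val_idx,
        )
        test_records = [records[i] for i in test_idx]
        preds = res.predict_records(test_records)
        obs = np.array([r.outcome for r in test_records])
        metrics.append(evaluate(preds, obs))
        for idx, o, p in zip(test_idx, obs, preds):
            rows.append(
                {"fold": fold_id, "index": int(idx), "observed": o, "predicted": p}
            )
    return CVResults(
        fold_metrics=metrics,
        fold_plan=plan,
        predictions=pd.DataFrame(rows),
    )
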