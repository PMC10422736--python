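"""Outcome normalization, data splitting, optimization and metrics.

Outcomes are z-score normalized before regression (x_hat = (x - mu) / sigma,
mu and sigma from the training portion only) and predictions are inverse-
scaled before any metric is computed. Splitting follows an 80:20 train/test
convention with a further 20% of the training portion held out for early
stopping; k-fold cross-validation partitions the dataset into k disjoint
test sets (CV without replacement).

R^2 is reported as the squared Pearson correlation between predictions and
observations (the convention of the reaction yield-prediction literature);
the coefficient of determination is carried alongside for reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor


class DegenerateDataError(ValueError):
    """Raised when data has no variance to normalize or correlate against."""


@dataclass
class OutcomeScaler:
    """z-score normalization parameters (mu, sigma) with inverse transform."""

    mu: float
    sigma: float

    @classmethod
    def fit(cls, outcomes: np.ndarray) -> "OutcomeScaler":
        outcomes = np.asarray(outcomes, dtype=np.float64)
        if outcomes.size < 2:
            raise DegenerateDataError("need at least 2 samples to fit a scaler")
        sigma = float(outcomes.std())
        if sigma == 0.0:
            raise DegenerateDataError("outcomes have zero variance")
        return cls(mu=float(outcomes.mean()), sigma=sigma)

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=np.float64) - self.mu) / self.sigma

    def inverse_transform(self, x_hat: np.ndarray) -> np.ndarray:
        return np.asarray(x_hat, dtype=np.float64) * self.sigma + self.mu


@dataclass
class FoldPlan:
    """Disjoint train/validation/test index sets for k-fold CV."""

    k: int
    folds: list[tuple[np.ndarray, np.ndarray, np.ndarray]]
    seed: int


def train_val_test_split(
    n: int,
    test_fraction: float = 0.2,
    val_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Single 80:20 train/test split with a validation share of the train part."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = int(round(n * test_fraction))
    test = perm[:n_test]
    rest = perm[n_test:]
    n_val = int(round(len(rest) * val_fraction))
    val = rest[:n_val]
    train = rest[n_val:]
    return np.sort(train), np.sort(val), np.sort(test)


def make_folds(n: int, k: int, val_fraction: float = 0.2, seed: int = 0) -> FoldPlan:
    """k-fold plan: test sets partition [0, n); validation is carved from
    each fold's training portion."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"cannot make {k} folds from {n} samples")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test_sets = np.array_split(perm, k)
    folds = []
    for i, test in enumerate(test_sets):
        rest = np.concatenate([t for j, t in enumerate(test_sets) if j != i])
        n_val = int(round(len(rest) * val_fraction))
        val = rest[:n_val]
        train = rest[n_val:]
        folds.append((np.sort(train), np.sort(val), np.sort(test)))
    return FoldPlan(k=k, folds=folds, seed=seed)


@dataclass
class Metrics:
    """Test-set regression metrics: R^2 (squared Pearson), MAE, RMSE."""

    r2: float
    mae: float
    rmse: float
    r2_cod: float = field(default=np.nan)  # coefficient of determination

    def as_dict(self) -> dict[str, float]:
        return {"r2": self.r2, "mae": self.mae, "rmse": self.rmse}


def evaluate(predictions: np.ndarray, observations: np.ndarray) -> Metrics:
    """Metrics in original outcome units."""
    predictions = np.asarray(predictions, dtype=np.float64)
    observations = np.asarray(observations, dtype=np.float64)
    if predictions.shape != observations.shape:
        raise ValueError(
            f"length mismatch: {predictions.shape} vs {observations.shape}"
        )
    if predictions.size < 2:
        raise ValueError("need at least 2 points to evaluate")
    if observations.std() == 0.0:
        raise DegenerateDataError("observations have zero variance")
    err = predictions - observations
    mae = float(np.abs(err).mean())
    rmse = float(np.sqrt((err**2).mean()))
    if predictions.std() == 0.0:
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(predictions, observations)[0, 1] ** 2)
    ss_res = float((err**2).sum())
    ss_tot = float(((observations - observations.mean()) ** 2).sum())
    return Metrics(r2=r2, mae=mae, rmse=rmse, r2_cod=1.0 - ss_res / ss_tot)


def summarize_metrics(per_fold: list[Metrics]) -> dict[str, dict[str, float]]:
    """Mean and standard deviation of each metric across folds."""
    out: dict[str, dict[str, float]] = {}
    for name in ("r2", "mae", "rmse"):
        vals = np.array([getattr(m, name) for m in per_fold])
        out[name] = {"mean": float(vals.mean()), "std": float(vals.std())}
    return out


@dataclass
class OptimizerConfig:
    """Adam settings and the early-stopping rule."""

    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 10
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8


class Adam:
    """Adam over a flat dict of parameter tensors."""

    def __init__(self, params: dict[str, Tensor], config: OptimizerConfig):
        self.params = params
        self.config = config
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.t = 0

    def step(self) -> None:
        c = self.config
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = c.beta1 * self.m[k] + (1 - c.beta1) * g
            self.v[k] = c.beta2 * self.v[k] + (1 - c.beta2) * g * g
            m_hat = self.m[k] / (1 - c.beta1**self.t)
            v_hat = self.v[k] / (1 - c.beta2**self.t)
            p.data = p.data - c.learning_rate * m_hat / (np.sqrt(v_hat) + c.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


def mse_loss(predictions: Tensor, targets: np.ndarray) -> Tensor:
    diff = predictions - Tensor(np.asarray(targets, dtype=np.float64))
    return (diff * diff).mean()


def early_stopped_loop(
    *,
    n_train: int,
    step_fn,
    val_fn,
    snapshot_fn,
    restore_fn,
    config: OptimizerConfig,
    rng: np.random.Generator,
) -> list[dict[str, float]]:
    """Generic early-stopped epoch loop.

    step_fn(indices) runs one minibatch update and returns its loss;
    val_fn() returns the validation loss; snapshot_fn()/restore_fn(s)
    checkpoint the best-validation parameters. Stops after `patience`
    epochs without validation improvement (patience=0: first
    non-improving epoch ends training). Returns the per-epoch log.
    """
    best_val = np.inf
    best_snapshot = snapshot_fn()
    stale = 0
    log: list[dict[str, float]] = []
    for epoch in range(config.max_epochs):
        order = rng.permutation(n_train)
        losses = []
        for start in range(0, n_train, config.batch_size):
            batch = order[start : start + config.batch_size]
            losses.append(step_fn(batch))
        train_loss = float(np.mean(losses))
        if not np.isfinite(train_loss):
            raise FloatingPointError(
                f"training diverged at epoch {epoch}: loss={train_loss}"
            )
        val_loss = float(val_fn())
        log.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_snapshot = snapshot_fn()
            stale = 0
        else:
            stale += 1
            if stale > config.patience:
                break
    restore_fn(best_snapshot)
    return log


def run_cv(records, schema, config, k: int, seed: int = 0):
    """k-fold cross-validation; see :func:`rxnyield.model.cross_validate`."""
    from .model import cross_validate

    return cross_validate(records, schema, config=config, k=k, seed=seed)
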