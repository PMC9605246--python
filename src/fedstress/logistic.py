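"""Binary logistic regression with batch and local-SGD fitting.

The model is p(stress | x) = sigmoid(w · z + b) on standardized features
z = (x − center) / spread.  ``fit_batch`` minimizes the L2-regularized
negative log-likelihood

    F(w, b) = Σ_i [log(1 + exp(z_i·w + b)) − y_i (z_i·w + b)] + (λ/2)‖w‖²

(intercept unpenalized) to a gradient-norm tolerance.  ``fit_local_sgd`` runs
mini-batch gradient descent on F/n from a given starting model — the local
update primitive of the federated strategy; both optimize the same objective,
so full-batch SGD with a decaying rate converges to the batch solution.

λ defaults to 1.0, the common library default (inverse-regularization C = 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit


class DegenerateLabelsError(ValueError):
    """Raised when a training set contains a single class."""


@dataclass
class TrainConfig:
    l2_strength: float = 1.0
    max_iterations: int = 500
    tolerance: float = 1e-6
    learning_rate: float = 0.05
    local_epochs: int = 1
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.l2_strength < 0:
            raise ValueError("l2_strength must be >= 0")
        for name in ("max_iterations", "tolerance", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.local_epochs < 0:
            raise ValueError("local_epochs must be >= 0")


@dataclass
class Scaler:
    """Per-feature (center, spread) standardization; zero spread maps to 1."""

    center: np.ndarray
    spread: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Scaler":
        center = X.mean(axis=0)
        spread = X.std(axis=0)
        return cls(center=center, spread=np.where(spread > 0, spread, 1.0))

    @classmethod
    def from_moments(cls, mean: np.ndarray, var: np.ndarray) -> "Scaler":
        spread = np.sqrt(np.maximum(var, 0.0))
        return cls(center=np.asarray(mean, float), spread=np.where(spread > 0, spread, 1.0))

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.center) / self.spread


@dataclass
class LRModel:
    weights: np.ndarray
    intercept: float
    scaler: Scaler
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, float)
        if self.weights.shape != self.scaler.center.shape:
            raise ValueError("weights and scaler dimensions disagree")

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "intercept": float(self.intercept),
            "scaler": {"center": self.scaler.center.tolist(), "spread": self.scaler.spread.tolist()},
            "feature_names": list(self.feature_names),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LRModel":
        return cls(
            weights=np.asarray(d["weights"], float),
            intercept=float(d["intercept"]),
            scaler=Scaler(
                center=np.asarray(d["scaler"]["center"], float),
                spread=np.asarray(d["scaler"]["spread"], float),
            ),
            feature_names=list(d.get("feature_names", [])),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "LRModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _check_dims(model: LRModel, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[1] != model.weights.size:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match model dimension {model.weights.size}"
        )
    return X


def predict_proba(model: LRModel, X: np.ndarray) -> np.ndarray:
    """P(stress) for each row; numerically stable for extreme logits."""
    X = _check_dims(model, X)
    z = model.scaler.transform(X)
    return expit(z @ model.weights + model.intercept)


def predict_label(model: LRModel, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """1 (stress) iff P(stress) >= threshold."""
    return (predict_proba(model, X) >= threshold).astype(np.int64)


def _validate_training_set(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("features and labels must have the same number of rows")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    classes = np.unique(y)
    if not np.all(np.isin(classes, (0.0, 1.0))):
        raise ValueError("labels must be binary 0/1")
    if classes.size < 2:
        raise DegenerateLabelsError("training set contains a single class")
    return X, y


def fit_batch(
    X: np.ndarray,
    y: np.ndarray,
    config: TrainConfig | None = None,
    scaler: Scaler | None = None,
    feature_names: list[str] | None = None,
) -> LRModel:
    """L2-regularized maximum-likelihood fit (L-BFGS on the exact gradient)."""
    config = config or TrainConfig()
    X, y = _validate_training_set(X, y)
    scaler = scaler or Scaler.fit(X)
    Z = scaler.transform(X)
    lam = config.l2_strength

    def objective(theta: np.ndarray) -> tuple[float, np.ndarray]:
        w, b = theta[:-1], theta[-1]
        logits = Z @ w + b
        loss = float(np.sum(np.logaddexp(0.0, logits) - y * logits) + 0.5 * lam * w @ w)
        p = expit(logits)
        grad = np.empty_like(theta)
        grad[:-1] = Z.T @ (p - y) + lam * w
        grad[-1] = np.sum(p - y)
        return loss, grad

    res = minimize(
        objective,
        np.zeros(Z.shape[1] + 1),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": config.max_iterations, "gtol": config.tolerance, "ftol": 1e-14},
    )
    return LRModel(
        weights=res.x[:-1],
        intercept=float(res.x[-1]),
        scaler=scaler,
        feature_names=list(feature_names or []),
    )


def fit_local_sgd(
    start: LRModel, X: np.ndarray, y: np.ndarray, config: TrainConfig | None = None
) -> LRModel:
    """Mini-batch gradient descent on the mean regularized log-loss.

    Runs ``config.local_epochs`` shuffled passes from ``start``'s weights,
    re-using (not refitting) the start model's scaler; deterministic under
    ``config.seed``.  Zero epochs or a zero learning rate return an unchanged
    copy of the start model.
    """
    config = config or TrainConfig()
    X, y = _validate_training_set(X, y)
    if X.shape[1] != start.weights.size:
        raise ValueError("feature dimension does not match the start model")
    Z = start.scaler.transform(X)
    n = y.size
    w = start.weights.copy()
    b = float(start.intercept)
    lam = config.l2_strength
    lr = config.learning_rate
    rng = np.random.default_rng(config.seed)
    for _ in range(config.local_epochs):
        order = rng.permutation(n)
        for a in range(0, n, config.batch_size):
            batch = order[a : a + config.batch_size]
            Zb, yb = Z[batch], y[batch]
            p = expit(Zb @ w + b)
            w -= lr * (Zb.T @ (p - yb) / batch.size + lam * w / n)
            b -= lr * float(np.mean(p - yb))
    return LRModel(weights=w, intercept=b, scaler=start.scaler, feature_names=start.feature_names)


def zero_model(scaler: Scaler, feature_names: list[str] | None = None) -> LRModel:
    """Zero-weight, zero-intercept model — the federated server's start point."""
    return LRModel(
        weights=np.zeros_like(scaler.center),
        intercept=0.0,
        scaler=scaler,
        feature_names=list(feature_names or []),
    )


def with_seed(config: TrainConfig, seed: int) -> TrainConfig:
    return replace(config, seed=int(seed))
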