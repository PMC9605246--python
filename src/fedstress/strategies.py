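"""The three learning topologies: individual, centralized, federated (FedAvg).

All three share one split protocol: each participant's windows are divided
80:20 into train and test first, so every strategy is evaluated on identical
per-participant test rows.  Individual learning fits one model per participant
on their own training rows; centralized learning fits one model on the pooled
training rows; federated learning simulates FedAvg — each round every client
runs a local SGD update from the current global model and the server replaces
the global weights with the client-sample-count-weighted mean.

The federated code path enforces the privacy contract structurally: the server
loop talks to clients only through ``FederatedClient.moments()`` (count, mean,
variance — used once to build the shared standardizer) and
``FederatedClient.local_update()`` (returns a model and a count).  No feature
matrix crosses that interface.

The default split mode is ``stratified_random`` with a fixed seed.  Because
0.25 s-step windows overlap heavily, a random split leaks near-duplicate rows
between train and test, which inflates within-participant scores; a
``chronological`` mode (last 20 % of windows as test) is provided for
leak-free evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Protocol, Sequence

import numpy as np
import pandas as pd

from .features import FEATURE_COLUMNS, feature_values
from .logistic import (
    DegenerateLabelsError,
    LRModel,
    Scaler,
    TrainConfig,
    fit_batch,
    fit_local_sgd,
    predict_label,
    zero_model,
)

SPLIT_MODES = ("stratified_random", "chronological")
STRATEGY_NAMES = ("individual", "centralized", "federated")


@dataclass
class SplitSpec:
    train_fraction: float = 0.8
    mode: str = "stratified_random"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.mode not in SPLIT_MODES:
            raise ValueError(f"unknown split mode {self.mode!r}")


@dataclass
class FederatedConfig:
    rounds: int = 20
    local_epochs: int = 1
    client_fraction: float = 1.0
    train: TrainConfig = field(default_factory=TrainConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if self.local_epochs < 1:
            raise ValueError("local_epochs must be >= 1")
        if not 0.0 < self.client_fraction <= 1.0:
            raise ValueError("client_fraction must lie in (0, 1]")


@dataclass
class PredictionSet:
    y_true: np.ndarray
    y_pred: np.ndarray
    window_ids: np.ndarray


@dataclass
class StrategyResult:
    strategy: str
    models: dict  # participant_id -> LRModel, or {"global": LRModel}
    predictions: dict[int, PredictionSet]


def _participant_split(df: pd.DataFrame, spec: SplitSpec, pid: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    n = len(df)
    if spec.mode == "chronological":
        n_test = int(round(n * (1.0 - spec.train_fraction)))
        return df.iloc[: n - n_test], df.iloc[n - n_test :]
    labels = df["label"].to_numpy()
    if np.unique(labels).size < 2:
        raise DegenerateLabelsError(
            f"participant {pid}: stratified split needs both classes present"
        )
    rng = np.random.default_rng((spec.seed * 100_003 + pid) % 2**31)
    test_idx: list[np.ndarray] = []
    for cls in np.unique(labels):
        pos = np.flatnonzero(labels == cls)
        n_test = int(round(pos.size * (1.0 - spec.train_fraction)))
        test_idx.append(rng.permutation(pos)[:n_test])
    test = np.sort(np.concatenate(test_idx))
    mask = np.zeros(n, dtype=bool)
    mask[test] = True
    return df.iloc[~mask], df.iloc[mask]


def split_train_test(
    matrix: pd.DataFrame, spec: SplitSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """80:20 train/test split, performed within each participant.

    ``stratified_random`` preserves class proportions (within rounding) and is
    deterministic per (seed, participant); ``chronological`` holds out the
    final 20 % of windows by start time.
    """
    trains, tests = [], []
    for pid, group in matrix.groupby("participant", sort=True):
        tr, te = _participant_split(group, spec, int(pid))
        trains.append(tr)
        tests.append(te)
    return pd.concat(trains), pd.concat(tests)


def _split_cohort(
    matrices: Mapping[int, pd.DataFrame], spec: SplitSpec
) -> dict[int, tuple[pd.DataFrame, pd.DataFrame]]:
    return {int(pid): _participant_split(df, spec, int(pid)) for pid, df in matrices.items()}


def _xy(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    return feature_values(df), df["label"].to_numpy(np.int64)


def _predictions(model: LRModel, test: pd.DataFrame) -> PredictionSet:
    X, y = _xy(test)
    return PredictionSet(
        y_true=y, y_pred=predict_label(model, X), window_ids=test.index.to_numpy()
    )


def run_individual(
    matrices: Mapping[int, pd.DataFrame],
    split: SplitSpec,
    config: TrainConfig | None = None,
) -> StrategyResult:
    """One model per participant, trained and tested on their own data only."""
    config = config or TrainConfig()
    models: dict[int, LRModel] = {}
    preds: dict[int, PredictionSet] = {}
    for pid, df in sorted(matrices.items()):
        train, test = _participant_split(df, split, int(pid))
        X, y = _xy(train)
        try:
            model = fit_batch(X, y, config, feature_names=list(FEATURE_COLUMNS))
        except DegenerateLabelsError as err:
            raise DegenerateLabelsError(f"participant {pid}: {err}") from err
        models[int(pid)] = model
        preds[int(pid)] = _predictions(model, test)
    return StrategyResult("individual", models, preds)


def run_centralized(
    matrices: Mapping[int, pd.DataFrame],
    split: SplitSpec,
    config: TrainConfig | None = None,
) -> StrategyResult:
    """One model on the pooled training rows, evaluated per participant."""
    config = config or TrainConfig()
    splits = _split_cohort(matrices, split)
    pooled = pd.concat([tr for tr, _ in splits.values()])
    X, y = _xy(pooled)
    model = fit_batch(X, y, config, feature_names=list(FEATURE_COLUMNS))
    preds = {pid: _predictions(model, te) for pid, (_, te) in sorted(splits.items())}
    return StrategyResult("centralized", {"global": model}, preds)


class Client(Protocol):
    """What the federated server may see of a client: moments and updates."""

    client_id: int

    def moments(self) -> tuple[int, np.ndarray, np.ndarray]: ...

    def local_update(self, model: LRModel, config: TrainConfig) -> tuple[LRModel, int]: ...


class FederatedClient:
    """Holds one participant's training rows privately on the 'device'."""

    def __init__(self, client_id: int, features: np.ndarray, labels: np.ndarray):
        self.client_id = int(client_id)
        self._X = np.asarray(features, float)
        self._y = np.asarray(labels, np.int64)

    def moments(self) -> tuple[int, np.ndarray, np.ndarray]:
        """(n, per-feature mean, per-feature population variance)."""
        return len(self._y), self._X.mean(axis=0), self._X.var(axis=0)

    def local_update(self, model: LRModel, config: TrainConfig) -> tuple[LRModel, int]:
        return fit_local_sgd(model, self._X, self._y, config), len(self._y)


def fedavg_aggregate(client_models: Sequence[LRModel], client_counts: Sequence[int]) -> LRModel:
    """Sample-count-weighted mean of client weights and intercepts."""
    if len(client_models) != len(client_counts) or not client_models:
        raise ValueError("need one positive count per client model")
    counts = np.asarray(client_counts, float)
    if np.any(counts <= 0):
        raise ValueError("client counts must be positive")
    ref = client_models[0]
    for m in client_models[1:]:
        if m.weights.shape != ref.weights.shape:
            raise ValueError("client models have mismatched dimensions")
        if not (
            np.array_equal(m.scaler.center, ref.scaler.center)
            and np.array_equal(m.scaler.spread, ref.scaler.spread)
        ):
            raise ValueError("client models must share the broadcast scaler")
    frac = counts / counts.sum()
    weights = np.sum([f * m.weights for f, m in zip(frac, client_models)], axis=0)
    intercept = float(np.sum([f * m.intercept for f, m in zip(frac, client_models)]))
    return LRModel(weights, intercept, ref.scaler, ref.feature_names)


def pooled_scaler(moments: Sequence[tuple[int, np.ndarray, np.ndarray]]) -> Scaler:
    """Standardizer from count-weighted pooling of per-client means/variances."""
    counts = np.asarray([m[0] for m in moments], float)
    means = np.stack([m[1] for m in moments])
    variances = np.stack([m[2] for m in moments])
    frac = counts[:, None] / counts.sum()
    mean = (frac * means).sum(axis=0)
    var = (frac * (variances + means**2)).sum(axis=0) - mean**2
    return Scaler.from_moments(mean, var)


def federated_rounds(clients: Sequence[Client], config: FederatedConfig) -> LRModel:
    """Run the FedAvg server loop against an abstract client interface."""
    scaler = pooled_scaler([c.moments() for c in clients])
    global_model = zero_model(scaler, list(FEATURE_COLUMNS))
    rng = np.random.default_rng(config.seed)
    n_pick = max(1, int(round(config.client_fraction * len(clients))))
    for rnd in range(config.rounds):
        if n_pick < len(clients):
            chosen = [clients[i] for i in rng.choice(len(clients), n_pick, replace=False)]
        else:
            chosen = list(clients)
        updates, counts = [], []
        for client in chosen:
            cfg = replace(
                config.train,
                local_epochs=config.local_epochs,
                seed=(config.seed * 1_000_003 + rnd * 1009 + client.client_id) % 2**31,
            )
            model, n = client.local_update(global_model, cfg)
            updates.append(model)
            counts.append(n)
        global_model = fedavg_aggregate(updates, counts)
    return global_model


def run_federated(
    matrices: Mapping[int, pd.DataFrame],
    split: SplitSpec,
    fed_config: FederatedConfig | None = None,
) -> StrategyResult:
    """Simulated FedAvg over the cohort; only models and counts leave clients."""
    fed_config = fed_config or FederatedConfig()
    splits = _split_cohort(matrices, split)
    clients = []
    for pid, (train, _) in sorted(splits.items()):
        X, y = _xy(train)
        if np.unique(y).size < 2:
            raise DegenerateLabelsError(f"participant {pid}: training split has one class")
        clients.append(FederatedClient(pid, X, y))
    global_model = federated_rounds(clients, fed_config)
    preds = {pid: _predictions(global_model, te) for pid, (_, te) in sorted(splits.items())}
    return StrategyResult("federated", {"global": global_model}, preds)
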