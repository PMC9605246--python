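"""Learning topologies: splits, FedAvg aggregation, the three strategy runners."""

import numpy as np
import pandas as pd
import pytest

from fedstress.cohort import CohortHeterogeneity, generate_cohort
from fedstress.experiment import extract_cohort_features
from fedstress.features import FEATURE_COLUMNS, feature_values
from fedstress.logistic import (
    DegenerateLabelsError,
    LRModel,
    Scaler,
    TrainConfig,
    fit_batch,
    predict_proba,
)
from fedstress.strategies import (
    FederatedClient,
    FederatedConfig,
    SplitSpec,
    fedavg_aggregate,
    federated_rounds,
    pooled_scaler,
    run_centralized,
    run_federated,
    run_individual,
    split_train_test,
)


def toy_matrix(rng, n=100, pid=1, pos_fraction=0.4):
    n_pos = int(round(n * pos_fraction))
    X = rng.normal(size=(n, len(FEATURE_COLUMNS)))
    y = np.array([0] * (n - n_pos) + [1] * n_pos)
    X[:, 0] += 3.0 * y  # informative feature
    df = pd.DataFrame(X, columns=list(FEATURE_COLUMNS))
    df["label"] = y
    df["participant"] = pid
    return df


class TestSplit:
    def test_eighty_twenty_counts(self, rng):
        train, test = split_train_test(toy_matrix(rng), SplitSpec(seed=3))
        assert (len(train), len(test)) == (80, 20)

    def test_stratified_preserves_class_proportions(self, rng):
        df = toy_matrix(rng, n=100, pos_fraction=0.4)  # 60/40 mix
        _, test = split_train_test(df, SplitSpec(seed=3))
        assert (test["label"] == 0).sum() == 12
        assert (test["label"] == 1).sum() == 8

    def test_split_is_seed_deterministic(self, rng):
        df = toy_matrix(rng)
        a = split_train_test(df, SplitSpec(seed=5))[1]
        b = split_train_test(df, SplitSpec(seed=5))[1]
        assert a.equals(b)

    def test_chronological_takes_final_windows(self, rng):
        df = toy_matrix(rng)
        train, test = split_train_test(df, SplitSpec(mode="chronological"))
        assert list(test.index) == list(range(80, 100))
        assert list(train.index) == list(range(80))

    def test_stratified_single_class_rejected(self, rng):
        df = toy_matrix(rng)
        df["label"] = 0
        with pytest.raises(DegenerateLabelsError):
            split_train_test(df, SplitSpec())

    @pytest.mark.parametrize("kwargs", [{"train_fraction": 0.0}, {"mode": "jackknife"}])
    def test_invalid_spec_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SplitSpec(**kwargs)


def small_model(w, b, d=3):
    return LRModel(np.full(d, float(w)), float(b), Scaler(np.zeros(d), np.ones(d)))


class TestFedAvgAggregate:
    def test_identical_models_average_to_themselves(self):
        models = [small_model(1.5, 0.3) for _ in range(4)]
        agg = fedavg_aggregate(models, [10, 20, 5, 8])
        np.testing.assert_allclose(agg.weights, models[0].weights, rtol=1e-12)
        assert agg.intercept == pytest.approx(models[0].intercept, rel=1e-12)

    def test_count_weighted_mean(self):
        agg = fedavg_aggregate([small_model(0, 0), small_model(4, 4)], [1, 3])
        np.testing.assert_allclose(agg.weights, 3.0)
        assert agg.intercept == pytest.approx(3.0)

    def test_single_client_passthrough(self):
        m = small_model(2.2, -1.0)
        agg = fedavg_aggregate([m], [7])
        np.testing.assert_array_equal(agg.weights, m.weights)

    def test_rejects_mismatched_dimensions_and_bad_counts(self):
        with pytest.raises(ValueError):
            fedavg_aggregate([small_model(1, 0, d=3), small_model(1, 0, d=4)], [1, 1])
        with pytest.raises(ValueError):
            fedavg_aggregate([small_model(1, 0)], [0])

    def test_aggregate_lies_in_coordinatewise_convex_hull(self, rng):
        scaler = Scaler(np.zeros(6), np.ones(6))
        models = [LRModel(rng.normal(size=6), rng.normal(), scaler) for _ in range(5)]
        counts = rng.integers(1, 50, size=5).tolist()
        agg = fedavg_aggregate(models, counts)
        W = np.stack([m.weights for m in models])
        assert np.all(agg.weights >= W.min(axis=0) - 1e-12)
        assert np.all(agg.weights <= W.max(axis=0) + 1e-12)


class TestStrategyRunners:
    def test_individual_reduces_to_batch_fit_for_one_participant(self, rng):
        df = toy_matrix(rng)
        split = SplitSpec(seed=1)
        result = run_individual({1: df}, split)
        train, test = split_train_test(df, split)
        direct = fit_batch(feature_values(train), train["label"].to_numpy())
        model = result.models[1]
        np.testing.assert_allclose(
            predict_proba(model, feature_values(test)),
            predict_proba(direct, feature_values(test)),
            atol=1e-6,
        )

    def test_individual_yields_one_model_per_participant(self, cohort_matrices):
        result = run_individual(cohort_matrices, SplitSpec(seed=1))
        assert sorted(result.models) == sorted(cohort_matrices)
        assert sorted(result.predictions) == sorted(cohort_matrices)

    def test_individual_results_are_isolated_across_participants(self, cohort_matrices):
        split = SplitSpec(seed=1)
        full = run_individual(cohort_matrices, split)
        reduced = run_individual({1: cohort_matrices[1]}, split)
        np.testing.assert_array_equal(
            full.predictions[1].y_pred, reduced.predictions[1].y_pred
        )

    def test_centralized_on_one_participant_equals_individual(self, rng):
        df = toy_matrix(rng)
        split = SplitSpec(seed=2)
        cen = run_centralized({1: df}, split)
        ind = run_individual({1: df}, split)
        np.testing.assert_array_equal(cen.predictions[1].y_pred, ind.predictions[1].y_pred)

    def test_centralized_structure(self, cohort_matrices):
        result = run_centralized(cohort_matrices, SplitSpec(seed=1))
        assert list(result.models) == ["global"]
        assert len(result.predictions) == len(cohort_matrices)

    def test_degenerate_split_error_names_participant(self, rng):
        df = toy_matrix(rng, pid=7)
        df["label"] = 0
        with pytest.raises(DegenerateLabelsError, match="participant 7"):
            run_individual({7: df}, SplitSpec())


class TestFederated:
    def test_single_client_converges_to_local_batch_fit(self, rng):
        df = toy_matrix(rng, n=80)
        split = SplitSpec(seed=4)
        cfg = FederatedConfig(
            rounds=400,
            local_epochs=5,
            train=TrainConfig(learning_rate=0.3, batch_size=64),
            seed=4,
        )
        fed = run_federated({1: df}, split, cfg)
        train, _ = split_train_test(df, split)
        X, y = feature_values(train), train["label"].to_numpy()
        batch = fit_batch(X, y, scaler=fed.models["global"].scaler)
        g = fed.models["global"]
        dist = np.linalg.norm(g.weights - batch.weights) + abs(g.intercept - batch.intercept)
        assert dist < 1e-2

    def test_identical_clients_one_round_equals_one_central_gradient_step(self, rng):
        df = toy_matrix(rng, n=40)
        X, y = feature_values(df), df["label"].to_numpy()
        clients = [FederatedClient(i, X, y) for i in range(1, 4)]
        cfg = FederatedConfig(
            rounds=1, local_epochs=1, train=TrainConfig(learning_rate=0.1, batch_size=len(y))
        )
        agg = federated_rounds(clients, cfg)
        scaler = pooled_scaler([c.moments() for c in clients])
        from scipy.special import expit

        Z = scaler.transform(X)
        p = np.full(len(y), 0.5)  # zero start model
        w_step = -0.1 * (Z.T @ (p - y) / len(y))
        b_step = -0.1 * float(np.mean(p - y))
        np.testing.assert_allclose(agg.weights, w_step, atol=1e-10)
        assert agg.intercept == pytest.approx(b_step, abs=1e-12)

    def test_run_is_bit_deterministic(self, cohort_matrices):
        cfg = FederatedConfig(rounds=3, seed=11)
        a = run_federated(cohort_matrices, SplitSpec(seed=2), cfg)
        b = run_federated(cohort_matrices, SplitSpec(seed=2), cfg)
        np.testing.assert_array_equal(
            a.models["global"].weights, b.models["global"].weights
        )
        for pid in a.predictions:
            np.testing.assert_array_equal(a.predictions[pid].y_pred, b.predictions[pid].y_pred)

    def test_server_needs_only_moments_and_updates(self, rng):
        """The privacy contract: the server loop runs against stub clients
        exposing nothing but client_id, moments() and local_update()."""
        df = toy_matrix(rng, n=40)
        X, y = feature_values(df), df["label"].to_numpy()

        class StubClient:
            client_id = 1

            def moments(self):
                return len(y), X.mean(axis=0), X.var(axis=0)

            def local_update(self, model, config):
                return model, len(y)

            def __getattr__(self, name):  # anything else is a contract breach
                raise AssertionError(f"server accessed private client attribute {name!r}")

        model = federated_rounds([StubClient()], FederatedConfig(rounds=2))
        assert model.weights.shape == (len(FEATURE_COLUMNS),)

    def test_rejects_invalid_round_counts(self):
        with pytest.raises(ValueError):
            FederatedConfig(rounds=0)

    def test_homogeneous_cohort_centralized_and_federated_agree(self, short_plan):
        cohort = generate_cohort(
            3,
            heterogeneity=CohortHeterogeneity(0.0, 0.0, 0.0, 0.0),
            atypical_fraction=0.0,
            seed=8,
            plan=short_plan,
        )
        matrices = extract_cohort_features(cohort)
        split = SplitSpec(seed=8)
        cen = run_centralized(matrices, split)
        fed = run_federated(matrices, split, FederatedConfig(rounds=20, seed=8))

        def acc(result):
            correct = total = 0
            for pred in result.predictions.values():
                correct += (pred.y_true == pred.y_pred).sum()
                total += len(pred.y_true)
            return correct / total

        assert abs(acc(cen) - acc(fed)) < 0.05
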