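"""Feed-forward net training, prediction, metrics and the repeat driver."""

import numpy as np
import pandas as pd
import pytest

from driverprog.classifier import (
    ClassifierConfig,
    FeedForwardNet,
    evaluate,
    predict,
    train,
)


def auc_oracle(labels, scores):
    """Mann-Whitney formulation of the ROC AUC."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def mcc_oracle(labels, calls):
    tp = int(((labels == 1) & (calls == 1)).sum())
    tn = int(((labels == 0) & (calls == 0)).sum())
    fp = int(((labels == 0) & (calls == 1)).sum())
    fn = int(((labels == 1) & (calls == 0)).sum())
    denom = np.sqrt(float((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)))
    return 0.0 if denom == 0 else (tp * tn - fp * fn) / denom


@pytest.fixture
def separable_data(rng):
    X = np.vstack([rng.normal(-2, 0.3, (10, 2)), rng.normal(2, 0.3, (10, 2))])
    y = np.array([0] * 10 + [1] * 10)
    return X, y


class TestFeedForwardNet:
    def test_separable_data_reaches_perfect_training_accuracy(self, separable_data):
        X, y = separable_data
        model = FeedForwardNet(ClassifierConfig(seed=1)).fit(X, y)
        acc = ((model.predict_proba(X) >= 0.5).astype(int) == y).mean()
        assert acc == 1.0

    def test_same_seed_is_bit_reproducible(self, separable_data):
        X, y = separable_data
        cfg = ClassifierConfig(seed=99)
        p1 = FeedForwardNet(cfg).fit(X, y).predict_proba(X)
        p2 = FeedForwardNet(cfg).fit(X, y).predict_proba(X)
        assert np.array_equal(p1, p2)

    def test_single_row_equals_batch_row(self, separable_data):
        X, y = separable_data
        model = FeedForwardNet(ClassifierConfig(seed=0)).fit(X, y)
        batch = model.predict_proba(X)
        single = model.predict_proba(X[3])
        assert single[0] == pytest.approx(batch[3])

    def test_probabilities_in_unit_interval(self, separable_data, rng):
        X, y = separable_data
        model = FeedForwardNet(ClassifierConfig(seed=0)).fit(X, y)
        probs = model.predict_proba(np.zeros((4, 2)))
        assert ((probs >= 0) & (probs <= 1)).all()

    def test_single_class_rejected(self, rng):
        X = rng.random((6, 3))
        with pytest.raises(ValueError, match="single class"):
            FeedForwardNet().fit(X, np.zeros(6))

    def test_early_stopping_cuts_epochs(self, separable_data):
        X, y = separable_data
        cfg = ClassifierConfig(seed=1, max_epochs=200, early_stop_loss=0.5, early_stop_count=5)
        model = FeedForwardNet(cfg).fit(X, y)
        assert len(model.loss_history_) < 200

    def test_feature_count_mismatch(self, separable_data):
        X, y = separable_data
        model = FeedForwardNet(ClassifierConfig(seed=0)).fit(X, y)
        with pytest.raises(ValueError, match="feature count"):
            model.predict_proba(np.zeros((2, 5)))


class TestTrainPredictWrappers:
    def test_predict_reorders_columns_by_trained_genes(self, separable_data):
        X, y = separable_data
        df = pd.DataFrame(X, columns=["gA", "gB"])
        model = train(df, y, ClassifierConfig(seed=0))
        swapped = df[["gB", "gA"]]
        assert np.allclose(predict(model, swapped), predict(model, df))

    def test_predict_names_missing_genes(self, separable_data):
        X, y = separable_data
        model = train(pd.DataFrame(X, columns=["gA", "gB"]), y, ClassifierConfig(seed=0))
        with pytest.raises(ValueError, match="gB"):
            predict(model, pd.DataFrame(X[:, :1], columns=["gA"]))


class TestEvaluate:
    def test_perfect_separation(self):
        rep = evaluate(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0]))
        assert rep.auc == 1.0 and rep.mcc == 1.0 and rep.f1 == 1.0

    def test_hand_computed_four_sample_case(self):
        rep = evaluate(np.array([0.9, 0.8, 0.3, 0.1]), np.array([1, 1, 0, 0]))
        assert rep.auc == 1.0
        assert rep.f1 == 1.0
        assert rep.balanced_accuracy == 1.0

    def test_random_probs_near_half_auc(self, rng):
        labels = rng.integers(0, 2, 2000)
        probs = rng.random(2000)
        rep = evaluate(probs, labels)
        assert rep.auc == pytest.approx(0.5, abs=0.05)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            evaluate(np.array([0.1, 0.9]), np.array([1, 1]))

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_independent_formulas(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, 60)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        probs = rng.random(60)
        rep = evaluate(probs, labels)
        assert rep.auc == pytest.approx(auc_oracle(labels, probs), abs=1e-9)
        calls = (probs >= 0.5).astype(int)
        assert rep.mcc == pytest.approx(mcc_oracle(labels, calls), abs=1e-9)


@pytest.fixture(scope="module")
def tiny_run(tiny_cohort, tiny_network):
    from driverprog.classifier import run_experiment

    cfg = ClassifierConfig(hidden_layers=(16, 8, 4), max_epochs=40)
    return run_experiment(
        tiny_cohort,
        tiny_network,
        config=cfg,
        n_repeats=2,
        pvalue_grid=(0.1, 0.01),
        cv_folds=3,
        seed=11,
    )


class TestRunExperiment:
    def test_one_report_per_repeat(self, tiny_run):
        assert len(tiny_run.repeats) == 2
        for rep in tiny_run.repeats:
            assert 0.0 <= rep.metrics.auc <= 1.0

    def test_fixed_seed_reproduces_run(self, tiny_cohort, tiny_network, tiny_run):
        from driverprog.classifier import run_experiment

        cfg = ClassifierConfig(hidden_layers=(16, 8, 4), max_epochs=40)
        again = run_experiment(
            tiny_cohort,
            tiny_network,
            config=cfg,
            n_repeats=2,
            pvalue_grid=(0.1, 0.01),
            cv_folds=3,
            seed=11,
        )
        for r1, r2 in zip(tiny_run.repeats, again.repeats):
            assert r1.metrics.auc == r2.metrics.auc
            assert r1.selection.selected_genes == r2.selection.selected_genes
            assert r1.train_samples == r2.train_samples

    def test_splits_paired_across_ablation_arms(self, tiny_cohort, tiny_network, tiny_run):
        from driverprog.classifier import run_experiment

        cfg = ClassifierConfig(hidden_layers=(16, 8, 4), max_epochs=40)
        ablated = run_experiment(
            tiny_cohort,
            tiny_network,
            config=cfg,
            n_repeats=2,
            pvalue_grid=(0.1, 0.01),
            cv_folds=3,
            seed=11,
            network_mode="unweighted",
        )
        for r1, r2 in zip(tiny_run.repeats, ablated.repeats):
            assert r1.train_samples == r2.train_samples
            assert r1.test_samples == r2.test_samples
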