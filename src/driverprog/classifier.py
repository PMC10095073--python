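"""Feed-forward prognosis classifier and the repeat-experiment driver.

The classifier is a compact fully-connected network: three hidden layers with
ReLU activations, a sigmoid output, binary cross-entropy loss, Adam at
learning rate 0.001 and mini-batches of 2, for at most 200 epochs. Training
terminates early once the per-epoch mean loss has been below 1e-4 on more
than 20 (cumulative) epochs. All randomness (weight init, batch shuffling)
is governed by the config seed, so a fixed seed makes runs bit-reproducible.

``run_experiment`` wires the whole pipeline: per repeat, a stratified 5:5
train/test split, p-value-threshold selection by 5-fold CV on the training
half, training on the training half's win-rate features, and evaluation on
the held-out half (AUC, PR-AUC, balanced accuracy, F1, MCC). Ablation hooks
swap the patient-specific network for random-weight or unweighted variants
and the win-rate features for raw impact scores, with splits paired across
variants by seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import (
    average_precision_score,
    balanced_accuracy_score,
    f1_score,
    matthews_corrcoef,
    roc_auc_score,
)
from sklearn.model_selection import train_test_split

from driverprog.cohort_io import CohortDataset
from driverprog.impact_score import PENALTY_DEFAULT, cohort_features
from driverprog.feature_select import PVALUE_GRID_DEFAULT, SelectionResult, choose_threshold
from driverprog.network_io import GeneNetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassifierConfig:
    """Hyperparameters of the feed-forward net.

    ``hidden_layers=None`` means a geometric taper from the input width n:
    [n/4, n/16, n/64] (clipped below at 8/4/2 units). Only the depth (3),
    activations, learning rate, batch size, epoch budget and early-stopping
    rule are fixed by the protocol; widths are free.
    """

    hidden_layers: tuple[int, int, int] | None = None
    learning_rate: float = 0.001
    batch_size: int = 2
    max_epochs: int = 200
    early_stop_loss: float = 1e-4
    early_stop_count: int = 20
    early_stop_mode: str = "cumulative"  # or "consecutive"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.hidden_layers is not None and len(self.hidden_layers) != 3:
            raise ValueError("the default architecture has exactly 3 hidden layers")

    def with_seed(self, seed: int) -> "ClassifierConfig":
        return replace(self, seed=int(seed))

    def resolve_hidden(self, n_features: int) -> tuple[int, int, int]:
        if self.hidden_layers is not None:
            return self.hidden_layers
        return (
            max(n_features // 4, 64),
            max(n_features // 16, 32),
            max(n_features // 64, 16),
        )


@dataclass
class MetricsReport:
    auc: float
    pr_auc: float
    balanced_accuracy: float
    f1: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return {
            "auc": self.auc,
            "pr_auc": self.pr_auc,
            "balanced_accuracy": self.balanced_accuracy,
            "f1": self.f1,
            "mcc": self.mcc,
        }


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class FeedForwardNet:
    """Three-hidden-layer ReLU net with sigmoid output, BCE loss and Adam."""

    def __init__(self, config: ClassifierConfig | None = None):
        self.config = config if config is not None else ClassifierConfig()
        self.weights_: list[np.ndarray] | None = None
        self.biases_: list[np.ndarray] | None = None
        self.n_features_: int | None = None
        self.loss_history_: list[float] = []

    # -- forward -----------------------------------------------------------
    def _forward(self, X: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        acts = [X]
        h = X
        for k, (W, b) in enumerate(zip(self.weights_, self.biases_)):
            z = h @ W + b
            h = _sigmoid(z) if k == len(self.weights_) - 1 else np.maximum(z, 0.0)
            acts.append(h)
        return h.ravel(), acts

    def fit(self, X: np.ndarray, y: np.ndarray) -> "FeedForwardNet":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("X must be samples x features matching y")
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training set contains a single class")
        if np.bincount(y.astype(int)).min() < 2:
            raise ValueError("need at least 2 samples per class")
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        n, n_feat = X.shape
        self.n_features_ = n_feat
        sizes = [n_feat, *cfg.resolve_hidden(n_feat), 1]
        # He init for the ReLU layers, Xavier-ish for the sigmoid output
        self.weights_ = [
            rng.normal(0.0, np.sqrt(2.0 / sizes[k]), size=(sizes[k], sizes[k + 1]))
            for k in range(len(sizes) - 1)
        ]
        self.biases_ = [np.zeros(sizes[k + 1]) for k in range(len(sizes) - 1)]

        mW = [np.zeros_like(W) for W in self.weights_]
        vW = [np.zeros_like(W) for W in self.weights_]
        mb = [np.zeros_like(b) for b in self.biases_]
        vb = [np.zeros_like(b) for b in self.biases_]
        b1, b2, eps = 0.9, 0.999, 1e-8
        step = 0
        low_loss_epochs = 0
        self.loss_history_ = []

        for _epoch in range(cfg.max_epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                xb, yb = X[idx], y[idx]
                probs, acts = self._forward(xb)
                p = np.clip(probs, 1e-12, 1 - 1e-12)
                epoch_loss += float(-np.sum(yb * np.log(p) + (1 - yb) * np.log(1 - p)))
                # backprop: BCE + sigmoid gives delta = p - y at the output
                delta = ((probs - yb) / len(idx))[:, None]
                grads_W, grads_b = [], []
                for k in range(len(self.weights_) - 1, -1, -1):
                    grads_W.append(acts[k].T @ delta)
                    grads_b.append(delta.sum(axis=0))
                    if k > 0:
                        delta = (delta @ self.weights_[k].T) * (acts[k] > 0)
                grads_W.reverse()
                grads_b.reverse()
                step += 1
                for k in range(len(self.weights_)):
                    mW[k] = b1 * mW[k] + (1 - b1) * grads_W[k]
                    vW[k] = b2 * vW[k] + (1 - b2) * grads_W[k] ** 2
                    mb[k] = b1 * mb[k] + (1 - b1) * grads_b[k]
                    vb[k] = b2 * vb[k] + (1 - b2) * grads_b[k] ** 2
                    mW_hat = mW[k] / (1 - b1**step)
                    vW_hat = vW[k] / (1 - b2**step)
                    mb_hat = mb[k] / (1 - b1**step)
                    vb_hat = vb[k] / (1 - b2**step)
                    self.weights_[k] -= cfg.learning_rate * mW_hat / (np.sqrt(vW_hat) + eps)
                    self.biases_[k] -= cfg.learning_rate * mb_hat / (np.sqrt(vb_hat) + eps)
            mean_loss = epoch_loss / n
            self.loss_history_.append(mean_loss)
            if mean_loss < cfg.early_stop_loss:
                low_loss_epochs += 1
            elif cfg.early_stop_mode == "consecutive":
                low_loss_epochs = 0
            if low_loss_epochs > cfg.early_stop_count:
                break
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.weights_ is None:
            raise RuntimeError("model is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_:
            raise ValueError(
                f"feature count mismatch: model expects {self.n_features_}, got {X.shape[1]}"
            )
        probs, _ = self._forward(X)
        return probs


def train(features: pd.DataFrame, labels: np.ndarray, config: ClassifierConfig | None = None) -> FeedForwardNet:
    """Fit the feed-forward net on a samples x selected-genes win-rate matrix."""
    model = FeedForwardNet(config)
    model.feature_genes_ = list(features.columns)
    model.fit(features.to_numpy(), np.asarray(labels))
    return model


def predict(model: FeedForwardNet, features: pd.DataFrame) -> np.ndarray:
    """Per-sample probability of bad prognosis; columns must match training."""
    genes = getattr(model, "feature_genes_", None)
    if genes is not None:
        missing = [g for g in genes if g not in features.columns]
        if missing:
            raise ValueError(f"features missing trained genes: {missing}")
        features = features[genes]
    return model.predict_proba(features.to_numpy())


def evaluate(probs: np.ndarray, labels: np.ndarray, threshold: float = 0.5) -> MetricsReport:
    """Threshold-free (AUC, PR-AUC) and thresholded (bACC, F1, MCC) metrics."""
    labels = np.asarray(labels).ravel()
    probs = np.asarray(probs, dtype=float).ravel()
    if len(np.unique(labels)) < 2:
        raise ValueError("labels contain a single class")
    calls = (probs >= threshold).astype(int)
    return MetricsReport(
        auc=float(roc_auc_score(labels, probs)),
        pr_auc=float(average_precision_score(labels, probs)),
        balanced_accuracy=float(balanced_accuracy_score(labels, calls)),
        f1=float(f1_score(labels, calls, zero_division=0)),
        mcc=float(matthews_corrcoef(labels, calls)),
    )


@dataclass
class RepeatResult:
    metrics: MetricsReport
    selection: SelectionResult
    train_samples: list[str]
    test_samples: list[str]
    final_scores: pd.Series  # per-gene mean win rate over training samples


@dataclass
class ExperimentResult:
    repeats: list[RepeatResult]
    features: pd.DataFrame  # cohort-wide samples x genes feature matrix
    network_mode: str
    feature_mode: str

    @property
    def mean_auc(self) -> float:
        return float(np.mean([r.metrics.auc for r in self.repeats]))

    def metrics_frame(self) -> pd.DataFrame:
        rows = [r.metrics.as_dict() for r in self.repeats]
        df = pd.DataFrame(rows)
        df.insert(0, "repeat", np.arange(len(rows)))
        return df


def run_experiment(
    dataset: CohortDataset,
    network: GeneNetwork,
    config: ClassifierConfig | None = None,
    n_repeats: int = 10,
    test_size: float = 0.5,
    pvalue_grid: Sequence[float] = PVALUE_GRID_DEFAULT,
    cv_folds: int = 5,
    penalty: float = PENALTY_DEFAULT,
    network_mode: str = "patient",
    feature_mode: str = "win_rate",
    initial_score_mode: str = "expression",
    seed: int = 0,
) -> ExperimentResult:
    """Repeat the full train/evaluate protocol ``n_repeats`` times.

    Feature vectors depend only on each sample's own data, so the cohort-wide
    feature matrix is computed once and shared across repeats. Split, CV and
    model seeds are derived from ``seed`` alone, so ablation arms run with
    identical splits (paired comparison) and a fixed seed reproduces the run.
    """
    config = config if config is not None else ClassifierConfig()
    rng = np.random.default_rng(seed)
    split_seeds = rng.integers(0, 2**31 - 1, size=n_repeats)
    cv_seeds = rng.integers(0, 2**31 - 1, size=n_repeats)
    model_seeds = rng.integers(0, 2**31 - 1, size=n_repeats)

    features = cohort_features(
        dataset,
        network,
        penalty=penalty,
        feature_mode=feature_mode,
        network_mode=network_mode,
        initial_score_mode=initial_score_mode,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    samples = dataset.samples
    y = dataset.label_array(samples)
    expr = dataset.tumor_expr[samples]

    repeats: list[RepeatResult] = []
    for r in range(n_repeats):
        train_s, test_s = train_test_split(
            samples,
            test_size=test_size,
            stratify=y,
            random_state=int(split_seeds[r] % (2**31 - 1)),
        )
        y_train = dataset.label_array(train_s)
        y_test = dataset.label_array(test_s)
        selection = choose_threshold(
            features.loc[train_s],
            expr[train_s],
            y_train,
            grid=tuple(pvalue_grid),
            k=cv_folds,
            classifier_config=config,
            seed=int(cv_seeds[r] % (2**31 - 1)),
        )
        model = train(
            features.loc[train_s, selection.selected_genes],
            y_train,
            config.with_seed(int(model_seeds[r])),
        )
        probs = predict(model, features.loc[test_s])
        metrics = evaluate(probs, y_test)
        repeats.append(
            RepeatResult(
                metrics=metrics,
                selection=selection,
                train_samples=list(train_s),
                test_samples=list(test_s),
                final_scores=features.loc[train_s].mean(axis=0),
            )
        )
        logger.info(
            "repeat %d: threshold %g, %d genes, test AUC %.3f",
            r,
            selection.chosen_threshold,
            len(selection.selected_genes),
            metrics.auc,
        )
    return ExperimentResult(
        repeats=repeats, features=features, network_mode=network_mode, feature_mode=feature_mode
    )
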