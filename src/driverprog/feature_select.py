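"""Gene selection by differential expression between prognosis groups.

Genes are tested for a good-vs-bad expression difference with a two-sided
Welch t-test, and the p-value cutoff is picked from a small grid by stratified
k-fold cross-validation on the training half: for each fold, p-values are
computed on the fold's training part only, the classifier is trained on the
win-rate features of the passing genes, and the cutoff with the highest mean
held-out AUC wins (ties go to the stricter cutoff). The final gene set is
re-derived on the full training set at the chosen cutoff.

Note the deliberate asymmetry: the t-test runs on raw EXPRESSION, while the
classifier consumes WIN RATES of the selected genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

PVALUE_GRID_DEFAULT = (0.1, 0.05, 0.01, 0.005)


@dataclass
class SelectionResult:
    pvalues: pd.Series
    chosen_threshold: float
    selected_genes: list[str]
    fold_auc: dict[float, float]
    fold_selected: list[list[str]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        sel = set(self.selected_genes)
        return pd.DataFrame(
            {
                "gene": self.pvalues.index,
                "pvalue": self.pvalues.values,
                "selected": [g in sel for g in self.pvalues.index],
            }
        )


def per_gene_test(expr_good: pd.DataFrame, expr_bad: pd.DataFrame) -> pd.Series:
    """Two-sided Welch t-test p-value per gene (rows) between the two groups.

    Degenerate genes (zero variance in both groups, including constants) get
    p = 1 by convention.
    """
    if expr_good.shape[1] < 2 or expr_bad.shape[1] < 2:
        raise ValueError("each prognosis group needs at least 2 samples")
    if list(expr_good.index) != list(expr_bad.index):
        raise ValueError("gene lists differ between groups")
    res = stats.ttest_ind(expr_good.values, expr_bad.values, axis=1, equal_var=False)
    pvals = np.asarray(res.pvalue, dtype=float)
    var_good = expr_good.values.var(axis=1)
    var_bad = expr_bad.values.var(axis=1)
    pvals[(var_good == 0) & (var_bad == 0)] = 1.0
    pvals[np.isnan(pvals)] = 1.0
    return pd.Series(pvals, index=expr_good.index, name="pvalue")


def _select(pvalues: pd.Series, threshold: float) -> list[str]:
    return list(pvalues.index[pvalues.values < threshold])


def choose_threshold(
    train_features: pd.DataFrame,
    train_expr: pd.DataFrame,
    train_labels: np.ndarray,
    grid: tuple[float, ...] = PVALUE_GRID_DEFAULT,
    k: int = 5,
    classifier_config=None,
    seed: int | None = None,
) -> SelectionResult:
    """Pick the p-value cutoff maximizing mean k-fold AUC on the training set.

    ``train_features`` is samples x genes (win rates), ``train_expr`` is genes
    x samples (expression, same samples), ``train_labels`` is binary (1=bad).
    P-values are computed inside each fold from that fold's training part
    only, so selection never sees held-out labels. A fold/cutoff with no
    passing genes scores an uninformative AUC of 0.5.
    """
    from driverprog.classifier import ClassifierConfig, FeedForwardNet  # deferred: avoids cycle

    if not grid:
        raise ValueError("threshold grid is empty")
    train_labels = np.asarray(train_labels)
    if len(np.unique(train_labels)) < 2:
        raise ValueError("training set must contain both classes")
    samples = list(train_features.index)
    if list(train_expr.columns) != samples:
        train_expr = train_expr[samples]
    config = classifier_config if classifier_config is not None else ClassifierConfig()

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_pvals: list[pd.Series] = []
    fold_splits = list(skf.split(np.zeros(len(samples)), train_labels))
    for tr_idx, _ in fold_splits:
        tr_samples = [samples[i] for i in tr_idx]
        tr_labels = train_labels[tr_idx]
        good = [s for s, y in zip(tr_samples, tr_labels) if y == 0]
        bad = [s for s, y in zip(tr_samples, tr_labels) if y == 1]
        fold_pvals.append(per_gene_test(train_expr[good], train_expr[bad]))

    fold_auc: dict[float, float] = {}
    fold_selected: list[list[str]] = []
    for t_i, threshold in enumerate(grid):
        aucs = []
        for f_i, (tr_idx, va_idx) in enumerate(fold_splits):
            genes = _select(fold_pvals[f_i], threshold)
            if not genes:
                aucs.append(0.5)
                continue
            X_tr = train_features.iloc[tr_idx][genes].to_numpy()
            X_va = train_features.iloc[va_idx][genes].to_numpy()
            model = FeedForwardNet(config.with_seed((seed or 0) * 100 + f_i))
            model.fit(X_tr, train_labels[tr_idx])
            probs = model.predict_proba(X_va)
            aucs.append(roc_auc_score(train_labels[va_idx], probs))
        fold_auc[threshold] = float(np.mean(aucs))
    # widest-threshold fold selections recorded for leakage diagnostics
    fold_selected = [_select(p, max(grid)) for p in fold_pvals]

    best_auc = max(fold_auc.values())
    chosen = min(t for t, a in fold_auc.items() if a == best_auc)

    good = [s for s, y in zip(samples, train_labels) if y == 0]
    bad = [s for s, y in zip(samples, train_labels) if y == 1]
    pvalues = per_gene_test(train_expr[good], train_expr[bad])
    selected = _select(pvalues, chosen)
    if not selected:
        logger.warning(
            "no gene passed p<%g on the full training set; falling back to 10 smallest p-values",
            chosen,
        )
        selected = list(pvalues.nsmallest(10).index)
    return SelectionResult(
        pvalues=pvalues,
        chosen_threshold=chosen,
        selected_genes=selected,
        fold_auc=fold_auc,
        fold_selected=fold_selected,
    )
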