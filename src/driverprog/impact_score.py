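"""Driver-impact scores by damped network propagation, mutation penalty and
win-rate normalization.

Starting from f, the per-gene absolute expression difference between the tumor
sample and the mean of the normal group, scores are propagated through the
patient network by the PageRank-style fixed point

    S = (1 - d) * f + d * (W_norm @ S)

with a per-gene damping factor d_g = Asum_g / (Asum_g + 3) driven by the
gene's incoming-edge count Asum_g in the oriented network: well-connected
genes trust their neighbourhood, isolated genes keep their own score.
Genes without a somatic mutation in the patient are then penalized by the
factor p (0.85 by default), and the penalized scores are converted to win
rates: the fraction of comparison genes a gene outscores (ties count 0.5).
Mutated genes are compared against all other genes; non-mutated genes only
against the patient's mutated genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Set

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata

from driverprog.cohort_io import CohortDataset
from driverprog.network_io import GeneNetwork, incoming_degree
from driverprog.patient_network import build_patient_network, normalize_W

logger = logging.getLogger(__name__)

PENALTY_DEFAULT = 0.85


@dataclass
class ImpactVector:
    S: np.ndarray
    converged: bool
    iterations: int


@dataclass
class WinRateVector:
    V: np.ndarray


def damping_vector(in_degree: np.ndarray) -> np.ndarray:
    """d_g = Asum_g / (Asum_g + 3); 0 for isolated genes, -> 1 for hubs."""
    deg = np.asarray(in_degree, dtype=float)
    if (deg < 0).any():
        raise ValueError("incoming degrees must be nonnegative")
    return deg / (deg + 3.0)


def initial_scores(
    tumor_col: np.ndarray, normal_mean: np.ndarray, normalize: bool = False
) -> np.ndarray:
    """f_g = |tumor_g - mean-normal_g| on the expression scale.

    With ``normalize`` the vector is divided by its sum, making scores
    comparable across patients; the propagation is linear in f and the win
    rate is rank-based, so this only stabilizes numerics.
    """
    tumor_col = np.asarray(tumor_col, dtype=float)
    normal_mean = np.asarray(normal_mean, dtype=float)
    if tumor_col.shape != normal_mean.shape:
        raise ValueError("tumor and normal-mean vectors differ in length")
    f = np.abs(tumor_col - normal_mean)
    if normalize:
        total = f.sum()
        if total > 0:
            f = f / total
    return f


def propagate(
    W_norm: sp.spmatrix,
    f: np.ndarray,
    d: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> ImpactVector:
    """Iterate S <- (1-d)*f + d*(W_norm @ S) from S = f to its fixed point.

    Converges whenever all d < 1 and W_norm's columns sum to at most 1 (the
    iteration matrix diag(d) @ W_norm then has spectral radius < 1). If the
    max-abs change has not dropped below ``tol`` after ``max_iter`` sweeps the
    result is returned flagged unconverged.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    f = np.asarray(f, dtype=float)
    d = np.asarray(d, dtype=float)
    if not (W_norm.shape[0] == W_norm.shape[1] == f.size == d.size):
        raise ValueError("dimension mismatch between W_norm, f and d")
    base = (1.0 - d) * f
    S = f.copy()
    for it in range(1, max_iter + 1):
        S_new = base + d * (W_norm @ S)
        delta = np.max(np.abs(S_new - S)) if S.size else 0.0
        S = S_new
        if delta <= tol:
            return ImpactVector(S=S, converged=True, iterations=it)
    logger.warning("propagation did not converge in %d iterations (delta=%.3g)", max_iter, delta)
    return ImpactVector(S=S, converged=False, iterations=max_iter)


def apply_penalty(S: np.ndarray, mutated_mask: np.ndarray, p: float = PENALTY_DEFAULT) -> np.ndarray:
    """Multiply the scores of non-mutated genes by the penalty p in (0, 1]."""
    if not 0 < p <= 1:
        raise ValueError("penalty must be in (0, 1]")
    S = np.asarray(S, dtype=float)
    mutated_mask = np.asarray(mutated_mask, dtype=bool)
    return np.where(mutated_mask, S, S * p)


def win_rate(S: np.ndarray, mutated_mask: np.ndarray) -> WinRateVector:
    """Win rates in [0, 1]: the fraction of comparison genes a gene outscores.

    A mutated gene is compared with all other n-1 genes; a non-mutated gene
    only with the patient's mutated genes. Ties count 0.5. If the patient has
    no mutated gene at all, the comparison set is undefined and every gene
    falls back to the all-genes win rate (with a warning).
    """
    S = np.asarray(S, dtype=float)
    mutated_mask = np.asarray(mutated_mask, dtype=bool)
    n = S.size
    if n < 2:
        raise ValueError("need at least 2 genes")
    V = np.empty(n, dtype=float)

    # Midranks give wins + 0.5*ties against all other genes in one pass.
    all_wins = rankdata(S, method="average") - 1.0

    if not mutated_mask.any():
        logger.warning("patient has no mutated genes; win rates computed against all genes")
        return WinRateVector(V=all_wins / (n - 1))

    V[mutated_mask] = all_wins[mutated_mask] / (n - 1)

    mut_scores = np.sort(S[mutated_mask])
    m = mut_scores.size
    non_mask = ~mutated_mask
    lo = np.searchsorted(mut_scores, S[non_mask], side="left")
    hi = np.searchsorted(mut_scores, S[non_mask], side="right")
    V[non_mask] = (lo + 0.5 * (hi - lo)) / m
    return WinRateVector(V=V)


def patient_feature_vector(
    network: GeneNetwork,
    in_degree: np.ndarray,
    tumor_col: np.ndarray,
    normal_mean: np.ndarray,
    mutated: Set[str],
    penalty: float = PENALTY_DEFAULT,
    feature_mode: str = "win_rate",
    network_mode: str = "patient",
    initial_score_mode: str = "expression",
    tol: float = 1e-6,
    max_iter: int = 1000,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Full per-sample scoring: build W, propagate, penalize, win-rate.

    ``network_mode`` selects the propagation substrate: the patient-specific
    weighted network ("patient"), random edge weights ("random_weight"), or
    the bare unweighted adjacency ("unweighted"). ``feature_mode`` selects the
    returned vector: win rates ("win_rate"), penalized impact scores
    ("score_no_winrate"), or unpenalized impact scores ("raw_score").
    ``initial_score_mode`` seeds the propagation with the absolute expression
    difference ("expression", default) or the tumor-vs-normal rank difference
    R ("rank").
    """
    mutated_mask = np.zeros(network.n_genes, dtype=bool)
    for g in mutated:
        i = network.index.get(g)
        if i is not None:
            mutated_mask[i] = True

    if network_mode == "patient":
        pn = build_patient_network(network, tumor_col, normal_mean, mutated)
        W_norm = pn.W_norm
    elif network_mode == "random_weight":
        if rng is None:
            rng = np.random.default_rng()
        rows, cols = network.edge_arrays()
        n = network.n_genes
        W = sp.csr_matrix((rng.uniform(size=rows.size), (rows, cols)), shape=(n, n))
        W_norm = normalize_W(W)
    elif network_mode == "unweighted":
        W_norm = normalize_W(network.adjacency.astype(float))
    else:
        raise ValueError(f"unknown network_mode {network_mode!r}")

    d = damping_vector(in_degree)
    if initial_score_mode == "expression":
        f = initial_scores(tumor_col, normal_mean)
    elif initial_score_mode == "rank":
        from driverprog.patient_network import compute_rank_diff

        f = compute_rank_diff(tumor_col, normal_mean).R
    else:
        raise ValueError(f"unknown initial_score_mode {initial_score_mode!r}")
    impact = propagate(W_norm, f, d, tol=tol, max_iter=max_iter)
    if feature_mode == "raw_score":
        return impact.S
    S_pen = apply_penalty(impact.S, mutated_mask, p=penalty)
    if feature_mode == "score_no_winrate":
        return S_pen
    if feature_mode != "win_rate":
        raise ValueError(f"unknown feature_mode {feature_mode!r}")
    return win_rate(S_pen, mutated_mask).V


def cohort_features(
    dataset: CohortDataset,
    network: GeneNetwork,
    penalty: float = PENALTY_DEFAULT,
    feature_mode: str = "win_rate",
    network_mode: str = "patient",
    initial_score_mode: str = "expression",
    seed: int | None = None,
) -> pd.DataFrame:
    """Samples x genes feature matrix for all labelled tumor samples.

    The network is restricted to the cohort's gene universe first; cohort
    genes missing from the network stay as isolated nodes (damping 0, score
    f). Randomness (random-weight ablation only) is governed by ``seed``.
    """
    net = network.restrict_to(dataset.genes)
    in_deg = incoming_degree(net)
    normal_mean = dataset.normal_expr.mean(axis=1).to_numpy()
    rng = np.random.default_rng(seed)
    rows = {}
    for s in dataset.samples:
        rows[s] = patient_feature_vector(
            net,
            in_deg,
            dataset.tumor_expr[s].to_numpy(),
            normal_mean,
            dataset.mutations.get(s, set()),
            penalty=penalty,
            feature_mode=feature_mode,
            network_mode=network_mode,
            initial_score_mode=initial_score_mode,
            rng=rng,
        )
    return pd.DataFrame.from_dict(rows, orient="index", columns=dataset.genes)


def write_feature_matrix(features: pd.DataFrame, path) -> None:
    """Write the samples x genes win-rate matrix as TSV (gene header row)."""
    features.to_csv(path, sep="\t", index_label="sample")
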