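"""Per-patient weighted gene networks W = A (x) Phi.

For one tumor sample the shared oriented network is reweighted in three steps:

1. R_g = |Trank_g - Nrank_g|, the absolute difference between the gene's
   expression rank within the tumor sample and the rank of its mean expression
   across the normal group (higher expression = higher rank, midranks on ties).
2. Phi_ij = (R_i + R_j) * min(R_i, R_j) on every oriented edge: an edge whose
   two endpoints are both strongly dysregulated outweighs one carried by a
   single gene, even at equal rank-difference sum.
3. A_ij = 2 if either endpoint carries a somatic mutation in this patient,
   1 otherwise (0 off-network), and W = A * Phi elementwise.

W is column-normalized before propagation so each source gene distributes unit
influence over its outgoing edges; together with per-gene damping < 1 this
makes the propagation fixed point well defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Set

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata

from driverprog.network_io import GeneNetwork


@dataclass
class RankDiff:
    """Tumor-vs-normal rank displacement per gene."""

    R: np.ndarray
    Trank: np.ndarray
    Nrank: np.ndarray


@dataclass
class PatientNetwork:
    """One patient's matrices: mutation-aware adjacency A (values {0,1,2}),
    rank-difference edge weights Phi, W = A*Phi, and the column-normalized
    propagation operator W_norm."""

    A: sp.csr_matrix
    Phi: sp.csr_matrix
    W: sp.csr_matrix
    W_norm: sp.csr_matrix


def compute_rank_diff(tumor_col: np.ndarray, normal_mean: np.ndarray) -> RankDiff:
    """Rank the tumor column and the mean-normal vector ascending (largest
    expression -> rank n) and take the absolute rank difference. Ties receive
    average (mid) ranks, which may be fractional."""
    tumor_col = np.asarray(tumor_col, dtype=float)
    normal_mean = np.asarray(normal_mean, dtype=float)
    if tumor_col.shape != normal_mean.shape:
        raise ValueError(
            f"length mismatch: tumor {tumor_col.shape} vs normal mean {normal_mean.shape}"
        )
    if tumor_col.size < 2:
        raise ValueError("need at least 2 genes to rank")
    trank = rankdata(tumor_col, method="average")
    nrank = rankdata(normal_mean, method="average")
    return RankDiff(R=np.abs(trank - nrank), Trank=trank, Nrank=nrank)


def compute_phi(R: np.ndarray, network: GeneNetwork) -> sp.csr_matrix:
    """Phi_ij = (R_i + R_j) * min(R_i, R_j) on the network's oriented edges.

    The formula is symmetric in the two endpoints, so reciprocal edges carry
    the same weight.
    """
    R = np.asarray(R, dtype=float)
    rows, cols = network.edge_arrays()
    data = (R[rows] + R[cols]) * np.minimum(R[rows], R[cols])
    n = network.n_genes
    return sp.csr_matrix((data, (rows, cols)), shape=(n, n))


def build_A(network: GeneNetwork, mutated: Set[str]) -> sp.csr_matrix:
    """Mutation-aware adjacency: 2 on edges touching a mutated gene, 1 on
    other edges, 0 elsewhere. Mutated genes outside the network universe are
    ignored."""
    mask = np.zeros(network.n_genes, dtype=bool)
    for g in mutated:
        i = network.index.get(g)
        if i is not None:
            mask[i] = True
    rows, cols = network.edge_arrays()
    data = np.where(mask[rows] | mask[cols], 2.0, 1.0)
    n = network.n_genes
    return sp.csr_matrix((data, (rows, cols)), shape=(n, n))


def build_W(A: sp.spmatrix, Phi: sp.spmatrix) -> sp.csr_matrix:
    """Elementwise product W = A * Phi."""
    if A.shape != Phi.shape:
        raise ValueError(f"shape mismatch: A {A.shape} vs Phi {Phi.shape}")
    W = A.multiply(Phi).tocsr()
    W.eliminate_zeros()  # edges with R=0 at an endpoint carry no weight
    return W


def normalize_W(W: sp.spmatrix) -> sp.csr_matrix:
    """Column-normalize W: every nonzero column sums to 1, zero columns stay
    zero. Each source gene then distributes unit influence over its out-edges,
    and diag(d) @ W_norm has spectral radius < 1 for damping d < 1."""
    W = W.tocsc(copy=True)
    col_sums = np.asarray(W.sum(axis=0)).ravel()
    scale = np.ones_like(col_sums)
    nz = col_sums != 0
    scale[nz] = 1.0 / col_sums[nz]
    W = W @ sp.diags(scale)
    return W.tocsr()


def build_patient_network(
    network: GeneNetwork,
    tumor_col: np.ndarray,
    normal_mean: np.ndarray,
    mutated: Set[str],
) -> PatientNetwork:
    """Assemble A, Phi, W and the normalized propagation operator for one
    tumor sample. Expression vectors are aligned to ``network.genes``."""
    rank_diff = compute_rank_diff(tumor_col, normal_mean)
    Phi = compute_phi(rank_diff.R, network)
    A = build_A(network, mutated)
    W = build_W(A, Phi)
    return PatientNetwork(A=A, Phi=Phi, W=W, W_norm=normalize_W(W))


def iter_patient_networks(
    network: GeneNetwork,
    tumor_expr: pd.DataFrame,
    normal_expr: pd.DataFrame,
    mutations: dict[str, Set[str]],
    samples: Iterable[str] | None = None,
) -> Iterator[tuple[str, PatientNetwork]]:
    """Yield (sample, PatientNetwork) for each tumor column, aligned to the
    network's gene order."""
    genes = network.genes
    normal_mean = normal_expr.loc[genes].mean(axis=1).to_numpy()
    cols = list(tumor_expr.columns) if samples is None else list(samples)
    for s in cols:
        tumor_col = tumor_expr.loc[genes, s].to_numpy()
        yield s, build_patient_network(network, tumor_col, normal_mean, mutations.get(s, set()))


def write_patient_network(pn: PatientNetwork, genes: list[str], path) -> None:
    """Debug writer: one row (source, target, A, Phi, W) per oriented edge."""
    coo = pn.W.tocoo()
    with open(path, "w") as fh:
        fh.write("source\ttarget\tA\tPhi\tW\n")
        for i, j in zip(coo.row, coo.col):
            fh.write(
                f"{genes[j]}\t{genes[i]}\t{pn.A[i, j]:g}\t{pn.Phi[i, j]:g}\t{pn.W[i, j]:g}\n"
            )
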