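"""Prognostic gene lists from repeated experiments, and their connectivity.

A gene counts toward the prognostic list when its final score — by default
the mean win rate across a repeat's training samples — ranks in the top k
(default 30) of that repeat; genes reaching the top k in at least
``min_count`` of the repeats (default 3 of 10) are selected. The induced
subnetwork of the selected genes is summarized by its average per-gene edge
density over the patient-specific networks, against the whole-network
baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from driverprog.patient_network import PatientNetwork


@dataclass
class GeneFrequencyTable:
    counts: pd.Series  # per-gene number of repeats with a top-k rank
    k: int
    min_count: int
    n_repeats: int

    @property
    def selected_genes(self) -> list[str]:
        return list(self.counts.index[self.counts.values >= self.min_count])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.counts.index,
                "count": self.counts.values,
                "selected": self.counts.values >= self.min_count,
            }
        )


def final_scores(V_train: pd.DataFrame, labels: np.ndarray | None = None, mode: str = "mean_v") -> pd.Series:
    """Per-gene final score of one repeat from its training-sample win rates.

    ``mean_v`` averages over all training samples; ``mean_v_diff`` takes the
    bad-group mean minus the good-group mean (requires labels, 1 = bad).
    """
    if mode == "mean_v":
        return V_train.mean(axis=0)
    if mode == "mean_v_diff":
        if labels is None:
            raise ValueError("mean_v_diff needs labels")
        labels = np.asarray(labels).ravel()
        return V_train[labels == 1].mean(axis=0) - V_train[labels == 0].mean(axis=0)
    raise ValueError(f"unknown final-score mode {mode!r}")


def rank_frequency(
    scores_per_repeat: Sequence[pd.Series],
    k: int = 30,
    min_count: int = 3,
) -> GeneFrequencyTable:
    """Count, per gene, the repeats in which it ranked in the top k."""
    if not scores_per_repeat:
        raise ValueError("no repeats given")
    genes = scores_per_repeat[0].index
    counts = pd.Series(0, index=genes, dtype=int)
    for scores in scores_per_repeat:
        top = scores.nlargest(k).index
        counts.loc[top] += 1
    return GeneFrequencyTable(counts=counts, k=k, min_count=min_count, n_repeats=len(scores_per_repeat))


def edge_density(
    gene_subset: Sequence[str],
    patient_networks: Iterable[tuple[str, PatientNetwork]],
    genes: Sequence[str],
) -> tuple[float, float]:
    """Average per-gene edge count of the induced subgraph vs the whole net.

    For each patient network, the subset statistic is the number of nonzero W
    entries with both endpoints in ``gene_subset`` divided by the subset size;
    the baseline is total nonzero W entries divided by the total gene count.
    Both are averaged over patients. Returns (subset_density, baseline).
    """
    gene_subset = list(gene_subset)
    if len(gene_subset) < 2:
        raise ValueError("gene subset must contain at least 2 genes")
    index = {g: i for i, g in enumerate(genes)}
    try:
        sub_idx = np.array([index[g] for g in gene_subset])
    except KeyError as e:
        raise ValueError(f"subset gene {e} not in gene universe") from None
    sub_densities, base_densities = [], []
    for _sample, pn in patient_networks:
        W = pn.W
        sub = W[sub_idx][:, sub_idx]
        sub_densities.append(sub.nnz / len(sub_idx))
        base_densities.append(W.nnz / len(genes))
    if not sub_densities:
        raise ValueError("no patient networks given")
    return float(np.mean(sub_densities)), float(np.mean(base_densities))
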