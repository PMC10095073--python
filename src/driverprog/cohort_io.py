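"""Loading and filtering expression, mutation and clinical data into a cohort.

Conventions for the TSV inputs:

* expression: genes as rows, samples as columns, first column the gene symbol.
  Samples listed in the clinical table are tumor samples; all other expression
  columns are treated as the normal reference group.
* clinical: columns ``sample``, ``vital_status`` (dead/alive), ``survival_years``.
* mutations: columns ``sample``, ``gene``; any appearance marks the gene as
  somatically mutated in that sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GOOD = "good"
BAD = "bad"


@dataclass
class CohortDataset:
    """Aligned expression, mutations and prognosis labels for one cancer type.

    ``tumor_expr`` and ``normal_expr`` are gene x sample DataFrames over the
    same gene index; ``labels`` maps every tumor column to "good" or "bad".
    """

    genes: list[str]
    tumor_expr: pd.DataFrame
    normal_expr: pd.DataFrame
    mutations: dict[str, set[str]]
    labels: dict[str, str]
    criterion_years: float

    def __post_init__(self) -> None:
        if list(self.tumor_expr.index) != list(self.genes):
            raise ValueError("tumor_expr index does not match gene list")
        if list(self.normal_expr.index) != list(self.genes):
            raise ValueError("normal_expr index does not match gene list")
        missing = set(self.labels) - set(self.tumor_expr.columns)
        if missing:
            raise ValueError(f"labelled samples without expression column: {sorted(missing)}")
        if set(self.labels.values()) - {GOOD, BAD}:
            raise ValueError("labels must be 'good' or 'bad'")

    @property
    def samples(self) -> list[str]:
        """Labelled tumor samples, in expression-column order."""
        return [s for s in self.tumor_expr.columns if s in self.labels]

    def label_array(self, samples: list[str] | None = None) -> np.ndarray:
        """Binary labels (1 = bad prognosis) for the given samples."""
        samples = self.samples if samples is None else samples
        return np.array([1 if self.labels[s] == BAD else 0 for s in samples])


def filter_low_expression(
    expr: pd.DataFrame, zero_fraction: float = 0.8
) -> tuple[pd.DataFrame, list[str]]:
    """Drop genes whose expression is zero in more than ``zero_fraction`` of samples.

    A gene is kept iff its fraction of exactly-zero values is <= zero_fraction
    (a gene at the boundary is kept: the rule removes only "more than"). Gene
    order is preserved. Raises if nothing survives.
    """
    if not 0 < zero_fraction <= 1:
        raise ValueError("zero_fraction must be in (0, 1]")
    frac_zero = (expr.values == 0).mean(axis=1)
    keep = frac_zero <= zero_fraction
    if not keep.any():
        raise ValueError("all genes removed by the zero-expression filter")
    kept = expr.loc[keep]
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("zero-expression filter removed %d of %d genes", n_dropped, len(expr))
    return kept, list(kept.index)


def assign_labels(
    vital_status: Mapping[str, str],
    survival_years: Mapping[str, float],
    criterion_years: float,
    censored_policy: str = "exclude",
) -> dict[str, str]:
    """Binary prognosis labels from survival data.

    A patient who died before the criterion year is labelled bad; one who died
    at/after it, or who is alive with follow-up reaching it, is labelled good.
    Patients alive but censored before the criterion are excluded by default
    (``censored_policy="good"`` keeps the literal "good if not died" reading).
    """
    if criterion_years <= 0:
        raise ValueError("criterion_years must be positive")
    if censored_policy not in ("exclude", "good"):
        raise ValueError("censored_policy must be 'exclude' or 'good'")
    labels: dict[str, str] = {}
    n_excluded = 0
    for sample, status in vital_status.items():
        status = status.strip().lower()
        if status not in ("dead", "alive"):
            raise ValueError(f"{sample}: vital status must be dead/alive, got {status!r}")
        t = float(survival_years[sample])
        if t < 0:
            raise ValueError(f"{sample}: negative survival time {t}")
        if status == "dead":
            labels[sample] = BAD if t < criterion_years else GOOD
        elif t >= criterion_years or censored_policy == "good":
            labels[sample] = GOOD
        else:
            n_excluded += 1
    if n_excluded:
        logger.info("excluded %d sample(s) censored before the criterion year", n_excluded)
    return labels


def load_expression(path: str | Path) -> pd.DataFrame:
    """Gene x sample expression TSV (first column gene symbol)."""
    expr = pd.read_csv(path, sep="\t", index_col=0)
    if expr.index.has_duplicates:
        raise ValueError(f"{path}: duplicate gene symbols")
    return expr.astype(float)


def load_clinical(path: str | Path) -> pd.DataFrame:
    clin = pd.read_csv(path, sep="\t", dtype={"sample": str})
    required = {"sample", "vital_status", "survival_years"}
    if not required.issubset(clin.columns):
        raise ValueError(f"{path}: clinical TSV needs columns {sorted(required)}")
    return clin.set_index("sample")


def load_mutations(path: str | Path) -> dict[str, set[str]]:
    mut = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample", "gene"}.issubset(mut.columns):
        raise ValueError(f"{path}: mutation TSV needs columns ['sample', 'gene']")
    out: dict[str, set[str]] = {}
    for sample, gene in zip(mut["sample"], mut["gene"]):
        out.setdefault(sample, set()).add(gene)
    return out


def load_cohort(
    expression_path: str | Path,
    clinical_path: str | Path,
    mutations_path: str | Path,
    criterion_years: float,
    zero_fraction: float = 0.8,
    censored_policy: str = "exclude",
    filter_scope: str = "pooled",
) -> CohortDataset:
    """Assemble a :class:`CohortDataset` from the three standard TSVs.

    The zero-expression filter is applied to tumor and normal samples pooled
    (``filter_scope="tumor"`` restricts it to tumor columns). Tumor samples
    whose label is excluded (censored early) are dropped from the dataset.
    """
    expr = load_expression(expression_path)
    clin = load_clinical(clinical_path)
    mutations = load_mutations(mutations_path)

    tumor_samples = [s for s in expr.columns if s in clin.index]
    normal_samples = [s for s in expr.columns if s not in clin.index]
    if not tumor_samples:
        raise ValueError("no expression column matches a clinical sample")
    if not normal_samples:
        raise ValueError("no normal (non-clinical) expression columns found")

    if filter_scope == "pooled":
        _, genes = filter_low_expression(expr, zero_fraction)
    elif filter_scope == "tumor":
        _, genes = filter_low_expression(expr[tumor_samples], zero_fraction)
    else:
        raise ValueError("filter_scope must be 'pooled' or 'tumor'")

    labels = assign_labels(
        clin["vital_status"].to_dict(),
        clin["survival_years"].to_dict(),
        criterion_years,
        censored_policy=censored_policy,
    )
    labels = {s: l for s, l in labels.items() if s in tumor_samples}
    kept_tumor = [s for s in tumor_samples if s in labels]
    unknown = {g for genes_ in mutations.values() for g in genes_} - set(expr.index)
    if unknown:
        logger.info("%d mutated gene symbol(s) absent from expression; ignored", len(unknown))
    mutations = {
        s: {g for g in gset if g in set(genes)} for s, gset in mutations.items() if s in kept_tumor
    }
    return CohortDataset(
        genes=genes,
        tumor_expr=expr.loc[genes, kept_tumor],
        normal_expr=expr.loc[genes, normal_samples],
        mutations={s: mutations.get(s, set()) for s in kept_tumor},
        labels={s: labels[s] for s in kept_tumor},
        criterion_years=criterion_years,
    )
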