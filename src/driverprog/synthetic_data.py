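"""Self-contained synthetic cohorts with planted prognostic structure.

The generator emulates the data shape the pipeline consumes in production —
a sparse directed gene network, tumor/normal expression, per-sample somatic
mutation sets and survival-derived prognosis labels — with a known ground
truth planted in it:

* a set of "planted" driver genes forming a densified module in the network;
* tumor samples shift the planted genes' expression away from the normal
  baseline (rank displacement), and bad-prognosis tumors shift them further
  by ``group_effect`` standard deviations (in log space);
* mutations hit planted genes ``driver_mutation_boost`` times more often
  than the Bernoulli background rate.

Expression baselines are log-normal with a small-value floor, so a few genes
legitimately fail the 80%-zeros filter; matrices are emitted on the
log2(x + 1) scale conventionally used for expression data fed to machine
learning pipelines. Generation is a pure function of the spec: the same spec
always yields the identical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from driverprog.cohort_io import BAD, GOOD, CohortDataset
from driverprog.network_io import EdgeList, GeneNetwork, integrate_and_orient


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground-truth parameters of one synthetic cohort.

    ``rank_shift`` and ``group_effect`` are expressed in units of the
    per-gene log-scale standard deviation; ``mutation_rate`` is the
    per-gene per-sample background probability, multiplied by
    ``driver_mutation_boost`` (capped at 1) on planted genes.
    """

    n_genes: int = 300
    n_edges: int = 1500
    n_tumor_good: int = 60
    n_tumor_bad: int = 60
    n_normal: int = 20
    n_censored: int = 0
    n_planted_genes: int = 20
    rank_shift: float = 0.25
    group_effect: float = 3.0
    mutation_rate: float = 0.02
    driver_mutation_boost: float = 10.0
    criterion_years: float = 2.0
    log_sd: float = 0.5
    sample_scale_sd: float = 0.4
    module_edge_fraction: float = 0.15
    seed: int = 42

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_tumor_good, self.n_tumor_bad, self.n_normal) < 1:
            raise ValueError("all sample/gene counts must be positive")
        if self.n_planted_genes > self.n_genes:
            raise ValueError("more planted genes than genes")
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.n_edges > self.n_genes * (self.n_genes - 1):
            raise ValueError("n_edges exceeds the number of possible directed edges")

    @property
    def genes(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i + 1:0{width}d}" for i in range(self.n_genes)]

    @property
    def planted_genes(self) -> list[str]:
        return self.genes[: self.n_planted_genes]


def demo_spec(**overrides) -> SyntheticSpec:
    """The fixed quick-start cohort: 300 genes / 1500 edges, 60 good + 60 bad
    tumors, 20 normals, 20 planted drivers with a 3-SD prognosis effect.

    The tumor count mirrors the median scale of the TCGA cohorts this kind of
    protocol is run on; the batch-2, 200-epoch classifier needs training
    halves of that order to generalize.
    """
    return replace(SyntheticSpec(), **overrides)


def generate_edge_list(spec: SyntheticSpec) -> EdgeList:
    """Random directed edges with a densified module on the planted genes.

    About 15% of the edge budget is spent inside the planted module so its
    internal per-gene density exceeds the global one; roughly half of the
    background edges are marked undirected, mimicking a functional-interaction
    component next to directed regulatory edges.
    """
    rng = np.random.default_rng([spec.seed, 0])
    genes = spec.genes
    n = spec.n_genes
    k = spec.n_planted_genes
    module_pairs = k * (k - 1)
    n_module = min(module_pairs, int(spec.module_edge_fraction * spec.n_edges)) if k >= 2 else 0

    chosen: set[tuple[int, int]] = set()
    if n_module:
        flat = rng.choice(module_pairs, size=n_module, replace=False)
        for x in flat:
            i, j = divmod(int(x), k - 1)
            j = j + 1 if j >= i else j
            chosen.add((i, j))
    while len(chosen) < spec.n_edges:
        need = spec.n_edges - len(chosen)
        src = rng.integers(0, n, size=2 * need + 10)
        tgt = rng.integers(0, n, size=2 * need + 10)
        for i, j in zip(src, tgt):
            if i != j:
                chosen.add((int(i), int(j)))
            if len(chosen) == spec.n_edges:
                break
    directed_flags = rng.random(len(chosen)) < 0.5
    edges = [
        (genes[i], genes[j], bool(flag))
        for (i, j), flag in zip(sorted(chosen), directed_flags)
    ]
    return EdgeList(edges=edges, source_name="synthetic")


def generate_network(spec: SyntheticSpec) -> GeneNetwork:
    """Oriented synthetic network over the full gene universe.

    Isolated genes (when ``n_edges`` is small) are appended so the network's
    gene list always covers the spec's universe.
    """
    if spec.n_edges == 0:
        import scipy.sparse as sp

        n = spec.n_genes
        return GeneNetwork(genes=spec.genes, adjacency=sp.csr_matrix((n, n), dtype=np.int8))
    net = integrate_and_orient([generate_edge_list(spec)])
    return net.restrict_to(spec.genes)


def generate_cohort(spec: SyntheticSpec, network: GeneNetwork | None = None) -> CohortDataset:
    """Expression, mutations and labels with the spec's planted structure.

    Per-gene log-scale baselines are drawn once; normal samples are log-normal
    around them; all tumors displace planted genes by ``rank_shift`` log-SD
    and bad tumors by a further ``group_effect`` log-SD. Values below 1 are
    floored to 0, so low-baseline genes produce the zeros that exercise the
    expression filter. Planted baselines are kept moderately expressed (an
    unexpressed driver would be invisible to every downstream step).
    """
    rng = np.random.default_rng([spec.seed, 1])
    genes = spec.genes
    n = spec.n_genes
    planted = np.zeros(n, dtype=bool)
    planted[: spec.n_planted_genes] = True

    mu = rng.normal(3.0, 1.5, size=n)  # log-scale baseline per gene
    mu[planted] = np.maximum(mu[planted], 1.5)
    sd = spec.log_sd

    def draw(n_samples: int, shift: np.ndarray) -> np.ndarray:
        log_expr = rng.normal(mu[:, None] + shift[:, None], sd, size=(n, n_samples))
        expr = np.exp(log_expr)
        expr[expr < 1.0] = 0.0
        # emit on the log2(x+1) scale conventionally used for expression
        # matrices fed to ML pipelines; zeros stay zero, ranks are unchanged
        out = np.log2(expr + 1.0)
        # per-sample technical scale offsets (library size / purity effects):
        # within-sample ranks are untouched, cross-sample magnitudes are not
        offsets = rng.normal(0.0, spec.sample_scale_sd, size=n_samples)
        out[out > 0] += np.broadcast_to(offsets, out.shape)[out > 0]
        return np.maximum(out, 0.0)

    zero_shift = np.zeros(n)
    tumor_shift = np.where(planted, spec.rank_shift * sd, 0.0)
    bad_shift = np.where(planted, (spec.rank_shift + spec.group_effect) * sd, 0.0)

    normal = draw(spec.n_normal, zero_shift)
    good = draw(spec.n_tumor_good, tumor_shift)
    bad = draw(spec.n_tumor_bad, bad_shift)

    good_names = [f"TCGA-GOOD-{i + 1:03d}" for i in range(spec.n_tumor_good)]
    bad_names = [f"TCGA-BAD-{i + 1:03d}" for i in range(spec.n_tumor_bad)]
    normal_names = [f"NORMAL-{i + 1:03d}" for i in range(spec.n_normal)]
    tumor_expr = pd.DataFrame(
        np.hstack([good, bad]), index=genes, columns=good_names + bad_names
    )
    normal_expr = pd.DataFrame(normal, index=genes, columns=normal_names)

    p_gene = np.where(
        planted, np.minimum(spec.mutation_rate * spec.driver_mutation_boost, 1.0), spec.mutation_rate
    )
    mutations: dict[str, set[str]] = {}
    for s in tumor_expr.columns:
        hit = rng.random(n) < p_gene
        mutations[s] = {g for g, h in zip(genes, hit) if h}

    labels = {s: GOOD for s in good_names}
    labels.update({s: BAD for s in bad_names})

    return CohortDataset(
        genes=genes,
        tumor_expr=tumor_expr,
        normal_expr=normal_expr,
        mutations=mutations,
        labels=labels,
        criterion_years=spec.criterion_years,
    )


def write_cohort_files(spec: SyntheticSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write the four standard TSVs (network, expression, clinical, mutations).

    Survival times are generated consistently with the labels: bad-prognosis
    patients die before the criterion year, good ones survive past it, and
    ``n_censored`` extra tumor samples are alive with short follow-up (these
    are excluded by the labelling rule on load).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([spec.seed, 2])

    edge_list = generate_edge_list(spec) if spec.n_edges else EdgeList(edges=[])
    network_path = out_dir / "network.tsv"
    with open(network_path, "w") as fh:
        for s, t, directed in edge_list.edges:
            fh.write(f"{s}\t{t}\t{'directed' if directed else 'undirected'}\n")

    dataset = generate_cohort(spec)
    cens_names = [f"TCGA-CENS-{i + 1:03d}" for i in range(spec.n_censored)]
    expr = pd.concat([dataset.tumor_expr, dataset.normal_expr], axis=1)
    if spec.n_censored:
        expr = pd.concat([dataset.tumor_expr, _censored_expression(spec), dataset.normal_expr], axis=1)
    expr_path = out_dir / "expression.tsv"
    expr.to_csv(expr_path, sep="\t", index_label="gene", float_format="%.4f")

    clinical_rows = []
    crit = spec.criterion_years
    for s, lab in dataset.labels.items():
        if lab == BAD:
            clinical_rows.append((s, "dead", round(float(rng.uniform(0.05, crit * 0.95)), 3)))
        else:
            if rng.random() < 0.5:
                clinical_rows.append((s, "alive", round(float(rng.uniform(crit, crit * 3)), 3)))
            else:
                clinical_rows.append((s, "dead", round(float(rng.uniform(crit, crit * 3)), 3)))
    for s in cens_names:
        clinical_rows.append((s, "alive", round(float(rng.uniform(0.0, crit * 0.9)), 3)))
    clinical_path = out_dir / "clinical.tsv"
    pd.DataFrame(clinical_rows, columns=["sample", "vital_status", "survival_years"]).to_csv(
        clinical_path, sep="\t", index=False
    )

    mutations_path = out_dir / "mutations.tsv"
    with open(mutations_path, "w") as fh:
        fh.write("sample\tgene\n")
        for s in dataset.tumor_expr.columns:
            for g in sorted(dataset.mutations.get(s, set())):
                fh.write(f"{s}\t{g}\n")
        if spec.n_censored:
            mut_rng = np.random.default_rng([spec.seed, 4])
            n = spec.n_genes
            planted = np.zeros(n, dtype=bool)
            planted[: spec.n_planted_genes] = True
            p_gene = np.where(
                planted,
                np.minimum(spec.mutation_rate * spec.driver_mutation_boost, 1.0),
                spec.mutation_rate,
            )
            for s in cens_names:
                hit = mut_rng.random(n) < p_gene
                for g, h in zip(spec.genes, hit):
                    if h:
                        fh.write(f"{s}\t{g}\n")

    return {
        "network": network_path,
        "expression": expr_path,
        "clinical": clinical_path,
        "mutations": mutations_path,
    }


def _censored_expression(spec: SyntheticSpec) -> pd.DataFrame:
    """Expression columns for the censored (excluded-on-load) tumor samples."""
    rng = np.random.default_rng([spec.seed, 5])
    n = spec.n_genes
    planted = np.zeros(n, dtype=bool)
    planted[: spec.n_planted_genes] = True
    mu = np.random.default_rng([spec.seed, 1]).normal(3.0, 1.5, size=n)
    mu[planted] = np.maximum(mu[planted], 1.5)
    shift = np.where(planted, spec.rank_shift * spec.log_sd, 0.0)
    log_expr = rng.normal(mu[:, None] + shift[:, None], spec.log_sd, size=(n, spec.n_censored))
    expr = np.exp(log_expr)
    expr[expr < 1.0] = 0.0
    out = np.log2(expr + 1.0)
    offsets = rng.normal(0.0, spec.sample_scale_sd, size=spec.n_censored)
    out[out > 0] += np.broadcast_to(offsets, out.shape)[out > 0]
    out = np.maximum(out, 0.0)
    cens_names = [f"TCGA-CENS-{i + 1:03d}" for i in range(spec.n_censored)]
    return pd.DataFrame(out, index=spec.genes, columns=cens_names)
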