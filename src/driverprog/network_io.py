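"""Reading, integrating and orienting the gene networks shared by all patients.

The propagation substrate is a single directed network obtained by merging one
or more edge lists (typically an undirected functional-interaction network plus
directed regulatory networks). Because impact scores should flow from a
dysregulated target back to the regulators that can explain it, every directed
input edge u->v is stored reversed (v->u), the DawnRank convention; undirected
edges contribute both orientations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

_TRUE = {"1", "true", "t", "yes", "directed", "d"}
_FALSE = {"0", "false", "f", "no", "undirected", "u"}


@dataclass
class EdgeList:
    """Raw edges from one resource: (source, target, directed) triples."""

    edges: list[tuple[str, str, bool]]
    source_name: str = ""

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class GeneNetwork:
    """Oriented integrated network.

    ``adjacency[i, j]`` is nonzero iff the oriented edge j -> i exists, so a
    column holds one source gene's outgoing edges and a row one target gene's
    incoming edges. ``genes`` fixes the matrix index.
    """

    genes: list[str]
    adjacency: sp.csr_matrix
    index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.index:
            self.index = {g: i for i, g in enumerate(self.genes)}
        if len(self.index) != len(self.genes):
            raise ValueError("gene list contains duplicates")
        if self.adjacency.shape != (len(self.genes), len(self.genes)):
            raise ValueError("adjacency shape does not match gene list")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz)

    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(targets, sources) index arrays of the oriented edges."""
        coo = self.adjacency.tocoo()
        return coo.row, coo.col

    def has_edge(self, source: str, target: str) -> bool:
        return self.adjacency[self.index[target], self.index[source]] != 0

    def restrict_to(self, genes: Sequence[str]) -> "GeneNetwork":
        """Induced subnetwork on ``genes`` (in the given order).

        Genes absent from this network are kept as isolated nodes so that the
        cohort's gene universe stays consistent: isolated genes simply retain
        their initial score under propagation (damping 0).
        """
        genes = list(genes)
        rows, cols = self.edge_arrays()
        pos = {g: k for k, g in enumerate(genes)}
        new_rows, new_cols = [], []
        for r, c in zip(rows, cols):
            tg, sg = self.genes[r], self.genes[c]
            if tg in pos and sg in pos:
                new_rows.append(pos[tg])
                new_cols.append(pos[sg])
        n = len(genes)
        adj = sp.csr_matrix(
            (np.ones(len(new_rows), dtype=np.int8), (new_rows, new_cols)), shape=(n, n)
        )
        return GeneNetwork(genes=genes, adjacency=adj)


def read_edge_list(
    path: str | Path,
    directed_default: bool = True,
    header: bool = False,
) -> EdgeList:
    """Read a TSV edge list (source, target[, directed]).

    The optional third column overrides ``directed_default`` per edge; exact
    duplicate (source, target, directed) triples are dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"edge list not found: {path}")
    edges: list[tuple[str, str, bool]] = []
    seen: set[tuple[str, str, bool]] = set()
    n_read = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if header and lineno == 1:
                continue
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) not in (2, 3):
                raise ValueError(
                    f"{path}:{lineno}: expected 2-3 tab-separated columns, got {len(parts)}"
                )
            source, target = parts[0].strip(), parts[1].strip()
            if not source or not target:
                raise ValueError(f"{path}:{lineno}: empty gene symbol")
            directed = directed_default
            if len(parts) == 3:
                flag = parts[2].strip().lower()
                if flag in _TRUE:
                    directed = True
                elif flag in _FALSE:
                    directed = False
                else:
                    raise ValueError(f"{path}:{lineno}: unrecognised directedness flag {parts[2]!r}")
            n_read += 1
            triple = (source, target, directed)
            if triple not in seen:
                seen.add(triple)
                edges.append(triple)
    logger.info(
        "read %d edges from %s (%d duplicates dropped)", len(edges), path, n_read - len(edges)
    )
    return EdgeList(edges=edges, source_name=path.name)


def integrate_and_orient(lists: Iterable[EdgeList]) -> GeneNetwork:
    """Union the input edge lists into one oriented network.

    Directed edges u->v are stored reversed (v->u); undirected edges {u, v}
    contribute both orientations. Duplicate oriented edges collapse; self-loops
    are dropped with a warning (they would inflate a gene's own damping and
    feed its score back to itself).
    """
    lists = list(lists)
    genes: dict[str, None] = {}  # insertion-ordered set
    oriented: set[tuple[str, str]] = set()
    n_self = 0
    for el in lists:
        for source, target, directed in el.edges:
            genes.setdefault(source)
            genes.setdefault(target)
            if source == target:
                n_self += 1
                continue
            if directed:
                oriented.add((target, source))  # reversed
            else:
                oriented.add((source, target))
                oriented.add((target, source))
    if not genes:
        raise ValueError("empty network: no edges in any input list")
    if n_self:
        logger.warning("dropped %d self-loop edge(s)", n_self)
    gene_list = list(genes)
    index = {g: i for i, g in enumerate(gene_list)}
    n = len(gene_list)
    rows = np.fromiter((index[t] for _, t in oriented), dtype=np.int64, count=len(oriented))
    cols = np.fromiter((index[s] for s, _ in oriented), dtype=np.int64, count=len(oriented))
    adj = sp.csr_matrix((np.ones(len(oriented), dtype=np.int8), (rows, cols)), shape=(n, n))
    adj.data[:] = 1  # collapse any accidental duplicates
    return GeneNetwork(genes=gene_list, adjacency=adj, index=index)


def incoming_degree(network: GeneNetwork) -> np.ndarray:
    """Number of oriented edges x -> g for each gene g (row sums)."""
    return np.asarray(network.adjacency.sum(axis=1)).ravel().astype(np.int64)


def write_edge_list(network: GeneNetwork, path: str | Path) -> None:
    """Write the oriented network as a (source, target) TSV for inspection."""
    rows, cols = network.edge_arrays()
    with open(path, "w") as fh:
        fh.write("source\ttarget\n")
        for r, c in zip(rows, cols):
            fh.write(f"{network.genes[c]}\t{network.genes[r]}\n")
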