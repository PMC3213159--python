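"""Permutation test for interaction enrichment within a called gene set.

Counts genetic/physical interaction edges internal to a gene set and
compares the count to same-size gene sets drawn uniformly from a sampling
frame, giving an empirical p-value.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd


class InteractionGraph:
    """Undirected gene-gene graph with genetic/physical edge labels.

    Self-loops are ignored on input; duplicate (pair, label) records
    collapse to one. An edge may carry several labels.
    """

    def __init__(self) -> None:
        self._g = nx.Graph()

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str, str]]) -> "InteractionGraph":
        ig = cls()
        for a, b, label in edges:
            ig.add_edge(a, b, label)
        return ig

    @classmethod
    def from_tsv(cls, path, gene_a_col: str = "gene_a",
                 gene_b_col: str = "gene_b",
                 label_col: str = "label") -> "InteractionGraph":
        """Load a BioGRID-style tab export (gene_a, gene_b, label columns)."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls.from_edges(
            zip(df[gene_a_col], df[gene_b_col], df[label_col])
        )

    def add_edge(self, a: str, b: str, label: str) -> None:
        if a == b:
            return
        if self._g.has_edge(a, b):
            self._g.edges[a, b]["labels"].add(label)
        else:
            self._g.add_edge(a, b, labels={label})

    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes)

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def edges(self):
        for a, b, data in self._g.edges(data=True):
            yield a, b, frozenset(data["labels"])


def internal_edges(genes: set[str], graph: InteractionGraph,
                   label: str | None = None) -> int:
    """Number of graph edges with both endpoints in ``genes``.

    With a label filter each matching edge counts once; without one, an
    edge counts once per label it carries (genetic + physical connections
    are totalled separately).
    """
    genes = set(genes)
    total = 0
    for a, b, labels in graph.edges():
        if a in genes and b in genes:
            if label is None:
                total += len(labels)
            elif label in labels:
                total += 1
    return total


@dataclass
class PermutationResult:
    observed: int
    p_value: float
    n_perm: int
    n_at_least: int
    set_size: int


def permutation_enrichment(
    genes: set[str],
    graph: InteractionGraph,
    n_perm: int = 1000,
    seed: int | None = None,
    frame: set[str] | None = None,
    label: str | None = None,
    add_one: bool = True,
) -> PermutationResult:
    """Empirical p for the internal-edge count of a gene set.

    Draws ``n_perm`` uniform same-size gene sets from the sampling frame
    (default: graph nodes plus the query genes, so unannotated genes can be
    drawn) and counts draws with at least the observed number of internal
    edges. ``add_one`` applies the (r+1)/(n+1) estimator so p is never 0;
    disable it for the raw fraction.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    genes = set(genes)
    frame_set = sorted(frame if frame is not None else (graph.nodes | genes))
    size = len(genes)
    if size > len(frame_set):
        raise ValueError("gene set larger than the sampling frame")

    observed = internal_edges(genes, graph, label)

    # adjacency restricted to the frame for fast permutation counting
    index = {g: i for i, g in enumerate(frame_set)}
    edge_list = []
    for a, b, labels in graph.edges():
        if a in index and b in index:
            weight = len(labels) if label is None else (1 if label in labels else 0)
            if weight:
                edge_list.append((index[a], index[b], weight))

    rng = np.random.default_rng(seed)
    n_frame = len(frame_set)
    hits = 0
    member = np.zeros(n_frame, dtype=bool)
    for _ in range(n_perm):
        draw = rng.choice(n_frame, size=size, replace=False)
        member[:] = False
        member[draw] = True
        count = sum(w for i, j, w in edge_list if member[i] and member[j])
        if count >= observed:
            hits += 1
    if add_one:
        p = (hits + 1) / (n_perm + 1)
    else:
        p = hits / n_perm
    return PermutationResult(observed=observed, p_value=float(p),
                             n_perm=n_perm, n_at_least=hits, set_size=size)


def write_edges(graph: InteractionGraph, path) -> None:
    rows = [
        (a, b, label)
        for a, b, labels in graph.edges()
        for label in sorted(labels)
    ]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "label"]).to_csv(
        path, sep="\t", index=False
    )


__all__ = [
    "InteractionGraph",
    "internal_edges",
    "PermutationResult",
    "permutation_enrichment",
    "write_edges",
]
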