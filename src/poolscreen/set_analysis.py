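"""Gene-set accounting: Venn regions, hypergeometric enrichment,
expression-overlap tests, and hierarchical clustering of fitness profiles.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import hypergeom


@dataclass
class GeneSetCollection:
    """A gene universe and a flat map of category name -> gene set."""

    universe: set[str]
    categories: dict[str, set[str]]

    def __post_init__(self) -> None:
        for name, genes in self.categories.items():
            extra = genes - self.universe
            if extra:
                raise ValueError(
                    f"category {name!r} contains genes outside the universe: "
                    f"{sorted(extra)[:5]}"
                )


@dataclass(frozen=True)
class ExpressionCall:
    gene: str
    condition: str
    status: str  # induced | repressed | unchanged

    def __post_init__(self) -> None:
        if self.status not in ("induced", "repressed", "unchanged"):
            raise ValueError(f"unknown expression status {self.status!r}")


def call_expression(log2_ratios: Mapping[str, float], condition: str,
                    fold: float = 1.5) -> list[ExpressionCall]:
    """Classify genes as induced/repressed by the fold-change rule.

    A gene is induced (repressed) when its average expression change is more
    than ``fold`` times higher (lower) than unstressed cells.
    """
    cut = np.log2(fold)
    out = []
    for gene, lr in log2_ratios.items():
        if np.isnan(lr):
            status = "unchanged"
        elif lr > cut:
            status = "induced"
        elif lr < -cut:
            status = "repressed"
        else:
            status = "unchanged"
        out.append(ExpressionCall(gene, condition, status))
    return out


# -- Venn accounting -------------------------------------------------------

def overlap_table(callsets: Mapping[str, set[str]] | Iterable) -> dict:
    """Exclusive region counts for k sets (all 2^k - 1 regions) plus the union.

    ``callsets`` maps label -> gene set (CallSet objects are accepted too).
    Region keys are sorted tuples of member labels; the regions partition
    the union.
    """
    if not isinstance(callsets, Mapping):
        sets = {}
        for cs in callsets:
            label = getattr(cs, "pretreatment", None)
            if label is None:
                raise TypeError("pass a mapping of label -> set, or CallSets")
            if label in sets:
                raise ValueError(f"duplicate pretreatment label {label!r}")
            sets[label] = set(cs.called)
    else:
        sets = {k: set(v) for k, v in callsets.items()}
    labels = sorted(sets)
    union = set().union(*sets.values()) if sets else set()
    regions: dict[tuple[str, ...], int] = {}
    for gene in union:
        members = tuple(lab for lab in labels if gene in sets[lab])
        regions[members] = regions.get(members, 0) + 1
    # make every region explicit, including empty ones
    from itertools import combinations

    for k in range(1, len(labels) + 1):
        for combo in combinations(labels, k):
            regions.setdefault(combo, 0)
    return {"regions": regions, "union": len(union)}


# -- hypergeometric enrichment --------------------------------------------

def hypergeom_pvalue(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail P(X >= k) for drawing n from N with K marked."""
    return float(hypergeom.sf(k - 1, N, K, n))


def hypergeom_enrich(
    hits: set[str],
    collection: GeneSetCollection,
    alpha: float = 0.01,
    tail: str = "upper",
) -> pd.DataFrame:
    """Per-category hypergeometric enrichment with Bonferroni control.

    The Bonferroni factor is the number of categories in the collection
    (not just those with overlap). ``tail='lower'`` tests depletion.
    """
    offenders = set(hits) - collection.universe
    if offenders:
        raise ValueError(
            f"hits outside the universe: {sorted(offenders)}"
        )
    N = len(collection.universe)
    n = len(hits)
    m = len(collection.categories)
    rows = []
    for name, genes in sorted(collection.categories.items()):
        K = len(genes)
        k = len(hits & genes)
        if tail == "upper":
            p = hypergeom_pvalue(N, K, n, k)
        elif tail == "lower":
            p = float(hypergeom.cdf(k, N, K, n))
        else:
            raise ValueError(f"unknown tail {tail!r}")
        p_bonf = min(1.0, p * m)
        rows.append((name, N, K, n, k, p, p_bonf, p_bonf < alpha))
    return pd.DataFrame(
        rows,
        columns=["category", "N", "K", "n", "k", "p", "p_bonferroni",
                 "significant"],
    ).set_index("category")


def expression_overlap(
    hits: set[str],
    calls: Iterable[ExpressionCall],
    universe: set[str],
    condition: str | None = None,
    status: str = "induced",
) -> dict:
    """Fraction of hits with the given expression status, plus enrichment p.

    The status set acts as the category in a one-sided hypergeometric test
    against the universe.
    """
    if not hits:
        raise ValueError("hits must be non-empty")
    marked = {
        c.gene for c in calls
        if c.status == status and (condition is None or c.condition == condition)
    } & universe
    overlap = hits & marked
    p = hypergeom_pvalue(len(universe), len(marked), len(hits), len(overlap))
    return {
        "fraction": len(overlap) / len(hits),
        "n_overlap": len(overlap),
        "n_hits": len(hits),
        "n_marked": len(marked),
        "p": p,
    }


# -- clustering ------------------------------------------------------------

def uncentered_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Cosine-like similarity sum(xy)/sqrt(sum(x^2) sum(y^2)), no centering."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    denom = np.sqrt((x * x).sum() * (y * y).sum())
    if denom == 0:
        return float("nan")
    return float((x * y).sum() / denom)


def uncentered_distance_matrix(matrix: np.ndarray) -> np.ndarray:
    """Condensed distance vector 1 - r over rows."""
    norms = np.sqrt((matrix * matrix).sum(axis=1))
    unit = matrix / norms[:, None]
    sim = unit @ unit.T
    np.clip(sim, -1.0, 1.0, out=sim)
    dist = 1.0 - sim
    iu = np.triu_indices(len(matrix), k=1)
    return dist[iu]


@dataclass
class ClusterResult:
    linkage: np.ndarray
    leaf_order: list[str]
    dropped: list[str]


def cluster_profiles(matrix: pd.DataFrame, method: str = "average") -> ClusterResult:
    """Agglomerative clustering of fitness profiles.

    Distance is 1 minus the uncentered Pearson correlation; linkage defaults
    to average (the viewer-compatible convention). All-zero rows have no
    defined similarity and are dropped with a warning. Missing values are
    treated as zero contribution. Leaf order is deterministic given input
    order.
    """
    values = matrix.fillna(0.0).to_numpy(dtype=float)
    norms = np.sqrt((values * values).sum(axis=1))
    keep = norms > 0
    dropped = [str(i) for i in matrix.index[~keep]]
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} all-zero row(s) with undefined similarity",
            stacklevel=2,
        )
    sub = values[keep]
    if sub.shape[0] < 2:
        raise ValueError("need at least two non-degenerate rows to cluster")
    condensed = uncentered_distance_matrix(sub)
    Z = linkage(condensed, method=method)
    order = leaves_list(Z)
    kept_index = matrix.index[keep]
    return ClusterResult(
        linkage=Z,
        leaf_order=[str(kept_index[i]) for i in order],
        dropped=dropped,
    )


def write_clustered(matrix: pd.DataFrame, result: ClusterResult, cdt_path,
                    gtr_path) -> None:
    """Tree-viewer-style output: leaf-ordered table (CDT-like) + merge list
    (GTR-like)."""
    ordered = matrix.loc[result.leaf_order]
    out = ordered.copy()
    out.insert(0, "GID", [f"GENE{i}X" for i in range(len(ordered))])
    out.columns = [str(c) for c in out.columns]
    out.to_csv(cdt_path, sep="\t", index_label="NAME")
    rows = []
    n = len(result.leaf_order)
    for i, (a, b, dist, _count) in enumerate(result.linkage):
        rows.append((f"NODE{i + 1}X", _node_name(int(a), n), _node_name(int(b), n),
                     1.0 - dist))
    pd.DataFrame(rows, columns=["node", "left", "right", "similarity"]).to_csv(
        gtr_path, sep="\t", index=False
    )


def _node_name(i: int, n_leaves: int) -> str:
    return f"GENE{i}X" if i < n_leaves else f"NODE{i - n_leaves + 1}X"


# -- GMT / TSV IO ----------------------------------------------------------

def read_gmt(path) -> dict[str, set[str]]:
    cats = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            cats[parts[0]] = set(g for g in parts[2:] if g)
    return cats


def write_gmt(categories: Mapping[str, set[str]], path,
              description: str = "") -> None:
    with open(path, "w") as fh:
        for name in sorted(categories):
            genes = "\t".join(sorted(categories[name]))
            fh.write(f"{name}\t{description}\t{genes}\n")


def read_expression_calls(path) -> list[ExpressionCall]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        ExpressionCall(r["gene"], r["condition"], r["status"])
        for _, r in df.iterrows()
    ]


__all__ = [
    "GeneSetCollection",
    "ExpressionCall",
    "call_expression",
    "overlap_table",
    "hypergeom_pvalue",
    "hypergeom_enrich",
    "expression_overlap",
    "uncentered_pearson",
    "uncentered_distance_matrix",
    "ClusterResult",
    "cluster_profiles",
    "write_clustered",
    "read_gmt",
    "write_gmt",
    "read_expression_calls",
]
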