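"""File I/O, count-matrix ingestion, and co-occurrence network extraction.

A sequencing read count matrix (genes x samples) is a contingency table over
two factor variables; it enters the estimator as weighted observations, one
per nonzero entry, with the count as the weight.  The committed partition
tree also supports a qualitative readout: category labels that share a
terminal region with at least one sample are "bound together" there, and
counting such co-memberships across terminal regions yields a co-occurrence
network (for diagnosis data, a disease network).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .space import FactorSpace, ObservationSet
from .tree import OPTTree

__all__ = [
    "CooccurrenceEdge",
    "read_observations",
    "read_count_matrix",
    "write_count_matrix",
    "subsample_counts",
    "cooccurrence_network",
    "cooccurrence_graph",
]


@dataclass(frozen=True)
class CooccurrenceEdge:
    """An unordered label pair with the number of terminal regions sharing it."""

    code_a: str
    code_b: str
    weight: float

    def __post_init__(self) -> None:
        if self.code_a == self.code_b:
            raise ValueError("self-loops are not meaningful here")
        if self.code_a > self.code_b:
            object.__setattr__(self, "code_a", self.code_b)
            object.__setattr__(self, "code_b", self.code_a)


def read_observations(
    path, sep: str | None = None, count_column: str = "count"
) -> pd.DataFrame:
    """Read a delimited observation table (header = variable names)."""
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep, dtype=str).rename(
        columns=lambda c: str(c)
    )


def read_count_matrix(
    path,
    fmt: str | None = None,
    variable_names: tuple[str, str] = ("row", "column"),
) -> tuple[FactorSpace, ObservationSet]:
    """Load a count matrix as a two-variable weighted observation set.

    ``fmt="mtx"`` reads MatrixMarket coordinate files (categories become
    ``r0001``-style positional labels); ``fmt="tsv"`` reads a labeled TSV
    matrix whose first column holds row labels and whose header holds column
    labels.  Total observation weight equals the matrix sum.
    """
    if fmt is None:
        fmt = "mtx" if str(path).endswith(".mtx") else "tsv"
    if fmt == "mtx":
        mat = scipy.sparse.coo_matrix(scipy.io.mmread(path))
        n_rows, n_cols = mat.shape
        row_labels = [f"r{i + 1:04d}" for i in range(n_rows)]
        col_labels = [f"c{j + 1:04d}" for j in range(n_cols)]
        rows, cols, counts = mat.row, mat.col, mat.data
    elif fmt == "tsv":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        row_labels = [str(x) for x in frame.index]
        col_labels = [str(x) for x in frame.columns]
        dense = frame.to_numpy(dtype=np.float64)
        rows, cols = np.nonzero(dense)
        counts = dense[rows, cols]
    else:
        raise ValueError(f"unknown count-matrix format {fmt!r}")
    if np.any(counts < 0):
        raise ValueError("negative counts are not allowed")
    keep = counts > 0
    rows, cols, counts = rows[keep], cols[keep], counts[keep]
    if counts.size == 0:
        raise ValueError("count matrix holds no positive entries")
    space = FactorSpace(list(variable_names), [row_labels, col_labels])
    codes = np.stack([rows, cols], axis=1).astype(np.int64)
    return space, ObservationSet(space, codes, counts.astype(np.float64))


def write_count_matrix(path, obs: ObservationSet, fmt: str | None = None) -> None:
    """Write a two-variable weighted observation set back to mtx/TSV."""
    if obs.space.n_variables != 2:
        raise ValueError("count matrices require exactly two variables")
    if fmt is None:
        fmt = "mtx" if str(path).endswith(".mtx") else "tsv"
    shape = obs.space.sizes
    mat = scipy.sparse.coo_matrix(
        (obs.weights, (obs.codes[:, 0], obs.codes[:, 1])), shape=shape
    )
    if fmt == "mtx":
        scipy.io.mmwrite(path, mat)
    elif fmt == "tsv":
        frame = pd.DataFrame(
            mat.toarray(),
            index=list(obs.space.categories[0]),
            columns=list(obs.space.categories[1]),
        )
        frame.to_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown count-matrix format {fmt!r}")


def subsample_counts(
    obs: ObservationSet, fraction: float, seed: int | np.random.Generator
) -> ObservationSet:
    """Binomial thinning: keep each unit of count with probability *fraction*.

    Requires integer weights.  ``fraction=1`` returns the observations
    unchanged; rows whose thinned count reaches zero are dropped.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    if fraction == 1.0:
        return ObservationSet(obs.space, obs.codes.copy(), obs.weights.copy())
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    counts = obs.weights
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("subsampling requires integer counts")
    thinned = rng.binomial(np.round(counts).astype(np.int64), fraction)
    keep = thinned > 0
    if not keep.any():
        raise ValueError("subsampling removed every observation; raise fraction")
    return ObservationSet(
        obs.space, obs.codes[keep], thinned[keep].astype(np.float64)
    )


def cooccurrence_network(
    tree: OPTTree,
    top_k: int = 20,
    weight_by: str = "regions",
    max_labels_per_region: int = 2_000,
) -> list[CooccurrenceEdge]:
    """Top co-occurring category labels across non-empty terminal regions.

    Every terminal region with at least one sample contributes one unit of
    weight (``weight_by="regions"``) or its sample count
    (``weight_by="samples"``) to every unordered pair of distinct labels
    present in the region — both within one variable's subset and across
    variables.  Zero-sample terminal regions are ignored.  Edges are sorted
    by weight descending, ties alphabetically, and the *top_k* heaviest are
    returned.
    """
    if weight_by not in ("regions", "samples"):
        raise ValueError("weight_by must be 'regions' or 'samples'")
    pair_weights: dict[tuple[str, str], float] = {}
    for leaf in tree.leaves():
        if leaf.n <= 0:
            continue
        labels = sorted(
            {
                lab
                for i in range(tree.space.n_variables)
                for lab in leaf.region.subset_labels(i)
            }
        )
        if len(labels) > max_labels_per_region:
            raise ValueError(
                f"terminal region holds {len(labels)} labels "
                f"(> {max_labels_per_region}); the pair enumeration would "
                "explode — the tree looks unpartitioned"
            )
        w = 1.0 if weight_by == "regions" else float(leaf.n)
        for a_idx in range(len(labels)):
            for b_idx in range(a_idx + 1, len(labels)):
                key = (labels[a_idx], labels[b_idx])
                pair_weights[key] = pair_weights.get(key, 0.0) + w
    ranked = sorted(pair_weights.items(), key=lambda kv: (-kv[1], kv[0]))
    return [
        CooccurrenceEdge(code_a=a, code_b=b, weight=w)
        for (a, b), w in ranked[:top_k]
    ]


def cooccurrence_graph(edges: list[CooccurrenceEdge]) -> nx.Graph:
    """The co-occurrence edges as a weighted undirected networkx graph."""
    graph = nx.Graph()
    for e in edges:
        graph.add_edge(e.code_a, e.code_b, weight=e.weight)
    return graph


def write_edges_tsv(path, edges: list[CooccurrenceEdge]) -> None:
    pd.DataFrame(
        [(e.code_a, e.code_b, e.weight) for e in edges],
        columns=["code_a", "code_b", "weight"],
    ).to_csv(path, sep="\t", index=False)
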