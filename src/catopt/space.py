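"""Factor sample spaces, regions, and observation sets.

The estimation problem lives on a product space of ``p`` unordered factor
variables, the *i*-th of which takes one of ``m_i`` categorical values.  A
*region* is a product of non-empty category subsets, one per variable; the
whole space, every intermediate node of a partition tree, and every single
combination cell are regions.  Category storage order carries no semantics
(the categories are unordered); it only fixes the encoding of labels as
integer codes.

Observations are stored as integer code matrices with a non-negative weight
per row, so that plain sample tables (weight 1 per row) and count matrices
(weight = count) share one code path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FactorSpace",
    "Region",
    "ObservationSet",
    "MarginalVector",
    "build_space",
    "region_cell_count",
    "region_sample_count",
    "marginal_population",
]


class FactorSpace:
    """The ``p`` factor variables and their category label sets.

    Parameters
    ----------
    variable_names
        Identifiers of the ``p`` variables.
    categories
        Per-variable sequence of category labels (sizes ``m_1 .. m_p``).
        Order is storage order only.
    """

    __slots__ = ("variable_names", "categories", "sizes", "_label_index")

    def __init__(
        self,
        variable_names: Sequence[str],
        categories: Sequence[Sequence[str]],
    ) -> None:
        names = tuple(str(v) for v in variable_names)
        if len(names) < 1:
            raise ValueError("a factor space needs at least one variable")
        if len(set(names)) != len(names):
            raise ValueError("variable names must be unique")
        if len(categories) != len(names):
            raise ValueError("one category list required per variable")
        cats = tuple(tuple(str(c) for c in cs) for cs in categories)
        for name, cs in zip(names, cats):
            if len(cs) < 1:
                raise ValueError(f"variable {name!r} has no categories")
            if len(set(cs)) != len(cs):
                raise ValueError(f"duplicate category label in variable {name!r}")
        self.variable_names = names
        self.categories = cats
        self.sizes = tuple(len(cs) for cs in cats)
        self._label_index = tuple({c: j for j, c in enumerate(cs)} for cs in cats)

    @property
    def n_variables(self) -> int:
        return len(self.variable_names)

    @property
    def n_cells(self) -> int:
        return int(np.prod([np.int64(m) for m in self.sizes]))

    def index_of(self, variable: int, label: str) -> int:
        try:
            return self._label_index[variable][str(label)]
        except KeyError:
            raise KeyError(
                f"unknown category {label!r} for variable "
                f"{self.variable_names[variable]!r}"
            ) from None

    def encode_row(self, labels: Sequence[str]) -> tuple[int, ...]:
        return tuple(self.index_of(i, lab) for i, lab in enumerate(labels))

    def whole_region(self) -> "Region":
        return Region(
            self, tuple(np.arange(m, dtype=np.int64) for m in self.sizes)
        )

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, FactorSpace)
            and self.variable_names == other.variable_names
            and self.categories == other.categories
        )

    def __hash__(self) -> int:
        return hash((self.variable_names, self.categories))

    def __repr__(self) -> str:
        dims = " x ".join(str(m) for m in self.sizes)
        return f"FactorSpace({dims}; {', '.join(self.variable_names)})"


class Region:
    """A product region ``A``: one non-empty category subset per variable."""

    __slots__ = ("space", "subsets", "_cell_count")

    def __init__(
        self,
        space: FactorSpace,
        subsets: Sequence[np.ndarray],
        *,
        _validate: bool = True,
    ) -> None:
        subs = tuple(np.asarray(s, dtype=np.int64) for s in subsets)
        if _validate:
            if len(subs) != space.n_variables:
                raise ValueError("one subset required per variable")
            for i, s in enumerate(subs):
                if s.size == 0:
                    raise ValueError(f"empty subset for variable {i}")
                if s.min() < 0 or s.max() >= space.sizes[i]:
                    raise ValueError(f"subset indices out of range for variable {i}")
                if np.unique(s).size != s.size:
                    raise ValueError(f"duplicate indices in subset for variable {i}")
        self.space = space
        self.subsets = subs
        self._cell_count: int | None = None

    @classmethod
    def from_labels(
        cls, space: FactorSpace, subsets: Sequence[Iterable[str]]
    ) -> "Region":
        return cls(
            space,
            tuple(
                np.sort([space.index_of(i, lab) for lab in labs])
                for i, labs in enumerate(subsets)
            ),
        )

    @property
    def cell_count(self) -> int:
        """C(A): number of combination cells in the region."""
        if self._cell_count is None:
            c = 1
            for s in self.subsets:
                c *= int(s.size)
            self._cell_count = c
        return self._cell_count

    @property
    def is_single_cell(self) -> bool:
        return all(s.size == 1 for s in self.subsets)

    def replace(self, variable: int, subset: np.ndarray) -> "Region":
        subs = list(self.subsets)
        subs[variable] = np.asarray(subset, dtype=np.int64)
        return Region(self.space, subs, _validate=False)

    def subset_labels(self, variable: int) -> tuple[str, ...]:
        cats = self.space.categories[variable]
        return tuple(cats[j] for j in self.subsets[variable])

    def contains(self, codes: np.ndarray) -> np.ndarray:
        """Boolean mask of rows (n x p code matrix) lying inside the region."""
        codes = np.atleast_2d(codes)
        mask = np.ones(codes.shape[0], dtype=bool)
        for i, s in enumerate(self.subsets):
            lut = np.zeros(self.space.sizes[i], dtype=bool)
            lut[s] = True
            mask &= lut[codes[:, i]]
        return mask

    def all_cells(self, max_cells: int = 1_000_000) -> np.ndarray:
        """Code matrix (C(A) x p) enumerating every cell of the region."""
        if self.cell_count > max_cells:
            raise ValueError(
                f"refusing to enumerate {self.cell_count} cells (> {max_cells})"
            )
        grids = np.meshgrid(*self.subsets, indexing="ij")
        return np.stack([g.ravel() for g in grids], axis=1)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Region)
            and self.space == other.space
            and all(
                np.array_equal(np.sort(a), np.sort(b))
                for a, b in zip(self.subsets, other.subsets)
            )
        )

    def __repr__(self) -> str:
        dims = " x ".join(str(s.size) for s in self.subsets)
        return f"Region({dims} of {self.space!r})"


class ObservationSet:
    """Encoded, optionally weighted observations over a :class:`FactorSpace`."""

    __slots__ = ("space", "codes", "weights")

    def __init__(
        self,
        space: FactorSpace,
        codes: np.ndarray,
        weights: np.ndarray | None = None,
    ) -> None:
        codes = np.asarray(codes, dtype=np.int64)
        if codes.ndim != 2 or codes.shape[1] != space.n_variables:
            raise ValueError("codes must be an (n, p) matrix")
        for i, m in enumerate(space.sizes):
            col = codes[:, i]
            if col.size and (col.min() < 0 or col.max() >= m):
                raise ValueError(f"invalid category code for variable {i}")
        if weights is None:
            weights = np.ones(codes.shape[0], dtype=np.float64)
        else:
            weights = np.asarray(weights, dtype=np.float64)
            if weights.shape != (codes.shape[0],):
                raise ValueError("one weight per row required")
            if np.any(weights < 0) or not np.all(np.isfinite(weights)):
                raise ValueError("weights must be finite and non-negative")
        self.space = space
        self.codes = codes
        self.weights = weights

    @property
    def n_rows(self) -> int:
        return self.codes.shape[0]

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())

    def rows_in(self, region: Region) -> np.ndarray:
        """Indices of rows lying inside *region*."""
        return np.nonzero(region.contains(self.codes))[0]

    def __repr__(self) -> str:
        return (
            f"ObservationSet(n_rows={self.n_rows}, "
            f"total_weight={self.total_weight:g}, space={self.space!r})"
        )


@dataclass(frozen=True)
class MarginalVector:
    """Marginal population M_A(x^i) of one variable within a region.

    ``weights[j]`` is the summed sample weight of region rows whose *i*-th
    coordinate equals the *j*-th category of the region's subset for the
    variable (subset storage order).  Entries sum to N(A).
    """

    variable: int
    weights: np.ndarray

    @property
    def total(self) -> float:
        return float(self.weights.sum())


def build_space(
    table: pd.DataFrame,
    explicit_categories: dict[str, Sequence[str]] | None = None,
    count_column: str = "count",
) -> tuple[FactorSpace, ObservationSet]:
    """Encode a label-valued observation table.

    Columns are variables, rows are observations; a column named
    *count_column* (default ``"count"``), if present, carries row weights.
    Categories are the observed labels (sorted for determinism), extended by
    *explicit_categories* where given; when a variable has explicit
    categories, every observed label must be listed.
    """
    if table.shape[0] == 0:
        raise ValueError("observation table is empty")
    table = table.copy()
    if count_column in table.columns:
        weights = pd.to_numeric(table[count_column], errors="raise").to_numpy(
            dtype=np.float64
        )
        if np.any(weights < 0) or not np.all(np.isfinite(weights)):
            raise ValueError("count column must be finite and non-negative")
        table = table.drop(columns=[count_column])
    else:
        weights = np.ones(table.shape[0], dtype=np.float64)
    if table.shape[1] == 0:
        raise ValueError("no factor variable columns found")
    if table.isna().any().any():
        raise ValueError("missing values are not supported")

    names = [str(c) for c in table.columns]
    explicit_categories = explicit_categories or {}
    categories: list[list[str]] = []
    for name in names:
        observed = sorted({str(v) for v in table[name]})
        if name in explicit_categories:
            listed = [str(c) for c in explicit_categories[name]]
            missing = set(observed) - set(listed)
            if missing:
                raise ValueError(
                    f"labels {sorted(missing)} of variable {name!r} are not in "
                    "explicit_categories"
                )
            categories.append(listed)
        else:
            categories.append(observed)

    space = FactorSpace(names, categories)
    codes = np.empty((table.shape[0], len(names)), dtype=np.int64)
    for i, name in enumerate(names):
        lut = space._label_index[i]
        codes[:, i] = [lut[str(v)] for v in table[name]]
    return space, ObservationSet(space, codes, weights)


def region_cell_count(region: Region) -> int:
    """C(A) = product of per-variable subset sizes."""
    return region.cell_count


def region_sample_count(
    region: Region, obs: ObservationSet, rows: np.ndarray | None = None
) -> float:
    """N(A): summed weight of observations inside the region.

    When *rows* is given, it must index rows already known to lie in the
    region (fast path used by the tree builder).
    """
    if rows is not None:
        return float(obs.weights[rows].sum())
    return float(obs.weights[region.contains(obs.codes)].sum())


def marginal_population(
    region: Region,
    obs: ObservationSet,
    variable: int,
    rows: np.ndarray | None = None,
) -> MarginalVector:
    """M_A(x^i): per-category sample weight of one variable within a region.

    Entry ``j`` counts rows of the region whose coordinate for *variable*
    equals the ``j``-th category of the region's subset; entries sum to N(A).
    """
    if rows is None:
        rows = obs.rows_in(region)
    counts = np.bincount(
        obs.codes[rows, variable],
        weights=obs.weights[rows],
        minlength=region.space.sizes[variable],
    )
    return MarginalVector(variable=variable, weights=counts[region.subsets[variable]])
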