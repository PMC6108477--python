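"""Suboptimal binary splits guided by marginal populations.

Exhaustively scoring all ``2^(m-1) - 1`` bipartitions of a variable's
categories is infeasible for large ``m``.  Instead, categories are ranked by
their marginal population within the region and only the ``m - 1`` prefix
cuts of that ranking are considered; the cut minimising the within-group
dispersion

    T(s) = sum_{j<=s} (M_(j) - mean_{j<=s})^2 + sum_{j>s} (M_(j) - mean_{j>s})^2

is the suboptimal split ``s*`` for that variable.  One candidate split per
variable reduces the search to at most ``p`` options per region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .space import MarginalVector, ObservationSet, Region, marginal_population

__all__ = [
    "SplitOption",
    "rank_by_marginal",
    "split_dispersion",
    "dispersion_profile",
    "find_suboptimal_split",
    "candidate_splits",
    "split_rows",
    "MarginalSplitter",
    "RandomSplitter",
]


@dataclass
class SplitOption:
    """A committed or candidate binary split of a region on one variable.

    ``left``/``right`` replace the variable's category subset with two
    disjoint, non-empty parts; other variables are untouched.  ``s`` is the
    ranked cut position (1-based) and ``order`` the ranking permutation; both
    are ``None`` for splits not derived from the marginal ranking (the
    random-partition baseline).
    """

    variable: int
    left: Region
    right: Region
    n_left: float
    n_right: float
    s: int | None = None
    t_value: float | None = None
    order: np.ndarray | None = None


def rank_by_marginal(marginal: MarginalVector | np.ndarray) -> np.ndarray:
    """Ascending stable ordering of categories by marginal population.

    Ties keep the original storage order (stable sort), which makes every
    downstream choice deterministic.
    """
    weights = (
        marginal.weights if isinstance(marginal, MarginalVector) else np.asarray(marginal)
    )
    if weights.size == 0:
        raise ValueError("empty marginal vector")
    return np.argsort(weights, kind="stable")


def dispersion_profile(m_sorted: np.ndarray) -> np.ndarray:
    """T(s) for every cut s = 1 .. len-1 of an ascending marginal vector."""
    m = np.asarray(m_sorted, dtype=np.float64)
    if m.size < 2:
        raise ValueError("need at least two categories to split")
    cs = np.cumsum(m)
    css = np.cumsum(m * m)
    k = np.arange(1, m.size, dtype=np.float64)
    left = css[:-1] - cs[:-1] ** 2 / k
    right = (css[-1] - css[:-1]) - (cs[-1] - cs[:-1]) ** 2 / (m.size - k)
    # sums of squared deviations; clip tiny negative round-off
    return np.maximum(left + right, 0.0)


def split_dispersion(m_sorted: np.ndarray, s: int) -> float:
    """Within-group sum of squared deviations for the cut after position s."""
    m = np.asarray(m_sorted, dtype=np.float64)
    if not 1 <= s <= m.size - 1:
        raise ValueError(f"cut position s={s} out of range 1..{m.size - 1}")
    return float(dispersion_profile(m)[s - 1])


def find_suboptimal_split(
    region: Region,
    obs: ObservationSet,
    variable: int,
    rows: np.ndarray | None = None,
) -> SplitOption | None:
    """The T-minimising prefix cut of the marginal ranking for one variable.

    Returns ``None`` when the variable's subset has a single category.  Ties
    in T are broken toward the smallest ``s``.
    """
    subset = region.subsets[variable]
    if subset.size < 2:
        return None
    marg = marginal_population(region, obs, variable, rows=rows)
    order = rank_by_marginal(marg)
    m_sorted = marg.weights[order]
    profile = dispersion_profile(m_sorted)
    s = int(np.argmin(profile)) + 1
    left_cats = np.sort(subset[order[:s]])
    right_cats = np.sort(subset[order[s:]])
    return SplitOption(
        variable=variable,
        left=region.replace(variable, left_cats),
        right=region.replace(variable, right_cats),
        n_left=float(m_sorted[:s].sum()),
        n_right=float(m_sorted[s:].sum()),
        s=s,
        t_value=float(profile[s - 1]),
        order=order,
    )


def candidate_splits(
    region: Region,
    obs: ObservationSet,
    rows: np.ndarray | None = None,
) -> list[SplitOption]:
    """One suboptimal split per splittable variable, in variable order."""
    if rows is None:
        rows = obs.rows_in(region)
    options = []
    for i in range(region.space.n_variables):
        opt = find_suboptimal_split(region, obs, i, rows=rows)
        if opt is not None:
            options.append(opt)
    return options


def split_rows(
    obs: ObservationSet, rows: np.ndarray, option: SplitOption
) -> tuple[np.ndarray, np.ndarray]:
    """Partition region row indices into the option's left/right subregions."""
    lut = np.zeros(obs.space.sizes[option.variable], dtype=bool)
    lut[option.left.subsets[option.variable]] = True
    mask = lut[obs.codes[rows, option.variable]]
    return rows[mask], rows[~mask]


class MarginalSplitter:
    """Default split proposer: marginal-ranked, T-minimising prefix cuts."""

    def candidates(
        self, region: Region, obs: ObservationSet, rows: np.ndarray
    ) -> list[SplitOption]:
        return candidate_splits(region, obs, rows=rows)


class RandomSplitter:
    """Random-bipartition proposer for the random-partitioning OPT baseline.

    Each category of a variable's subset is assigned to a side uniformly at
    random, redrawing until both sides are non-empty.  Everything downstream
    (likelihoods, commitment, posterior) is unchanged.
    """

    def __init__(self, rng: np.random.Generator) -> None:
        self.rng = rng

    def candidates(
        self, region: Region, obs: ObservationSet, rows: np.ndarray
    ) -> list[SplitOption]:
        options = []
        for i in range(region.space.n_variables):
            subset = region.subsets[i]
            if subset.size < 2:
                continue
            sides = self.rng.integers(0, 2, size=subset.size)
            while sides.min() == sides.max():
                sides = self.rng.integers(0, 2, size=subset.size)
            left_cats = np.sort(subset[sides == 0])
            right_cats = np.sort(subset[sides == 1])
            marg = marginal_population(region, obs, i, rows=rows)
            n_left = float(marg.weights[sides == 0].sum())
            options.append(
                SplitOption(
                    variable=i,
                    left=region.replace(i, left_cats),
                    right=region.replace(i, right_cats),
                    n_left=n_left,
                    n_right=float(marg.total - n_left),
                )
            )
        return options
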