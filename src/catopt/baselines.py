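"""Comparison estimators: combination-wise MLE, categorical KDE, random OPT.

The conventional combination-wise estimator assigns each cell its observed
relative frequency.  The categorical kernel estimator smooths each
observation over the whole space with an Aitchison–Aitken product kernel:
per variable, weight ``1 - λ`` stays on the observed category and ``λ/(m-1)``
spreads to each other category (``λ`` the bandwidth, default 0.9).  The
random-partitioning OPT replaces the marginal-guided split proposals with
uniformly random bipartitions while keeping likelihoods, commitment, and
posterior identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .likelihood import OPTParams
from .partition import RandomSplitter
from .space import ObservationSet
from .table import ProbabilityTable
from .tree import OPTTree, build_tree, expected_cell_probabilities

__all__ = [
    "KDEConfig",
    "mle_estimate",
    "kde_estimate",
    "random_partition_tree",
    "get_estimator",
]


@dataclass
class KDEConfig:
    """Aitchison–Aitken kernel bandwidth λ ∈ [0, 1]; 0 recovers the MLE."""

    bandwidth: float = 0.9

    def __post_init__(self) -> None:
        if not 0.0 <= self.bandwidth <= 1.0:
            raise ValueError("bandwidth must lie in [0, 1]")


def mle_estimate(obs: ObservationSet) -> ProbabilityTable:
    """Combination-wise MLE: cell count / total weight (sparse)."""
    if obs.total_weight <= 0:
        raise ValueError("observations carry no weight")
    cells, inverse = np.unique(obs.codes, axis=0, return_inverse=True)
    probs = np.bincount(inverse, weights=obs.weights, minlength=cells.shape[0])
    probs = probs / obs.total_weight
    keep = probs > 0
    return ProbabilityTable(
        obs.space, cell_codes=cells[keep], cell_probs=probs[keep]
    )


def kde_estimate(
    obs: ObservationSet,
    cfg: KDEConfig | None = None,
    max_cells: int = 2_000_000,
) -> ProbabilityTable:
    """Categorical KDE with a product Aitchison–Aitken kernel.

    The estimate of a cell is the weight-averaged kernel product over
    observations; each kernel factor sums to one over its variable's
    categories, so the table is exactly normalized.
    """
    if cfg is None:
        cfg = KDEConfig()
    if obs.total_weight <= 0:
        raise ValueError("observations carry no weight")
    space = obs.space
    if space.n_cells > max_cells:
        raise ValueError(
            f"space has {space.n_cells} cells (> {max_cells}); the dense "
            "kernel estimate is intended for moderate spaces"
        )
    lam = cfg.bandwidth
    # per-variable kernel rows: k[x_obs, x_cell]
    kernels = []
    for m in space.sizes:
        if m == 1:
            k = np.ones((1, 1))
        else:
            k = np.full((m, m), lam / (m - 1))
            np.fill_diagonal(k, 1.0 - lam)
        kernels.append(k)

    cells, inverse = np.unique(obs.codes, axis=0, return_inverse=True)
    cell_w = np.bincount(inverse, weights=obs.weights, minlength=cells.shape[0])
    dense = np.zeros(space.sizes, dtype=np.float64)
    for row, w in zip(cells, cell_w):
        factors = [kernels[i][row[i]] for i in range(space.n_variables)]
        prod = factors[0]
        for f in factors[1:]:
            prod = np.multiply.outer(prod, f)
        dense += w * prod
    dense /= obs.total_weight
    return ProbabilityTable.from_dense(space, dense)


def random_partition_tree(
    obs: ObservationSet,
    params: OPTParams | None = None,
    seed: int | np.random.Generator = 0,
) -> OPTTree:
    """Committed OPT built with uniformly random bipartitions per variable."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    return build_tree(obs, params=params, splitter=RandomSplitter(rng))


def get_estimator(
    name: str,
    opt_params: OPTParams | None = None,
    kde_config: KDEConfig | None = None,
) -> Callable[[ObservationSet, np.random.Generator], ProbabilityTable]:
    """Estimator registry: callables (obs, rng) -> ProbabilityTable.

    Names: ``opt`` (posterior mean of the marginal-guided OPT), ``mle``,
    ``kde``, ``randopt`` (posterior mean of the random-partition OPT).
    """
    if name == "opt":

        def fit(obs, rng):
            return expected_cell_probabilities(build_tree(obs, params=opt_params))

    elif name == "mle":

        def fit(obs, rng):
            return mle_estimate(obs)

    elif name == "kde":

        def fit(obs, rng):
            return kde_estimate(obs, cfg=kde_config)

    elif name == "randopt":

        def fit(obs, rng):
            return expected_cell_probabilities(
                random_partition_tree(obs, params=opt_params, seed=rng)
            )

    else:
        raise ValueError(f"unknown estimator {name!r}")

    fit.__name__ = f"fit_{name}"
    return fit
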