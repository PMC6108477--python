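"""Region likelihoods Φ(A) of the optional Pólya tree, in log domain.

The likelihood of a region combines the case where its samples are uniform
(no further partitioning) with the ``p`` suboptimal binary splits:

    Φ(A) = ρ Φ0(A)
         + (1-ρ)/p · Σ_i  B(N1_i+α, N2_i+α)/B(α,α) · Φ(A_i1) Φ(A_i2)

with the uniform term Φ0(A) = C(A)^{-N(A)} (counting measure on the discrete
space), B the beta function, ρ the prior stopping weight and α a pseudo
count.  Terminal regions — a single cell, all-singleton subsets, or no
samples — have Φ = Φ0.  The full recursion is exponential in general; the
limited-lookahead variant truncates it after ``h`` levels, replacing deeper
regions by their uniform term.

Everything is computed with log-sum-exp and log-Gamma: Φ0 = C^{-N} underflows
at any realistic problem size otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

from .partition import MarginalSplitter, split_rows
from .space import ObservationSet, Region, region_sample_count

__all__ = [
    "OPTParams",
    "log_phi0",
    "log_beta_weight",
    "is_terminal",
    "log_phi_exact",
    "log_phi_lookahead",
]


@dataclass
class OPTParams:
    """Prior and approximation parameters of the OPT estimator.

    rho
        Prior weight of stopping versus further partitioning, in (0, 1).
    alpha
        Pseudo count of the Beta allocation / split weighting, > 0.
    beta
        Pseudo count of the uniform-Dirichlet cell extension, > 0.  Affects
        only the dispersion of sampled tables, not posterior means.
    lookahead_h
        Levels of lookahead when evaluating Φ during tree construction.
    commit_q
        Levels committed per step (q <= h); the standard choice is 1.
    """

    rho: float = 0.5
    alpha: float = 0.5
    beta: float = 0.5
    lookahead_h: int = 3
    commit_q: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.rho < 1.0:
            raise ValueError("rho must lie strictly between 0 and 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.lookahead_h < 1:
            raise ValueError("lookahead_h must be >= 1")
        if not 1 <= self.commit_q <= self.lookahead_h:
            raise ValueError("commit_q must satisfy 1 <= q <= h")


def log_phi0(cell_count: int, n: float) -> float:
    """log Φ0(A) = -N(A) log C(A): exact uniform-multinomial log likelihood."""
    if cell_count < 1:
        raise ValueError("cell count must be >= 1")
    if n < 0:
        raise ValueError("sample count must be non-negative")
    return -n * math.log(cell_count)


def log_beta_weight(n1: float, n2: float, alpha: float) -> float:
    """log [ B(n1+α, n2+α) / B(α, α) ] via log-Gamma."""
    if n1 < 0 or n2 < 0:
        raise ValueError("counts must be non-negative")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    num = gammaln(n1 + alpha) + gammaln(n2 + alpha) - gammaln(n1 + n2 + 2 * alpha)
    den = 2 * gammaln(alpha) - gammaln(2 * alpha)
    return float(num - den)


def is_terminal(
    region: Region,
    obs: ObservationSet | None = None,
    rows: np.ndarray | None = None,
    n: float | None = None,
) -> bool:
    """Whether further partitioning of the region is meaningless.

    True when the region is a single combination cell (equivalently all
    per-variable subsets are singletons) or contains no sample.
    """
    if region.cell_count == 1:
        return True
    if n is None:
        if obs is None:
            raise ValueError("provide obs or n to test for emptiness")
        n = region_sample_count(region, obs, rows=rows)
    return n == 0


def _log_phi(
    region: Region,
    obs: ObservationSet,
    rows: np.ndarray,
    params: OPTParams,
    depth_left: int | None,
    splitter,
    budget: list[int],
) -> float:
    """Shared Φ recursion; ``depth_left=None`` means recurse to terminal."""
    n = float(obs.weights[rows].sum())
    c = region.cell_count
    if is_terminal(region, n=n) or depth_left == 0:
        return log_phi0(c, n)
    budget[0] -= 1
    if budget[0] < 0:
        raise RuntimeError(
            "region evaluation budget exceeded; the exact recursion is meant "
            "for small spaces — use the lookahead variant instead"
        )
    p_whole = obs.space.n_variables
    terms = [math.log(params.rho) + log_phi0(c, n)]
    log_w = math.log1p(-params.rho) - math.log(p_whole)
    next_depth = None if depth_left is None else depth_left - 1
    for opt in splitter.candidates(region, obs, rows):
        lb = log_beta_weight(opt.n_left, opt.n_right, params.alpha)
        if next_depth == 0:
            ll = log_phi0(opt.left.cell_count, opt.n_left)
            lr = log_phi0(opt.right.cell_count, opt.n_right)
        else:
            rows_l, rows_r = split_rows(obs, rows, opt)
            ll = _log_phi(opt.left, obs, rows_l, params, next_depth, splitter, budget)
            lr = _log_phi(opt.right, obs, rows_r, params, next_depth, splitter, budget)
        terms.append(log_w + lb + ll + lr)
    return float(logsumexp(terms))


def log_phi_exact(
    region: Region,
    obs: ObservationSet,
    params: OPTParams,
    rows: np.ndarray | None = None,
    max_regions: int = 500_000,
    splitter=None,
) -> float:
    """log Φ(A) with the recursion carried to terminal regions.

    Intended for small spaces; raises once *max_regions* region evaluations
    are exceeded, which signals misuse on large spaces.
    """
    if rows is None:
        rows = obs.rows_in(region)
    if splitter is None:
        splitter = MarginalSplitter()
    return _log_phi(region, obs, rows, params, None, splitter, [max_regions])


def log_phi_lookahead(
    region: Region,
    obs: ObservationSet,
    params: OPTParams,
    depth_left: int,
    rows: np.ndarray | None = None,
    splitter=None,
) -> float:
    """log Φ(A) truncated after *depth_left* levels (LL-OPT approximation).

    Regions reached at depth 0 contribute their uniform term Φ0; with
    *depth_left* at least the depth of the full recursion this equals
    :func:`log_phi_exact`.
    """
    if depth_left < 0:
        raise ValueError("depth_left must be >= 0")
    if rows is None:
        rows = obs.rows_in(region)
    if splitter is None:
        splitter = MarginalSplitter()
    return _log_phi(
        region, obs, rows, params, depth_left, splitter, [2_000_000_000]
    )
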