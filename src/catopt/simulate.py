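"""Synthetic data generators, the RSSE metric, and the benchmark harness.

The simulation designs follow a common pattern: a *designed* joint
distribution over three factor variables is laid down on a product grid, the
category labels of each variable are independently shuffled (so estimators
cannot exploit the generative order — the categories are unordered), and
``n`` i.i.d. samples are drawn from the designed truth.  Estimator quality is
the root sum square error

    RSSE = sqrt( Σ_cells (estimated - true)^2 ).

Families
--------
* two-level uniform — each variable's fine categories group into hidden
  "super categories" holding masses ``p`` and ``1-p``, uniformly spread
  within a block; variables either perfectly dependent (aligned blocks) or
  perfectly independent (product of marginals).
* K-super uniform — the same with K hidden blocks per variable.
* discretized trivariate normal / log-normal — the continuous density is
  integrated over a uniform grid (mean ± 3σ per axis) and renormalized.
* additive exponential — Z_i = E0 + E_i with i.i.d. exponential components,
  a shared E0 inducing positive dependence.
* Clayton copula with uniform marginals — exact cell masses by finite
  differencing of the copula CDF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.legendre import leggauss
from scipy.stats import multivariate_normal

from .baselines import get_estimator
from .space import FactorSpace, ObservationSet, Region
from .table import ProbabilityTable

__all__ = [
    "SimulationSpec",
    "setting_spec",
    "gen_two_level_uniform",
    "gen_discretized_mvnormal",
    "gen_auxiliary",
    "shuffle_category_labels",
    "rsse",
    "run_benchmark",
    "summarize_benchmark",
]


# ---------------------------------------------------------------- utilities

def _make_space(m: Sequence[int]) -> FactorSpace:
    names = [f"X{i + 1}" for i in range(len(m))]
    width = max(3, len(str(max(m) - 1)))
    cats = [[f"c{j:0{width}d}" for j in range(mi)] for mi in m]
    return FactorSpace(names, cats)


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _sample_obs(truth: ProbabilityTable, n: int, rng: np.random.Generator) -> ObservationSet:
    codes = truth.sample(n, rng)
    return ObservationSet(truth.space, codes)


# ------------------------------------------------------- block-uniform truth

def _block_uniform_truth(
    space: FactorSpace,
    chunks: list[list[np.ndarray]],
    masses: list[np.ndarray],
    dependent: bool,
) -> ProbabilityTable:
    """Truth from per-variable category chunks with per-chunk masses.

    ``chunks[i][k]`` are the category indices of variable *i*'s *k*-th super
    category, carrying marginal mass ``masses[i][k]``.  Dependent mode takes
    the aligned diagonal blocks only (all variables in super *k* together,
    with mass ``masses[0][k]``); independent mode takes the full product of
    marginals.
    """
    p = space.n_variables
    blocks: list[tuple[Region, float]] = []
    if dependent:
        k_count = len(chunks[0])
        for k in range(k_count):
            region = Region(space, [chunks[i][k] for i in range(p)])
            blocks.append((region, float(masses[0][k])))
    else:
        index = [range(len(chunks[i])) for i in range(p)]
        for combo in np.array(np.meshgrid(*index, indexing="ij")).reshape(p, -1).T:
            region = Region(space, [chunks[i][combo[i]] for i in range(p)])
            mass = float(np.prod([masses[i][combo[i]] for i in range(p)]))
            blocks.append((region, mass))
    return ProbabilityTable(space, blocks=blocks)


def gen_two_level_uniform(
    m: Sequence[int] = (100, 100, 100),
    p_super: float | Sequence[float] = (0.7, 0.8, 0.9),
    dependent: bool = False,
    n: int = 10_000,
    seed: int | np.random.Generator = 0,
    shuffle: bool = True,
) -> tuple[ObservationSet, ProbabilityTable]:
    """Two hidden super categories per variable, uniform within blocks.

    Dependent mode places mass ``p`` uniformly on the aligned low block
    ∏(m_i/2) and ``1-p`` on the aligned high block (all ``p_super`` entries
    must agree); independent mode multiplies the per-variable two-level
    marginals, giving 2^p uniform blocks.
    """
    rng = _as_rng(seed)
    m = tuple(int(x) for x in m)
    if any(mi % 2 for mi in m):
        raise ValueError("two-level settings require even category counts")
    ps = (
        tuple(float(p_super) for _ in m)
        if np.isscalar(p_super)
        else tuple(float(x) for x in p_super)
    )
    if len(ps) != len(m) or any(not 0 < x < 1 for x in ps):
        raise ValueError("p_super must provide one value in (0,1) per variable")
    if dependent and len(set(ps)) != 1:
        raise ValueError("dependent mode requires a common super-category mass")
    space = _make_space(m)
    chunks = [
        [np.arange(mi // 2), np.arange(mi // 2, mi)] for mi in m
    ]
    masses = [np.array([pi, 1.0 - pi]) for pi in ps]
    truth = _block_uniform_truth(space, chunks, masses, dependent)
    obs = _sample_obs(truth, n, rng)
    if shuffle:
        obs, truth = shuffle_category_labels(obs, truth, rng)
    return obs, truth


# -------------------------------------------------- discretized densities

def _gauss_nodes(edges: np.ndarray, quad: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell Gauss-Legendre nodes/weights, flattened to (m*quad,)."""
    gx, gw = leggauss(quad)
    a, b = edges[:-1], edges[1:]
    mid = (a + b) / 2.0
    half = (b - a) / 2.0
    nodes = (mid[:, None] + half[:, None] * gx[None, :]).ravel()
    weights = (half[:, None] * gw[None, :]).ravel()
    return nodes, weights


def _discretize_pdf(
    pdf: Callable[[np.ndarray], np.ndarray],
    edges_per_axis: list[np.ndarray],
    quad: int = 5,
    chunk_cells: int = 4_000_000,
) -> np.ndarray:
    """Cell masses of a continuous density over a product grid.

    Product Gauss-Legendre rule with *quad* points per axis per cell; the
    result is renormalized (the grid truncates the density's support).
    """
    p = len(edges_per_axis)
    nodes, weights = zip(*(_gauss_nodes(e, quad) for e in edges_per_axis))
    sizes = tuple(e.size - 1 for e in edges_per_axis)
    out = np.zeros(sizes)
    tail = int(np.prod([n.size for n in nodes[1:]])) if p > 1 else 1
    step = max(1, chunk_cells // max(tail, 1))
    for start in range(0, sizes[0], step):
        stop = min(start + step, sizes[0])
        n0 = nodes[0][start * quad : stop * quad]
        w0 = weights[0][start * quad : stop * quad]
        mesh = np.meshgrid(n0, *nodes[1:], indexing="ij")
        pts = np.stack([g.ravel() for g in mesh], axis=1)
        vals = pdf(pts).reshape(mesh[0].shape)
        wmesh = np.meshgrid(w0, *weights[1:], indexing="ij")
        wprod = wmesh[0]
        for w in wmesh[1:]:
            wprod = wprod * w
        vals = vals * wprod
        shape = []
        for d in range(p):
            count = (stop - start) if d == 0 else sizes[d]
            shape.extend([count, quad])
        vals = vals.reshape(shape)
        out[start:stop] = vals.sum(axis=tuple(range(1, 2 * p, 2)))
    total = out.sum()
    if total <= 0:
        raise ValueError("density mass on the grid is zero")
    return out / total


def gen_discretized_mvnormal(
    m: Sequence[int] = (20, 20, 20),
    mean: Sequence[float] | None = None,
    cov: np.ndarray | None = None,
    corr: float = 0.8,
    n: int = 800,
    seed: int | np.random.Generator = 0,
    n_sigma: float = 3.0,
    quad: int = 5,
    shuffle: bool = True,
) -> tuple[ObservationSet, ProbabilityTable]:
    """Trivariate (or p-variate) normal mass over a uniform grid.

    The grid spans mean ± *n_sigma* standard deviations per axis and the
    truncated masses are renormalized.  When *cov* is omitted, an
    equicorrelation matrix with off-diagonal *corr* and unit variances is
    used.
    """
    rng = _as_rng(seed)
    m = tuple(int(x) for x in m)
    p = len(m)
    mean = np.zeros(p) if mean is None else np.asarray(mean, dtype=float)
    if cov is None:
        cov = np.full((p, p), float(corr))
        np.fill_diagonal(cov, 1.0)
    cov = np.asarray(cov, dtype=float)
    # positive definiteness check (raises on failure)
    np.linalg.cholesky(cov)
    sd = np.sqrt(np.diag(cov))
    dist = multivariate_normal(mean=mean, cov=cov)
    edges = [
        np.linspace(mean[i] - n_sigma * sd[i], mean[i] + n_sigma * sd[i], m[i] + 1)
        for i in range(p)
    ]
    dense = _discretize_pdf(dist.pdf, edges, quad=quad)
    space = _make_space(m)
    truth = ProbabilityTable.from_dense(space, dense)
    obs = _sample_obs(truth, n, rng)
    if shuffle:
        obs, truth = shuffle_category_labels(obs, truth, rng)
    return obs, truth


def _additive_exponential_pdf(rate: float, p: int) -> Callable[[np.ndarray], np.ndarray]:
    """Joint density of Z_i = E0 + E_i, E ~ i.i.d. Exp(rate)."""

    def pdf(pts: np.ndarray) -> np.ndarray:
        z = np.asarray(pts)
        s = z.sum(axis=-1)
        zmin = z.min(axis=-1)
        with np.errstate(over="ignore"):
            inner = np.expm1((p - 1) * rate * zmin) / ((p - 1) * rate)
        vals = rate ** (p + 1) * np.exp(-rate * s) * inner
        vals[np.any(z < 0, axis=-1)] = 0.0
        return vals

    return pdf


def _clayton_truth(m: Sequence[int], theta: float) -> np.ndarray:
    """Exact cell masses of a Clayton copula with uniform marginals."""
    p = len(m)
    grids = [np.linspace(0.0, 1.0, mi + 1) for mi in m]
    mesh = np.meshgrid(*grids, indexing="ij")
    u = np.stack(mesh, axis=-1)
    with np.errstate(divide="ignore"):
        s = np.where(u > 0, u, np.nan) ** (-theta)
    s = np.nansum(s, axis=-1) - (p - 1)
    # for u in (0,1]^p, s >= 1; the boundary (any u=0) carries CDF 0
    with np.errstate(divide="ignore", invalid="ignore"):
        inner = np.maximum(s, 1.0) ** (-1.0 / theta)
    cdf = np.where(np.any(u <= 0, axis=-1), 0.0, inner)
    for axis in range(p):
        cdf = np.diff(cdf, axis=axis)
    mass = np.maximum(cdf, 0.0)
    return mass / mass.sum()


def gen_auxiliary(
    family: str,
    m: Sequence[int] = (20, 20, 20),
    n: int = 800,
    seed: int | np.random.Generator = 0,
    shuffle: bool = True,
    **params,
) -> tuple[ObservationSet, ProbabilityTable]:
    """Additional simulation families with documented default parameters.

    Families: ``normal_uncorrelated``; ``lognormal`` (``corr``, default 0.8);
    ``additive_exponential`` (``rate``, default 1.0); ``clayton_uniform``
    (``theta``, default 2.0); ``multi_super_uniform`` (``k_super`` hidden
    blocks per variable, default 5; ``masses`` "linear" — k-th block mass
    proportional to K+1-k — or "equal", or an explicit vector; ``dependent``
    defaults False).
    """
    rng = _as_rng(seed)
    m = tuple(int(x) for x in m)
    p = len(m)
    space = _make_space(m)

    if family == "normal_uncorrelated":
        return gen_discretized_mvnormal(
            m=m, corr=0.0, n=n, seed=rng, shuffle=shuffle,
            quad=params.get("quad", 5),
        )
    if family == "lognormal":
        corr = float(params.get("corr", 0.8))
        cov = np.full((p, p), corr)
        np.fill_diagonal(cov, 1.0)
        np.linalg.cholesky(cov)
        dist = multivariate_normal(mean=np.zeros(p), cov=cov)

        def pdf(pts: np.ndarray) -> np.ndarray:
            z = np.asarray(pts)
            ok = np.all(z > 0, axis=-1)
            safe = np.where(z > 0, z, 1.0)
            vals = dist.pdf(np.log(safe)) / safe.prod(axis=-1)
            return np.where(ok, vals, 0.0)

        upper = float(np.exp(3.0))
        edges = [np.linspace(0.0, upper, mi + 1) for mi in m]
        dense = _discretize_pdf(pdf, edges, quad=params.get("quad", 5))
        truth = ProbabilityTable.from_dense(space, dense)
    elif family == "additive_exponential":
        rate = float(params.get("rate", 1.0))
        upper = (2.0 + 3.0 * np.sqrt(2.0)) / rate  # mean + 3 sd of E0 + E_i
        edges = [np.linspace(0.0, upper, mi + 1) for mi in m]
        dense = _discretize_pdf(
            _additive_exponential_pdf(rate, p), edges, quad=params.get("quad", 5)
        )
        truth = ProbabilityTable.from_dense(space, dense)
    elif family == "clayton_uniform":
        theta = float(params.get("theta", 2.0))
        if theta <= 0:
            raise ValueError("Clayton theta must be positive")
        truth = ProbabilityTable.from_dense(space, _clayton_truth(m, theta))
    elif family == "multi_super_uniform":
        k = int(params.get("k_super", 5))
        if any(mi % k for mi in m):
            raise ValueError("category counts must be divisible by k_super")
        masses_opt = params.get("masses", "linear")
        if isinstance(masses_opt, str):
            if masses_opt == "linear":
                w = np.arange(k, 0, -1, dtype=float)
            elif masses_opt == "equal":
                w = np.ones(k)
            else:
                raise ValueError(f"unknown masses option {masses_opt!r}")
        else:
            w = np.asarray(masses_opt, dtype=float)
            if w.size != k or np.any(w <= 0):
                raise ValueError("masses must be k_super positive values")
        w = w / w.sum()
        chunks = [np.array_split(np.arange(mi), k) for mi in m]
        truth = _block_uniform_truth(
            space, chunks, [w] * p, bool(params.get("dependent", False))
        )
    else:
        raise ValueError(f"unknown simulation family {family!r}")

    obs = _sample_obs(truth, n, rng)
    if shuffle:
        obs, truth = shuffle_category_labels(obs, truth, rng)
    return obs, truth


# ------------------------------------------------------------ label shuffle

def shuffle_category_labels(
    obs: ObservationSet,
    truth: ProbabilityTable,
    seed: int | np.random.Generator,
) -> tuple[ObservationSet, ProbabilityTable]:
    """Apply an independent random category permutation per variable.

    Observations and the truth table are permuted consistently, so the joint
    distribution is unchanged up to relabeling; estimators must not rely on
    the generative storage order.
    """
    rng = _as_rng(seed)
    space = obs.space
    perms = [rng.permutation(mi) for mi in space.sizes]
    codes = np.empty_like(obs.codes)
    for i, perm in enumerate(perms):
        codes[:, i] = perm[obs.codes[:, i]]
    new_obs = ObservationSet(space, codes, obs.weights.copy())

    blocks = [
        (
            Region(space, [np.sort(perms[i][r.subsets[i]]) for i in range(space.n_variables)]),
            mass,
        )
        for r, mass in truth.blocks
    ]
    cell_codes = np.empty_like(truth.cell_codes)
    for i, perm in enumerate(perms):
        cell_codes[:, i] = perm[truth.cell_codes[:, i]]
    new_truth = ProbabilityTable(
        space, blocks=blocks, cell_codes=cell_codes, cell_probs=truth.cell_probs.copy()
    )
    return new_obs, new_truth


# -------------------------------------------------------------------- RSSE

def rsse(est: ProbabilityTable, truth: ProbabilityTable) -> float:
    """Root sum square error between two tables over all cells."""
    if est.space != truth.space:
        raise ValueError("estimate and truth live on different spaces")
    diff = est.to_dense() - truth.to_dense()
    return float(np.sqrt(np.sum(diff * diff)))


# --------------------------------------------------------------- benchmark

@dataclass
class SimulationSpec:
    """A named simulation condition.

    ``setting`` is one of ``two_level_dependent``, ``two_level_independent``,
    ``mvnormal``, or an auxiliary family name accepted by
    :func:`gen_auxiliary`.  ``params`` passes family-specific knobs
    (``p_super``, ``corr``, ``rate``, ``theta``, ``k_super``, ``masses`` ...).
    """

    setting: str
    m: tuple[int, ...] = (20, 20, 20)
    n: int = 800
    params: dict = field(default_factory=dict)
    shuffle: bool = True

    def generate(
        self, seed: int | np.random.Generator
    ) -> tuple[ObservationSet, ProbabilityTable]:
        rng = _as_rng(seed)
        if self.setting == "two_level_dependent":
            return gen_two_level_uniform(
                m=self.m,
                p_super=self.params.get("p_super", 0.7),
                dependent=True,
                n=self.n,
                seed=rng,
                shuffle=self.shuffle,
            )
        if self.setting == "two_level_independent":
            return gen_two_level_uniform(
                m=self.m,
                p_super=self.params.get("p_super", (0.7, 0.8, 0.9)),
                dependent=False,
                n=self.n,
                seed=rng,
                shuffle=self.shuffle,
            )
        if self.setting == "mvnormal":
            return gen_discretized_mvnormal(
                m=self.m,
                corr=self.params.get("corr", 0.8),
                n=self.n,
                seed=rng,
                shuffle=self.shuffle,
                quad=self.params.get("quad", 5),
            )
        return gen_auxiliary(
            self.setting, m=self.m, n=self.n, seed=rng, shuffle=self.shuffle,
            **self.params,
        )


def setting_spec(setting: int, m: int = 20, n: int = 800) -> SimulationSpec:
    """Specs for the numbered two-level-uniform and normal settings.

    (1) dependent two-level uniform, p = 0.7 for all variables;
    (2) independent two-level uniform, p = (0.7, 0.8, 0.9);
    (3) discretized trivariate normal, low correlation (0.2);
    (4) discretized trivariate normal, high correlation (0.8).
    """
    dims = (m, m, m)
    if setting == 1:
        return SimulationSpec("two_level_dependent", dims, n, {"p_super": 0.7})
    if setting == 2:
        return SimulationSpec(
            "two_level_independent", dims, n, {"p_super": (0.7, 0.8, 0.9)}
        )
    if setting == 3:
        return SimulationSpec("mvnormal", dims, n, {"corr": 0.2})
    if setting == 4:
        return SimulationSpec("mvnormal", dims, n, {"corr": 0.8})
    raise ValueError("numbered settings 1-4 are available; use SimulationSpec directly")


def run_benchmark(
    spec: SimulationSpec,
    estimators: Sequence[str] | Mapping[str, Callable],
    replicates: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-replicate RSSEs of the requested estimators under one condition.

    Each replicate regenerates data (fresh label shuffle and samples) from a
    child seed of *seed*; estimators with internal randomness get their own
    child stream, so the whole table is reproducible under *seed*.
    """
    if not isinstance(estimators, Mapping):
        estimators = {name: get_estimator(name) for name in estimators}
    ss = np.random.SeedSequence(seed)
    records = []
    for rep, child in enumerate(ss.spawn(replicates)):
        data_seed, est_seed = child.spawn(2)
        obs, truth = spec.generate(np.random.default_rng(data_seed))
        for name, fit in estimators.items():
            est = fit(obs, np.random.default_rng(est_seed))
            records.append(
                {
                    "setting": spec.setting,
                    "estimator": name,
                    "m": max(spec.m),
                    "n": spec.n,
                    "replicate": rep,
                    "rsse": rsse(est, truth),
                }
            )
    return pd.DataFrame.from_records(records)


def summarize_benchmark(results: pd.DataFrame) -> pd.DataFrame:
    """Mean, standard deviation, and CV of RSSE per condition/estimator."""
    grouped = results.groupby(["setting", "estimator", "m", "n"])["rsse"]
    out = grouped.agg(mean_rsse="mean", sd_rsse="std").reset_index()
    out["sd_rsse"] = out["sd_rsse"].fillna(0.0)
    out["cv"] = out["sd_rsse"] / out["mean_rsse"]
    return out
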