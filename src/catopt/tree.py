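"""Committed limited-lookahead OPT trees and posterior inference.

The builder starts from the whole sample space and, at every region, weighs
stopping against the (at most ``p``) suboptimal splits.  Weights are the
summands of the lookahead likelihood

    stop:     ρ Φ0(A)
    split i:  (1-ρ)/p · B(N1+α, N2+α)/B(α,α) · Φ_{h-1}(A_i1) Φ_{h-1}(A_i2)

With ``q = 1`` the single best action is committed and the procedure recurses
into the committed children until a region is terminal or a stop is
committed.  The committed tree carries stopping probabilities
ρ(A|D) = ρ Φ0(A)/Φ(A) and split-selection probabilities, from which three
inference modes are derived:

* posterior-mean cell probabilities (deterministic; the default),
* the mode tree (the committed partition with Beta-mean mass allocation),
* random draws of a full distribution (Beta allocations and uniform-Dirichlet
  cell masses within stopped regions).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .likelihood import OPTParams, is_terminal, log_beta_weight, log_phi0, _log_phi
from .partition import MarginalSplitter, SplitOption, split_rows
from .space import FactorSpace, ObservationSet, Region
from .table import ProbabilityTable

__all__ = [
    "OPTNode",
    "OPTTree",
    "build_tree",
    "stopping_probability",
    "selection_probabilities",
    "expected_cell_probabilities",
    "sample_distribution",
    "mode_tree",
    "tree_to_dict",
    "tree_from_dict",
    "save_tree",
    "load_tree",
]


@dataclass
class OPTNode:
    """One region of the committed partition tree."""

    region: Region
    n: float
    log_phi: float
    log_phi0: float
    stop_prob: float
    terminal: bool
    committed_stop: bool
    depth: int
    split: SplitOption | None = None
    split_variables: list[int] = field(default_factory=list)
    selection_probs: np.ndarray | None = None
    children: list["OPTNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class OPTTree:
    """A committed partition tree with the parameters that built it."""

    root: OPTNode
    space: FactorSpace
    params: OPTParams
    n_nodes: int
    max_depth: int

    def iter_nodes(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(node.children)

    def leaves(self):
        return [node for node in self.iter_nodes() if node.is_leaf]


def build_tree(
    obs: ObservationSet,
    params: OPTParams | None = None,
    splitter=None,
) -> OPTTree:
    """Build the committed lookahead tree (deterministic for the default
    splitter; reproducible under the splitter's seed otherwise)."""
    if params is None:
        params = OPTParams()
    if splitter is None:
        splitter = MarginalSplitter()
    if obs.total_weight <= 0:
        raise ValueError("observations carry no weight")

    space = obs.space
    p_whole = space.n_variables
    log_rho = math.log(params.rho)
    log_w = math.log1p(-params.rho) - math.log(p_whole)
    budget = [2_000_000_000]
    h = params.lookahead_h

    root_region = space.whole_region()
    all_rows = np.arange(obs.n_rows, dtype=np.int64)

    counters = {"nodes": 0, "max_depth": 0}

    def make_node(region: Region, rows: np.ndarray, depth: int) -> OPTNode:
        counters["nodes"] += 1
        counters["max_depth"] = max(counters["max_depth"], depth)
        n = float(obs.weights[rows].sum())
        c = region.cell_count
        lp0 = log_phi0(c, n)
        if is_terminal(region, n=n):
            return OPTNode(
                region=region,
                n=n,
                log_phi=lp0,
                log_phi0=lp0,
                stop_prob=1.0,
                terminal=True,
                committed_stop=False,
                depth=depth,
            )

        options = splitter.candidates(region, obs, rows)
        stop_lw = log_rho + lp0
        opt_lws: list[float] = []
        opt_rows: list[tuple[np.ndarray, np.ndarray]] = []
        for opt in options:
            lb = log_beta_weight(opt.n_left, opt.n_right, params.alpha)
            if h - 1 == 0:
                ll = log_phi0(opt.left.cell_count, opt.n_left)
                lr = log_phi0(opt.right.cell_count, opt.n_right)
                opt_rows.append((None, None))
            else:
                rows_l, rows_r = split_rows(obs, rows, opt)
                ll = _log_phi(
                    opt.left, obs, rows_l, params, h - 1, splitter, budget
                )
                lr = _log_phi(
                    opt.right, obs, rows_r, params, h - 1, splitter, budget
                )
                opt_rows.append((rows_l, rows_r))
            opt_lws.append(log_w + lb + ll + lr)

        all_lws = [stop_lw] + opt_lws
        lphi = float(logsumexp(all_lws))
        stop_prob = float(min(1.0, math.exp(stop_lw - lphi)))
        if opt_lws:
            sel = np.exp(np.asarray(opt_lws) - logsumexp(opt_lws))
            sel /= sel.sum()
        else:
            sel = None

        node = OPTNode(
            region=region,
            n=n,
            log_phi=lphi,
            log_phi0=lp0,
            stop_prob=stop_prob,
            terminal=False,
            committed_stop=False,
            depth=depth,
            split_variables=[o.variable for o in options],
            selection_probs=sel,
        )

        best = int(np.argmax(opt_lws)) if opt_lws else -1
        if not opt_lws or stop_lw >= opt_lws[best]:
            # committing a stop: ties favour the simpler model
            node.committed_stop = True
            return node

        opt = options[best]
        rows_l, rows_r = opt_rows[best]
        if rows_l is None:
            rows_l, rows_r = split_rows(obs, rows, opt)
        node.split = opt
        node.children = [
            make_node(opt.left, rows_l, depth + 1),
            make_node(opt.right, rows_r, depth + 1),
        ]
        return node

    # the committed tree can be deep; avoid Python's default recursion cap
    import sys

    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, 100_000))
    try:
        root = make_node(root_region, all_rows, 0)
    finally:
        sys.setrecursionlimit(old_limit)

    return OPTTree(
        root=root,
        space=space,
        params=params,
        n_nodes=counters["nodes"],
        max_depth=counters["max_depth"],
    )


def stopping_probability(node: OPTNode) -> float:
    """ρ(A|D) = ρ Φ0(A)/Φ(A); 1 at terminal regions."""
    return node.stop_prob


def selection_probabilities(node: OPTNode) -> np.ndarray:
    """Normalized split-selection probabilities over the node's options."""
    if node.selection_probs is None:
        raise ValueError("node has no split option")
    return node.selection_probs


def _allocation_means(node: OPTNode, alpha: float) -> tuple[float, float]:
    """Posterior-mean mass shares of the committed children: Beta means."""
    opt = node.split
    denom = node.n + 2 * alpha
    return (opt.n_left + alpha) / denom, (opt.n_right + alpha) / denom


def expected_cell_probabilities(tree: OPTTree) -> ProbabilityTable:
    """Posterior-mean probability of every combination cell.

    Deterministic recursion on the committed tree: each region mixes its
    stop branch (mass spread uniformly over C(A) cells — the symmetric
    Dirichlet extension has mean 1/C(A) regardless of β) with the committed
    split branch, whose children receive Beta-mean allocations
    (N_child + α)/(N + 2α) of the continue mass.
    """
    alpha = tree.params.alpha
    blocks: list[tuple[Region, float]] = []
    stack = [(tree.root, 1.0)]
    while stack:
        node, mass = stack.pop()
        if mass <= 0.0:
            continue
        if node.is_leaf:
            blocks.append((node.region, mass))
            continue
        blocks.append((node.region, node.stop_prob * mass))
        go = (1.0 - node.stop_prob) * mass
        th_l, th_r = _allocation_means(node, alpha)
        stack.append((node.children[0], go * th_l))
        stack.append((node.children[1], go * th_r))
    return ProbabilityTable(tree.space, blocks=blocks)


def mode_tree(tree: OPTTree) -> tuple[list[Region], ProbabilityTable]:
    """The maximum-posterior partition and its cell probabilities.

    The committed structure *is* the per-node argmax between stopping and
    splitting (the commit rule compares exactly the ρΦ0 term against the
    split terms of Φ), so the mode partition is the committed tree's leaf
    set.  Leaf masses follow the Beta-mean allocations down the tree and are
    spread uniformly within each leaf.
    """
    alpha = tree.params.alpha
    regions: list[Region] = []
    blocks: list[tuple[Region, float]] = []
    stack = [(tree.root, 1.0)]
    while stack:
        node, mass = stack.pop()
        if node.is_leaf:
            regions.append(node.region)
            blocks.append((node.region, mass))
            continue
        th_l, th_r = _allocation_means(node, alpha)
        stack.append((node.children[0], mass * th_l))
        stack.append((node.children[1], mass * th_r))
    return regions, ProbabilityTable(tree.space, blocks=blocks)


def sample_distribution(
    tree: OPTTree,
    seed: int | np.random.Generator,
    max_cells: int = 200_000,
) -> ProbabilityTable:
    """One random distribution drawn from the posterior OPT.

    Walks the committed tree: each non-leaf region stops with probability
    ρ(A|D), otherwise allocates its mass to the committed children with a
    Dirichlet(N1+α, N2+α) draw (equivalently θ1/(θ1+θ2) ~ Beta); a region
    that stops draws per-cell masses from the symmetric
    Dirichlet(N/C+β, ..., N/C+β).
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    alpha, beta = tree.params.alpha, tree.params.beta
    codes_parts: list[np.ndarray] = []
    probs_parts: list[np.ndarray] = []

    def stop_here(region: Region, n: float, mass: float) -> None:
        c = region.cell_count
        if sum(cc.shape[0] for cc in codes_parts) + c > max_cells:
            raise ValueError(
                f"sampled table would exceed {max_cells} explicit cells; "
                "raise max_cells or sample on a smaller space"
            )
        theta = rng.dirichlet(np.full(c, n / c + beta))
        codes_parts.append(region.all_cells(max_cells=max_cells))
        probs_parts.append(mass * theta)

    stack = [(tree.root, 1.0)]
    while stack:
        node, mass = stack.pop()
        if node.is_leaf or rng.random() < node.stop_prob:
            stop_here(node.region, node.n, mass)
            continue
        opt = node.split
        th = rng.dirichlet([opt.n_left + alpha, opt.n_right + alpha])
        stack.append((node.children[0], mass * th[0]))
        stack.append((node.children[1], mass * th[1]))

    return ProbabilityTable(
        tree.space,
        cell_codes=np.concatenate(codes_parts, axis=0),
        cell_probs=np.concatenate(probs_parts),
    )


# ------------------------------------------------------------- serialization

def _node_to_dict(node: OPTNode, space: FactorSpace) -> dict:
    d = {
        "n": node.n,
        "log_phi": node.log_phi,
        "log_phi0": node.log_phi0,
        "stop_prob": node.stop_prob,
        "terminal": node.terminal,
        "committed_stop": node.committed_stop,
        "region": [list(node.region.subset_labels(i)) for i in range(space.n_variables)],
    }
    if node.selection_probs is not None:
        d["selection_probs"] = {
            space.variable_names[v]: float(pr)
            for v, pr in zip(node.split_variables, node.selection_probs)
        }
    if node.split is not None:
        d["split"] = {
            "variable": space.variable_names[node.split.variable],
            "left_labels": list(node.split.left.subset_labels(node.split.variable)),
            "s": node.split.s,
            "t_value": node.split.t_value,
        }
        d["children"] = [_node_to_dict(c, space) for c in node.children]
    return d


def tree_to_dict(tree: OPTTree) -> dict:
    return {
        "space": {
            "variable_names": list(tree.space.variable_names),
            "categories": [list(c) for c in tree.space.categories],
        },
        "params": {
            "rho": tree.params.rho,
            "alpha": tree.params.alpha,
            "beta": tree.params.beta,
            "lookahead_h": tree.params.lookahead_h,
            "commit_q": tree.params.commit_q,
        },
        "n_nodes": tree.n_nodes,
        "max_depth": tree.max_depth,
        "root": _node_to_dict(tree.root, tree.space),
    }


def _node_from_dict(d: dict, space: FactorSpace, depth: int) -> OPTNode:
    region = Region.from_labels(space, d["region"])
    node = OPTNode(
        region=region,
        n=float(d["n"]),
        log_phi=float(d["log_phi"]),
        log_phi0=float(d["log_phi0"]),
        stop_prob=float(d["stop_prob"]),
        terminal=bool(d["terminal"]),
        committed_stop=bool(d["committed_stop"]),
        depth=depth,
    )
    if "selection_probs" in d:
        items = list(d["selection_probs"].items())
        node.split_variables = [space.variable_names.index(k) for k, _ in items]
        node.selection_probs = np.array([v for _, v in items])
    if "split" in d:
        var = space.variable_names.index(d["split"]["variable"])
        left_idx = np.sort([space.index_of(var, lab) for lab in d["split"]["left_labels"]])
        right_idx = np.sort(
            np.setdiff1d(region.subsets[var], left_idx, assume_unique=True)
        )
        children = [_node_from_dict(c, space, depth + 1) for c in d["children"]]
        node.split = SplitOption(
            variable=var,
            left=region.replace(var, left_idx),
            right=region.replace(var, right_idx),
            n_left=children[0].n,
            n_right=children[1].n,
            s=d["split"].get("s"),
            t_value=d["split"].get("t_value"),
        )
        node.children = children
    return node


def tree_from_dict(d: dict) -> OPTTree:
    space = FactorSpace(
        d["space"]["variable_names"], d["space"]["categories"]
    )
    params = OPTParams(**d["params"])
    root = _node_from_dict(d["root"], space, 0)
    return OPTTree(
        root=root,
        space=space,
        params=params,
        n_nodes=int(d["n_nodes"]),
        max_depth=int(d["max_depth"]),
    )


def save_tree(tree: OPTTree, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(tree_to_dict(tree), fh)


def load_tree(path) -> OPTTree:
    with open(path, "r", encoding="utf-8") as fh:
        return tree_from_dict(json.load(fh))
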