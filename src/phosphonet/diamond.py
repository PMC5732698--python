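"""Iterative disease-module expansion by hypergeometric connectivity
significance.

At each iteration every candidate node adjacent to the current module is
scored by the tail probability of observing at least its number of links to
the module, given its degree, the module size and the network size; the most
significant node joins the module. Ties break deterministically: larger
links-to-module, then larger degree, then lexicographically smallest id.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import numpy as np
from scipy.stats import hypergeom

from phosphonet.errors import ParameterError, ValidationError
from phosphonet.network import SignallingNetwork


@dataclass(frozen=True)
class AddedNode:
    rank: int
    node: str
    p_value: float
    degree: int  # degree k at addition time
    ks: int  # links to the module at addition time


@dataclass
class ModuleExpansion:
    seeds: frozenset[str]
    added_nodes: list[AddedNode]

    @property
    def final_set(self) -> set[str]:
        return set(self.seeds) | {a.node for a in self.added_nodes}


def connectivity_pvalue(k: int, ks: int, N: int, s: int) -> float:
    """P(X >= ks) for X ~ Hypergeometric(N, s, k): the chance that a node of
    degree ``k`` has at least ``ks`` of its neighbours inside a module of
    size ``s`` drawn from ``N`` nodes."""
    if not (0 <= ks <= min(k, s) <= N):
        raise ParameterError(
            f"require 0 <= ks <= min(k, s) <= N, got k={k} ks={ks} N={N} s={s}"
        )
    if ks == 0:
        return 1.0
    return float(hypergeom.sf(ks - 1, N, s, k))


def diamond_expand(
    network: SignallingNetwork | nx.Graph,
    seeds: Iterable[str],
    n_iter: int = 200,
    alpha: int = 1,
) -> ModuleExpansion:
    """Expand a seed set by ``n_iter`` most-connectivity-significant nodes.

    ``alpha`` > 1 up-weights links to the *original* seeds: each such link
    (and each original seed) is counted ``alpha`` times, with the degree and
    network size adjusted accordingly so the hypergeometric bounds stay
    valid. ``alpha`` = 1 is the plain algorithm.

    Stops early only if no candidate with a module link remains. The
    returned per-node degree/links values are the unweighted counts at the
    iteration of addition.
    """
    graph = network.graph if isinstance(network, SignallingNetwork) else network
    if n_iter < 1:
        raise ParameterError(f"n_iter must be >= 1, got {n_iter}")
    if alpha < 1:
        raise ParameterError(f"alpha must be >= 1, got {alpha}")
    seeds = set(seeds)
    if not seeds:
        raise ValidationError("cannot expand empty module")
    off = seeds - set(graph.nodes)
    on = seeds & set(graph.nodes)
    if not on:
        raise ValidationError("no seed is present on the network")
    if off:
        import logging

        logging.getLogger(__name__).warning(
            "diamond_expand: ignoring %d off-network seed(s)", len(off)
        )

    N = graph.number_of_nodes()
    s0 = len(on)
    degree = dict(graph.degree())
    module = set(on)

    # links to original seeds / to added nodes, tracked separately so the
    # seed weighting applies only to the former
    ks_seed: dict[str, int] = {}
    ks_added: dict[str, int] = {}
    for seed in on:
        for nb in graph.neighbors(seed):
            if nb not in module:
                ks_seed[nb] = ks_seed.get(nb, 0) + 1

    added: list[AddedNode] = []
    N_w = N + (alpha - 1) * s0
    for rank in range(1, n_iter + 1):
        candidates = [n for n in ks_seed.keys() | ks_added.keys() if n not in module]
        candidates = [
            n for n in candidates if ks_seed.get(n, 0) + ks_added.get(n, 0) >= 1
        ]
        if not candidates:
            break
        s_w = alpha * s0 + len(added)
        ks_arr = np.empty(len(candidates), dtype=np.int64)
        k_arr = np.empty(len(candidates), dtype=np.int64)
        for i, n in enumerate(candidates):
            kseed = ks_seed.get(n, 0)
            kadd = ks_added.get(n, 0)
            ks_arr[i] = alpha * kseed + kadd
            k_arr[i] = degree[n] + (alpha - 1) * kseed
        pvals = hypergeom.sf(ks_arr - 1, N_w, s_w, k_arr)
        best_i = min(
            range(len(candidates)),
            key=lambda i: (pvals[i], -ks_arr[i], -k_arr[i], candidates[i]),
        )
        best = candidates[best_i]
        added.append(
            AddedNode(
                rank=rank,
                node=best,
                p_value=float(pvals[best_i]),
                degree=degree[best],
                ks=ks_seed.get(best, 0) + ks_added.get(best, 0),
            )
        )
        module.add(best)
        for nb in graph.neighbors(best):
            if nb not in module:
                ks_added[nb] = ks_added.get(nb, 0) + 1
    return ModuleExpansion(seeds=frozenset(on), added_nodes=added)


def expansion_frame(expansion: ModuleExpansion):
    """Tabular view (rank, node, degree, ks, p_value)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "rank": a.rank,
                "node": a.node,
                "degree": a.degree,
                "ks": a.ks,
                "p_value": a.p_value,
            }
            for a in expansion.added_nodes
        ]
    )
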