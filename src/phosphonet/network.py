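"""Signalling-network loading, tissue-expression filtering, seed mapping and
effective sub-network extraction."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from phosphonet.errors import ParameterError, ValidationError

logger = logging.getLogger(__name__)

#: Ordinal expression levels, lowest to highest.
EXPRESSION_LEVELS = ("NotDetected", "Low", "Medium", "High")
_LEVEL_RANK = {name: i for i, name in enumerate(EXPRESSION_LEVELS)}


@dataclass
class SignallingNetwork:
    """Undirected simple protein graph with optional per-tissue expression
    annotations (protein -> tissue -> ordinal level)."""

    graph: nx.Graph
    expression: dict[str, dict[str, str]] = field(default_factory=dict)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def __contains__(self, node: str) -> bool:
        return node in self.graph

    def number_of_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class SeedMappingReport:
    """Partition of a seed set against the unfiltered and filtered networks."""

    mapped: set[str]
    unmapped_filtered: set[str]  # removed by the tissue filter
    unmapped_absent: set[str]  # never in the network

    @property
    def n_mapped(self) -> int:
        return len(self.mapped)


def load_network(path) -> SignallingNetwork:
    """Load an undirected edge list (2-column TSV, or SIF with the relation
    in the middle column). Duplicate edges are collapsed and self-loops
    dropped (with a logged count)."""
    path = Path(path)
    graph = nx.Graph()
    n_self = 0
    n_lines = 0
    is_sif = path.suffix.lower() == ".sif"
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if is_sif:
                if len(parts) < 3:
                    logger.warning("%s line %d: short SIF line skipped", path, lineno)
                    continue
                pairs = [(parts[0], t) for t in parts[2:]]
            else:
                if len(parts) < 2:
                    logger.warning("%s line %d: dangling row skipped", path, lineno)
                    continue
                pairs = [(parts[0], parts[1])]
            for a, b in pairs:
                n_lines += 1
                if a == b:
                    n_self += 1
                    continue
                graph.add_edge(a, b)
    if n_lines == 0:
        raise ValidationError(f"{path}: no edges found")
    if n_self:
        logger.info("%s: dropped %d self-loop(s)", path, n_self)
    return SignallingNetwork(graph=graph)


def load_expression(path) -> pd.DataFrame:
    """Expression table: columns protein, tissue, level."""
    df = pd.read_csv(path, sep="\t")
    required = {"protein", "tissue", "level"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"expression table missing column(s): {sorted(missing)}")
    bad = set(df["level"]) - set(EXPRESSION_LEVELS)
    if bad:
        raise ValidationError(f"unknown expression level(s): {sorted(bad)}")
    return df


def attach_expression(network: SignallingNetwork, table: pd.DataFrame) -> None:
    """Attach per-tissue levels to the network (in place)."""
    expr: dict[str, dict[str, str]] = {}
    for protein, tissue, level in table[["protein", "tissue", "level"]].itertuples(
        index=False
    ):
        expr.setdefault(str(protein), {})[str(tissue)] = str(level)
    network.expression = expr


def tissue_filter(
    network: SignallingNetwork,
    expression: pd.DataFrame,
    tissues: Iterable[str],
    min_level: str = "Low",
) -> SignallingNetwork:
    """Remove nodes with no evidence of expression in any listed tissue.

    A node is retained iff it reaches ``min_level`` or higher in at least one
    listed tissue, or has no entry at all in the expression table
    (retain-unknowns policy: removal requires positive evidence of absence).
    Removed nodes take their incident edges with them.
    """
    tissues = list(tissues)
    if not tissues:
        raise ParameterError("tissues must be non-empty")
    if min_level not in _LEVEL_RANK:
        raise ParameterError(f"unknown level {min_level!r}; use {EXPRESSION_LEVELS}")
    known_tissues = set(expression["tissue"])
    unknown = [t for t in tissues if t not in known_tissues]
    if unknown:
        raise ValidationError(
            f"tissue(s) {unknown} not in expression table; known: {sorted(known_tissues)}"
        )

    min_rank = _LEVEL_RANK[min_level]
    sub = expression[expression["tissue"].isin(tissues)]
    levels: dict[str, int] = {}
    for protein, level in sub[["protein", "level"]].itertuples(index=False):
        rank = _LEVEL_RANK[str(level)]
        key = str(protein)
        levels[key] = max(levels.get(key, -1), rank)

    n_no_data = 0
    keep = []
    for node in network.graph.nodes:
        if node not in levels:
            n_no_data += 1
            keep.append(node)
        elif levels[node] >= min_rank:
            keep.append(node)
    logger.info(
        "tissue_filter: kept %d/%d nodes (%d without expression data)",
        len(keep),
        network.graph.number_of_nodes(),
        n_no_data,
    )
    filtered = SignallingNetwork(graph=network.graph.subgraph(keep).copy())
    if network.expression:
        filtered.expression = {
            n: network.expression[n] for n in keep if n in network.expression
        }
    else:
        attach_expression(filtered, expression)
    return filtered


def map_seeds(
    seeds: Iterable[str],
    unfiltered: SignallingNetwork,
    filtered: SignallingNetwork,
) -> SeedMappingReport:
    """Classify each seed as mapped (on the filtered network), filtered out
    (on the unfiltered network only) or absent (never in the network)."""
    seeds = set(seeds)
    mapped = {s for s in seeds if s in filtered}
    filtered_out = {s for s in seeds - mapped if s in unfiltered}
    absent = seeds - mapped - filtered_out
    return SeedMappingReport(
        mapped=mapped, unmapped_filtered=filtered_out, unmapped_absent=absent
    )


def effective_network(
    network: SignallingNetwork,
    seeds: Iterable[str],
    method: str = "neighbours",
    restart: float = 0.5,
    mass_threshold: float = 1e-4,
) -> SignallingNetwork:
    """Sub-network focused on the seeds.

    ``neighbours`` (default): induced subgraph on seeds plus their first
    network neighbours. ``diffusion``: random-walk-with-restart variant —
    nodes whose steady-state visiting mass is at least ``mass_threshold``
    are kept (seeds always kept).
    """
    seeds = set(seeds)
    on_net = seeds & network.nodes
    if not on_net:
        raise ValidationError("no seed is present on the network")
    if seeds - on_net:
        logger.warning(
            "effective_network: %d seed(s) not on network ignored", len(seeds - on_net)
        )
    if method == "neighbours":
        keep = set(on_net)
        for s in on_net:
            keep.update(network.graph.neighbors(s))
    elif method == "diffusion":
        if not 0.0 < restart < 1.0:
            raise ParameterError("restart must be in (0, 1)")
        personalization = {n: (1.0 if n in on_net else 0.0) for n in network.graph}
        mass = nx.pagerank(
            network.graph, alpha=1.0 - restart, personalization=personalization
        )
        keep = {n for n, m in mass.items() if m >= mass_threshold} | on_net
    else:
        raise ParameterError(f"unknown method {method!r}")
    sub = SignallingNetwork(graph=network.graph.subgraph(keep).copy())
    sub.expression = {
        n: network.expression[n] for n in keep if n in network.expression
    }
    return sub


def load_id_mapping(path) -> dict[str, str]:
    """Two-column TSV mapping (e.g. accession -> gene symbol)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["src", "dst"], dtype=str)
    return dict(zip(df["src"], df["dst"]))
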