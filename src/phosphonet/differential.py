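"""Condition-unique, shared and differentially-regulated shared pathways,
plus pathway-protein graph export and local phospho-signalling context."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from phosphonet.enrichment import PathwayDB
from phosphonet.errors import ParameterError, ValidationError
from phosphonet.network import SignallingNetwork
from phosphonet.seeds import KinasePrediction

logger = logging.getLogger(__name__)


@dataclass
class SharedDifferentialEntry:
    pathway_id: str
    hits_a: int
    hits_b: int
    direction: str  # "A" or "B"


@dataclass
class DifferentialPathwayReport:
    comparison_a: str
    comparison_b: str
    unique_a: set[str] = field(default_factory=set)
    unique_b: set[str] = field(default_factory=set)
    shared: set[str] = field(default_factory=set)
    hc_validated_unique_a: set[str] = field(default_factory=set)
    hc_validated_unique_b: set[str] = field(default_factory=set)
    shared_differential: list[SharedDifferentialEntry] = field(default_factory=list)
    # pathway id -> protein -> confidence tier (HC / QP / network-only)
    protein_tiers: dict[str, dict[str, str]] = field(default_factory=dict)


def set_ops(
    pathways_a: Iterable[str], pathways_b: Iterable[str]
) -> tuple[set[str], set[str], set[str]]:
    """(A - B, B - A, A & B) on significant-pathway id sets."""
    a, b = set(pathways_a), set(pathways_b)
    return a - b, b - a, a & b


def hc_filter(
    pathway_hits: Mapping[str, Iterable[str]], hc_proteins: Iterable[str]
) -> set[str]:
    """Keep pathways whose hit list contains at least one high-confidence
    protein."""
    hc = set(hc_proteins)
    return {pid for pid, hits in pathway_hits.items() if hc & set(hits)}


def shared_differential(
    shared: Iterable[str],
    hits_a: Mapping[str, int],
    hits_b: Mapping[str, int],
    fraction: float = 0.25,
) -> list[SharedDifferentialEntry]:
    """Shared pathways with at least ``fraction`` (default 25%) more protein
    hits in one condition than the other (inclusive inequality; a pathway
    hit only in one condition flags that condition)."""
    if fraction < 0:
        raise ParameterError(f"fraction must be >= 0, got {fraction}")
    entries: list[SharedDifferentialEntry] = []
    for pid in sorted(shared):
        na = int(hits_a.get(pid, 0))
        nb = int(hits_b.get(pid, 0))
        if na < 0 or nb < 0:
            raise ParameterError(f"negative hit count for {pid}")
        if na > nb and na >= (1.0 + fraction) * nb:
            entries.append(SharedDifferentialEntry(pid, na, nb, "A"))
        elif nb > na and nb >= (1.0 + fraction) * na:
            entries.append(SharedDifferentialEntry(pid, na, nb, "B"))
    return entries


def assign_protein_tiers(
    proteins: Iterable[str],
    hc_proteins: Iterable[str],
    qp_proteins: Iterable[str],
) -> dict[str, str]:
    """Confidence tier per protein: HC > QP > network-only."""
    hc, qp = set(hc_proteins), set(qp_proteins)
    tiers = {}
    for p in proteins:
        if p in hc:
            tiers[p] = "HC"
        elif p in qp:
            tiers[p] = "QP"
        else:
            tiers[p] = "network-only"
    return tiers


def build_report(
    comparison_a: str,
    comparison_b: str,
    significant_a: Iterable[str],
    significant_b: Iterable[str],
    hits_a: Mapping[str, Iterable[str]],
    hits_b: Mapping[str, Iterable[str]],
    hc_proteins: Iterable[str],
    qp_proteins: Iterable[str],
    fraction: float = 0.25,
) -> DifferentialPathwayReport:
    """Full differential classification from two enrichment outcomes."""
    unique_a, unique_b, shared = set_ops(significant_a, significant_b)
    hc = set(hc_proteins)
    report = DifferentialPathwayReport(
        comparison_a=comparison_a,
        comparison_b=comparison_b,
        unique_a=unique_a,
        unique_b=unique_b,
        shared=shared,
    )
    report.hc_validated_unique_a = hc_filter(
        {pid: hits_a.get(pid, ()) for pid in unique_a}, hc
    )
    report.hc_validated_unique_b = hc_filter(
        {pid: hits_b.get(pid, ()) for pid in unique_b}, hc
    )
    report.shared_differential = shared_differential(
        shared,
        {pid: len(set(hits_a.get(pid, ()))) for pid in shared},
        {pid: len(set(hits_b.get(pid, ()))) for pid in shared},
        fraction,
    )
    for pid in sorted(unique_a | unique_b | shared):
        proteins = set(hits_a.get(pid, ())) | set(hits_b.get(pid, ()))
        report.protein_tiers[pid] = assign_protein_tiers(proteins, hc, qp_proteins)
    return report


def _pathway_class(report: DifferentialPathwayReport, pid: str) -> str:
    if pid in report.unique_a:
        return "unique_A"
    if pid in report.unique_b:
        return "unique_B"
    if any(e.pathway_id == pid for e in report.shared_differential):
        return "shared_differential"
    return "shared"


def export_pathway_graph(
    report: DifferentialPathwayReport,
    db: PathwayDB,
    regulation: Mapping[str, Mapping[str, str]] | None = None,
    include_shared: bool = False,
    graphml_path=None,
    edges_path=None,
) -> nx.Graph:
    """Bipartite pathway-protein graph with hierarchy edges.

    Pathway nodes carry their differential class; protein nodes their
    confidence tier and (optionally) per-comparison regulation direction.
    By default only unique and shared-differential pathways are included.
    Written as GraphML plus a flat TSV edge list when paths are given.
    """
    selected = set(report.unique_a) | set(report.unique_b) | {
        e.pathway_id for e in report.shared_differential
    }
    if include_shared:
        selected |= report.shared

    g = nx.Graph()
    for pid in sorted(selected):
        name = db.name(pid) if pid in db.pathways else pid
        g.add_node(pid, kind="pathway", name=name, pathway_class=_pathway_class(report, pid))
        for protein, tier in sorted(report.protein_tiers.get(pid, {}).items()):
            if protein not in g:
                attrs = {"kind": "protein", "confidence": tier}
                if regulation and protein in regulation:
                    for comp, direction in regulation[protein].items():
                        attrs[f"regulation_{comp}"] = direction
                g.add_node(protein, **attrs)
            g.add_edge(pid, protein, kind="hit")
    for parent, child in db.hierarchy:
        if parent in selected and child in selected:
            g.add_edge(parent, child, kind="hierarchy")
        elif (parent in selected) != (child in selected):
            logger.warning(
                "hierarchy edge %s-%s only partially in graph; skipped", parent, child
            )
    if graphml_path is not None:
        nx.write_graphml(g, graphml_path)
    if edges_path is not None:
        rows = [
            {"source": u, "target": v, "kind": d.get("kind", "")}
            for u, v, d in sorted(g.edges(data=True))
        ]
        pd.DataFrame(rows, columns=["source", "target", "kind"]).to_csv(
            edges_path, sep="\t", index=False
        )
    return g


def local_phospho_context(
    proteins: Iterable[str],
    effective_net: SignallingNetwork,
    retained_predictions: Sequence[KinasePrediction] = (),
    regulation: Mapping[str, Mapping[str, str]] | None = None,
) -> nx.Graph:
    """Induced subgraph on the given proteins, their retained predicted
    kinases and their first neighbours, annotated with kinase/substrate
    roles, predicted kinase->substrate edges and per-comparison regulation."""
    proteins = set(proteins)
    graph = effective_net.graph
    on_net = proteins & set(graph.nodes)
    if not on_net:
        raise ValidationError("none of the proteins is on the effective network")

    kin_by_substrate: dict[str, set[str]] = {}
    for p in retained_predictions:
        kin_by_substrate.setdefault(p.substrate, set()).add(p.kinase_id)

    keep = set(on_net)
    for prot in on_net:
        keep.update(graph.neighbors(prot))
        keep.update(k for k in kin_by_substrate.get(prot, ()) if k in graph)
    sub = graph.subgraph(keep).copy()

    substrates = {p.substrate for p in retained_predictions}
    kinases = {p.kinase_id for p in retained_predictions}
    for node in sub.nodes:
        roles = []
        if node in substrates or node in on_net:
            roles.append("substrate")
        if node in kinases:
            roles.append("kinase")
        sub.nodes[node]["role"] = "+".join(roles) if roles else "neighbour"
        if regulation and node in regulation:
            for comp, direction in regulation[node].items():
                sub.nodes[node][f"regulation_{comp}"] = direction
    for p in retained_predictions:
        if p.kinase_id in sub and p.substrate in sub:
            if sub.has_edge(p.kinase_id, p.substrate):
                sub.edges[p.kinase_id, p.substrate]["predicted_kinase_substrate"] = True
            else:
                sub.add_edge(
                    p.kinase_id, p.substrate, predicted_kinase_substrate=True
                )
    return sub


def report_frame(report: DifferentialPathwayReport, db: PathwayDB | None = None) -> pd.DataFrame:
    """Flat one-row-per-pathway view of the differential report."""
    diff_dir = {e.pathway_id: e for e in report.shared_differential}
    rows = []
    for pid in sorted(report.unique_a | report.unique_b | report.shared):
        cls = _pathway_class(report, pid)
        entry = diff_dir.get(pid)
        tiers = report.protein_tiers.get(pid, {})
        rows.append(
            {
                "pathway_id": pid,
                "name": db.name(pid) if db and pid in db.pathways else "",
                "class": cls,
                "hc_validated": (
                    pid in report.hc_validated_unique_a
                    or pid in report.hc_validated_unique_b
                ),
                "hits_a": entry.hits_a if entry else len(tiers),
                "hits_b": entry.hits_b if entry else len(tiers),
                "direction": entry.direction if entry else "",
                "proteins": ",".join(
                    f"{p}:{t}" for p, t in sorted(tiers.items())
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "pathway_id",
            "name",
            "class",
            "hc_validated",
            "hits_a",
            "hits_b",
            "direction",
            "proteins",
        ],
    )
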