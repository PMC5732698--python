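"""Hypergeometric pathway (gene-set) over-representation with
Benjamini-Hochberg FDR control."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from phosphonet.errors import ParameterError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class PathwayDB:
    """Pathway id -> (name, member set), plus an optional parent->child
    hierarchy over pathway ids."""

    pathways: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)
    hierarchy: list[tuple[str, str]] = field(default_factory=list)

    def members(self, pathway_id: str) -> frozenset[str]:
        return self.pathways[pathway_id][1]

    def name(self, pathway_id: str) -> str:
        return self.pathways[pathway_id][0]

    def __len__(self) -> int:
        return len(self.pathways)

    def validate_hierarchy(self) -> None:
        for parent, child in self.hierarchy:
            for pid in (parent, child):
                if pid not in self.pathways:
                    raise ValidationError(f"hierarchy references unknown pathway {pid!r}")


@dataclass
class EnrichmentResult:
    pathway_id: str
    name: str
    hits: frozenset[str]
    n_hits: int
    n_members: int  # members within the universe
    p_value: float
    q_value: float = float("nan")
    significant: bool = False


def load_gmt(path) -> PathwayDB:
    """Standard GMT: tab-separated ``id  description  member...`` lines.
    Duplicate members within a line are deduplicated; duplicate pathway ids
    are an error."""
    db = PathwayDB()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(
                    f"{path} line {lineno}: GMT line needs >= 3 fields"
                )
            pid, name, members = parts[0], parts[1], parts[2:]
            if pid in db.pathways:
                raise ValidationError(f"{path} line {lineno}: duplicate pathway id {pid!r}")
            member_set = frozenset(m for m in members if m)
            if not member_set:
                raise ValidationError(f"{path} line {lineno}: pathway {pid!r} has no members")
            db.pathways[pid] = (name, member_set)
    return db


def load_hierarchy(path, db: PathwayDB | None = None) -> list[tuple[str, str]]:
    """Two-column TSV of parent_id, child_id pairs; validated against the
    pathway db when given."""
    df = pd.read_csv(path, sep="\t", header=None, names=["parent", "child"], dtype=str)
    pairs = [(str(p), str(c)) for p, c in zip(df["parent"], df["child"])]
    if db is not None:
        for parent, child in pairs:
            for pid in (parent, child):
                if pid not in db.pathways:
                    raise ValidationError(f"hierarchy references unknown pathway {pid!r}")
        db.hierarchy = pairs
    return pairs


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values:
    q_(i) = min_{j >= i} m * p_(j) / j, clipped to [0, 1]."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def enrich(
    query: Iterable[str],
    db: PathwayDB,
    universe: Iterable[str],
    fdr: float = 0.01,
    min_members: int = 3,
) -> list[EnrichmentResult]:
    """One-sided hypergeometric over-representation test per pathway.

    Members outside the universe are ignored; query proteins outside the
    universe are dropped with a warning. Pathways with fewer than
    ``min_members`` members inside the universe are skipped. Results carry
    BH q-values over all tested pathways and are sorted by (q, p, id).
    """
    if not 0 < fdr <= 1:
        raise ParameterError(f"fdr must be in (0, 1], got {fdr}")
    universe = set(universe)
    if not universe:
        raise ValidationError("empty universe")
    query = set(query)
    if not query:
        raise ValidationError("empty query")
    outside = query - universe
    if outside:
        logger.warning("enrich: dropping %d query protein(s) outside universe", len(outside))
        query &= universe
        if not query:
            raise ValidationError("no query protein inside the universe")

    N, n = len(universe), len(query)
    results: list[EnrichmentResult] = []
    n_skipped = 0
    for pid in sorted(db.pathways):
        name, members = db.pathways[pid]
        members_u = members & universe
        K = len(members_u)
        if K < min_members:
            n_skipped += 1
            continue
        hits = frozenset(query & members_u)
        x = len(hits)
        p = 1.0 if x == 0 else float(hypergeom.sf(x - 1, N, K, n))
        results.append(
            EnrichmentResult(
                pathway_id=pid,
                name=name,
                hits=hits,
                n_hits=x,
                n_members=K,
                p_value=p,
            )
        )
    if n_skipped:
        logger.info("enrich: skipped %d pathway(s) with < %d members in universe", n_skipped, min_members)
    if results:
        q = bh_fdr([r.p_value for r in results])
        for r, qv in zip(results, q):
            r.q_value = float(qv)
            r.significant = r.q_value <= fdr
    results.sort(key=lambda r: (r.q_value, r.p_value, r.pathway_id))
    return results


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pathway_id": r.pathway_id,
                "name": r.name,
                "n_members": r.n_members,
                "n_hits": r.n_hits,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "significant": r.significant,
                "hits": ",".join(sorted(r.hits)),
            }
            for r in results
        ]
    )
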