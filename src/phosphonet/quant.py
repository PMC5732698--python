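"""Replicate-level phosphosite quantitation statistics and regulation calls.

Builds the high-confidence (HC) and all-channel (QP) datasets from a
phosphopeptide quantitation table, computes per-site log2 comparison ratios
over replicates, classifies regulation against a symmetric log2 threshold,
applies the strict replicate/CI filter, and assigns intensity-binned outlier
p-values (asymmetric, side-specific spread).
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import erfc

from phosphonet.errors import ParameterError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

#: The four quantified conditions (reporter channels).
CONDITIONS = ("WT", "WT_FGF", "FUS", "FUS_FGF")

VALID_RESIDUES = frozenset("STY")

_SITE_RE = re.compile(r"^([A-Z])(\d+)$")


@dataclass(frozen=True)
class ComparisonDefinition:
    """A pairwise condition comparison; ratio = numerator / denominator.

    Orientation convention: the variant/stimulated condition is the
    numerator, so positive log2 ratios mean up-regulation in that condition.
    """

    id: str
    numerator: str
    denominator: str

    def __post_init__(self):
        for cond in (self.numerator, self.denominator):
            if cond not in CONDITIONS:
                raise ValidationError(f"unknown condition {cond!r}")


#: The three standard comparisons.
COMPARISONS: dict[str, ComparisonDefinition] = {
    "C1": ComparisonDefinition("C1", "FUS", "WT"),
    "C2": ComparisonDefinition("C2", "FUS_FGF", "WT_FGF"),
    "C3": ComparisonDefinition("C3", "WT_FGF", "WT"),
}


@dataclass
class PhosphoPeptideRecord:
    """One quantified phosphopeptide observation in one replicate."""

    peptide_id: str
    protein_accession: str
    gene_symbol: str
    sites: list[tuple[int, str]]  # (1-based position, residue S/T/Y)
    replicate_id: int
    intensities: dict[str, float]  # condition -> reporter intensity
    id_fdr: float
    total_intensity: float = 0.0
    context: str | None = None  # optional 11-mer around the (first) site

    def __post_init__(self):
        if not self.sites:
            raise ValidationError(f"{self.peptide_id}: empty site list")
        positions = [p for p, _ in self.sites]
        if any(p1 >= p2 for p1, p2 in zip(positions, positions[1:])):
            raise ValidationError(
                f"{self.peptide_id}: site positions must be strictly increasing"
            )
        for pos, res in self.sites:
            if res not in VALID_RESIDUES:
                raise ValidationError(
                    f"{self.peptide_id}: residue {res!r} at {pos} not in S/T/Y"
                )
        unknown = set(self.intensities) - set(CONDITIONS)
        if unknown:
            raise ValidationError(
                f"{self.peptide_id}: unknown condition(s) {sorted(unknown)}"
            )

    @property
    def site_key(self) -> str:
        """Composite key, e.g. ``CTTN(T401/S405)``. Multi-site peptides are
        kept as one composite key; sites are never split."""
        inner = "/".join(f"{res}{pos}" for pos, res in self.sites)
        return f"{self.protein_accession}({inner})"


@dataclass
class SiteQuantSummary:
    """Per-site, per-comparison ratio statistics and regulation call."""

    site_key: str
    protein_accession: str
    comparison_id: str
    replicate_log2_ratios: list[float]
    mu: float
    sigma: float
    ci_low: float
    ci_high: float
    mean_total_intensity: float
    regulation: str = "unchanged"  # up / down / unchanged
    strict: bool = False
    sigb_p: float | None = None
    sigb_flag: bool = False

    @property
    def n_replicates(self) -> int:
        return len(self.replicate_log2_ratios)


def parse_sites(text: str) -> list[tuple[int, str]]:
    """Parse a site annotation such as ``Y132`` or ``T401/S405``."""
    sites: list[tuple[int, str]] = []
    for chunk in str(text).strip().split("/"):
        m = _SITE_RE.match(chunk.strip())
        if not m:
            raise ValidationError(f"unparsable site string {chunk!r}")
        res, pos = m.group(1), int(m.group(2))
        if res not in VALID_RESIDUES:
            raise ValidationError(f"residue {res!r} not in S/T/Y")
        sites.append((pos, res))
    return sites


#: Default column mapping for quantitation tables.
DEFAULT_SCHEMA: dict[str, str] = {
    "peptide_id": "peptide_id",
    "protein": "protein",
    "gene": "gene",
    "sites": "sites",
    "replicate": "replicate",
    "WT": "WT",
    "WT_FGF": "WT_FGF",
    "FUS": "FUS",
    "FUS_FGF": "FUS_FGF",
    "id_fdr": "id_fdr",
    "total_intensity": "total_intensity",
    "context": "context",  # optional
}

_REQUIRED_SCHEMA_KEYS = (
    "peptide_id",
    "protein",
    "gene",
    "sites",
    "replicate",
    "WT",
    "WT_FGF",
    "FUS",
    "FUS_FGF",
    "id_fdr",
)


def load_quant_table(
    path, schema: Mapping[str, str] | None = None
) -> list[PhosphoPeptideRecord]:
    """Load a TSV quantitation table into phosphopeptide records.

    Missing intensity cells (empty or ``NA``) become absent entries in the
    record's intensity map. Rows whose site annotation cannot be parsed, or
    whose residues fall outside S/T/Y, abort the load with an error naming
    the offending row numbers (1-based, excluding the header).
    """
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)

    df = pd.read_csv(path, sep="\t", dtype={colmap["sites"]: str})
    missing = [
        colmap[key] for key in _REQUIRED_SCHEMA_KEYS if colmap[key] not in df.columns
    ]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    has_total = colmap["total_intensity"] in df.columns
    has_context = colmap["context"] in df.columns

    records: list[PhosphoPeptideRecord] = []
    bad_rows: list[tuple[int, str]] = []
    for idx, row in df.iterrows():
        rownum = int(idx) + 1
        try:
            sites = parse_sites(row[colmap["sites"]])
            intensities: dict[str, float] = {}
            for cond in CONDITIONS:
                val = row[colmap[cond]]
                if pd.notna(val):
                    intensities[cond] = float(val)
            total = (
                float(row[colmap["total_intensity"]])
                if has_total and pd.notna(row[colmap["total_intensity"]])
                else float(sum(intensities.values()))
            )
            context = None
            if has_context and pd.notna(row[colmap["context"]]):
                context = str(row[colmap["context"]])
            records.append(
                PhosphoPeptideRecord(
                    peptide_id=str(row[colmap["peptide_id"]]),
                    protein_accession=str(row[colmap["protein"]]),
                    gene_symbol=str(row[colmap["gene"]]),
                    sites=sites,
                    replicate_id=int(row[colmap["replicate"]]),
                    intensities=intensities,
                    id_fdr=float(row[colmap["id_fdr"]]),
                    total_intensity=total,
                    context=context,
                )
            )
        except ValidationError as exc:
            bad_rows.append((rownum, str(exc)))
    if bad_rows:
        detail = "; ".join(f"row {n}: {msg}" for n, msg in bad_rows[:20])
        raise ValidationError(f"{len(bad_rows)} invalid row(s): {detail}")
    return records


def build_hc_dataset(
    records: Iterable[PhosphoPeptideRecord], hc_fdr: float = 0.01
) -> list[PhosphoPeptideRecord]:
    """High-confidence dataset: stringent identification FDR, no
    channel-completeness requirement."""
    return [r for r in records if r.id_fdr <= hc_fdr]


def build_qp_dataset(
    records: Iterable[PhosphoPeptideRecord], qp_fdr: float = 0.05
) -> list[PhosphoPeptideRecord]:
    """Broad quantitation dataset: relaxed identification FDR but all four
    condition channels observed (> 0)."""
    return [
        r
        for r in records
        if r.id_fdr <= qp_fdr
        and all(r.intensities.get(c, 0.0) > 0.0 for c in CONDITIONS)
    ]


def summarise_comparison(
    records: Iterable[PhosphoPeptideRecord],
    comparison: ComparisonDefinition,
    threshold: float = 0.5,
    ci_multiplier: float = 1.96,
) -> list[SiteQuantSummary]:
    """Group records by composite site key and compute per-comparison
    replicate log2 ratios, mean, standard deviation and mu +/- 1.96 sigma
    interval.

    A record missing (or with non-positive) numerator or denominator
    intensity is skipped for this comparison. sigma is the sample standard
    deviation of the replicate log2 ratios, defined as 0 when only one
    replicate contributed.
    """
    groups: dict[str, list[PhosphoPeptideRecord]] = {}
    for rec in records:
        groups.setdefault(rec.site_key, []).append(rec)

    summaries: list[SiteQuantSummary] = []
    for site_key in sorted(groups):
        grp = groups[site_key]
        ratios: list[float] = []
        totals: list[float] = []
        for rec in grp:
            num = rec.intensities.get(comparison.numerator, 0.0)
            den = rec.intensities.get(comparison.denominator, 0.0)
            if num <= 0.0 or den <= 0.0:
                logger.debug(
                    "skip %s replicate %d for %s: missing/non-positive channel",
                    site_key,
                    rec.replicate_id,
                    comparison.id,
                )
                continue
            ratios.append(math.log2(num / den))
            totals.append(rec.total_intensity)
        if not ratios:
            continue
        mu = float(np.mean(ratios))
        sigma = float(np.std(ratios, ddof=1)) if len(ratios) > 1 else 0.0
        summary = SiteQuantSummary(
            site_key=site_key,
            protein_accession=grp[0].protein_accession,
            comparison_id=comparison.id,
            replicate_log2_ratios=ratios,
            mu=mu,
            sigma=sigma,
            ci_low=mu - ci_multiplier * sigma,
            ci_high=mu + ci_multiplier * sigma,
            mean_total_intensity=float(np.mean(totals)),
        )
        summary.regulation = classify_regulation(summary, threshold)
        summary.strict = strict_filter(summary)
        summaries.append(summary)
    return summaries


def classify_regulation(summary: SiteQuantSummary, threshold: float = 0.5) -> str:
    """Call up/down/unchanged at an inclusive symmetric log2 threshold."""
    if threshold < 0:
        raise ParameterError(f"threshold must be >= 0, got {threshold}")
    if summary.mu >= threshold:
        return "up"
    if summary.mu <= -threshold:
        return "down"
    return "unchanged"


def strict_filter(summary: SiteQuantSummary) -> bool:
    """True iff the site was seen in more than one replicate and its
    mu +/- 1.96 sigma interval excludes 0 on the log2 scale (i.e. excludes
    ratio 1 on the linear scale)."""
    if summary.n_replicates <= 1:
        return False
    return summary.ci_low > 0.0 or summary.ci_high < 0.0


def significance_b(
    summaries: Sequence[SiteQuantSummary], bin_size: int = 300
) -> list[SiteQuantSummary]:
    """Assign intensity-binned asymmetric outlier p-values.

    Sites are ordered by descending mean total intensity and partitioned into
    consecutive bins of ``bin_size`` (the remainder merges into the last
    bin; fewer than ``bin_size`` sites overall form a single bin). Within a
    bin the centre is the median of mu and the side-specific spreads are the
    distances from the median to the 15.87th / 84.13th percentiles. Each
    site gets z = (mu - m) / spread_on_its_side (signed) and
    p = erfc(z / sqrt(2)) / 2, the upper-tail probability: p < 0.5 for
    above-median sites, > 0.5 below, exactly 0.5 at the median. Under a
    symmetric null p is approximately uniform on (0, 1).

    Degenerate bins (zero spread on a side) yield p = 1 at the median and
    undefined (None) off-median values on that side.
    """
    if bin_size < 1:
        raise ParameterError(f"bin_size must be >= 1, got {bin_size}")
    if not summaries:
        return []
    order = sorted(
        range(len(summaries)),
        key=lambda i: (-summaries[i].mean_total_intensity, summaries[i].site_key),
    )
    n = len(order)
    n_bins = max(1, n // bin_size)
    for b in range(n_bins):
        start = b * bin_size
        end = (b + 1) * bin_size if b < n_bins - 1 else n
        idx = order[start:end]
        mus = np.array([summaries[i].mu for i in idx])
        lo, m, hi = np.percentile(mus, [15.87, 50.0, 84.13])
        spread_right = hi - m
        spread_left = m - lo
        for i in idx:
            s = summaries[i]
            delta = s.mu - m
            spread = spread_right if delta >= 0 else spread_left
            if spread <= 0.0:
                s.sigb_p = 1.0 if delta == 0.0 else None
                continue
            z = delta / spread
            s.sigb_p = float(erfc(z / math.sqrt(2.0)) / 2.0)
    return list(summaries)


def sigb_significant(summary: SiteQuantSummary, alpha: float = 0.05) -> bool:
    """Direction-aware outlier significance: upper tail for up-regulated
    sites, lower tail for down-regulated."""
    p = summary.sigb_p
    if p is None:
        return False
    if summary.mu >= 0:
        return p <= alpha
    return p >= 1.0 - alpha


def select_significant_sites(
    summaries: Sequence[SiteQuantSummary],
    threshold: float = 0.5,
    sigb_alpha: float = 0.05,
) -> list[SiteQuantSummary]:
    """Sites that are both substantially (|mu| >= threshold) and
    significantly (strict replicate/CI filter) regulated, annotated with the
    outlier-test flag and sorted by |mu| descending."""
    selected = []
    for s in summaries:
        if s.regulation == "unchanged" or not s.strict:
            continue
        s.sigb_flag = sigb_significant(s, sigb_alpha)
        selected.append(s)
    selected.sort(key=lambda s: (-abs(s.mu), s.site_key))
    return selected


def hc_qp_protein_overlap(
    hc_records: Iterable[PhosphoPeptideRecord],
    qp_records: Iterable[PhosphoPeptideRecord],
    denominator: str = "union",
) -> float | None:
    """Percentage of proteins identified in both datasets.

    ``denominator`` is ``union`` (Jaccard-style, default) or ``hc``.
    Returns None when both datasets are empty.
    """
    hc = {r.protein_accession for r in hc_records}
    qp = {r.protein_accession for r in qp_records}
    if not hc and not qp:
        return None
    common = hc & qp
    if denominator == "union":
        denom = len(hc | qp)
    elif denominator == "hc":
        if not hc:
            return None
        denom = len(hc)
    else:
        raise ParameterError(f"unknown denominator {denominator!r}")
    return 100.0 * len(common) / denom


def site_report_frame(summaries: Sequence[SiteQuantSummary]) -> pd.DataFrame:
    """Tabular site report (one row per site/comparison)."""
    return pd.DataFrame(
        [
            {
                "site_key": s.site_key,
                "comparison": s.comparison_id,
                "n_replicates": s.n_replicates,
                "mu": s.mu,
                "sigma": s.sigma,
                "ci_low": s.ci_low,
                "ci_high": s.ci_high,
                "regulation": s.regulation,
                "strict": s.strict,
                "sigb_p": s.sigb_p,
                "sigb_flag": s.sigb_flag,
            }
            for s in summaries
        ]
    )


def write_site_report(summaries: Sequence[SiteQuantSummary], path) -> None:
    site_report_frame(summaries).to_csv(path, sep="\t", index=False)
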