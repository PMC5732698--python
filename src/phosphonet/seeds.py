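"""Substrate and kinase seed inference.

Substrate seeds are proteins with at least one phosphosite whose replicate
ratio interval (mu +/- 1.96 sigma) strictly excludes 0 on the log2 scale
(observed in more than one replicate). Kinase seeds come from per-site
kinase predictions scoring a motif likelihood ratio (position weight matrix
vs background) times a network-proximity likelihood ratio, keeping kinases
at or above the median combined score.
"""

from __future__ import annotations

import logging
import math
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from phosphonet.errors import ParameterError, ValidationError
from phosphonet.network import SignallingNetwork
from phosphonet.quant import SiteQuantSummary

logger = logging.getLogger(__name__)

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")
PAD = "_"  # terminus padding; contributes likelihood factor 1
MOTIF_POSITIONS = tuple(range(-5, 6))


@dataclass(frozen=True)
class KinasePrediction:
    """One (phosphosite, kinase) likelihood-ratio prediction."""

    site_key: str
    substrate: str  # protein carrying the site
    kinase_id: str
    motif_lr: float
    proximity_lr: float

    @property
    def combined_lr(self) -> float:
        return self.motif_lr * self.proximity_lr


@dataclass
class SeedSet:
    """Seed proteins for one comparison with per-member provenance
    (substrate / kinase / both)."""

    comparison_id: str
    members: set[str] = field(default_factory=set)
    provenance: dict[str, str] = field(default_factory=dict)

    def add(self, protein: str, role: str) -> None:
        if protein in self.provenance and self.provenance[protein] != role:
            self.provenance[protein] = "both"
        else:
            self.provenance[protein] = role
        self.members.add(protein)

    @property
    def substrates(self) -> set[str]:
        return {p for p, r in self.provenance.items() if r in ("substrate", "both")}

    @property
    def kinases(self) -> set[str]:
        return {p for p, r in self.provenance.items() if r in ("kinase", "both")}


@dataclass
class MotifModel:
    """Position weight matrix over positions -5..+5 with background
    frequencies."""

    kinase_id: str
    pwm: pd.DataFrame  # index: positions -5..5; columns: 20 amino acids
    background: Mapping[str, float] | None = None  # None -> uniform 0.05

    def prob(self, position: int, residue: str) -> float:
        return float(self.pwm.at[position, residue])

    def bg(self, residue: str) -> float:
        if self.background is None:
            return 0.05
        return float(self.background[residue])


def substrate_seeds(
    qp_summaries: Iterable[SiteQuantSummary], comparison_id: str
) -> SeedSet:
    """Proteins with >= 1 site seen in more than one replicate whose
    mu +/- 1.96 sigma interval strictly excludes 0 (no magnitude threshold
    is applied at this stage — the seeding rule is CI-only)."""
    seed_set = SeedSet(comparison_id=comparison_id)
    for s in qp_summaries:
        if s.comparison_id != comparison_id:
            continue
        if s.n_replicates > 1 and (s.ci_low > 0.0 or s.ci_high < 0.0):
            seed_set.add(s.protein_accession, "substrate")
    return seed_set


def motif_score(context: str, model: MotifModel) -> float:
    """Likelihood ratio of an 11-mer context under the model vs background.

    The context is centred on the phosphosite (position 0 = residue 6 of
    11); termini may be padded with ``_`` which contributes a factor of 1.
    """
    if len(context) != len(MOTIF_POSITIONS):
        raise ValidationError(
            f"context must be {len(MOTIF_POSITIONS)} residues, got {len(context)}"
        )
    lr = 1.0
    for pos, residue in zip(MOTIF_POSITIONS, context.upper()):
        if residue == PAD:
            continue
        if residue not in AMINO_ACIDS:
            raise ValidationError(f"invalid residue {residue!r} in context {context!r}")
        lr *= model.prob(pos, residue) / model.bg(residue)
    return lr


def proximity_score(
    kinase: str,
    substrate: str,
    network: SignallingNetwork | nx.Graph,
    lam: float = 1.0,
    d0: float = 2.0,
    d_max: float = 6.0,
) -> float:
    """Network-proximity likelihood ratio exp(lam * (d0 - d)) from the
    shortest-path distance d between kinase and substrate; unmapped or
    disconnected pairs score at the ceiling distance ``d_max``. Calibrated
    so LR = 1 at the reference distance d0."""
    graph = network.graph if isinstance(network, SignallingNetwork) else network
    d = d_max
    if kinase in graph and substrate in graph:
        if kinase == substrate:
            d = 0.0
        else:
            try:
                d = min(
                    float(nx.shortest_path_length(graph, kinase, substrate)), d_max
                )
            except nx.NetworkXNoPath:
                d = d_max
    return math.exp(lam * (d0 - d))


def predict_kinases(
    site_contexts: Mapping[str, tuple[str, str]],
    models: Sequence[MotifModel],
    network: SignallingNetwork | nx.Graph,
    lam: float = 1.0,
    d0: float = 2.0,
    d_max: float = 6.0,
) -> list[KinasePrediction]:
    """Score every (site, kinase) pair.

    ``site_contexts`` maps site_key -> (substrate protein, 11-mer context).
    """
    predictions: list[KinasePrediction] = []
    for site_key in sorted(site_contexts):
        substrate, context = site_contexts[site_key]
        for model in models:
            predictions.append(
                KinasePrediction(
                    site_key=site_key,
                    substrate=substrate,
                    kinase_id=model.kinase_id,
                    motif_lr=motif_score(context, model),
                    proximity_lr=proximity_score(
                        model.kinase_id, substrate, network, lam, d0, d_max
                    ),
                )
            )
    return predictions


def retain_kinases(
    predictions: Sequence[KinasePrediction],
) -> tuple[list[KinasePrediction], set[str]]:
    """Keep predictions with combined likelihood ratio at or above the
    global median over all predictions (ties kept); returns the retained
    predictions and the distinct retained kinases."""
    if not predictions:
        logger.warning("retain_kinases: no predictions; empty seed contribution")
        return [], set()
    median = statistics.median(p.combined_lr for p in predictions)
    kept = [p for p in predictions if p.combined_lr >= median]
    return kept, {p.kinase_id for p in kept}


def build_seed_set(
    comparison_id: str, substrates: Iterable[str], kinases: Iterable[str]
) -> SeedSet:
    """Merge substrate and kinase seeds; proteins in both get provenance
    ``both``."""
    seed_set = SeedSet(comparison_id=comparison_id)
    for p in substrates:
        seed_set.add(p, "substrate")
    for p in kinases:
        seed_set.add(p, "kinase")
    return seed_set


def load_pwms(path) -> list[MotifModel]:
    """Load motif models from a tabular file.

    Layout: columns ``kinase``, ``position`` then the 20 amino acids.
    ``position`` holds -5..5 for PWM rows; an optional row with position
    ``background`` carries background frequencies (uniform otherwise).
    Each PWM row must sum to 1 (tolerance 1e-6).
    """
    df = pd.read_csv(path, sep="\t", dtype={"position": str})
    missing = {"kinase", "position"} - set(df.columns)
    if missing:
        raise ValidationError(f"PWM table missing column(s): {sorted(missing)}")
    aa_missing = set(AMINO_ACIDS) - set(df.columns)
    if aa_missing:
        raise ValidationError(f"PWM table missing residue column(s): {sorted(aa_missing)}")

    models: list[MotifModel] = []
    for kinase, grp in df.groupby("kinase", sort=True):
        background = None
        bg_rows = grp[grp["position"] == "background"]
        if len(bg_rows):
            background = {aa: float(bg_rows.iloc[0][aa]) for aa in AMINO_ACIDS}
        pwm_rows = grp[grp["position"] != "background"].copy()
        pwm_rows["position"] = pwm_rows["position"].astype(int)
        pwm = pwm_rows.set_index("position")[list(AMINO_ACIDS)].astype(float)
        pwm.index.name = None
        expected = set(MOTIF_POSITIONS)
        if set(pwm.index) != expected:
            raise ValidationError(
                f"PWM for {kinase}: positions must be exactly -5..5"
            )
        sums = pwm.sum(axis=1)
        if not ((sums - 1.0).abs() < 1e-6).all():
            raise ValidationError(f"PWM for {kinase}: rows must sum to 1")
        models.append(MotifModel(kinase_id=str(kinase), pwm=pwm.sort_index(), background=background))
    return models


def predictions_frame(
    predictions: Sequence[KinasePrediction], retained: set[str] | None = None,
    retained_predictions: Sequence[KinasePrediction] | None = None,
) -> pd.DataFrame:
    kept = set()
    if retained_predictions is not None:
        kept = {(p.site_key, p.kinase_id) for p in retained_predictions}
    return pd.DataFrame(
        [
            {
                "site_key": p.site_key,
                "kinase": p.kinase_id,
                "motif_lr": p.motif_lr,
                "proximity_lr": p.proximity_lr,
                "combined_lr": p.combined_lr,
                "retained": (p.site_key, p.kinase_id) in kept,
            }
            for p in predictions
        ]
    )
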