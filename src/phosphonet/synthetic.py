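"""Deterministic synthetic fixtures for every pipeline stage.

Generates four-channel replicated quantitation tables with planted regulated
sites, scale-free or Erdos-Renyi networks with a planted dense module,
pathway gene sets enriched for the module, tissue-expression tables and
kinase motif models. All generators are pure functions of (spec, seed):
identical inputs give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from phosphonet.errors import ParameterError
from phosphonet.seeds import AMINO_ACIDS, MOTIF_POSITIONS, MotifModel

_LN2 = math.log(2.0)


@dataclass
class SyntheticSpec:
    """Parameters for the synthetic dataset family."""

    seed: int = 0
    # quantitation table
    n_sites: int = 500
    n_proteins: int = 200
    n_regulated_per_comparison: int = 12
    effect_log2: float = 1.0
    replicate_cv: float = 0.1
    n_replicates: int = 3
    channel_dropout: float = 0.0
    hc_fraction: float = 0.7  # fraction of peptides at id_fdr <= 0.01
    qp_only_fraction: float = 0.2  # fraction in (0.01, 0.05]
    intensity_dependent_variance: bool = False
    # network
    network_n: int = 2000
    network_model: str = "ba"  # "ba" (preferential attachment) or "er"
    attachment_m: int = 3
    p_background: float = 0.01  # er background edge probability
    module_size: int = 60
    module_p_within: float = 0.25
    # pathways
    n_pathways: int = 50
    pathway_size_mean: int = 20
    module_pathway_fraction: float = 0.3
    # expression
    expression_dropout: float = 0.1
    notdetected_fraction: float = 0.1
    # motifs
    n_kinases: int = 4

    def __post_init__(self):
        for name in (
            "n_sites",
            "n_proteins",
            "n_replicates",
            "network_n",
            "module_size",
            "n_pathways",
            "pathway_size_mean",
            "n_kinases",
        ):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be positive")
        for name in (
            "channel_dropout",
            "hc_fraction",
            "qp_only_fraction",
            "module_p_within",
            "p_background",
            "module_pathway_fraction",
            "expression_dropout",
            "notdetected_fraction",
        ):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {val}")
        if self.n_regulated_per_comparison > self.n_sites:
            raise ParameterError("n_regulated_per_comparison exceeds n_sites")


_CONDITIONS = ("WT", "WT_FGF", "FUS", "FUS_FGF")
#: channel receiving the planted effect for each comparison (the numerator)
_EFFECT_CHANNEL = {"C1": "FUS", "C2": "FUS_FGF", "C3": "WT_FGF"}


def gen_quant_table(
    spec: SyntheticSpec,
    protein_names: Sequence[str] | None = None,
    comparisons: Sequence[str] = ("C1", "C3"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quantitation table plus planted-truth table.

    Each site gets a log-normal base abundance; each replicate/channel value
    is the base times multiplicative log-normal noise with the stated CV.
    Planted sites (disjoint across comparisons) have the numerator channel
    of their comparison multiplied by 2**(+-effect_log2). Optional channel
    dropout empties a random fraction of intensity cells.
    """
    rng = np.random.default_rng(spec.seed)
    if protein_names is None:
        protein_names = [f"P{i:04d}" for i in range(spec.n_proteins)]
    proteins = [protein_names[i % len(protein_names)] for i in range(spec.n_sites)]

    residues = rng.choice(["S", "T", "Y"], size=spec.n_sites, p=[0.6, 0.25, 0.15])
    positions = rng.integers(5, 1000, size=spec.n_sites)
    sigma_ln = math.log1p(spec.replicate_cv)  # ln-scale sd from natural-scale CV
    base = rng.lognormal(mean=math.log(1e6), sigma=1.0, size=spec.n_sites)

    # planted regulated sites, disjoint across comparisons
    order = rng.permutation(spec.n_sites)
    planted: dict[str, dict[int, int]] = {}
    cursor = 0
    for comp in comparisons:
        chosen = order[cursor : cursor + spec.n_regulated_per_comparison]
        cursor += spec.n_regulated_per_comparison
        signs = rng.choice([1, -1], size=len(chosen))
        planted[comp] = {int(i): int(sgn) for i, sgn in zip(chosen, signs)}

    # identification FDR tiers
    u = rng.random(spec.n_sites)
    id_fdr = np.where(
        u < spec.hc_fraction,
        rng.uniform(0.0, 0.01, spec.n_sites),
        np.where(
            u < spec.hc_fraction + spec.qp_only_fraction,
            rng.uniform(0.011, 0.05, spec.n_sites),
            rng.uniform(0.051, 0.3, spec.n_sites),
        ),
    )

    contexts = [
        "".join(rng.choice(list(AMINO_ACIDS), size=5))
        + res
        + "".join(rng.choice(list(AMINO_ACIDS), size=5))
        for res in residues
    ]

    rows = []
    for i in range(spec.n_sites):
        site = f"{residues[i]}{positions[i]}"
        noise_scale = sigma_ln
        if spec.intensity_dependent_variance:
            # low-abundance sites are noisier
            noise_scale = sigma_ln * float(
                np.clip((1e6 / base[i]) ** 0.25, 0.5, 3.0)
            )
        for rep in range(1, spec.n_replicates + 1):
            intensities = {}
            for cond in _CONDITIONS:
                val = base[i] * math.exp(rng.normal(0.0, noise_scale))
                for comp, sites_map in planted.items():
                    if i in sites_map and _EFFECT_CHANNEL[comp] == cond:
                        val *= 2.0 ** (sites_map[i] * spec.effect_log2)
                intensities[cond] = val
            if spec.channel_dropout > 0:
                for cond in _CONDITIONS:
                    if rng.random() < spec.channel_dropout:
                        intensities[cond] = np.nan
            present = [v for v in intensities.values() if not np.isnan(v)]
            rows.append(
                {
                    "peptide_id": f"pep{i:05d}_r{rep}",
                    "protein": proteins[i],
                    "gene": proteins[i],
                    "sites": site,
                    "replicate": rep,
                    **{c: intensities[c] for c in _CONDITIONS},
                    "id_fdr": float(id_fdr[i]),
                    "total_intensity": float(sum(present)),
                    "context": contexts[i],
                }
            )
    table = pd.DataFrame(rows)

    truth_rows = []
    for comp in comparisons:
        for i, sign in sorted(planted[comp].items()):
            truth_rows.append(
                {
                    "site_key": f"{proteins[i]}({residues[i]}{positions[i]})",
                    "protein": proteins[i],
                    "comparison": comp,
                    "direction": "up" if sign > 0 else "down",
                    "effect_log2": sign * spec.effect_log2,
                }
            )
    truth = pd.DataFrame(
        truth_rows,
        columns=["site_key", "protein", "comparison", "direction", "effect_log2"],
    )
    return table, truth


def gen_network(spec: SyntheticSpec) -> tuple[list[tuple[str, str]], list[str]]:
    """Background graph (preferential attachment or Erdos-Renyi) with a
    dense planted module overlaid; returns the sorted edge list and the
    module membership."""
    rng = np.random.default_rng(spec.seed + 1)
    if spec.module_size > spec.network_n:
        raise ParameterError("module_size exceeds network_n")
    if spec.network_model == "ba":
        g = nx.barabasi_albert_graph(
            spec.network_n, spec.attachment_m, seed=int(rng.integers(2**31))
        )
    elif spec.network_model == "er":
        g = nx.fast_gnp_random_graph(
            spec.network_n, spec.p_background, seed=int(rng.integers(2**31))
        )
    else:
        raise ParameterError(f"unknown network_model {spec.network_model!r}")

    module_idx = rng.choice(spec.network_n, size=spec.module_size, replace=False)
    module_idx = sorted(int(i) for i in module_idx)
    for ai in range(len(module_idx)):
        for bi in range(ai + 1, len(module_idx)):
            if rng.random() < spec.module_p_within:
                g.add_edge(module_idx[ai], module_idx[bi])

    name = lambda i: f"N{i:05d}"
    edges = sorted((min(name(a), name(b)), max(name(a), name(b))) for a, b in g.edges)
    module = [name(i) for i in module_idx]
    return edges, module


def gen_pathways(
    spec: SyntheticSpec, nodes: Sequence[str], module: Sequence[str]
) -> tuple[dict[str, list[str]], list[tuple[str, str]]]:
    """Pathway sets sampled from network nodes; a stated fraction is
    enriched for planted-module members (half of their members drawn from
    the module). Returns (pathway id -> members, parent-child hierarchy)."""
    rng = np.random.default_rng(spec.seed + 2)
    nodes = list(nodes)
    module = list(module)
    pathways: dict[str, list[str]] = {}
    for p in range(spec.n_pathways):
        pid = f"PW{p:04d}"
        size = max(3, int(rng.poisson(spec.pathway_size_mean)))
        enriched = p < int(round(spec.module_pathway_fraction * spec.n_pathways))
        members: set[str] = set()
        if enriched and module:
            n_mod = min(len(module), max(1, size // 2))
            members.update(
                str(m) for m in rng.choice(module, size=n_mod, replace=False)
            )
        remaining = size - len(members)
        if remaining > 0:
            members.update(
                str(m) for m in rng.choice(nodes, size=remaining, replace=False)
            )
        pathways[pid] = sorted(members)
    # shallow random hierarchy: each pathway after the first few gets one parent
    hierarchy = []
    ids = sorted(pathways)
    for pid in ids[5:]:
        parent = ids[int(rng.integers(0, 5))]
        if rng.random() < 0.3:
            hierarchy.append((parent, pid))
    return pathways, hierarchy


def gen_expression(spec: SyntheticSpec, nodes: Sequence[str]) -> pd.DataFrame:
    """Two-tissue ('normal', 'tumour') ordinal expression table.

    A ``expression_dropout`` fraction of nodes is absent from the table
    entirely; a ``notdetected_fraction`` is NotDetected in both tissues
    (the tissue filter's victims)."""
    rng = np.random.default_rng(spec.seed + 3)
    levels = ["Low", "Medium", "High"]
    rows = []
    for node in nodes:
        u = rng.random()
        if u < spec.expression_dropout:
            continue  # no entry at all
        both_nd = u < spec.expression_dropout + spec.notdetected_fraction
        for tissue in ("normal", "tumour"):
            if both_nd:
                level = "NotDetected"
            else:
                level = str(rng.choice(["NotDetected"] + levels, p=[0.2, 0.3, 0.3, 0.2]))
            rows.append({"protein": node, "tissue": tissue, "level": level})
    return pd.DataFrame(rows, columns=["protein", "tissue", "level"])


def gen_motif_models(
    spec: SyntheticSpec, kinase_ids: Sequence[str] | None = None, focus: float = 0.7
) -> list[MotifModel]:
    """Concentrated position weight matrices: each position has one
    preferred residue at probability ``focus``, the rest uniform."""
    rng = np.random.default_rng(spec.seed + 4)
    if kinase_ids is None:
        kinase_ids = [f"KIN{i}" for i in range(spec.n_kinases)]
    models = []
    n_aa = len(AMINO_ACIDS)
    for kid in kinase_ids:
        mat = np.full((len(MOTIF_POSITIONS), n_aa), (1.0 - focus) / (n_aa - 1))
        for r, pos in enumerate(MOTIF_POSITIONS):
            if pos == 0:
                pref = AMINO_ACIDS.index(str(rng.choice(["S", "T", "Y"])))
            else:
                pref = int(rng.integers(0, n_aa))
            mat[r, :] = (1.0 - focus) / (n_aa - 1)
            mat[r, pref] = focus
        pwm = pd.DataFrame(mat, index=list(MOTIF_POSITIONS), columns=list(AMINO_ACIDS))
        models.append(MotifModel(kinase_id=str(kid), pwm=pwm, background=None))
    return models


def sample_context(model: MotifModel, rng: np.random.Generator) -> str:
    """Draw an 11-mer position-wise from a motif model."""
    out = []
    for pos in MOTIF_POSITIONS:
        probs = model.pwm.loc[pos].to_numpy(dtype=float)
        probs = probs / probs.sum()
        out.append(str(rng.choice(list(AMINO_ACIDS), p=probs)))
    return "".join(out)


def write_pwms(models: Sequence[MotifModel], path) -> None:
    rows = []
    for model in models:
        for pos in MOTIF_POSITIONS:
            row = {"kinase": model.kinase_id, "position": pos}
            row.update({aa: float(model.pwm.at[pos, aa]) for aa in AMINO_ACIDS})
            rows.append(row)
        if model.background is not None:
            row = {"kinase": model.kinase_id, "position": "background"}
            row.update({aa: float(model.background[aa]) for aa in AMINO_ACIDS})
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_gmt(pathways: dict[str, Sequence[str]], path) -> None:
    with open(path, "w") as fh:
        for pid in sorted(pathways):
            members = "\t".join(pathways[pid])
            fh.write(f"{pid}\tsynthetic pathway {pid}\t{members}\n")


def write_edges(edges: Sequence[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")


def gen_fixture_enrichment_sets(
    universe_size: int = 2050,
    size_a: int = 322,
    size_b: int = 309,
    overlap: int = 299,
    seed: int = 0,
) -> tuple[set[str], set[str]]:
    """Two pathway-id sets with exact sizes and intersection, sampled from a
    synthetic id universe."""
    if overlap > min(size_a, size_b):
        raise ParameterError("overlap exceeds a set size")
    if size_a + size_b - overlap > universe_size:
        raise ParameterError("universe too small for requested sizes")
    rng = np.random.default_rng(seed)
    ids = [f"RID{i:05d}" for i in range(universe_size)]
    chosen = rng.choice(universe_size, size=size_a + size_b - overlap, replace=False)
    chosen = [ids[int(i)] for i in chosen]
    shared = set(chosen[:overlap])
    unique_a = set(chosen[overlap : overlap + (size_a - overlap)])
    unique_b = set(chosen[overlap + (size_a - overlap) :])
    return shared | unique_a, shared | unique_b
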