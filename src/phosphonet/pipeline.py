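"""End-to-end pipeline orchestration: config handling, staged execution,
provenance metadata and deterministic outputs."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from phosphonet import diamond as diamond_mod
from phosphonet import differential as diff_mod
from phosphonet import enrichment as enr_mod
from phosphonet import network as net_mod
from phosphonet import quant as quant_mod
from phosphonet import seeds as seeds_mod
from phosphonet.errors import StageError

logger = logging.getLogger(__name__)

STAGES = (
    "load",
    "datasets",
    "site_stats",
    "seeding",
    "network",
    "expansion",
    "enrichment",
    "differential",
)


@dataclass
class RunConfig:
    """All inputs and parameters for one pipeline run. Every parameter
    default is the protocol default; overrides are recorded in the run
    metadata."""

    quant: str = ""
    network: str = ""
    gmt: str = ""
    expression: str = ""
    hierarchy: str | None = None
    pwms: str | None = None

    comparisons: list[str] = field(default_factory=lambda: ["C1", "C3"])
    tissues: list[str] = field(default_factory=lambda: ["normal", "tumour"])

    hc_fdr: float = 0.01
    qp_fdr: float = 0.05
    log2_threshold: float = 0.5
    ci_multiplier: float = 1.96
    sigb_bin_size: int = 300
    sigb_alpha: float = 0.05
    kinase_lambda: float = 1.0
    kinase_d0: float = 2.0
    kinase_d_max: float = 6.0
    min_expression_level: str = "Low"
    effective_method: str = "neighbours"  # or "diffusion"
    diamond_n_iter: int = 200
    diamond_alpha: int = 1
    enrichment_fdr: float = 0.01
    enrichment_min_members: int = 3
    universe: str = "network_and_pathways"  # or "network"
    shared_fraction: float = 0.25

    seed: int = 0
    outdir: str = "phosphonet_out"

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        flat: dict[str, Any] = {}
        for section in ("inputs", "params"):
            flat.update(data.get(section) or {})
        for key, value in data.items():
            if key not in ("inputs", "params"):
                flat[key] = value
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(flat) - known
        if unknown:
            raise StageError("config", f"unknown config key(s): {sorted(unknown)}")
        return cls(**flat)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def validate_config(config: RunConfig) -> list[dict[str, str]]:
    """Range, existence and consistency checks. Returns a report of
    ``{"level": "error"|"warning", "message": ...}`` entries; never raises
    (run_pipeline enforces)."""
    report: list[dict[str, str]] = []

    def err(msg):
        report.append({"level": "error", "message": msg})

    def warn(msg):
        report.append({"level": "warning", "message": msg})

    for name in ("quant", "network", "gmt", "expression"):
        path = getattr(config, name)
        if not path:
            err(f"missing required input path: {name}")
        elif not Path(path).exists():
            err(f"{name} path does not exist: {path}")
    for name in ("hierarchy", "pwms"):
        path = getattr(config, name)
        if path and not Path(path).exists():
            err(f"{name} path does not exist: {path}")

    for name, lo, hi in (
        ("hc_fdr", 0.0, 1.0),
        ("qp_fdr", 0.0, 1.0),
        ("sigb_alpha", 0.0, 1.0),
        ("enrichment_fdr", 0.0, 1.0),
    ):
        val = getattr(config, name)
        if not lo < val <= hi:
            err(f"{name} must be in ({lo}, {hi}], got {val}")
    if config.log2_threshold < 0:
        err("log2_threshold must be >= 0")
    if config.ci_multiplier <= 0:
        err("ci_multiplier must be > 0")
    if config.shared_fraction < 0:
        err("shared_fraction must be >= 0")
    for name in ("sigb_bin_size", "diamond_n_iter", "diamond_alpha"):
        if getattr(config, name) < 1:
            err(f"{name} must be >= 1")
    bad = [c for c in config.comparisons if c not in quant_mod.COMPARISONS]
    if bad:
        err(f"unknown comparison id(s): {bad}")
    if len(config.comparisons) != 2:
        warn(
            f"differential analysis expects 2 comparisons, got {len(config.comparisons)}"
        )
    if not config.tissues:
        err("tissues must be non-empty")
    if config.min_expression_level not in net_mod.EXPRESSION_LEVELS:
        err(f"unknown min_expression_level {config.min_expression_level!r}")
    if config.effective_method not in ("neighbours", "diffusion"):
        err(f"unknown effective_method {config.effective_method!r}")
    if config.universe not in ("network_and_pathways", "network"):
        err(f"unknown universe {config.universe!r}")

    defaults = RunConfig()
    for f in dataclasses.fields(RunConfig):
        if f.name in ("quant", "network", "gmt", "expression", "hierarchy", "pwms",
                      "outdir", "seed", "comparisons", "tissues"):
            continue
        if getattr(config, f.name) != getattr(defaults, f.name):
            warn(f"non-default parameter {f.name} = {getattr(config, f.name)!r}")
    return report


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _records_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "peptide_id": r.peptide_id,
                "protein": r.protein_accession,
                "site_key": r.site_key,
                "replicate": r.replicate_id,
                "id_fdr": r.id_fdr,
            }
            for r in records
        ]
    )


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full differential pathway protocol and write every
    intermediate plus run metadata to the output directory.

    Any stage failure raises :class:`StageError` carrying the stage name; an
    ``INCOMPLETE`` marker is left in the output directory in that case.
    """
    issues = validate_config(config)
    errors = [i["message"] for i in issues if i["level"] == "error"]
    if errors:
        raise StageError("config", "; ".join(errors))
    for issue in issues:
        logger.warning("config: %s", issue["message"])

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    marker = outdir / "INCOMPLETE"
    marker.write_text("run in progress\n")

    counts: dict[str, Any] = {}
    stage = "load"
    try:
        records = quant_mod.load_quant_table(config.quant)
        counts["records"] = len(records)
        logger.info("stage=load records=%d", len(records))

        stage = "datasets"
        hc = quant_mod.build_hc_dataset(records, config.hc_fdr)
        qp = quant_mod.build_qp_dataset(records, config.qp_fdr)
        counts["hc_records"] = len(hc)
        counts["qp_records"] = len(qp)
        overlap = quant_mod.hc_qp_protein_overlap(hc, qp)
        counts["hc_qp_protein_overlap_pct"] = overlap
        _records_frame(hc).to_csv(outdir / "hc_records.tsv", sep="\t", index=False)
        _records_frame(qp).to_csv(outdir / "qp_records.tsv", sep="\t", index=False)
        logger.info(
            "stage=datasets hc=%d qp=%d overlap=%s", len(hc), len(qp), overlap
        )

        stage = "site_stats"
        hc_summaries: dict[str, list] = {}
        qp_summaries: dict[str, list] = {}
        for comp_id in config.comparisons:
            comp = quant_mod.COMPARISONS[comp_id]
            hs = quant_mod.summarise_comparison(
                hc, comp, config.log2_threshold, config.ci_multiplier
            )
            quant_mod.significance_b(hs, config.sigb_bin_size)
            hc_summaries[comp_id] = hs
            qp_summaries[comp_id] = quant_mod.summarise_comparison(
                qp, comp, config.log2_threshold, config.ci_multiplier
            )
            quant_mod.write_site_report(hs, outdir / f"site_report_{comp_id}.tsv")
            selected = quant_mod.select_significant_sites(
                hs, config.log2_threshold, config.sigb_alpha
            )
            quant_mod.write_site_report(
                selected, outdir / f"significant_sites_{comp_id}.tsv"
            )
            counts[f"hc_sites_{comp_id}"] = len(hs)
            counts[f"hc_significant_{comp_id}"] = len(selected)
            logger.info(
                "stage=site_stats comparison=%s sites=%d significant=%d",
                comp_id,
                len(hs),
                len(selected),
            )

        stage = "network"
        unfiltered = net_mod.load_network(config.network)
        expression = net_mod.load_expression(config.expression)
        filtered = net_mod.tissue_filter(
            unfiltered, expression, config.tissues, config.min_expression_level
        )
        counts["network_nodes"] = unfiltered.number_of_nodes()
        counts["network_nodes_filtered"] = filtered.number_of_nodes()
        logger.info(
            "stage=network nodes=%d filtered=%d",
            unfiltered.number_of_nodes(),
            filtered.number_of_nodes(),
        )

        stage = "seeding"
        models = seeds_mod.load_pwms(config.pwms) if config.pwms else []
        contexts = {
            r.site_key: (r.protein_accession, r.context)
            for r in qp
            if r.context and len(r.context) == len(seeds_mod.MOTIF_POSITIONS)
        }
        seed_sets: dict[str, seeds_mod.SeedSet] = {}
        for comp_id in config.comparisons:
            substrate = seeds_mod.substrate_seeds(qp_summaries[comp_id], comp_id)
            kinases: set[str] = set()
            predictions: list = []
            retained: list = []
            if models:
                sig_sites = {
                    s.site_key
                    for s in qp_summaries[comp_id]
                    if s.n_replicates > 1 and (s.ci_low > 0 or s.ci_high < 0)
                }
                site_ctx = {
                    k: v for k, v in contexts.items() if k in sig_sites
                }
                predictions = seeds_mod.predict_kinases(
                    site_ctx,
                    models,
                    filtered,
                    config.kinase_lambda,
                    config.kinase_d0,
                    config.kinase_d_max,
                )
                retained, kinases = seeds_mod.retain_kinases(predictions)
            seed_set = seeds_mod.build_seed_set(
                comp_id, substrate.members, kinases
            )
            seed_sets[comp_id] = seed_set
            seeds_mod.predictions_frame(
                predictions, retained_predictions=retained
            ).to_csv(outdir / f"predictions_{comp_id}.tsv", sep="\t", index=False)
            pd.DataFrame(
                [
                    {"protein": p, "provenance": seed_set.provenance[p]}
                    for p in sorted(seed_set.members)
                ],
                columns=["protein", "provenance"],
            ).to_csv(outdir / f"seeds_{comp_id}.tsv", sep="\t", index=False)
            counts[f"substrate_seeds_{comp_id}"] = len(substrate.members)
            counts[f"kinase_seeds_{comp_id}"] = len(kinases)
            counts[f"seeds_{comp_id}"] = len(seed_set.members)
            logger.info(
                "stage=seeding comparison=%s substrates=%d kinases=%d total=%d",
                comp_id,
                len(substrate.members),
                len(kinases),
                len(seed_set.members),
            )

        stage = "network"  # seed mapping + effective networks
        mappings: dict[str, net_mod.SeedMappingReport] = {}
        for comp_id in config.comparisons:
            mapping = net_mod.map_seeds(
                seed_sets[comp_id].members, unfiltered, filtered
            )
            mappings[comp_id] = mapping
            rows = (
                [{"protein": p, "status": "mapped"} for p in sorted(mapping.mapped)]
                + [
                    {"protein": p, "status": "filtered"}
                    for p in sorted(mapping.unmapped_filtered)
                ]
                + [
                    {"protein": p, "status": "absent"}
                    for p in sorted(mapping.unmapped_absent)
                ]
            )
            pd.DataFrame(rows, columns=["protein", "status"]).to_csv(
                outdir / f"seed_mapping_{comp_id}.tsv", sep="\t", index=False
            )
            counts[f"seeds_mapped_{comp_id}"] = mapping.n_mapped
            if mapping.mapped:
                eff = net_mod.effective_network(
                    filtered, mapping.mapped, method=config.effective_method
                )
                pd.DataFrame(
                    sorted(eff.graph.edges), columns=["source", "target"]
                ).to_csv(
                    outdir / f"effective_network_{comp_id}.tsv", sep="\t", index=False
                )
                counts[f"effective_nodes_{comp_id}"] = eff.number_of_nodes()
            logger.info(
                "stage=network comparison=%s mapped=%d filtered_out=%d absent=%d",
                comp_id,
                mapping.n_mapped,
                len(mapping.unmapped_filtered),
                len(mapping.unmapped_absent),
            )

        stage = "expansion"
        final_sets: dict[str, set[str]] = {}
        for comp_id in config.comparisons:
            mapped = mappings[comp_id].mapped
            if not mapped:
                raise StageError(
                    "expansion", f"no mapped seeds for comparison {comp_id}"
                )
            expansion = diamond_mod.diamond_expand(
                filtered, mapped, config.diamond_n_iter, config.diamond_alpha
            )
            final_sets[comp_id] = expansion.final_set
            diamond_mod.expansion_frame(expansion).to_csv(
                outdir / f"expansion_{comp_id}.tsv", sep="\t", index=False
            )
            with open(outdir / f"final_set_{comp_id}.txt", "w") as fh:
                for node in sorted(expansion.final_set):
                    fh.write(node + "\n")
            counts[f"final_set_{comp_id}"] = len(expansion.final_set)
            logger.info(
                "stage=expansion comparison=%s added=%d final=%d",
                comp_id,
                len(expansion.added_nodes),
                len(expansion.final_set),
            )

        stage = "enrichment"
        db = enr_mod.load_gmt(config.gmt)
        if config.hierarchy:
            enr_mod.load_hierarchy(config.hierarchy, db)
        all_members = set().union(*(m for _, m in db.pathways.values()))
        if config.universe == "network_and_pathways":
            universe = filtered.nodes & all_members
        else:
            universe = filtered.nodes
        enrichments: dict[str, list] = {}
        for comp_id in config.comparisons:
            results = enr_mod.enrich(
                final_sets[comp_id] & universe,
                db,
                universe,
                config.enrichment_fdr,
                config.enrichment_min_members,
            )
            enrichments[comp_id] = results
            enr_mod.enrichment_frame(results).to_csv(
                outdir / f"enrichment_{comp_id}.tsv", sep="\t", index=False
            )
            counts[f"enriched_pathways_{comp_id}"] = sum(
                r.significant for r in results
            )
            logger.info(
                "stage=enrichment comparison=%s tested=%d significant=%d",
                comp_id,
                len(results),
                counts[f"enriched_pathways_{comp_id}"],
            )

        stage = "differential"
        comp_a, comp_b = config.comparisons[0], config.comparisons[-1]
        hits_a = {
            r.pathway_id: r.hits for r in enrichments[comp_a] if r.significant
        }
        hits_b = {
            r.pathway_id: r.hits for r in enrichments[comp_b] if r.significant
        }
        hc_proteins = {r.protein_accession for r in hc}
        qp_proteins = {r.protein_accession for r in qp}
        report = diff_mod.build_report(
            comp_a,
            comp_b,
            hits_a,
            hits_b,
            hits_a,
            hits_b,
            hc_proteins,
            qp_proteins,
            config.shared_fraction,
        )
        diff_mod.report_frame(report, db).to_csv(
            outdir / "differential_report.tsv", sep="\t", index=False
        )
        regulation: dict[str, dict[str, str]] = {}
        for comp_id in config.comparisons:
            for s in hc_summaries[comp_id]:
                if s.regulation != "unchanged":
                    regulation.setdefault(s.protein_accession, {})[comp_id] = (
                        s.regulation
                    )
        diff_mod.export_pathway_graph(
            report,
            db,
            regulation=regulation,
            graphml_path=outdir / "pathway_graph.graphml",
            edges_path=outdir / "pathway_graph_edges.tsv",
        )
        counts["unique_a"] = len(report.unique_a)
        counts["unique_b"] = len(report.unique_b)
        counts["shared"] = len(report.shared)
        counts["hc_validated_unique_a"] = len(report.hc_validated_unique_a)
        counts["hc_validated_unique_b"] = len(report.hc_validated_unique_b)
        counts["shared_differential"] = len(report.shared_differential)
        logger.info(
            "stage=differential unique_a=%d unique_b=%d shared=%d",
            counts["unique_a"],
            counts["unique_b"],
            counts["shared"],
        )
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - annotate with stage name
        raise StageError(stage, str(exc)) from exc

    metadata = {
        "config": config.to_dict(),
        "counts": counts,
        "input_hashes": {
            name: _sha256(getattr(config, name))
            for name in ("quant", "network", "gmt", "expression", "hierarchy", "pwms")
            if getattr(config, name)
        },
        "stages": list(STAGES),
    }
    with open(outdir / "run_metadata.json", "w") as fh:
        json.dump(metadata, fh, indent=2, sort_keys=True)
        fh.write("\n")
    marker.unlink(missing_ok=True)
    return outdir


def simulate(outdir, seed: int = 0, spec=None) -> Path:
    """Generate a complete synthetic input bundle plus a ready-to-run
    config file."""
    from phosphonet import synthetic as syn

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = spec or syn.SyntheticSpec(seed=seed)

    edges, module = syn.gen_network(spec)
    syn.write_edges(edges, outdir / "network.tsv")
    with open(outdir / "module.txt", "w") as fh:
        fh.write("\n".join(module) + "\n")

    nodes = sorted({n for e in edges for n in e})
    n_prot = min(spec.n_proteins, len(nodes))
    # bias quantified proteins towards the planted module so expansion has
    # signal to find
    pool = list(module) + [n for n in nodes if n not in set(module)]
    proteins = pool[:n_prot]

    table, truth = syn.gen_quant_table(spec, protein_names=proteins)
    table.to_csv(outdir / "quant.tsv", sep="\t", index=False)
    truth.to_csv(outdir / "truth_sites.tsv", sep="\t", index=False)

    pathways, hierarchy = syn.gen_pathways(spec, nodes, module)
    syn.write_gmt(pathways, outdir / "pathways.gmt")
    with open(outdir / "hierarchy.tsv", "w") as fh:
        for parent, child in hierarchy:
            fh.write(f"{parent}\t{child}\n")

    expression = syn.gen_expression(spec, nodes)
    expression.to_csv(outdir / "expression.tsv", sep="\t", index=False)

    models = syn.gen_motif_models(spec, kinase_ids=nodes[: spec.n_kinases])
    syn.write_pwms(models, outdir / "pwms.tsv")

    config = RunConfig(
        quant=str(outdir / "quant.tsv"),
        network=str(outdir / "network.tsv"),
        gmt=str(outdir / "pathways.gmt"),
        hierarchy=str(outdir / "hierarchy.tsv"),
        expression=str(outdir / "expression.tsv"),
        pwms=str(outdir / "pwms.tsv"),
        seed=seed,
        outdir=str(outdir / "results"),
    )
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "inputs": {
                    "quant": config.quant,
                    "network": config.network,
                    "gmt": config.gmt,
                    "hierarchy": config.hierarchy,
                    "expression": config.expression,
                    "pwms": config.pwms,
                },
                "seed": config.seed,
                "outdir": config.outdir,
            },
            fh,
            sort_keys=True,
        )
    return outdir
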