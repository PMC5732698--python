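# phosphonet

Differential phospho-signalling network analysis. Starting from replicated
four-channel (isobaric-label) phosphopeptide quantitation tables, the pipeline:

1. builds a high-confidence (HC) dataset (stringent identification FDR) and a
   broad all-channel (QP) dataset (relaxed FDR, all four reporter channels
   observed);
2. computes per-phosphosite log2 comparison ratios over replicates, calls
   up/down regulation at a symmetric log2 threshold, applies a strict
   multi-replicate mu ± 1.96σ filter and an intensity-binned asymmetric
   outlier test;
3. derives substrate seeds (QP sites whose ratio interval excludes 1) and
   kinase seeds (position-weight-matrix motif likelihood × network-proximity
   likelihood, median-filtered);
4. maps seeds onto a tissue-expression-filtered signalling network and expands
   them with an iterative hypergeometric-connectivity module detector;
5. tests the expanded protein lists for pathway over-representation
   (hypergeometric + Benjamini-Hochberg FDR);
6. classifies pathways as condition-unique, shared, HC-validated, or
   differentially-regulated shared (≥25% more protein hits on one side), and
   exports a pathway-protein graph (GraphML + TSV).

A synthetic-data module generates every input format with planted ground truth
(regulated sites, dense network modules, module-enriched pathways), so the full
pipeline is testable offline.

## CLI

```sh
# generate a complete synthetic input bundle + ready-to-run config
phosphonet simulate --seed 1 --outdir demo

# run the full pipeline (writes every intermediate + run_metadata.json)
phosphonet run --config demo/config.yaml

# validate a config, or run a prefix of the stage list
phosphonet validate --config demo/config.yaml
phosphonet stage enrichment --config demo/config.yaml
```

Inputs (all plain text): quantitation TSV (configurable column map), network
edge list (2-column TSV or SIF), pathway GMT, optional pathway hierarchy TSV,
tissue-expression TSV (protein / tissue / level), optional kinase PWM table.
Parameters (FDRs, log2 threshold, CI multiplier, outlier-test bin size,
proximity λ/d0/d_max, tissue list, expansion iteration count, enrichment FDR,
shared-pathway fraction) all have protocol defaults and are configurable in
the YAML config; the run metadata records every value plus input hashes.

## Layout

- `src/phosphonet/quant.py` — datasets, ratio statistics, regulation calls,
  outlier test
- `src/phosphonet/seeds.py` — substrate seeds, motif/proximity kinase scoring
- `src/phosphonet/network.py` — network I/O, tissue filter, seed mapping,
  effective sub-networks
- `src/phosphonet/diamond.py` — connectivity-significance module expansion
- `src/phosphonet/enrichment.py` — GMT I/O, hypergeometric test, BH FDR
- `src/phosphonet/differential.py` — set operations, HC validation, 25% rule,
  graph export
- `src/phosphonet/synthetic.py` — deterministic fixture generators
- `src/phosphonet/pipeline.py`, `cli.py` — orchestration and CLI
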