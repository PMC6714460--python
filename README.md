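# mirhostnet

Tissue-specific functional-network analysis linking intronic microRNAs to
their disease-associated host genes.

Many microRNA genes sit inside an intron of a protein-coding *host* gene.
When the host gene is disease-associated (cardiovascular-disease genes such
as CDH13, SLC12A3 or CKAP5, hosting miR-3182, miR-6863 and miR-5582), the
miRNA's predicted targets can be interrogated against the host gene's own
tissue-specific functional neighbourhood: do the targets interact with the
host, in which tissues, how central are they in the tissue network, and what
functions are they enriched for? `mirhostnet` is for computational
biologists who want that analysis as a reproducible, testable pipeline
rather than a chain of manual downloads.

## What it computes

For each (host gene, miRNA) pair and each tissue:

- **Target integration** — union of predicted targets across predictors and
  mature forms, with per-gene provenance; validated interactions flag but
  never gate.
- **Overlap test** — with G scored genes, K host-associated, n targets and
  overlap k, the depletion tail P(X ≤ k) under X ~ Hypergeometric(G, K, n)
  (enrichment and two-sided variants available), computed in log space.
- **Fractional ranks** — each host-associated gene's association score is
  replaced by rank/N ∈ (0, 1] (average ranks on ties), making scores
  comparable across tissue networks; mean = (N+1)/(2N) exactly.
- **Filtering** — targets that pass the association criterion, screened at
  fractional rank ≥ 0.5 and truncated to the top 20 for enrichment.
- **Score and centrality comparisons** — two-sample rank-sum tests (exact
  null for small tie-free groups) of targets vs. all host-associated genes,
  and of host-interacting targets vs. all targets on standardized degree
  (% of |V|−1) and normalized betweenness; groups below `min_n` report
  "too few data" instead of a p-value.
- **Enrichment** — over-representation (hypergeometric + Benjamini–Hochberg
  FDR, default) or preranked running-sum enrichment with a gene-label
  permutation null, NES and sign-matched FDR.
- **Tissue specificity** — per-target counts of tissues passed, histogram
  and pairwise tissue overlap.

A synthetic-data generator emulates all four external inputs (predictor
dumps, per-tissue association score tables, validation databases, GMT
collections) with planted, ground-truth-recorded effects, so the whole
pipeline is testable offline. See `docs/methods.md` for the model details.

## Worked example

Simulate a two-tissue study with planted overlap depletion
(`target_assoc_bias: 0.2`) and planted centrality elevation
(`centrality_bias: 3.0`), then analyse it:

```bash
cat > scenario.yaml <<'EOF'
n_genes: 1000
n_targets_per_predictor: 200
tissues: [cardiac_muscle, skin]
target_assoc_bias: 0.2
centrality_bias: 3.0
n_gene_sets: 100
gene_set_size_range: [5, 20]
seed: 42
EOF
mirhostnet simulate --config scenario.yaml --out sim
mirhostnet run --config sim/analysis_config.yaml --out results
```

`results/run_metadata.json` then contains, for the cardiac-muscle network:

```
counts: {'associated': 100, 'overlap': 5, 'targets_in_universe': 300, 'universe': 999}
overlap_test: {'alternative': 'depletion', 'p_value': 7.63672261811e-11}
degree comparison p:      7.6454495446e-05
betweenness comparison p: 8.21629083637e-05
tissue-specificity histogram: {'1': 22}
```

Reading: of 300 predicted targets only 5 are among the 100 genes associated
with the host in cardiac muscle — far fewer than the ~30 a random draw would
give, so the depletion tail is ~8×10⁻¹¹ (the planted bias 0.2 is recovered).
Those host-interacting targets are significantly more central than targets
at large (both centrality p ≈ 8×10⁻⁵, the planted 3× attachment bias), and
every filtered target appears in exactly one tissue — the tissue-specific
pattern. Per-tissue tables are written alongside, e.g.
`results/HOSTG1_hsa-miR-0001/cardiac_muscle/filtered_targets.tsv`:

```
gene    netwas_score    fractional_rank validated
G00874  0.9554743238    0.95            False
G00851  0.9293951003    0.92            False
...
```

Identical config + seed reproduce every output file byte-for-byte.

## Command-line surface

- `mirhostnet simulate --config scenario.yaml --out DIR [--seed N]` — write
  a synthetic input bundle, its ground-truth sidecar and a ready-to-run
  `analysis_config.yaml`.
- `mirhostnet run --config analysis.yaml --out DIR` — run the full analysis;
  reports are TSV/JSON, with every threshold stamped in
  `run_metadata.json`.
- `mirhostnet enrich --mode {ora,preranked} --gmt F ...` — stand-alone
  enrichment of a query list or ranked list.

Analysis config keys (YAML): `association_threshold` (mandatory; defines
"interacting with the host gene"), `association_direction`, `min_fr` (0.5),
`top_n` (20), `min_n` (3), `edge_weight_threshold` (0.5),
`overlap_alternative` (depletion), `rank_test_alternative` (two-sided),
`centrality_alternative` (greater), `enrichment_mode` (ora), `n_perm`,
`self_target_mode` (warn), `seed`, and a `pairs` list giving, per host/miRNA
pair, the predicted/validated target tables, per-tissue association and
edge-list files, and a GMT collection. `simulate` writes a complete example.
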