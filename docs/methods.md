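# Methods

## The analysis

About two thirds of human microRNAs are intronic: their genes sit inside an
intron of a protein-coding *host* gene and are often co-transcribed with it.
When the host gene is itself disease-associated — here, cardiovascular-disease
genes such as CDH13, SLC12A3 and CKAP5, which host miR-3182, miR-6863 and
miR-5582 — a natural question is whether the miRNA's targets are functionally
entangled with the host gene's own interactome, and whether that entanglement
is tissue-specific.

`mirhostnet` implements this question as a pipeline over four inputs:

1. **Predicted targets** from two sequence-based predictors, combined by
   union (each predictor has a substantial false-negative rate; the union
   trades specificity for recall deliberately). A locus expressing two mature
   forms contributes the union over both forms. Validated interactions from
   up to three curated databases are pooled and used only to *flag* targets
   in outputs, never to gate the analysis.
2. **Tissue-specific association scores**: for each tissue, a
   posterior-probability-style score of every gene's functional association
   with the host gene (a NetWAS-style vector centred on the host). A gene
   "interacts with the host" in a tissue when its score passes the
   association criterion. The criterion has no universal value across data
   providers, so it is a mandatory config key stamped into every output.
3. **Tissue networks** on which centrality is computed.
4. **Gene-set collections** in GMT format for the enrichment stage.

Per tissue, the pipeline computes:

- **Overlap test.** With G scored genes, K of them host-associated, n targets
  and k host-associated targets, the tail of Hypergeometric(G, K, n) gives
  the probability of an overlap as weak (depletion, the default direction —
  the observed effect in the motivating data) or as strong (enrichment) as k.
  Tails are evaluated in log space; the two-sided variant doubles the smaller
  tail. The universe G is the set of genes scored in that tissue's
  association vector, host excluded.
- **Fractional ranks.** Raw association scores are not comparable across
  tissue networks, so each host-associated gene's score is replaced by its
  rank divided by N (the number of host-associated genes). Ties receive
  average ranks, which preserves the identity mean = (N+1)/(2N) exactly;
  ranks are invariant under any strictly monotone transform of the scores.
- **Score comparison.** Fractional ranks of the filtered targets versus all
  host-associated genes. Although the comparison is often described loosely
  as a signed-rank test, the groups are unpaired and unequal in size, so the
  two-sample rank-sum (Mann–Whitney) test with tie correction is the test
  actually computed; a paired signed-rank mode exists and refuses unequal
  lengths. The exact null distribution is used when both groups have ≤ 10
  tie-free observations, the normal approximation otherwise. Groups smaller
  than `min_n` (default 3) produce an explicit "too few data" record rather
  than a p-value. Stars: \*p < 0.05, \*\*p < 1e−5, \*\*\*p < 1e−10.
- **Top-target selection.** Filtered targets with fractional rank ≥ 0.5
  (configurable, `min_fr`), sorted by rank descending with gene symbol as the
  deterministic tie-break, truncated to the best 20 (`top_n`). Fewer than 20
  survivors is a legal outcome and is reported as such.
- **Centrality.** On the thresholded tissue graph (edge weight ≥ 0.5 by
  default; nodes are the full gene universe, so absent genes count as
  isolated with degree 0): degree standardized by the maximum possible
  degree |V|−1 as a percentage, and shortest-path betweenness normalized by
  (|V|−1)(|V|−2)/2. Host-interacting targets are compared against all
  predicted targets, one-sided (interacting > all).
- **Enrichment** of the top targets, two modes:
  - *ORA* (default): per gene set, hypergeometric enrichment of the query in
    the universe of scored genes, Benjamini–Hochberg FDR across sets.
    Feeding a short unranked gene list to an MSigDB-style overlap query is
    operationally exactly this computation.
  - *Preranked*: the weighted running-sum enrichment score down the full
    ranked gene list — increment |score|^p / Σ|score|^p at hits (p = 1 by
    default), decrement 1/(N − N_hits) at misses, ES = signed maximum
    deviation from zero. Significance by gene-label permutation: shuffling
    scores over genes makes a size-m set's hit positions uniform, so the
    null ES distribution depends only on m and the fixed score vector and is
    pooled per set size (the same observation fgsea exploits). Nominal p is
    the sign-matched tail with the add-one correction; NES = ES divided by
    the mean |null ES| of the same sign; the FDR q compares the observed NES
    tail with the pooled null NES tail, sign-matched and monotonized from
    the most extreme set inward. Phenotype permutation is not possible here
    (there are no expression samples), which is why the null is gene-label
    permutation.
- **Tissue specificity.** Across tissues, each filtered target is binned by
  the number of tissues in which it passed filtering, with a pairwise
  tissue-overlap matrix; the histogram total equals the number of distinct
  filtered targets by construction.

## The synthetic generator

No reusable archive of the original inputs exists, so the package ships a
generator that emulates all four resources with *known* ground truth,
recorded in a JSON sidecar next to the written files.

- **Association scores** are a two-component disjoint uniform mixture around
  the criterion c (default 0.5): associated genes score in (c, 1], the rest
  in [0, c). This makes ground-truth labels exact — the filtering stage must
  recover them verbatim — and robust to any threshold inside the gap. The
  associated count is exactly `round(assoc_fraction · (n_genes − 1))`,
  rounding half away from zero for cross-platform reproducibility. Real
  association scores are not two clean uniforms; this is a construction for
  testability, not an inference about real score distributions.
- **Targets**: the union of two predictors is drawn in one pass without
  replacement — a shared block of exactly `round(overlap · n)` genes plus
  per-predictor remainders — so that under neutral bias the union is a
  uniform draw and the downstream overlap statistic is exactly
  hypergeometric (this is what makes the type-I-error test meaningful).
  Sampling weight of host-associated genes is multiplied by
  `target_assoc_bias` (1 = null, < 1 plants depletion, > 1 enrichment);
  bias is applied against the reference (first) tissue's labels, since
  sequence-based predictions are tissue-independent. The host gene is never
  a target.
- **Tissue graphs** are weighted Erdős–Rényi with per-node attachment
  multipliers: edge (i, j) appears with probability p₀·mᵢ·mⱼ where
  host-associated targets have m = `centrality_bias` and p₀ is calibrated so
  the mean pair probability equals `edge_density`. This is the simplest
  model in which the bias provably raises the boosted nodes' expected degree
  monotonically. Degree distributions are binomial, not scale-free; the
  generator validates the statistics, not the topology of real interactomes.
- **Gene sets**: uniformly sized random sets, plus one designated set seeded
  with `planted_set_overlap` of the top-ranked targets.

Reference study conditions (generator defaults): 2000-gene universe, five
tissues (cardiac muscle, heart, vascular endothelium, hair follicle, skin),
10% of genes host-associated per tissue, two predictors of 100 targets
sharing half their calls (union 150), edge density 0.02, 500 gene sets of
10–40 genes, all planted biases at their null values. Every artefact is a
pure function of (parameters, seed): independent RNG streams are derived per
artefact and tissue via `SeedSequence([seed, stream, substream])`, and
writing the same scenario twice is byte-identical.

Because the generator plants effects through these simple mechanisms,
passing tests demonstrate that the pipeline *detects what was planted at the
stated strengths* — calibrated type-I error, power against bias 0.2
depletion, recovery of 5× centrality elevation and of a 15-of-20 planted
gene set — not that the original biological findings are correct.

## Numerical and design choices

- Gene identity is the uppercased symbol string; normalization is
  idempotent; symbols like "NA"/"NULL" survive file round-trips.
- Hypergeometric tails via `scipy.stats.hypergeom.logcdf/logsf`; rank tests
  via `scipy.stats.mannwhitneyu`; centrality via networkx's Brandes
  algorithm; BH via statsmodels — each is contract-tested against an
  independent brute-force oracle (enumeration of draws, of rank assignments,
  of geodesics; a literal step-up) in the suite.
- ES sign ties (|max deviation| = |min deviation|) resolve positive; a
  completely tied score comparison reports p = 1.
- Fully degenerate inputs are legal where the field's data make them
  reachable: empty filtered sets, all-below-cutoff selections, empty edge
  sets (density 0), single-tissue configs.
- Report floats are serialized at 12 significant digits; metadata carries
  the config hash, seed, thresholds and package version, making every
  bundle self-describing and byte-reproducible.
- Simulation sizes in the validation battery (e.g. 1000 null replicates,
  100 centrality seeds, 50 enrichment runs) were chosen as the smallest
  counts at which the targeted rates have standard errors comfortably below
  the tolerance bands.

## Known limitations

- The generator does not model sequence-level seed matching, realistic
  degree distributions, or the SVM-based procedure behind real
  tissue-network scores.
- Preranked FDR uses the size-pooled gene-label permutation null; with very
  heterogeneous set sizes and strong score outliers, per-set nulls could
  differ slightly from the pooled ones.
- The ORA universe defaults to the genes scored in the tissue's association
  vector; other universes (e.g. all genes on the prediction platform) are
  configurable but not auto-detected.
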