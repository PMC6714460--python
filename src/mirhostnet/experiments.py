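"""Replicated simulation studies validating the pipeline's statistics.

Each function repeats a synthetic scenario over many seeds and measures an
operating characteristic of one pipeline stage: type-I error of the overlap
test under the null, its power under planted depletion, recovery of planted
centrality elevation, calibration of the permutation enrichment p-values,
and recovery of a planted enriched gene set. The scenario dimensions are
the package's reference study conditions (2000-gene universe, 200
host-associated genes per tissue, 150-target union from two predictors
sharing half their calls).
"""

from __future__ import annotations

from dataclasses import replace


from . import enrichment as enr
from . import filtering, netstats, synthetic
from .synthetic import SyntheticScenario
from .types import AssociationCriterion

REFERENCE = SyntheticScenario(tissues=("cardiac_muscle",))


def _scenario(base: SyntheticScenario, seed: int, **overrides) -> SyntheticScenario:
    return replace(base, seed=seed, **overrides)


def overlap_rejection_rate(
    n_reps: int,
    base_seed: int,
    target_assoc_bias: float = 1.0,
    alpha: float = 0.05,
    scenario: SyntheticScenario = REFERENCE,
) -> float:
    """Fraction of replicates where the depletion test rejects at alpha.

    With ``target_assoc_bias=1`` this estimates the type-I error (targets
    drawn uniformly, so the overlap is exactly hypergeometric); with bias
    below 1 it estimates power against planted depletion.
    """
    tissue = scenario.tissues[0]
    crit = AssociationCriterion(scenario.assoc_threshold)
    rejections = 0
    for i in range(n_reps):
        sc = _scenario(scenario, base_seed + i, target_assoc_bias=target_assoc_bias)
        vector, assoc_truth = synthetic.generate_association_vector(sc, tissue)
        ta, tb = synthetic.generate_target_predictions(sc, assoc_truth)
        union = ta.targets | tb.targets
        associated = filtering.host_associated_genes(vector, crit)
        res = netstats.hypergeometric_overlap_test(
            len(vector),
            len(associated),
            len(union & vector.genes),
            len(union & associated),
            alternative="depletion",
        )
        rejections += res.p_value < alpha
    return rejections / n_reps


def centrality_recovery_rate(
    n_seeds: int,
    base_seed: int,
    centrality_bias: float = 5.0,
    edge_density: float = 0.02,
    n_genes: int = 500,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Fraction of seeds where host-interacting targets test as more central.

    One-sided (interacting > all targets) comparisons on standardized
    degree and on normalized betweenness, after thresholding edge weights
    at 0.5.
    """
    base = _scenario(
        REFERENCE, 0, n_genes=n_genes, edge_density=edge_density,
        centrality_bias=centrality_bias,
    )
    tissue = base.tissues[0]
    wins = {"degree": 0, "betweenness": 0}
    performed = 0
    for i in range(n_seeds):
        sc = _scenario(base, base_seed + i)
        _, assoc = synthetic.generate_association_vector(sc, tissue)
        ta, tb = synthetic.generate_target_predictions(sc, assoc)
        union = ta.targets | tb.targets
        graph = synthetic.generate_tissue_graph(sc, tissue, assoc, union)
        profile = netstats.centrality_profile(graph, weight_threshold=0.5)
        deg, btw = netstats.compare_target_centrality(
            profile, union, assoc & union, alternative="greater"
        )
        if not deg.performed:
            continue
        performed += 1
        wins["degree"] += deg.p_value < alpha
        wins["betweenness"] += btw.p_value < alpha
    if performed == 0:
        raise RuntimeError("no seed produced enough host-interacting targets")
    return {k: v / performed for k, v in wins.items()}


def _planted_enrichment_run(seed: int, mode: str, n_perm: int) -> bool:
    """Does the planted set attain the minimum q in one seeded run?"""
    sc = _scenario(
        REFERENCE, seed, planted_set_overlap=15, target_assoc_bias=5.0,
        n_gene_sets=500,
    )
    bundle = synthetic.generate_scenario(sc, with_graphs=False)
    tissue = sc.tissues[0]
    vector = bundle.vectors[tissue]
    associated = bundle.associated[tissue]
    union = bundle.predictor_tables[0].targets | bundle.predictor_tables[1].targets
    franks = filtering.fractional_rank(vector, associated)
    filtered = union & associated
    fts = filtering.select_top_targets(
        filtered, franks, vector, host_gene=sc.host_gene, mirna_id=sc.mirna_id
    )
    if mode == "ora":
        results = enr.overrepresentation_test(fts.genes, bundle.gene_sets, vector.genes)
    else:
        ranked = sorted(vector.genes, key=lambda g: (-vector.scores[g], g))
        results = enr.preranked_significance(
            ranked,
            [vector.scores[g] for g in ranked],
            bundle.gene_sets,
            n_perm=n_perm,
            seed=seed,
        )
    best_q = min(r.fdr_q for r in results)
    planted_q = next(
        r.fdr_q for r in results if r.set_name == bundle.planted_set_name
    )
    return planted_q <= best_q


def planted_enrichment_recovery(
    n_runs: int, base_seed: int, mode: str, n_perm: int = 200
) -> float:
    """Fraction of seeded runs in which the planted set ranks first by q."""
    wins = sum(
        _planted_enrichment_run(base_seed + i, mode, n_perm) for i in range(n_runs)
    )
    return wins / n_runs


def preranked_null_calibration(
    n_reps: int, base_seed: int, alpha: float = 0.05, n_perm: int = 500
) -> float:
    """Fraction of gene sets at nominal p < alpha on signal-free ranked lists.

    Gene sets are drawn independently of the scores, so every set is null;
    a calibrated permutation p-value puts ~alpha of them below alpha.
    """
    base = _scenario(
        REFERENCE, 0, n_genes=500, n_targets_per_predictor=50,
        n_gene_sets=200, gene_set_size_range=(10, 40),
    )
    tissue = base.tissues[0]
    hits = total = 0
    for i in range(n_reps):
        sc = _scenario(base, base_seed + i)
        vector, _ = synthetic.generate_association_vector(sc, tissue)
        collection, _ = synthetic.generate_gene_set_collection(sc, ())
        ranked = sorted(vector.scores, key=lambda g: (-vector.scores[g], g))
        results = enr.preranked_significance(
            ranked,
            [vector.scores[g] for g in ranked],
            collection,
            n_perm=n_perm,
            seed=base_seed + 7919 + i,
        )
        hits += sum(r.p_nominal < alpha for r in results)
        total += len(results)
    return hits / total
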