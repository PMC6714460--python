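"""Synthetic inputs with controlled statistical structure.

Emulates the four external resources the analysis consumes — predictor
target dumps, per-tissue host-gene-centred association score tables,
validated-interaction tables, and a GMT gene-set collection — with planted
effects (overlap depletion/enrichment, centrality elevation, one enriched
gene set) whose ground truth is recorded alongside, so every downstream
stage is testable without downloads.

Determinism contract: every artefact is a pure function of the scenario
parameters and seed; writing the same scenario twice yields byte-identical
files. Independent RNG streams are derived per artefact from
``numpy.random.SeedSequence([seed, stream])``.

Association scores use a two-component disjoint-uniform mixture around the
criterion ``assoc_threshold`` c: associated genes score in (c, 1], the rest
in [0, c). This makes ground-truth association labels exact and robust to
any threshold choice inside the gap.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io as io_formats
from .errors import ConfigurationError
from .types import (
    GeneSet,
    GeneSetCollection,
    TargetPredictionTable,
    TissueAssociationVector,
    TissueGraph,
)

DEFAULT_TISSUES = (
    "cardiac_muscle",
    "heart",
    "vascular_endothelium",
    "hair_follicle",
    "skin",
)

# stream ids for per-artefact RNG derivation
_STREAM_ASSOC = 1
_STREAM_TARGETS = 2
_STREAM_GRAPH = 3
_STREAM_GENESETS = 4
_STREAM_VALIDATED = 5


def round_half_away(x: float) -> int:
    """Round half away from zero (platform-independent expected counts)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of one synthetic study (one miRNA, one host gene).

    Defaults describe the reference condition used throughout the test
    battery: a 2000-gene universe in which 10% of genes are associated with
    the host per tissue, two predictors of 100 targets each sharing half
    their calls (union 150), and no planted effect (all biases at their
    null value 1).
    """

    n_genes: int = 2000
    host_gene: str = "HOSTG1"
    mirna_id: str = "hsa-miR-0001"
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    assoc_fraction: float = 0.1
    assoc_threshold: float = 0.5
    n_targets_per_predictor: int = 100
    predictor_overlap: float = 0.5
    target_assoc_bias: float = 1.0
    centrality_bias: float = 1.0
    edge_density: float = 0.02
    n_gene_sets: int = 500
    gene_set_size_range: tuple[int, int] = (10, 40)
    planted_set_overlap: int = 0
    n_validated_per_db: int = 5
    seed: int = 0

    def __post_init__(self):
        for name in ("assoc_fraction", "predictor_overlap", "edge_density"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if not (0 < self.assoc_threshold < 1):
            raise ConfigurationError("assoc_threshold must lie strictly in (0, 1)")
        if self.target_assoc_bias < 0:
            raise ConfigurationError("target_assoc_bias must be >= 0")
        if self.centrality_bias < 1:
            raise ConfigurationError("centrality_bias must be >= 1")
        if self.n_targets_per_predictor > self.n_genes - 1:
            raise ConfigurationError(
                "n_targets_per_predictor exceeds n_genes - 1 "
                "(the host gene is never a target)"
            )
        lo, hi = self.gene_set_size_range
        if not (1 <= lo <= hi):
            raise ConfigurationError("invalid gene_set_size_range")
        if not self.tissues:
            raise ConfigurationError("at least one tissue required")
        if len(set(self.tissues)) != len(self.tissues):
            raise ConfigurationError("tissue names must be unique")

    @property
    def universe(self) -> tuple[str, ...]:
        """All gene symbols including the host gene."""
        width = max(5, len(str(self.n_genes)))
        return (self.host_gene,) + tuple(
            f"G{i:0{width}d}" for i in range(1, self.n_genes)
        )

    @property
    def non_host_genes(self) -> tuple[str, ...]:
        return self.universe[1:]

    def rng(self, stream: int, substream: int = 0) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([self.seed, stream, substream])
        )


def generate_association_vector(
    scenario: SyntheticScenario, tissue: str
) -> tuple[TissueAssociationVector, frozenset[str]]:
    """Scores of every non-host gene plus the ground-truth associated set.

    Exactly ``round_half_away(assoc_fraction * (n_genes - 1))`` genes score
    in (c, 1] (associated); the rest score in [0, c). Which genes are
    associated varies by tissue (independent streams), giving the
    tissue-specific filtering pattern downstream.
    """
    if tissue not in scenario.tissues:
        raise ConfigurationError(f"unknown tissue {tissue!r}")
    tissue_idx = scenario.tissues.index(tissue)
    rng = scenario.rng(_STREAM_ASSOC, tissue_idx)
    genes = np.array(scenario.non_host_genes)
    n = len(genes)
    n_assoc = round_half_away(scenario.assoc_fraction * n)
    order = rng.permutation(n)
    assoc_idx = order[:n_assoc]
    c = scenario.assoc_threshold
    scores = np.empty(n)
    # non-associated: Uniform[0, c); associated: Uniform(c, 1]
    scores[:] = rng.random(n) * c
    scores[assoc_idx] = 1.0 - rng.random(n_assoc) * (1.0 - c)
    vector = TissueAssociationVector(
        host_gene=scenario.host_gene,
        tissue=tissue,
        scores=dict(zip(genes.tolist(), scores.tolist())),
    )
    return vector, frozenset(genes[assoc_idx].tolist())


def _biased_weights(
    genes: np.ndarray, associated: frozenset[str], bias: float
) -> np.ndarray:
    w = np.ones(len(genes))
    if bias != 1.0:
        mask = np.fromiter((g in associated for g in genes), bool, len(genes))
        w[mask] = bias
    return w


def generate_target_predictions(
    scenario: SyntheticScenario, associated: frozenset[str]
) -> tuple[TargetPredictionTable, TargetPredictionTable]:
    """Two predictor tables with controlled overlap and association bias.

    ``associated`` is the ground-truth associated set of the reference
    tissue (predictions are sequence-based, hence tissue-independent; the
    bias is planted against one tissue's labels). The shared count is
    exactly ``round_half_away(predictor_overlap * n_targets_per_predictor)``;
    sampling weight of associated genes is multiplied by
    ``target_assoc_bias`` and renormalized; the host gene is excluded.
    """
    rng = scenario.rng(_STREAM_TARGETS)
    n = scenario.n_targets_per_predictor
    n_shared = round_half_away(scenario.predictor_overlap * n)
    n_union = 2 * n - n_shared
    genes = np.array(scenario.non_host_genes)
    w = _biased_weights(genes, associated, scenario.target_assoc_bias)
    if n_union > int((w > 0).sum()):
        raise ConfigurationError(
            f"cannot draw {n_union} distinct targets from "
            f"{int((w > 0).sum())} eligible genes"
        )
    # one draw of the whole union without replacement, then split:
    # first n_shared are shared, next (n - n_shared) go to each predictor.
    if scenario.target_assoc_bias == 1.0:
        picked = rng.choice(genes, size=n_union, replace=False)
    else:
        picked = rng.choice(genes, size=n_union, replace=False, p=w / w.sum())
    shared = picked[:n_shared]
    extra_a = picked[n_shared:n]
    extra_b = picked[n:]
    t_a = frozenset(np.concatenate([shared, extra_a]).tolist())
    t_b = frozenset(np.concatenate([shared, extra_b]).tolist())
    make = lambda src, t: TargetPredictionTable(
        mirna_id=scenario.mirna_id, source=src, targets=t
    )
    return make("predictorA", t_a), make("predictorB", t_b)


def generate_validated_interactions(
    scenario: SyntheticScenario, predicted_targets: frozenset[str]
) -> tuple[TargetPredictionTable, ...]:
    """Three small validation-database tables sampled from predicted targets."""
    rng = scenario.rng(_STREAM_VALIDATED)
    pool = np.array(sorted(predicted_targets))
    tables = []
    for db in ("validationDB1", "validationDB2", "validationDB3"):
        k = min(scenario.n_validated_per_db, len(pool))
        picked = rng.choice(pool, size=k, replace=False) if k else np.array([])
        tables.append(
            TargetPredictionTable(
                mirna_id=scenario.mirna_id,
                source=db,
                targets=frozenset(picked.tolist()),
            )
        )
    return tuple(tables)


def generate_tissue_graph(
    scenario: SyntheticScenario,
    tissue: str,
    associated: frozenset[str],
    targets: frozenset[str],
) -> TissueGraph:
    """Weighted Erdos-Renyi graph with per-node attachment multipliers.

    Host-associated targets (``associated & targets``) carry attachment
    multiplier ``centrality_bias``; edge (i, j) is present with probability
    ``p0 * m_i * m_j`` (capped at 1) where p0 is calibrated so the expected
    density over all pairs equals ``edge_density``. Weights ~ Uniform(0, 1].
    The simplest model in which the bias has a provable monotone effect on
    expected degree.
    """
    if tissue not in scenario.tissues:
        raise ConfigurationError(f"unknown tissue {tissue!r}")
    tissue_idx = scenario.tissues.index(tissue)
    rng = scenario.rng(_STREAM_GRAPH, tissue_idx)
    genes = np.array(scenario.universe)
    n = len(genes)
    boosted = associated & targets
    m = np.ones(n)
    if scenario.centrality_bias != 1.0 and boosted:
        mask = np.fromiter((g in boosted for g in genes), bool, n)
        m[mask] = scenario.centrality_bias
    iu, ju = np.triu_indices(n, k=1)
    pair_mult = m[iu] * m[ju]
    if scenario.edge_density == 0:
        return TissueGraph(tissue=tissue, nodes=frozenset(genes.tolist()), edges={})
    p0 = scenario.edge_density * len(pair_mult) / pair_mult.sum()
    p = np.minimum(p0 * pair_mult, 1.0)
    present = rng.random(len(p)) < p
    ei, ej = iu[present], ju[present]
    weights = 1.0 - rng.random(len(ei))  # (0, 1]
    edges = {}
    for a_i, b_i, w in zip(ei.tolist(), ej.tolist(), weights.tolist()):
        a, b = genes[a_i], genes[b_i]
        edges[TissueGraph.canonical_edge(a, b)] = w
    return TissueGraph(tissue=tissue, nodes=frozenset(genes.tolist()), edges=edges)


def generate_gene_set_collection(
    scenario: SyntheticScenario, top_targets: tuple[str, ...]
) -> tuple[GeneSetCollection, str]:
    """Random gene sets plus one designated set seeded with top targets.

    Returns the collection and the designated set's name. The designated
    set holds ``planted_set_overlap`` of the given top targets (taken in
    order) plus random non-target filler up to its drawn size.
    """
    k = scenario.planted_set_overlap
    if k > 0 and not top_targets:
        raise ConfigurationError("planted_set_overlap > 0 requires top targets")
    if k > len(top_targets):
        raise ConfigurationError(
            f"planted_set_overlap={k} exceeds |top_targets|={len(top_targets)}"
        )
    rng = scenario.rng(_STREAM_GENESETS)
    genes = np.array(scenario.non_host_genes)
    lo, hi = scenario.gene_set_size_range
    width = max(4, len(str(scenario.n_gene_sets)))
    sets: list[GeneSet] = []
    planted_name = f"GS_{1:0{width}d}_PLANTED"
    for i in range(scenario.n_gene_sets):
        size = int(rng.integers(lo, hi + 1))
        if i == 0:
            name = planted_name
            size = max(size, k)
            planted = list(top_targets[:k])
            pool = np.array([g for g in genes if g not in set(planted)])
            filler = rng.choice(pool, size=size - k, replace=False)
            members = frozenset(planted) | frozenset(filler.tolist())
        else:
            name = f"GS_{i + 1:0{width}d}"
            members = frozenset(rng.choice(genes, size=size, replace=False).tolist())
        sets.append(GeneSet(name=name, description="synthetic gene set", members=members))
    return GeneSetCollection(sets=tuple(sets)), planted_name


@dataclass(frozen=True)
class ScenarioBundle:
    """Everything one scenario generates, plus ground truth."""

    scenario: SyntheticScenario
    vectors: dict[str, TissueAssociationVector]
    associated: dict[str, frozenset[str]]
    predictor_tables: tuple[TargetPredictionTable, TargetPredictionTable]
    validated_tables: tuple[TargetPredictionTable, ...]
    graphs: dict[str, TissueGraph]
    gene_sets: GeneSetCollection
    planted_set_name: str


def generate_scenario(
    scenario: SyntheticScenario, with_graphs: bool = True
) -> ScenarioBundle:
    """Run every generator for one scenario, sharing ground truth."""
    vectors: dict[str, TissueAssociationVector] = {}
    associated: dict[str, frozenset[str]] = {}
    for tissue in scenario.tissues:
        vectors[tissue], associated[tissue] = generate_association_vector(
            scenario, tissue
        )
    ref = scenario.tissues[0]
    tab_a, tab_b = generate_target_predictions(scenario, associated[ref])
    all_targets = tab_a.targets | tab_b.targets
    validated = generate_validated_interactions(scenario, all_targets)
    graphs = {}
    if with_graphs:
        for tissue in scenario.tissues:
            graphs[tissue] = generate_tissue_graph(
                scenario, tissue, associated[tissue], all_targets
            )
    # top targets (by reference-tissue score among targets) seed the planted set
    ref_scores = vectors[ref].scores
    ranked = sorted(
        (g for g in all_targets if g in ref_scores),
        key=lambda g: (-ref_scores[g], g),
    )
    gene_sets, planted_name = generate_gene_set_collection(
        scenario, tuple(ranked[: max(scenario.planted_set_overlap, 20)])
    )
    return ScenarioBundle(
        scenario=scenario,
        vectors=vectors,
        associated=associated,
        predictor_tables=(tab_a, tab_b),
        validated_tables=validated,
        graphs=graphs,
        gene_sets=gene_sets,
        planted_set_name=planted_name,
    )


def write_scenario(bundle: ScenarioBundle, out_dir: str | Path) -> dict[str, str]:
    """Write every artefact plus the ground-truth sidecar; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    for tissue, vec in bundle.vectors.items():
        p = out / f"assoc_{tissue}.tsv"
        io_formats.write_association_table(vec, p)
        paths[f"assoc_{tissue}"] = str(p)
    for tab in bundle.predictor_tables + bundle.validated_tables:
        p = out / f"targets_{tab.source}.tsv"
        io_formats.write_target_table(tab, p)
        paths[f"targets_{tab.source}"] = str(p)
    for tissue, graph in bundle.graphs.items():
        p = out / f"edges_{tissue}.tsv"
        io_formats.write_edge_list(graph, p)
        paths[f"edges_{tissue}"] = str(p)
    gmt = out / "gene_sets.gmt"
    io_formats.write_gmt(bundle.gene_sets, gmt)
    paths["gene_sets"] = str(gmt)
    truth = {
        "scenario": dataclasses.asdict(bundle.scenario),
        "associated": {t: sorted(s) for t, s in bundle.associated.items()},
        "targets_per_predictor": {
            tab.source: sorted(tab.targets) for tab in bundle.predictor_tables
        },
        "validated": {
            tab.source: sorted(tab.targets) for tab in bundle.validated_tables
        },
        "planted_set_name": bundle.planted_set_name,
    }
    truth_path = out / "ground_truth.json"
    with open(truth_path, "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["ground_truth"] = str(truth_path)
    return paths
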