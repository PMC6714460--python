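"""Core in-memory containers shared by every pipeline stage.

Gene identity throughout the package is by symbol string, uppercased on
ingest; the analysis operates at symbol level (CCND2, RBM28, AQP1, ...) so
no identifier mapping layer is needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import math


def normalize_symbol(symbol: str) -> str:
    """Uppercase and strip a gene symbol. Idempotent."""
    return symbol.strip().upper()


@dataclass(frozen=True)
class TargetPredictionTable:
    """miRNA -> target gene set from one predictor or validation database."""

    mirna_id: str
    source: str
    targets: frozenset[str]
    scores: Mapping[str, float] | None = None

    def __post_init__(self):
        for g in self.targets:
            if not g:
                raise ValueError("empty gene symbol in target table")

    def __len__(self) -> int:
        return len(self.targets)


@dataclass(frozen=True)
class TissueAssociationVector:
    """Per-tissue functional-association scores of every gene to one host gene.

    ``scores`` holds a NetWAS-style posterior score per gene symbol; the host
    gene itself is never a key (readers drop it with a warning).
    """

    host_gene: str
    tissue: str
    scores: Mapping[str, float]

    def __post_init__(self):
        if self.host_gene in self.scores:
            raise ValueError("host gene must not appear in its own association vector")
        for g, s in self.scores.items():
            if not math.isfinite(s):
                raise ValueError(f"non-finite association score for {g}")

    def __len__(self) -> int:
        return len(self.scores)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.scores)


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: frozenset[str]

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")


@dataclass(frozen=True)
class GeneSetCollection:
    """Ordered collection of named gene sets (GMT semantics)."""

    sets: tuple[GeneSet, ...]

    def __post_init__(self):
        names = [s.name for s in self.sets]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate gene set name(s): {dup}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)


@dataclass(frozen=True)
class TissueGraph:
    """Undirected weighted gene graph for one tissue.

    Edges are stored once in canonical (min, max) symbol order; no self-loops;
    weights strictly positive.
    """

    tissue: str
    nodes: frozenset[str]
    edges: Mapping[tuple[str, str], float]

    def __post_init__(self):
        for (a, b), w in self.edges.items():
            if a == b:
                raise ValueError(f"self-loop on {a}")
            if a > b:
                raise ValueError(f"edge ({a}, {b}) not in canonical order")
            if not (w > 0):
                raise ValueError(f"non-positive weight on edge ({a}, {b})")
            if a not in self.nodes or b not in self.nodes:
                raise ValueError(f"edge ({a}, {b}) references unknown node")

    @staticmethod
    def canonical_edge(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class IntegratedTargetSet:
    """Union of target evidence for one miRNA locus.

    ``provenance`` maps each target to the set of contributing sources (a
    predictor name, optionally suffixed with the mature form it came from);
    ``validated`` flags targets supported by at least one validation database.
    """

    mirna_ids: tuple[str, ...]
    targets: frozenset[str]
    provenance: Mapping[str, frozenset[str]]
    validated: frozenset[str] = frozenset()

    def __post_init__(self):
        if set(self.provenance) != set(self.targets):
            raise ValueError("provenance keys must equal the target set")
        for g, srcs in self.provenance.items():
            if not srcs:
                raise ValueError(f"target {g} has no contributing source")

    def __len__(self) -> int:
        return len(self.targets)


@dataclass(frozen=True)
class AssociationCriterion:
    """Threshold rule deciding which genes count as host-associated.

    ``direction='above'`` keeps scores strictly greater than ``threshold``;
    ``'below'`` keeps scores strictly smaller. Fixed per run and stamped into
    all output metadata.
    """

    threshold: float
    direction: str = "above"

    def __post_init__(self):
        if self.direction not in ("above", "below"):
            raise ValueError("direction must be 'above' or 'below'")

    def passes(self, score: float) -> bool:
        if self.direction == "above":
            return score > self.threshold
        return score < self.threshold


@dataclass(frozen=True)
class FilteredTargetMember:
    gene: str
    netwas_score: float
    fractional_rank: float
    validated: bool


@dataclass(frozen=True)
class FilteredTargetSet:
    """Targets surviving host-association filtering in one tissue.

    Members carry the NetWAS-style score, its fractional rank among the N
    host-associated genes, and the validation flag; sorted descending by
    fractional rank (ties broken by gene symbol ascending).
    """

    host_gene: str
    mirna_id: str
    tissue: str
    members: tuple[FilteredTargetMember, ...]
    n_associated: int

    def __post_init__(self):
        key = [(-m.fractional_rank, m.gene) for m in self.members]
        if key != sorted(key):
            raise ValueError("members must be sorted by fractional rank desc, gene asc")
        for m in self.members:
            if not (0 < m.fractional_rank <= 1):
                raise ValueError(f"fractional rank of {m.gene} outside (0, 1]")

    def __len__(self) -> int:
        return len(self.members)

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(m.gene for m in self.members)


@dataclass(frozen=True)
class OverlapTestResult:
    """Hypergeometric overlap test between targets and host-associated genes."""

    universe_size: int
    associated_count: int
    target_count: int
    overlap: int
    alternative: str
    p_value: float

    def __post_init__(self):
        G, K, n, k = (
            self.universe_size,
            self.associated_count,
            self.target_count,
            self.overlap,
        )
        if not (max(0, K + n - G) <= k <= min(K, n)):
            raise ValueError(f"infeasible overlap k={k} for (G={G}, K={K}, n={n})")
        if not (0 <= self.p_value <= 1):
            raise ValueError("p-value outside [0, 1]")


@dataclass(frozen=True)
class RankComparisonResult:
    """Two-group rank-based score comparison with a small-sample skip rule."""

    group_a_size: int
    group_b_size: int
    performed: bool
    statistic: float | None = None
    p_value: float | None = None
    reason_if_skipped: str | None = None
    stars: str = ""

    def __post_init__(self):
        if not self.performed and self.p_value is not None:
            raise ValueError("skipped comparison must not carry a p-value")


@dataclass(frozen=True)
class CentralityProfile:
    """Standardized centralities of every node in one tissue graph."""

    tissue: str
    degree_pct: Mapping[str, float]
    betweenness_norm: Mapping[str, float]

    def __post_init__(self):
        for g, v in self.degree_pct.items():
            if not (0 <= v <= 100):
                raise ValueError(f"degree_pct of {g} outside [0, 100]")
        for g, v in self.betweenness_norm.items():
            if not (-1e-12 <= v <= 1 + 1e-12):
                raise ValueError(f"betweenness_norm of {g} outside [0, 1]")


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    description: str
    overlap_count: int
    set_size: int
    p_nominal: float
    fdr_q: float
    es: float | None = None
    nes: float | None = None


@dataclass(frozen=True)
class TissueSpecificitySummary:
    """Cross-tissue sharing pattern of filtered targets.

    ``tissue_counts`` maps each filtered target to the number of tissues in
    which it passed filtering; ``histogram`` bins targets by that count; the
    histogram total equals the number of distinct filtered targets.
    """

    tissue_counts: Mapping[str, int]
    histogram: Mapping[int, int]
    overlap_matrix: Mapping[tuple[str, str], int]

    def __post_init__(self):
        if sum(self.histogram.values()) != len(self.tissue_counts):
            raise ValueError("histogram total must equal number of distinct targets")
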