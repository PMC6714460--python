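"""Statistical comparisons on the tissue networks.

Three families of tests:

* hypergeometric overlap test between a miRNA's targets and the genes
  associated with its host gene (is the overlap weaker or stronger than a
  random draw of the same size from the universe?);
* two-group rank comparisons of score or centrality distributions
  (two-sample rank-sum / Mann-Whitney with tie correction; an exact null
  for small tie-free groups; a skip rule for groups too small to compare);
* standardized network centrality: degree as a percentage of the maximum
  possible degree |V|-1, and shortest-path betweenness normalized to
  [0, 1] by (|V|-1)(|V|-2)/2.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
from scipy.stats import hypergeom, mannwhitneyu, wilcoxon

from .types import (
    CentralityProfile,
    OverlapTestResult,
    RankComparisonResult,
    TissueGraph,
)

#: significance stars at the thresholds used in all comparison figures
STAR_THRESHOLDS = ((1e-10, "***"), (1e-5, "**"), (0.05, "*"))

DEFAULT_MIN_N = 3


def significance_stars(p: float) -> str:
    for thr, stars in STAR_THRESHOLDS:
        if p < thr:
            return stars
    return ""


def hypergeometric_overlap_test(
    universe_size: int,
    associated_count: int,
    target_count: int,
    overlap: int,
    alternative: str = "depletion",
) -> OverlapTestResult:
    """Tail probability of the observed overlap under a random draw.

    With X ~ Hypergeometric(G, K, n): depletion p = P(X <= k), enrichment
    p = P(X >= k), two-sided doubles the smaller tail (capped at 1).
    Tails are evaluated in log space for numerical stability at extreme k.
    """
    G, K, n, k = universe_size, associated_count, target_count, overlap
    if not (0 <= K <= G and 0 <= n <= G):
        raise ValueError(f"infeasible counts (G={G}, K={K}, n={n})")
    if not (max(0, K + n - G) <= k <= min(K, n)):
        raise ValueError(f"infeasible overlap k={k} for (G={G}, K={K}, n={n})")
    if alternative not in ("depletion", "enrichment", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    log_lower = hypergeom.logcdf(k, G, K, n)          # P(X <= k)
    log_upper = hypergeom.logsf(k - 1, G, K, n)       # P(X >= k)
    if alternative == "depletion":
        p = math.exp(log_lower)
    elif alternative == "enrichment":
        p = math.exp(log_upper)
    else:
        p = min(1.0, 2.0 * math.exp(min(log_lower, log_upper)))
    return OverlapTestResult(
        universe_size=G,
        associated_count=K,
        target_count=n,
        overlap=k,
        alternative=alternative,
        p_value=min(p, 1.0),
    )


def rank_score_comparison(
    scores_a,
    scores_b,
    alternative: str = "two-sided",
    min_n: int = DEFAULT_MIN_N,
    paired: bool = False,
) -> RankComparisonResult:
    """Rank-based comparison of two score groups with a skip rule.

    Defaults to the two-sample rank-sum (Mann-Whitney) test with tie
    correction — the test that is well-defined for the unpaired,
    unequal-size groups this pipeline compares. ``paired=True`` switches to
    the one-sample signed-rank test and refuses unequal lengths. The exact
    null is used when both groups have <= 10 observations and the pooled
    data is tie-free; the normal approximation otherwise. When either group
    is smaller than ``min_n`` no test is performed ("too few data").
    """
    a = np.asarray(list(scores_a), dtype=float)
    b = np.asarray(list(scores_b), dtype=float)
    if (a.size and not np.isfinite(a).all()) or (b.size and not np.isfinite(b).all()):
        raise ValueError("non-finite scores")
    if min(a.size, b.size) < min_n:
        return RankComparisonResult(
            group_a_size=int(a.size),
            group_b_size=int(b.size),
            performed=False,
            reason_if_skipped="too few data",
        )
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison requires equal-length groups")
        if np.array_equal(a, b):
            stat, p = 0.0, 1.0
        else:
            stat, p = wilcoxon(a, b, alternative=_scipy_alt(alternative))
    else:
        pooled = np.concatenate([a, b])
        if np.all(pooled == pooled[0]):
            # all observations identical: no evidence either way
            stat, p = a.size * b.size / 2.0, 1.0
        else:
            has_ties = len(np.unique(pooled)) < pooled.size
            method = "exact" if (max(a.size, b.size) <= 10 and not has_ties) else "asymptotic"
            stat, p = mannwhitneyu(
                a, b, alternative=_scipy_alt(alternative), method=method
            )
    p = float(min(p, 1.0))
    return RankComparisonResult(
        group_a_size=int(a.size),
        group_b_size=int(b.size),
        performed=True,
        statistic=float(stat),
        p_value=p,
        stars=significance_stars(p),
    )


def _scipy_alt(alternative: str) -> str:
    mapping = {"two-sided": "two-sided", "greater": "greater", "less": "less"}
    if alternative not in mapping:
        raise ValueError(f"unknown alternative {alternative!r}")
    return mapping[alternative]


def build_graph(graph: TissueGraph, weight_threshold: float = 0.0) -> nx.Graph:
    """Unweighted simple graph keeping edges with weight >= threshold.

    The node set is always the full universe — genes without any retained
    edge remain as isolated, degree-0 nodes.
    """
    g = nx.Graph()
    g.add_nodes_from(sorted(graph.nodes))
    g.add_edges_from(
        (a, b) for (a, b), w in graph.edges.items() if w >= weight_threshold
    )
    return g


def degree_pct(graph: nx.Graph) -> dict[str, float]:
    """Degree standardized by the maximum possible degree, as a percentage."""
    n = graph.number_of_nodes()
    if n < 2:
        return {v: 0.0 for v in graph.nodes}
    return {v: d / (n - 1) * 100.0 for v, d in graph.degree()}


def betweenness_norm(graph: nx.Graph) -> dict[str, float]:
    """Normalized shortest-path betweenness centrality in [0, 1].

    Fraction of all-pairs geodesics passing through each node, with even
    splitting among equal-length paths; normalizer (|V|-1)(|V|-2)/2 for
    undirected graphs (networkx's Brandes accumulation with
    ``normalized=True``).
    """
    return dict(nx.betweenness_centrality(graph, normalized=True, weight=None))


def centrality_profile(
    graph: TissueGraph, weight_threshold: float = 0.0
) -> CentralityProfile:
    g = build_graph(graph, weight_threshold)
    return CentralityProfile(
        tissue=graph.tissue,
        degree_pct=degree_pct(g),
        betweenness_norm=betweenness_norm(g),
    )


def compare_target_centrality(
    profile: CentralityProfile,
    all_targets: frozenset[str],
    host_interacting_targets: frozenset[str],
    alternative: str = "greater",
    min_n: int = DEFAULT_MIN_N,
) -> tuple[RankComparisonResult, RankComparisonResult]:
    """Do host-interacting targets sit more centrally than targets at large?

    Returns (degree comparison, betweenness comparison), each one-sided
    (interacting > all) by default. Targets absent from the tissue graph
    would contribute degree 0; with the graph built on the full universe
    every target is present, isolated nodes included.
    """
    degree_cmp = rank_score_comparison(
        [profile.degree_pct[g] for g in sorted(host_interacting_targets)],
        [profile.degree_pct[g] for g in sorted(all_targets)],
        alternative=alternative,
        min_n=min_n,
    )
    betweenness_cmp = rank_score_comparison(
        [profile.betweenness_norm[g] for g in sorted(host_interacting_targets)],
        [profile.betweenness_norm[g] for g in sorted(all_targets)],
        alternative=alternative,
        min_n=min_n,
    )
    return degree_cmp, betweenness_cmp
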