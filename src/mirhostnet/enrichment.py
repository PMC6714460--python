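"""Gene-set enrichment of top-ranked targets, in two modes.

Over-representation analysis (ORA, the default): hypergeometric enrichment
of a small unranked query list (the top filtered targets) against each set
of a collection, with Benjamini-Hochberg FDR across sets. This is the
operational meaning of running a 20-gene list through an MSigDB overlap
query.

Preranked mode: the weighted Kolmogorov-Smirnov-like running-sum
enrichment score computed down a full ranked gene list. At each hit the
sum rises by |score|^p / sum(|score|^p over hits); at each miss it falls
by 1/(N - N_hits); the enrichment score (ES) is the signed maximum
deviation from zero. Significance comes from a gene-label permutation null
(scores shuffled over genes), which for a set of size m is equivalent to
drawing m uniform random positions in the list — so the null ES
distribution depends only on m and the fixed score vector, and is pooled
per set size. NES divides ES by the mean |null ES| of the same sign; the
FDR q-value compares the observed NES tail against the pooled null NES
tail, sign-matched, monotonized from the most extreme set inward.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .types import EnrichmentResult, GeneSetCollection

logger = logging.getLogger(__name__)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up FDR q-values (monotone non-decreasing after sorting by p)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def overrepresentation_test(
    query,
    collection: GeneSetCollection,
    universe,
    include_zero_overlap: bool = True,
) -> list[EnrichmentResult]:
    """Hypergeometric enrichment of a query gene list in each set.

    For each set: with G = |universe|, K = |set ∩ universe|, n = |query|
    and k the observed overlap, p = P(X >= k) under Hypergeometric(G, K, n);
    q-values by Benjamini-Hochberg across every tested set.
    """
    universe = frozenset(universe)
    query = frozenset(query)
    if not universe:
        raise ValueError("empty universe")
    if not query:
        raise ValueError("empty query")
    if not query <= universe:
        missing = sorted(query - universe)[:5]
        raise ValueError(f"query genes outside the universe, e.g. {missing}")
    G, n = len(universe), len(query)
    rows = []
    for s in collection:
        members = s.members & universe
        K = len(members)
        k = len(members & query)
        if k == 0 and not include_zero_overlap:
            continue
        p = float(hypergeom.sf(k - 1, G, K, n)) if K else 1.0
        rows.append((s.name, s.description, k, K, min(p, 1.0)))
    qvals = benjamini_hochberg([r[4] for r in rows])
    results = [
        EnrichmentResult(
            set_name=name,
            description=desc,
            overlap_count=k,
            set_size=K,
            p_nominal=p,
            fdr_q=float(q),
        )
        for (name, desc, k, K, p), q in zip(rows, qvals)
    ]
    results.sort(key=lambda r: (r.fdr_q, r.set_name))
    return results


def _es_from_positions(
    positions: np.ndarray, scores: np.ndarray, n_total: int, weight_exponent: float
) -> float:
    """ES for one set given sorted 0-based hit positions in the ranked list."""
    m = positions.size
    if m == 0:
        raise ValueError("gene set has no members in the ranked list")
    if m == n_total:
        return 1.0  # no misses: the running sum climbs monotonically to 1
    w = np.abs(scores[positions]) ** weight_exponent
    total = w.sum()
    if total == 0:
        w = np.ones(m)
        total = float(m)
    cum = np.cumsum(w) / total
    miss = (positions - np.arange(m)) / (n_total - m)
    after = cum - miss            # running sum just after each hit
    before = np.concatenate([[0.0], cum[:-1]]) - miss  # just before each hit
    pos_extreme = after.max()
    neg_extreme = before.min()
    return float(pos_extreme if pos_extreme >= -neg_extreme else neg_extreme)


def preranked_es(
    ranked_genes,
    scores,
    gene_set,
    weight_exponent: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Enrichment score and full running-sum profile for one gene set.

    ``ranked_genes`` must be ordered by score descending; returns
    (ES, running sum after each list position).
    """
    genes = list(ranked_genes)
    s = np.asarray(list(scores), dtype=float)
    if len(genes) != s.size:
        raise ValueError("ranked_genes and scores differ in length")
    members = frozenset(gene_set)
    hit = np.fromiter((g in members for g in genes), bool, len(genes))
    if not hit.any():
        raise ValueError("gene set has no members in the ranked list")
    n, m = len(genes), int(hit.sum())
    w = np.zeros(n)
    w[hit] = np.abs(s[hit]) ** weight_exponent
    total = w.sum()
    if total == 0:
        w[hit] = 1.0
        total = float(m)
    steps = w / total
    if m < n:
        steps[~hit] = -1.0 / (n - m)
    profile = np.cumsum(steps)
    es = _es_from_positions(np.flatnonzero(hit), s, n, weight_exponent)
    return es, profile


def _null_es_pool(
    size: int,
    scores: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    weight_exponent: float,
) -> np.ndarray:
    n = scores.size
    out = np.empty(n_perm)
    for i in range(n_perm):
        pos = np.sort(rng.choice(n, size=size, replace=False))
        out[i] = _es_from_positions(pos, scores, n, weight_exponent)
    return out


def preranked_significance(
    ranked_genes,
    scores,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
) -> list[EnrichmentResult]:
    """Permutation significance for every set against one ranked list.

    Gene-label permutation null, nominal p from the sign-matched tail
    (with the add-one correction), NES = ES / mean(|null ES| of the same
    sign), and a GSEA-style sign-matched NES-based FDR. Deterministic
    under a fixed seed. Sets with no member in the ranked list are dropped
    with a log message.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be at least 10")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives coarse p-values", stacklevel=2)
    genes = list(ranked_genes)
    s = np.asarray(list(scores), dtype=float)
    index = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)

    tested = []  # (set, sorted positions)
    for gs in collection:
        pos = np.sort([index[g] for g in gs.members if g in index])
        if pos.size == 0:
            logger.info("set %s has no members in the ranked list; skipped", gs.name)
            continue
        tested.append((gs, pos))
    if not tested:
        return []

    sizes = sorted({pos.size for _, pos in tested})
    pools = {
        m: _null_es_pool(m, s, n_perm, rng, weight_exponent) for m in sizes
    }

    def same_sign_stats(pool: np.ndarray, es: float) -> tuple[float, float]:
        """(nominal p, mean |null| of matching sign) for one observed ES."""
        if es >= 0:
            side = pool[pool >= 0]
            more = int((side >= es).sum())
        else:
            side = pool[pool < 0]
            more = int((side <= es).sum())
        if side.size == 0:
            return 1.0, np.nan
        p = (1 + more) / (1 + side.size)
        return min(p, 1.0), float(np.abs(side).mean())

    obs = []
    null_nes_all = []
    for gs, pos in tested:
        es = _es_from_positions(pos, s, len(genes), weight_exponent)
        pool = pools[pos.size]
        p, denom = same_sign_stats(pool, es)
        nes = es / denom if denom and np.isfinite(denom) and denom > 0 else 0.0
        obs.append([gs, es, p, nes])
        # normalize the null pool of this size into null NES space
        pos_mean = np.abs(pool[pool >= 0]).mean() if (pool >= 0).any() else np.nan
        neg_mean = np.abs(pool[pool < 0]).mean() if (pool < 0).any() else np.nan
        nn = np.where(pool >= 0, pool / pos_mean, pool / neg_mean)
        null_nes_all.append(nn[np.isfinite(nn)])
    null_nes = np.concatenate(null_nes_all)

    obs_nes = np.array([o[3] for o in obs])
    qvals = _gsea_fdr(obs_nes, null_nes)

    results = [
        EnrichmentResult(
            set_name=gs.name,
            description=gs.description,
            overlap_count=len([g for g in gs.members if g in index]),
            set_size=len(gs.members),
            p_nominal=float(p),
            fdr_q=float(q),
            es=float(es),
            nes=float(nes),
        )
        for (gs, es, p, nes), q in zip(obs, qvals)
    ]
    results.sort(key=lambda r: (r.fdr_q, r.p_nominal, r.set_name))
    return results


def _gsea_fdr(obs_nes: np.ndarray, null_nes: np.ndarray) -> np.ndarray:
    """Sign-matched NES-based FDR: null tail fraction over observed tail
    fraction at each observed NES, capped at 1, monotonized from the most
    extreme NES inward."""
    q = np.ones(obs_nes.size)
    for sign in (1, -1):
        idx = np.flatnonzero(obs_nes >= 0) if sign > 0 else np.flatnonzero(obs_nes < 0)
        if idx.size == 0:
            continue
        null_side = null_nes[null_nes >= 0] if sign > 0 else null_nes[null_nes < 0]
        for i in idx:
            v = obs_nes[i]
            if sign > 0:
                null_frac = (null_side >= v).mean() if null_side.size else 1.0
                obs_frac = (obs_nes[idx] >= v).mean()
            else:
                null_frac = (null_side <= v).mean() if null_side.size else 1.0
                obs_frac = (obs_nes[idx] <= v).mean()
            q[i] = min(1.0, null_frac / obs_frac) if obs_frac > 0 else 1.0
        # monotonize: a more extreme NES never has a larger q
        order = idx[np.argsort(-sign * obs_nes[idx])]
        q[order] = np.minimum.accumulate(q[order])
    return q
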