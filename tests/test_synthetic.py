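"""The generator's planted structure must match its ground-truth sidecar."""

import numpy as np
import pytest

from mirhostnet import synthetic
from mirhostnet.errors import ConfigurationError
from mirhostnet.synthetic import SyntheticScenario, round_half_away


def scenario(**kw) -> SyntheticScenario:
    base = dict(
        n_genes=200,
        n_targets_per_predictor=30,
        tissues=("cardiac_muscle",),
        n_gene_sets=10,
        gene_set_size_range=(5, 10),
        seed=1,
    )
    base.update(kw)
    return SyntheticScenario(**base)


class TestAssociationVector:
    @pytest.mark.parametrize(
        "n_genes,frac,expected",
        [(1000, 0.1, round_half_away(0.1 * 999)), (200, 0.0, 0), (200, 1.0, 199)],
    )
    def test_exact_associated_count(self, n_genes, frac, expected):
        sc = scenario(n_genes=n_genes, assoc_fraction=frac, n_targets_per_predictor=10)
        vec, assoc = synthetic.generate_association_vector(sc, "cardiac_muscle")
        assert len(assoc) == expected
        above = {g for g, s in vec.scores.items() if s > sc.assoc_threshold}
        assert above == assoc  # disjoint-mixture construction is threshold-exact

    def test_scores_respect_mixture_components(self):
        sc = scenario(assoc_fraction=0.2)
        vec, assoc = synthetic.generate_association_vector(sc, "cardiac_muscle")
        c = sc.assoc_threshold
        for g, s in vec.scores.items():
            assert 0 <= s <= 1
            if g in assoc:
                assert s > c
            else:
                assert s < c

    def test_same_seed_identical_output(self):
        sc = scenario()
        v1, a1 = synthetic.generate_association_vector(sc, "cardiac_muscle")
        v2, a2 = synthetic.generate_association_vector(sc, "cardiac_muscle")
        assert v1.scores == v2.scores and a1 == a2

    def test_unknown_tissue_rejected(self):
        with pytest.raises(ConfigurationError):
            synthetic.generate_association_vector(scenario(), "liver")

    def test_host_gene_never_scored(self):
        sc = scenario()
        vec, _ = synthetic.generate_association_vector(sc, "cardiac_muscle")
        assert sc.host_gene not in vec.scores
        assert len(vec) == sc.n_genes - 1


class TestTargetPredictions:
    def test_counts_and_exact_overlap(self):
        sc = scenario(predictor_overlap=0.4)
        _, assoc = synthetic.generate_association_vector(sc, "cardiac_muscle")
        ta, tb = synthetic.generate_target_predictions(sc, assoc)
        assert len(ta) == len(tb) == sc.n_targets_per_predictor
        assert len(ta.targets & tb.targets) == round_half_away(0.4 * 30)
        assert sc.host_gene not in ta.targets | tb.targets

    def test_full_overlap_gives_identical_sets(self):
        sc = scenario(predictor_overlap=1.0)
        _, assoc = synthetic.generate_association_vector(sc, "cardiac_muscle")
        ta, tb = synthetic.generate_target_predictions(sc, assoc)
        assert ta.targets == tb.targets

    def test_zero_bias_avoids_associated_genes(self):
        sc = scenario(target_assoc_bias=0.0, assoc_fraction=0.2)
        _, assoc = synthetic.generate_association_vector(sc, "cardiac_muscle")
        ta, tb = synthetic.generate_target_predictions(sc, assoc)
        assert not (ta.targets | tb.targets) & assoc

    def test_neutral_bias_matches_assoc_fraction(self):
        """Monte Carlo: with bias 1 the associated fraction among targets
        matches assoc_fraction within 3 standard errors."""
        frac = 0.2
        hits = total = 0
        for seed in range(1000):
            sc = scenario(
                n_genes=100, n_targets_per_predictor=10, assoc_fraction=frac,
                predictor_overlap=0.0, seed=seed,
            )
            _, assoc = synthetic.generate_association_vector(sc, "cardiac_muscle")
            ta, tb = synthetic.generate_target_predictions(sc, assoc)
            union = ta.targets | tb.targets
            hits += len(union & assoc)
            total += len(union)
        se = np.sqrt(frac * (1 - frac) / total)
        assert abs(hits / total - frac) < 3 * se

    def test_infeasible_draw_rejected(self):
        sc = scenario(n_genes=50, n_targets_per_predictor=40, predictor_overlap=0.0)
        _, assoc = synthetic.generate_association_vector(sc, "cardiac_muscle")
        with pytest.raises(ConfigurationError):
            synthetic.generate_target_predictions(sc, assoc)  # union of 80 from 49


class TestTissueGraph:
    def test_zero_density_empty_graph(self):
        sc = scenario(edge_density=0.0)
        g = synthetic.generate_tissue_graph(sc, "cardiac_muscle", frozenset(), frozenset())
        assert len(g.edges) == 0 and len(g.nodes) == sc.n_genes

    def test_density_and_weights(self):
        sc = scenario(edge_density=0.05)
        _, assoc = synthetic.generate_association_vector(sc, "cardiac_muscle")
        ta, tb = synthetic.generate_target_predictions(sc, assoc)
        g = synthetic.generate_tissue_graph(
            sc, "cardiac_muscle", assoc, ta.targets | tb.targets
        )
        n_pairs = sc.n_genes * (sc.n_genes - 1) / 2
        observed = len(g.edges) / n_pairs
        se = np.sqrt(0.05 * 0.95 / n_pairs)
        assert abs(observed - 0.05) < 4 * se
        assert all(0 < w <= 1 for w in g.edges.values())

    def test_neutral_bias_no_degree_elevation(self):
        """With centrality_bias=1, boosted-node mean degree tracks the
        universe mean (Monte Carlo over 200 seeds, 3-SE band)."""
        diffs = []
        for seed in range(200):
            sc = scenario(n_genes=120, edge_density=0.05, centrality_bias=1.0, seed=seed)
            _, assoc = synthetic.generate_association_vector(sc, "cardiac_muscle")
            ta, tb = synthetic.generate_target_predictions(sc, assoc)
            g = synthetic.generate_tissue_graph(
                sc, "cardiac_muscle", assoc, ta.targets | tb.targets
            )
            boosted = assoc & (ta.targets | tb.targets)
            if not boosted:
                continue
            deg = {v: 0 for v in g.nodes}
            for (a, b) in g.edges:
                deg[a] += 1
                deg[b] += 1
            diffs.append(
                np.mean([deg[v] for v in boosted]) - np.mean(list(deg.values()))
            )
        se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) < 3 * se

    def test_planted_bias_elevates_degree(self):
        """centrality_bias=5 puts boosted mean degree above the universe
        mean in at least 95% of seeds."""
        wins = trials = 0
        for seed in range(200):
            sc = scenario(
                n_genes=500, n_targets_per_predictor=100, edge_density=0.02,
                centrality_bias=5.0, seed=seed,
            )
            _, assoc = synthetic.generate_association_vector(sc, "cardiac_muscle")
            ta, tb = synthetic.generate_target_predictions(sc, assoc)
            g = synthetic.generate_tissue_graph(
                sc, "cardiac_muscle", assoc, ta.targets | tb.targets
            )
            boosted = assoc & (ta.targets | tb.targets)
            if not boosted:
                continue
            deg = {v: 0 for v in g.nodes}
            for (a, b) in g.edges:
                deg[a] += 1
                deg[b] += 1
            trials += 1
            wins += np.mean([deg[v] for v in boosted]) > np.mean(list(deg.values()))
        assert wins / trials >= 0.95


class TestGeneSets:
    def test_planting_forces_membership(self):
        sc = scenario(planted_set_overlap=5)
        top = tuple(f"G{i:05d}" for i in range(1, 21))
        coll, planted_name = synthetic.generate_gene_set_collection(sc, top)
        planted = coll[planted_name]
        assert set(top[:5]) <= planted.members
        lo, hi = sc.gene_set_size_range
        for s in coll:
            assert lo <= len(s.members) <= max(hi, 5)

    def test_overplanting_rejected(self):
        sc = scenario(planted_set_overlap=5)
        with pytest.raises(ConfigurationError):
            synthetic.generate_gene_set_collection(sc, ("G00001",))

    def test_no_planting_no_guarantee(self):
        sc = scenario(planted_set_overlap=0)
        coll, _ = synthetic.generate_gene_set_collection(sc, ())
        assert len(coll) == sc.n_gene_sets


class TestDeterminism:
    def test_written_scenario_byte_identical(self, tmp_path, small_scenario):
        b1 = synthetic.generate_scenario(small_scenario)
        b2 = synthetic.generate_scenario(small_scenario)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        p1 = synthetic.write_scenario(b1, d1)
        p2 = synthetic.write_scenario(b2, d2)
        assert set(k for k in p1) == set(k for k in p2)
        for key in p1:
            assert (
                open(p1[key], "rb").read() == open(p2[key], "rb").read()
            ), f"{key} differs between identical runs"


def test_round_half_away_rule():
    assert [round_half_away(x) for x in (0.5, 1.5, 2.5, -0.5, 99.9)] == [1, 2, 3, -1, 100]
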