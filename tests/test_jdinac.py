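import numpy as np
import pytest

from snpdiffnet import (
    DifferentialNetwork,
    ImportanceTable,
    JdinacConfig,
    PairDensityModel,
    PairKDE,
    build_network,
    find_hubs,
    fit_pair_density,
    jdinac_importance,
    jdinac_single_split,
    log_density_ratio,
)
from snpdiffnet.ingest import GeneScoreMatrix


class TestPairKDE:
    def test_density_at_origin_standard_normal(self, rng):
        kde = PairKDE(rng.standard_normal((1000, 2)))
        target = 1 / (2 * np.pi)
        assert kde.pdf([[0.0, 0.0]])[0] == pytest.approx(target, rel=0.15)

    def test_integrates_to_one_on_covering_grid(self, rng):
        kde = PairKDE(rng.standard_normal((400, 2)))
        xs = np.linspace(-5, 5, 161)
        gx, gy = np.meshgrid(xs, xs)
        integral = kde.pdf(np.column_stack([gx.ravel(), gy.ravel()])).sum() * (xs[1] - xs[0]) ** 2
        assert integral == pytest.approx(1.0, abs=1e-2)

    def test_identical_samples_give_identical_evaluations(self, rng):
        data = rng.standard_normal((50, 2))
        pts = rng.standard_normal((20, 2))
        assert np.array_equal(PairKDE(data).logpdf(pts), PairKDE(data.copy()).logpdf(pts))

    def test_too_few_points_error(self):
        with pytest.raises(ValueError, match=">= 5"):
            fit_pair_density([1, 2, 3, 4], [1, 2, 3, 4])

    def test_zero_variance_dimension_falls_back_with_warning(self):
        data = np.column_stack([np.full(10, 2.0), np.arange(10.0)])
        with pytest.warns(UserWarning, match="zero variance"):
            kde = PairKDE(data)
        assert np.all(kde.bandwidths > 0)
        assert np.isfinite(kde.logpdf([[2.0, 5.0]])[0])

    def test_silverman_bandwidths(self, rng):
        data = rng.standard_normal((200, 2)) * [1.0, 3.0]
        kde = PairKDE(data)
        expect = data.std(axis=0, ddof=1) * 200 ** (-1 / 6)
        assert np.allclose(kde.bandwidths, expect)


class TestLogDensityRatio:
    def test_same_fitted_sample_gives_exact_zero(self, rng):
        data = rng.standard_normal((100, 2))
        model = PairDensityModel("a", "b", PairKDE(data), PairKDE(data.copy()))
        lr = log_density_ratio(model, rng.standard_normal((30, 2)))
        assert np.all(lr == 0.0)

    def test_two_gaussian_closed_form(self, rng):
        # f1 = N((1,1), I), f0 = N((0,0), I): log ratio at x is x1 + x2 - 1
        model = PairDensityModel(
            "a", "b",
            PairKDE(rng.standard_normal((4000, 2)) + 1.0),
            PairKDE(rng.standard_normal((4000, 2))),
        )
        lr = log_density_ratio(model, [[1.0, 1.0]])[0]
        assert lr == pytest.approx(1.0, abs=0.15)

    def test_point_outside_both_supports_floors_to_zero(self, rng):
        model = PairDensityModel(
            "a", "b",
            PairKDE(rng.standard_normal((50, 2))),
            PairKDE(rng.standard_normal((50, 2)) + 0.5),
        )
        assert log_density_ratio(model, [[500.0, -500.0]], floor=1e-10)[0] == 0.0

    def test_label_swap_negates_features_exactly(self, rng):
        d1 = rng.standard_normal((60, 2))
        d0 = rng.standard_normal((60, 2)) * 1.5
        pts = rng.standard_normal((25, 2))
        fwd = log_density_ratio(PairDensityModel("a", "b", PairKDE(d1), PairKDE(d0)), pts)
        rev = log_density_ratio(PairDensityModel("a", "b", PairKDE(d0), PairKDE(d1)), pts)
        assert np.array_equal(fwd, -rev)

    def test_floor_must_be_positive(self, rng):
        data = rng.standard_normal((20, 2))
        model = PairDensityModel("a", "b", PairKDE(data), PairKDE(data))
        with pytest.raises(ValueError):
            log_density_ratio(model, [[0.0, 0.0]], floor=0.0)


class TestNetworkAssembly:
    def make_imp(self):
        return ImportanceTable({("A", "B"): 13, ("A", "C"): 11, ("B", "C"): 2}, T=20)

    def test_threshold_and_ranking(self):
        net = build_network(self.make_imp(), min_score=10)
        assert [(a, b) for a, b, _ in net.edges] == [("A", "B"), ("A", "C")]
        assert net.nodes == ["A", "B", "C"]

    def test_min_score_above_max_gives_empty_network(self):
        net = build_network(self.make_imp(), min_score=14)
        assert net.edges == [] and net.nodes == []

    def test_min_score_zero_keeps_every_pair(self):
        net = build_network(self.make_imp(), min_score=0)
        assert len(net.edges) == 3

    def test_rank_ties_break_lexicographically(self):
        imp = ImportanceTable({("B", "C"): 5, ("A", "D"): 5, ("A", "B"): 9}, T=10)
        net = build_network(imp, 1)
        assert [(a, b) for a, b, _ in net.edges] == [("A", "B"), ("A", "D"), ("B", "C")]

    def test_omega_bounds_enforced(self):
        with pytest.raises(ValueError):
            ImportanceTable({("A", "B"): 11}, T=10)

    def test_star_hub(self):
        edges = [("h", f"l{k}", 5) for k in range(4)]
        net = DifferentialNetwork(
            nodes=["h", "l0", "l1", "l2", "l3"], edges=edges, min_score=3, T=10
        )
        assert find_hubs(net, 4) == ["h"]

    def test_triangle_and_empty_have_no_degree4_hub(self):
        tri = DifferentialNetwork(
            nodes=["a", "b", "c"],
            edges=[("a", "b", 3), ("a", "c", 3), ("b", "c", 3)],
            min_score=1, T=10,
        )
        assert find_hubs(tri, 4) == []
        empty = DifferentialNetwork(nodes=[], edges=[], min_score=1, T=10)
        assert find_hubs(empty, 4) == []

    def test_graph_export(self, tmp_path):
        net = build_network(self.make_imp(), min_score=10)
        net.min_hub_degree = 2
        net.write_sif(tmp_path / "n.sif")
        net.write_graphml(tmp_path / "n.graphml")
        sif = (tmp_path / "n.sif").read_text().splitlines()
        assert sif[0] == "A\tinteracts\tB"
        import networkx as nx

        g = nx.read_graphml(tmp_path / "n.graphml")
        assert g.nodes["A"]["hub"] is True
        assert g.edges["A", "B"]["omega"] == 13


class TestSplitInference:
    def test_single_split_is_deterministic(self, small_cohort, fast_jdinac):
        _, g, _, s = small_cohort
        a = jdinac_single_split(s, g.y, None, fast_jdinac, split_seed=5)
        b = jdinac_single_split(s, g.y, None, fast_jdinac, split_seed=5)
        assert a == b

    def test_importance_bounded_and_symmetric_pairs(self, small_cohort, fast_jdinac):
        _, g, _, s = small_cohort
        imp = jdinac_importance(s, g.y, None, fast_jdinac)
        p = s.n_genes
        assert len(imp.omega) == p * (p - 1) // 2
        assert all(0 <= w <= fast_jdinac.T for w in imp.omega.values())
        assert all(a < b for a, b in imp.omega)  # unordered pairs stored sorted

    def test_t_equals_one_gives_binary_omega(self, small_cohort):
        _, g, _, s = small_cohort
        cfg = JdinacConfig(T=1, cv_folds=3, n_lambdas=6, seed=2)
        imp = jdinac_importance(s, g.y, None, cfg)
        assert set(imp.omega.values()) <= {0, 1}

    def test_sample_permutation_leaves_importance_unchanged(self, small_cohort, rng):
        _, g, _, s = small_cohort
        cfg = JdinacConfig(T=2, cv_folds=3, n_lambdas=6, seed=3)
        base = jdinac_importance(s, g.y, None, cfg)
        perm = rng.permutation(len(s.sample_ids))
        s2 = GeneScoreMatrix(
            sample_ids=[s.sample_ids[i] for i in perm],
            gene_ids=s.gene_ids,
            scores=s.scores[perm],
        )
        permuted = jdinac_importance(s2, g.y[perm], None, cfg)
        assert permuted.omega == base.omega

    def test_needs_both_classes_and_two_genes(self, small_cohort, fast_jdinac):
        _, g, _, s = small_cohort
        with pytest.raises(ValueError, match="class"):
            jdinac_single_split(s, np.zeros(len(g.y), int), None, fast_jdinac, 1)
        one_gene = GeneScoreMatrix(s.sample_ids, s.gene_ids[:1], s.scores[:, :1])
        with pytest.raises(ValueError, match="2 genes"):
            jdinac_single_split(one_gene, g.y, None, fast_jdinac, 1)

    def test_missing_scores_rejected(self, small_cohort, fast_jdinac):
        _, g, _, s = small_cohort
        bad = s.scores.copy()
        bad[0, 0] = np.nan
        s2 = GeneScoreMatrix(s.sample_ids, s.gene_ids, bad)
        with pytest.raises(ValueError, match="missing"):
            jdinac_single_split(s2, g.y, None, fast_jdinac, 1)

    def test_planted_pair_beats_null_pairs(self, small_cohort):
        """Mean importance of the planted pair exceeds the null-pair mean."""
        _, g, _, s = small_cohort
        cfg = JdinacConfig(T=4, cv_folds=3, n_lambdas=10, seed=4)
        imp = jdinac_importance(s, g.y, g.covariate_matrix(), cfg)
        planted = imp.omega[("a", "b")]
        null_mean = np.mean([w for p, w in imp.omega.items() if p != ("a", "b")])
        assert planted > null_mean

    def test_importance_table_roundtrip(self, tmp_path):
        imp = ImportanceTable({("A", "B"): 3, ("A", "C"): 1}, T=4)
        imp.write(tmp_path / "imp.tsv")
        import pandas as pd

        df = pd.read_csv(tmp_path / "imp.tsv", sep="\t")
        assert list(df.columns) == ["gene1", "gene2", "importance", "T"]
        assert df.iloc[0].importance == 3
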