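import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from splinegan.network import (
    EdgeTable,
    PcorMatrix,
    build_gan,
    dynamic_weights,
    edge_probabilities,
    graph_density,
    reconstruct_gan,
    shrinkage_pcor,
)
from splinegan.simulate import simulate_ggm_timecourse


class TestDynamicWeights:
    def test_equally_spaced_times_give_half_weight_endpoints(self):
        w = dynamic_weights(np.array([1.0, 2.0, 3.0, 4.0, 5.0]))
        assert np.allclose(w, np.array([0.5, 1, 1, 1, 0.5]) / 4.0)
        assert w.sum() == pytest.approx(1.0)

    def test_paper_time_grid_matches_hand_trapezoid(self):
        w = dynamic_weights(np.array([0.25, 0.5, 1, 2, 4, 8, 24]))
        expected = np.array([0.125, 0.375, 0.75, 1.5, 3, 10, 8])
        assert np.allclose(w, expected / expected.sum())

    def test_replicates_split_their_time_weight(self):
        single = dynamic_weights(np.array([0.25, 0.5, 1, 2, 4, 8, 24]))
        double = dynamic_weights(np.repeat([0.25, 0.5, 1, 2, 4, 8, 24], 2))
        assert np.allclose(double, np.repeat(single, 2) / 2.0)

    def test_single_time_rejected(self):
        with pytest.raises(ValueError):
            dynamic_weights(np.array([2.0, 2.0]))


class TestShrinkagePcor:
    def test_two_genes_partial_equals_shrunken_correlation(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((2, 20))
        pc = shrinkage_pcor(x)
        r = np.corrcoef(x)[0, 1]
        assert pc.matrix[0, 1] == pytest.approx((1 - pc.shrinkage_lambda) * r, abs=1e-10)

    def test_lambda_zero_matches_direct_covariance_inversion(self):
        rng = np.random.default_rng(1)
        omega = np.array([[1.0, 0.4, 0.0], [0.4, 1.0, 0.3], [0.0, 0.3, 1.0]])
        chol = np.linalg.cholesky(np.linalg.inv(omega))
        x = chol @ rng.standard_normal((3, 200))
        w = np.full(200, 1 / 200)
        pc = shrinkage_pcor(x, weights=w, shrinkage=0.0)
        # oracle: weighted sample covariance -> invert -> standardize
        cov = np.cov(x, aweights=w, ddof=0)
        prec = np.linalg.inv(cov)
        d = np.sqrt(np.diag(prec))
        oracle = -prec / np.outer(d, d)
        np.fill_diagonal(oracle, 1.0)
        assert np.allclose(pc.matrix, oracle, atol=1e-8)

    def test_uniform_weights_reduce_to_static_estimator(self):
        """With uniform weights lambda* must equal the classic unweighted formula."""
        rng = np.random.default_rng(2)
        x = rng.standard_normal((6, 15))
        pc = shrinkage_pcor(x)  # weights default to uniform
        n = x.shape[1]
        xs = (x - x.mean(1, keepdims=True)) / x.std(1, ddof=1, keepdims=True)
        r = (xs @ xs.T) / (n - 1)
        iu = np.triu_indices(6, 1)
        var_sum = 0.0
        for i, j in zip(*iu):
            u = xs[i] * xs[j]
            var_sum += n / (n - 1) ** 3 * ((u - u.mean()) ** 2).sum()
        lam_oracle = min(1.0, var_sum / (r[iu] ** 2).sum())
        assert pc.shrinkage_lambda == pytest.approx(lam_oracle, abs=1e-10)

    def test_pure_noise_high_dimension_shrinks_hard(self):
        rng = np.random.default_rng(3)
        pc = shrinkage_pcor(rng.standard_normal((80, 12)))
        iu = np.triu_indices(80, 1)
        assert pc.shrinkage_lambda > 0.6
        assert np.abs(pc.matrix[iu]).max() < 0.2

    def test_structural_invariants_and_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((8, 25))
        genes = [f"G{i}" for i in range(8)]
        pc = shrinkage_pcor(x, genes=genes)
        assert 0.0 <= pc.shrinkage_lambda <= 1.0
        assert np.allclose(pc.matrix, pc.matrix.T)
        assert np.allclose(np.diag(pc.matrix), 1.0)
        assert np.all(np.abs(pc.matrix) <= 1.0)
        perm = rng.permutation(8)
        pc_perm = shrinkage_pcor(x[perm], genes=[genes[i] for i in perm])
        assert np.allclose(pc_perm.matrix, pc.matrix[np.ix_(perm, perm)], atol=1e-10)

    def test_constant_gene_rejected(self):
        x = np.vstack([np.ones(10), np.random.default_rng(0).standard_normal(10)])
        with pytest.raises(ValueError, match="zero weighted variance"):
            shrinkage_pcor(x)


class TestEdgeProbabilities:
    def test_all_zero_partial_correlations_give_zero_probabilities(self):
        pc = PcorMatrix(genes=list("ABCD"), matrix=np.eye(4), shrinkage_lambda=1.0,
                        sample_weights=np.full(10, 0.1), n_eff=10.0)
        et = edge_probabilities(pc)
        assert np.allclose(et.table["prob"], 0.0)

    def test_null_data_rarely_reaches_the_edge_threshold(self):
        rng = np.random.default_rng(7)
        pc = shrinkage_pcor(rng.standard_normal((50, 30)))
        et = edge_probabilities(pc)
        assert (et.table["prob"] >= 0.95).mean() <= 0.01

    def test_probability_monotone_in_abs_pcor_given_mixture(self):
        rng = np.random.default_rng(8)
        pc = shrinkage_pcor(rng.standard_normal((30, 40)))
        et = edge_probabilities(pc)
        tab = et.table.sort_values("pcor")
        # within each sign, larger |r| should not get smaller prob by much more
        # than KDE wiggle; check the extreme deciles dominate the middle
        lo = tab["prob"].iloc[: len(tab) // 10].mean()
        mid = tab["prob"].iloc[4 * len(tab) // 10: 6 * len(tab) // 10].mean()
        hi = tab["prob"].iloc[-len(tab) // 10:].mean()
        assert lo >= mid and hi >= mid

    def test_planted_strong_edge_detected_across_seeds(self):
        times = tuple(np.linspace(0.25, 24, 20))
        hits = 0
        for seed in range(50):
            expt, truth = simulate_ggm_timecourse(
                10, 1, 0.8, times=times, reps=2, seed=seed
            )
            _, et, _ = reconstruct_gan(expt, expt.genes)
            (edge,) = truth.true_network
            tab = et.table
            row = tab[
                ((tab.gene_a == edge[0]) & (tab.gene_b == edge[1]))
                | ((tab.gene_a == edge[1]) & (tab.gene_b == edge[0]))
            ]
            hits += float(row["prob"].iloc[0]) >= 0.95
        assert hits >= 45  # >= 90% of 50 replicate seeds


def _edge_table(probs):
    n = len(probs)
    return EdgeTable(
        table=pd.DataFrame(
            {
                "gene_a": [f"A{i}" for i in range(n)],
                "gene_b": [f"B{i}" for i in range(n)],
                "pcor": np.linspace(0.1, 0.9, n),
                "prob": probs,
            }
        ),
        eta0=0.9,
        kappa=20.0,
    )


class TestBuildGan:
    def test_threshold_is_inclusive(self):
        gan = build_gan(_edge_table([0.95, 0.9499]), threshold=0.95)
        assert gan.n_edges == 1

    def test_lower_threshold_retains_superset(self):
        et = _edge_table(list(np.linspace(0.5, 1.0, 12)))
        loose = build_gan(et, threshold=0.90)
        tight = build_gan(et, threshold=0.95)
        assert tight.edge_set() <= loose.edge_set()

    def test_no_passing_edge_gives_empty_network(self):
        gan = build_gan(_edge_table([0.5, 0.7]), threshold=0.95)
        assert gan.is_empty and gan.n_nodes == 0

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            build_gan(_edge_table([0.5]), threshold=1.5)


class TestGraphDensity:
    @pytest.mark.parametrize(
        "nodes,edges,expected",
        [
            (1140, 12198, 0.00939),
            (3483, 114629, 0.00945),
            (2735, 84695, 0.01133),
            (336, 3268, 0.02903),
            (2299, 126378, 0.02392),
            (773, 16862, 0.02826),
            (3, 3, 0.5),
        ],
    )
    def test_reported_densities(self, nodes, edges, expected):
        assert round(graph_density(nodes, edges), 5) == pytest.approx(expected)

    def test_errors(self):
        with pytest.raises(ValueError):
            graph_density(1, 0)
        with pytest.raises(ValueError):
            graph_density(5, -1)
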