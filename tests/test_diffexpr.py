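import numpy as np
import pytest

from splinegan.design import build_design
from splinegan.diffexpr import (
    ModerationParams,
    adjust_bh,
    differential_expression,
    estimate_moderation,
    fit_gene_models,
    fit_ols,
    moderated_f,
    select_differential,
)
from splinegan.simulate import simulate_de
from tests.conftest import make_experiment


class TestOls:
    def test_matches_normal_equations_oracle(self, paper_layout_experiment):
        design = build_design(paper_layout_experiment, df=3)
        fits = fit_gene_models(paper_layout_experiment, design)
        x = design.matrix
        y = paper_layout_experiment.values.to_numpy()
        oracle = np.linalg.pinv(x.T @ x) @ x.T @ y.T  # brute-force normal equations
        assert np.allclose(fits.coefficients, oracle.T, atol=1e-8)
        resid = y - fits.coefficients @ x.T
        assert np.allclose(fits.s2, (resid**2).sum(axis=1) / (28 - 8), atol=1e-10)

    def test_identical_groups_give_exactly_zero_differential_block(self):
        rng = np.random.default_rng(1)
        half = rng.normal(size=(5, 14))
        expt = make_experiment(np.hstack([half, half]))  # treatment copies control
        design = build_design(expt, df=3)
        fits = fit_gene_models(expt, design)
        assert np.allclose(fits.diff_coefficients, 0.0, atol=1e-8)

    def test_exact_model_fit_yields_zero_residual_variance(self):
        rng = np.random.default_rng(2)
        expt0 = make_experiment(rng.normal(size=(1, 28)))
        design = build_design(expt0, df=3)
        beta = rng.normal(size=8)
        expt = make_experiment((design.matrix @ beta)[None, :])
        fits = fit_gene_models(expt, build_design(expt, df=3))
        assert fits.s2[0] == pytest.approx(0.0, abs=1e-16)


class TestModeration:
    def test_hyperparameter_recovery_from_simulated_variances(self):
        rng = np.random.default_rng(10)
        d0_true, s02_true, dg, n = 4.0, 0.05, 20, 5000
        sigma2 = d0_true * s02_true / rng.chisquare(d0_true, n)
        s2 = sigma2 * rng.chisquare(dg, n) / dg
        params = estimate_moderation(s2, dg)
        assert params.prior_df == pytest.approx(d0_true, rel=0.25)
        assert params.prior_var == pytest.approx(s02_true, rel=0.10)

    def test_equal_variances_trigger_infinite_prior_df(self):
        params = estimate_moderation(np.full(10, 0.7), 20)
        assert np.isinf(params.prior_df)
        assert np.allclose(params.posterior_var, 0.7)

    def test_two_genes_with_unit_variances(self):
        params = estimate_moderation(np.array([1.0, 1.0]), 5)
        assert np.allclose(params.posterior_var, [1.0, 1.0])

    def test_posterior_between_prior_and_sample_variance(self):
        rng = np.random.default_rng(4)
        s2 = rng.chisquare(5, 200) / 5 * 0.1
        params = estimate_moderation(s2, 10)
        lo = np.minimum(s2, params.prior_var)
        hi = np.maximum(s2, params.prior_var)
        assert np.all(params.posterior_var >= lo - 1e-12)
        assert np.all(params.posterior_var <= hi + 1e-12)

    def test_zero_variance_genes_still_get_positive_posterior(self):
        rng = np.random.default_rng(5)
        s2 = np.concatenate([[0.0], rng.chisquare(10, 100) / 10])
        params = estimate_moderation(s2, 10)
        assert params.posterior_var[0] > 0

    def test_all_zero_variances_is_an_error(self):
        with pytest.raises(ValueError):
            estimate_moderation(np.zeros(5), 10)


class TestModeratedF:
    def test_prior_df_zero_recovers_classical_block_f(self, paper_layout_experiment):
        design = build_design(paper_layout_experiment, df=3)
        fits = fit_gene_models(paper_layout_experiment, design)
        moderation = ModerationParams(prior_df=0.0, prior_var=1.0, posterior_var=fits.s2)
        f_stat, _ = moderated_f(fits, moderation)
        # oracle: full vs reduced model residual sums of squares
        x_full = design.matrix
        x_red = design.matrix[:, : design.m + 1]
        y = paper_layout_experiment.values.to_numpy()
        for g in range(y.shape[0]):
            rss_full = _rss(y[g], x_full)
            rss_red = _rss(y[g], x_red)
            f_oracle = (rss_red - rss_full) / (design.m + 1) / fits.s2[g]
            assert f_stat[g] == pytest.approx(f_oracle, abs=1e-8 * max(1.0, f_oracle))

    def test_zero_differential_gives_f_zero_p_one(self):
        rng = np.random.default_rng(6)
        half = rng.normal(size=(3, 14))
        expt = make_experiment(np.hstack([half, half]))
        design = build_design(expt, df=3)
        fits = fit_gene_models(expt, design)
        f_stat, p = moderated_f(fits, estimate_moderation(fits.s2, fits.residual_df))
        assert np.allclose(f_stat, 0.0, atol=1e-16)
        assert np.allclose(p, 1.0)

    def test_quadratic_in_differential_coefficients(self, paper_layout_experiment):
        design = build_design(paper_layout_experiment, df=3)
        fits = fit_gene_models(paper_layout_experiment, design)
        moderation = estimate_moderation(fits.s2, fits.residual_df)
        f1, _ = moderated_f(fits, moderation)
        fits.coefficients = fits.coefficients.copy()
        fits.coefficients[:, design.diff_slice] *= 2.0
        f2, _ = moderated_f(fits, moderation)
        assert np.allclose(f2, 4.0 * f1)

    def test_invariant_under_basis_reparameterization(self, paper_layout_experiment):
        """Any design spanning the same space yields identical moderated F."""
        expt = paper_layout_experiment
        design = build_design(expt, df=3)
        res = differential_expression(expt, df=3)
        # alternative parameterization: QR-orthonormalized group blocks
        q, _ = np.linalg.qr(design.matrix[:, :4])
        x_alt = np.column_stack([q, expt.group_indicator()[:, None] * q])
        coef, s2, dg, cov = fit_ols(expt.values.to_numpy(), x_alt, 4)
        from splinegan.diffexpr import GeneFits

        fits_alt = GeneFits(expt.genes, coef, s2, dg, cov, m=3)
        moderation = estimate_moderation(s2, dg)
        f_alt, _ = moderated_f(fits_alt, moderation)
        assert np.allclose(f_alt, res.table["F"].to_numpy(), atol=1e-8)


def _rss(y, x):
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    r = y - x @ coef
    return float(r @ r)


class TestBhAndSelection:
    def test_hand_computed_example(self):
        assert np.allclose(adjust_bh(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03])

    def test_degenerate_inputs(self):
        assert np.allclose(adjust_bh(np.array([0.2])), [0.2])
        assert np.allclose(adjust_bh(np.ones(4)), 1.0)
        with pytest.raises(ValueError):
            adjust_bh(np.array([0.5, 1.5]))

    def test_selection_is_strict_and_ordered(self):
        import pandas as pd

        table = pd.DataFrame(
            {"gene": ["A", "B", "C"], "adj_p": [0.051, 0.05, 0.049]}
        )
        assert select_differential(table, fdr=0.05) == ["C"]
        assert select_differential(table.iloc[0:0], fdr=0.05) == []

    def test_power_on_strong_effects(self):
        expt, truth = simulate_de(2000, frac_de=0.05, effect_size=3.0, seed=2)
        res = differential_expression(expt)
        selected = set(select_differential(res.table))
        assert len(truth.de_genes) == 100
        assert len(selected & truth.de_genes) >= 80
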