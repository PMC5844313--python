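"""Covariance assembly, restricted likelihood, REML fits and the LRT."""

import numpy as np
import pytest

from interplot.geometry import (
    CompetitionFunction,
    FunctionKind,
    build_incidence,
    clone_index_from_layout,
)
from interplot.mixed_model import (
    CHISQ_CRIT_1DF,
    CHISQ_CRIT_2DF,
    ModelKind,
    ModelSpec,
    VarianceComponents,
    assemble_V,
    fit_reml,
    lrt,
    predict,
    reml_loglik,
)
from interplot.simulate import SimParams, simulate_trial

from conftest import grid_layout, strip_layout


def _toy_spec(kind=ModelKind.BASE, n_ranges=4, n_cols=3, n_clones=5, seed=0, S=None):
    rng = np.random.default_rng(seed)
    clones = [f"G{i}" for i in rng.integers(0, n_clones, size=n_ranges * n_cols)]
    layout = grid_layout(n_ranges, n_cols, clones=clones)
    index = clone_index_from_layout(layout)
    inc = build_incidence(layout, index, CompetitionFunction(FunctionKind.NN_LONG))
    g = len(index)
    A = rng.standard_normal((g, 2 * g))
    K = A @ A.T / (2 * g) + 0.2 * np.eye(g)
    return ModelSpec(kind, inc, K, S=S), layout


def oracle_restricted_loglik(y, V):
    """Literal dense evaluation of the restricted likelihood (intercept-only)."""
    n = len(y)
    Vinv = np.linalg.inv(V)
    one = np.ones(n)
    xvx = one @ Vinv @ one
    mu = (one @ Vinv @ y) / xvx
    r = y - mu
    sign, logdet = np.linalg.slogdet(V)
    assert sign > 0
    return -0.5 * ((n - 1) * np.log(2 * np.pi) + logdet + np.log(xvx) + r @ Vinv @ r)


class TestAssembleV:
    def test_base_identity_kinship(self):
        spec, _ = _toy_spec()
        spec = ModelSpec(ModelKind.BASE, spec.incidence, np.eye(spec.K.shape[0]))
        vc = VarianceComponents(sigma_g2=1.0, sigma_e2=1.0)
        V = assemble_V(spec, vc)
        Z1 = spec.incidence.Z1
        np.testing.assert_allclose(V, Z1 @ Z1.T + np.eye(len(V)), atol=1e-12)

    def test_m1_nests_base_when_competition_vanishes(self):
        spec1, _ = _toy_spec(ModelKind.M1)
        spec0 = ModelSpec(ModelKind.BASE, spec1.incidence, spec1.K)
        vc1 = VarianceComponents(sigma_g2=0.7, sigma_c2=0.0, sigma_gc=0.0, sigma_e2=0.4)
        vc0 = VarianceComponents(sigma_g2=0.7, sigma_e2=0.4)
        np.testing.assert_allclose(assemble_V(spec1, vc1), assemble_V(spec0, vc0), atol=1e-12)

    def test_m2_hand_computed_strip(self):
        # 3 plots stacked across ranges; II is the 0/1 tridiagonal matrix
        layout = grid_layout(3, 1, clones=["A", "B", "C"])
        inc = build_incidence(
            layout, {"A": 0, "B": 1, "C": 2}, CompetitionFunction(FunctionKind.NN_LONG)
        )
        spec = ModelSpec(ModelKind.M2, inc, np.eye(3))
        vc = VarianceComponents(sigma_g2=0.0, sigma_p2=1.0, sigma_pr=0.0, sigma_r2=1.0)
        II = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        np.testing.assert_allclose(
            assemble_V(spec, vc), II @ II.T + np.eye(3), atol=1e-12
        )


class TestRemlLoglik:
    @pytest.mark.parametrize("kind", [ModelKind.BASE, ModelKind.M1, ModelKind.M2, ModelKind.M3])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_literal_dense_oracle(self, kind, seed):
        spec, layout = _toy_spec(kind, n_ranges=5, n_cols=3, seed=seed)
        rng = np.random.default_rng(seed + 100)
        y = rng.standard_normal(layout.n_plots)
        vc = VarianceComponents(
            sigma_g2=0.8,
            sigma_c2=0.3 if spec.has_genetic_competition else 0.0,
            sigma_gc=0.2 if spec.has_genetic_competition else 0.0,
            sigma_p2=0.5 if spec.has_error_competition else 0.0,
            sigma_r2=0.9 if spec.has_error_competition else 0.0,
            sigma_pr=-0.3 if spec.has_error_competition else 0.0,
            sigma_e2=0.0 if spec.has_error_competition else 0.9,
        )
        ours = reml_loglik(y, spec, vc)
        oracle = oracle_restricted_loglik(y, assemble_V(spec, vc))
        assert ours == pytest.approx(oracle, abs=1e-8)

    def test_shift_invariance(self):
        spec, layout = _toy_spec()
        rng = np.random.default_rng(7)
        y = rng.standard_normal(layout.n_plots)
        vc = VarianceComponents(sigma_g2=1.0, sigma_e2=1.0)
        assert reml_loglik(y, spec, vc) == pytest.approx(
            reml_loglik(y + 17.3, spec, vc), abs=1e-9
        )


class TestFitReml:
    def test_base_blups_match_closed_form_gblup(self):
        spec, layout = _toy_spec(seed=3)
        rng = np.random.default_rng(3)
        y = rng.standard_normal(layout.n_plots) + 2.0
        fit = fit_reml(y, spec, n_restarts=3, seed=0)
        assert fit.converged
        vc = fit.components
        Z1, K = spec.incidence.Z1, spec.K
        V = vc.sigma_g2 * Z1 @ K @ Z1.T + vc.sigma_e2 * np.eye(len(y))
        Vinv = np.linalg.inv(V)
        one = np.ones(len(y))
        mu = (one @ Vinv @ y) / (one @ Vinv @ one)
        ghat = vc.sigma_g2 * K @ Z1.T @ Vinv @ (y - mu)
        np.testing.assert_allclose(fit.blup_g, ghat, atol=1e-6)
        assert fit.mu_hat == pytest.approx(mu, abs=1e-6)

    def test_shrinkage_bound(self):
        spec, layout = _toy_spec(seed=4)
        rng = np.random.default_rng(4)
        y = rng.standard_normal(layout.n_plots)
        fit = fit_reml(y, spec, n_restarts=2, seed=0)
        assert np.var(fit.blup_g) <= fit.components.sigma_g2 * np.diag(spec.K).max() + 1e-9

    def test_degenerate_response_flags_nonconverged(self):
        spec, layout = _toy_spec()
        fit = fit_reml(np.full(layout.n_plots, 3.0), spec)
        assert not fit.converged
        assert np.isnan(fit.reml_loglik)

    @pytest.mark.parametrize("kind", [ModelKind.M1, ModelKind.M2, ModelKind.M3])
    def test_nesting_likelihood_ordering(self, kind, small_trial):
        """Maximized restricted likelihood of a nesting model >= Base."""
        config, kin = small_trial
        truth = simulate_trial(
            SimParams(sigma_c2=0.4, gr=0.5, fra_e=0.5),
            kin.values,
            config.genotype_ids,
            config.check_ids,
            seed=5,
            config=config,
        )
        base = fit_reml(truth.y, ModelSpec(ModelKind.BASE, truth.incidence, kin.values), seed=0)
        full = fit_reml(truth.y, ModelSpec(kind, truth.incidence, kin.values), seed=0)
        assert full.reml_loglik >= base.reml_loglik - 1e-4

    def test_genetic_block_psd(self, small_trial):
        config, kin = small_trial
        truth = simulate_trial(
            SimParams(sigma_c2=0.4, gr=0.5, gcor=0.4),
            kin.values,
            config.genotype_ids,
            config.check_ids,
            seed=6,
            config=config,
        )
        fit = fit_reml(truth.y, ModelSpec(ModelKind.M3, truth.incidence, kin.values), seed=0)
        vc = fit.components
        G = np.array([[vc.sigma_g2, vc.sigma_gc], [vc.sigma_gc, vc.sigma_c2]])
        E = np.array([[vc.sigma_p2, vc.sigma_pr], [vc.sigma_pr, vc.sigma_r2]])
        assert np.linalg.eigvalsh(G).min() >= -1e-8
        assert np.linalg.eigvalsh(E).min() >= -1e-8


class TestLrt:
    def test_equal_logliks_not_significant(self):
        fit = type("F", (), {"reml_loglik": -10.0})
        chisq, p, sig = lrt(fit, fit, 1)
        assert chisq == 0.0 and not sig

    def test_critical_values(self):
        from scipy.stats import chi2

        assert chi2.isf(0.1, 1) == pytest.approx(CHISQ_CRIT_1DF, abs=5e-4)
        assert chi2.isf(0.1, 2) == pytest.approx(CHISQ_CRIT_2DF, abs=5e-4)

    def test_boundary_pvalue(self):
        red = type("F", (), {"reml_loglik": 0.0})
        full = type("F", (), {"reml_loglik": CHISQ_CRIT_1DF / 2})
        chisq, p, sig = lrt(red, full, 1)
        assert p == pytest.approx(0.10, abs=1e-3)
        assert not sig  # exactly at the threshold is not beyond it

    def test_reported_table_statistic(self):
        """chi-square 15.52 on 1 df gives p about 8.1e-5."""
        red = type("F", (), {"reml_loglik": 0.0})
        full = type("F", (), {"reml_loglik": 15.52 / 2})
        _, p, sig = lrt(red, full, 1)
        assert p == pytest.approx(8.10e-05, rel=0.01)
        assert sig

    def test_negative_chisq_warns(self):
        red = type("F", (), {"reml_loglik": 0.0})
        full = type("F", (), {"reml_loglik": -0.5})
        with pytest.warns(UserWarning, match="optimizer"):
            chisq, _, _ = lrt(red, full, 1)
        assert chisq == 0.0


class TestPredict:
    def test_base_prediction_is_mu_plus_direct_effect(self):
        spec, layout = _toy_spec(seed=8)
        rng = np.random.default_rng(8)
        y = rng.standard_normal(layout.n_plots)
        fit = fit_reml(y, spec, seed=0)
        np.testing.assert_allclose(
            predict(fit), fit.mu_hat + spec.incidence.Z1 @ fit.blup_g, atol=1e-10
        )

    def test_interpolation_limit_as_residual_vanishes(self, small_trial):
        """With almost no residual variance the fit reproduces the data."""
        config, kin = small_trial
        truth = simulate_trial(
            SimParams(sigma_c2=0.2, gr=0.7, fra_e=0.0),
            kin.values,
            config.genotype_ids,
            config.check_ids,
            seed=9,
            config=config,
        )
        # response built almost entirely from genetic signal
        y = truth.incidence.Z1 @ truth.g + 1e-4 * truth.r
        spec = ModelSpec(ModelKind.BASE, truth.incidence, kin.values)
        fit = fit_reml(y, spec, n_restarts=3, seed=0)
        resid = y - predict(fit)
        assert np.abs(resid).max() < 0.05 * np.std(y)
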