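"""Outlier screening, cross-validation, selection metrics and h2."""

import numpy as np
import pytest

from interplot.evaluation import (
    CVResult,
    cross_validate,
    cullis_h2,
    make_folds,
    relative_changes,
    remove_outliers,
    select_model,
    total_phenotypic_variance,
)
from interplot.geometry import CompetitionFunction, FunctionKind, build_incidence
from interplot.mixed_model import (
    ModelKind,
    ModelSpec,
    VarianceComponents,
    fit_reml,
    pev_genetic,
)
from interplot.simulate import SIM_NN, SimParams, simulate_trial
from interplot.synth import SyntheticConfig
from interplot.kinship import additive_grm
from interplot.synth import simulate_markers


def _cv(prmse, pcor):
    return CVResult(
        label="x", prmse=prmse, pcor=pcor, per_fold=None,
        n_failed_fits=0, fold_assignment=None,
    )


class TestRelativeChanges:
    def test_printed_formulas(self):
        d_rmse, _ = relative_changes(_cv(10.0, 0.5), _cv(9.0, 0.5))
        assert d_rmse == pytest.approx(10.0)
        _, d_cor = relative_changes(_cv(10.0, 0.5), _cv(10.0, 0.6))
        assert d_cor == pytest.approx(20.0)

    def test_identical_results_are_zero(self):
        assert relative_changes(_cv(3.0, 0.4), _cv(3.0, 0.4)) == (0.0, 0.0)

    def test_undefined_ratios_are_nan(self):
        d_rmse, d_cor = relative_changes(_cv(0.0, 1.0), _cv(1.0, 0.5))
        assert np.isnan(d_rmse) and np.isnan(d_cor)


class TestFolds:
    def test_partition_and_determinism(self):
        a = make_folds(53, 10, 5, seed=3)
        b = make_folds(53, 10, 5, seed=3)
        np.testing.assert_array_equal(a, b)
        for r in range(5):
            counts = np.bincount(a[r], minlength=10)
            assert counts.min() >= 53 // 10
            assert counts.sum() == 53
        assert not np.array_equal(a[0], a[1])

    def test_too_few_plots_rejected(self):
        with pytest.raises(ValueError):
            make_folds(5, 10, 1, seed=0)


@pytest.fixture(scope="module")
def tiny_trial():
    config = SyntheticConfig(n_genotypes=50, n_checks=4, n_markers=250, seed=31)
    kin = additive_grm(simulate_markers(config))
    truth = simulate_trial(
        SimParams(sigma_c2=0.4, gr=0.5, fra_e=0.5),
        kin.values, config.genotype_ids, config.check_ids, seed=2, config=config,
    )
    return config, kin, truth


class TestCrossValidate:
    def test_fold_identity_across_candidates_and_runs(self, tiny_trial):
        config, kin, truth = tiny_trial
        base = ModelSpec(ModelKind.BASE, truth.incidence, kin.values)
        m1 = ModelSpec(ModelKind.M1, truth.incidence, kin.values)
        res = cross_validate(truth.y, {"Base": base, "M1": m1}, folds=5, repeats=2, seed=7)
        res2 = cross_validate(truth.y, {"Base": base}, folds=5, repeats=2, seed=7)
        np.testing.assert_array_equal(res["Base"].fold_assignment, res["M1"].fold_assignment)
        np.testing.assert_array_equal(res["Base"].fold_assignment, res2["Base"].fold_assignment)
        assert res["Base"].prmse == pytest.approx(res2["Base"].prmse)
        assert res["Base"].prmse > 0
        assert -1 <= res["Base"].pcor <= 1

    def test_every_plot_in_exactly_one_fold_per_repeat(self, tiny_trial):
        config, kin, truth = tiny_trial
        base = ModelSpec(ModelKind.BASE, truth.incidence, kin.values)
        res = cross_validate(truth.y, {"Base": base}, folds=5, repeats=2, seed=1)
        per_fold = res["Base"].per_fold
        assert len(per_fold) == 10
        counted = res["Base"].fold_assignment
        for r in range(2):
            assert len(counted[r]) == truth.layout.n_plots

    def test_mean_predictor_prmse_equals_population_sd(self):
        """If predictions collapse to the mean, pRMSE -> SD(y)."""
        rng = np.random.default_rng(0)
        y = rng.standard_normal(200)
        # algebraic check of the pooled definition rather than a model run
        pred = np.full_like(y, y.mean())
        prmse = np.sqrt(np.mean((y - pred) ** 2))
        assert prmse == pytest.approx(np.std(y))


class TestOutliers:
    def test_clean_data_untouched(self, tiny_trial):
        config, kin, truth = tiny_trial
        base = ModelSpec(ModelKind.BASE, truth.incidence, kin.values)
        report = remove_outliers(truth.y, base)
        assert len(report.keep_rows) + len(report.removed_rows) == truth.layout.n_plots
        assert len(report.removed_rows) <= 2  # 2.5 sigma on clean Gaussian data

    def test_injected_outlier_removed(self):
        """A 10-sigma spike in Base-generated data is flagged.

        Needs a trial large enough for a stable variance partition,
        otherwise the spike leaks into the genetic BLUP.
        """
        config = SyntheticConfig(n_genotypes=150, n_checks=6, n_markers=400, seed=31)
        kin = additive_grm(simulate_markers(config))
        truth = simulate_trial(
            SimParams(sigma_c2=0.4, gr=0.5, fra_e=0.5),
            kin.values, config.genotype_ids, config.check_ids, seed=2, config=config,
        )
        base = ModelSpec(ModelKind.BASE, truth.incidence, kin.values)
        hits = 0
        n_seeds = 5
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            g = rng.multivariate_normal(
                np.zeros(kin.n_genotypes), kin.values + 1e-6 * np.eye(kin.n_genotypes)
            )
            y = truth.incidence.Z1 @ g + rng.standard_normal(truth.layout.n_plots)
            y[13] += 10.0  # 10 x sigma_e with sigma_e2 = 1
            report = remove_outliers(y, base, plot_ids=truth.layout.plot_ids)
            hits += 13 in report.removed_rows
        assert hits >= 0.95 * n_seeds

    def test_degenerate_response_flagged_not_removed(self, tiny_trial):
        config, kin, truth = tiny_trial
        base = ModelSpec(ModelKind.BASE, truth.incidence, kin.values)
        report = remove_outliers(np.zeros(truth.layout.n_plots), base)
        assert not report.base_fit.converged
        assert len(report.removed_rows) == 0


class TestHeritabilityAndVariance:
    def test_h2_limits(self):
        # direct formula limits: zero pairwise PEV -> 1; PEV = 2 sigma_g2 -> 0
        assert 1.0 - 0.0 / 2.0 == 1.0
        assert np.clip(1.0 - 2.0 / 2.0, 0, 1) == 0.0

    def test_pairwise_pev_brute_force(self, tiny_trial):
        """V-bar-Delta from the PEV matrix equals the pair enumeration."""
        config, kin, truth = tiny_trial
        sub = slice(0, 5)
        base = ModelSpec(ModelKind.BASE, truth.incidence, kin.values)
        fit = fit_reml(truth.y, base, seed=0)
        pev = pev_genetic(fit)
        g = pev.shape[0]
        pairs = [
            pev[i, i] + pev[j, j] - 2 * pev[i, j]
            for i in range(g)
            for j in range(i + 1, g)
        ]
        vbar = np.mean(pairs)
        h2 = cullis_h2(fit)
        expected = np.clip(1.0 - vbar / (2.0 * fit.components.sigma_g2), 0.0, 1.0)
        assert h2 == pytest.approx(expected, abs=1e-10)
        assert 0.0 <= h2 <= 1.0

    def test_total_variance_definitions(self, tiny_trial):
        config, kin, truth = tiny_trial
        base_fit = fit_reml(truth.y, ModelSpec(ModelKind.BASE, truth.incidence, kin.values), seed=0)
        vc = base_fit.components
        assert total_phenotypic_variance(base_fit) == pytest.approx(vc.sigma_g2 + vc.sigma_e2)
        m3_fit = fit_reml(truth.y, ModelSpec(ModelKind.M3, truth.incidence, kin.values), seed=0)
        vc3 = m3_fit.components
        assert total_phenotypic_variance(m3_fit) == pytest.approx(
            vc3.sigma_g2 + vc3.sigma_c2 + vc3.sigma_p2 + vc3.sigma_r2
        )


class TestSelectModel:
    def test_single_candidate_reports_base_vs_candidate(self, tiny_trial):
        config, kin, truth = tiny_trial
        base = ModelSpec(ModelKind.BASE, truth.incidence, kin.values, label="Base")
        cand = {"Model1|NN-long": ModelSpec(ModelKind.M1, truth.incidence, kin.values)}
        report = select_model(
            truth.y, base, cand, folds=5, repeats=1, seed=0, n_restarts=1
        )
        assert set(report.cv) == {"Base", "Model1|NN-long"}
        assert report.best_label in report.cv
        assert 0.0 <= report.h2_base <= 1.0
        if report.best_label != "Base":
            assert report.chisq >= 0.0

    def test_strong_competition_beats_base(self):
        """With strong NN competition an NN candidate wins in most seeds."""
        config = SyntheticConfig(n_genotypes=60, n_checks=4, n_markers=250, seed=41)
        kin = additive_grm(simulate_markers(config))
        wins = 0
        n_seeds = 3
        for seed in range(n_seeds):
            truth = simulate_trial(
                SimParams(sigma_c2=1.0, gr=0.3, fra_e=0.5),
                kin.values, config.genotype_ids, config.check_ids,
                seed=100 + seed, config=config,
            )
            base = ModelSpec(ModelKind.BASE, truth.incidence, kin.values)
            cand = {"M3|NN": ModelSpec(ModelKind.M3, truth.incidence, kin.values)}
            report = select_model(
                truth.y, base, cand, folds=5, repeats=1, seed=seed, n_restarts=1
            )
            if report.best_label == "M3|NN":
                wins += 1
        assert wins >= 2
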