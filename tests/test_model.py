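"""Likelihood, per-class correlation MLE, LR tests and model selection."""

import numpy as np
import pytest
from scipy import stats

from epicoex.model import (
    GenotypeCorrelationModel,
    fit_correlations,
    fit_variance_dependent,
    log_likelihood,
    lr_test,
    select_best_model,
)
from epicoex.config import ScanConfig
from epicoex.partitions import (
    JOINT_GENOTYPES,
    enumerate_partitions,
    epistatic_partitions,
    marginal_partitions,
    null_partition,
)

from conftest import bvn_logpdf_oracle, draw_module, grid_search_rho_oracle


class TestLogLikelihood:
    def test_single_origin_sample_closed_form(self):
        null = null_partition()
        ll = log_likelihood([0.0], [0.0], null, {1: 0.0}, 1.0, [1])
        assert ll == pytest.approx(-np.log(2 * np.pi), abs=1e-12)
        ll = log_likelihood([0.0], [0.0], null, {1: 0.0}, 0.97, [1])
        assert ll == pytest.approx(-np.log(2 * np.pi * 0.97**2), abs=1e-12)

    def test_matches_per_sample_density_oracle(self):
        rng = np.random.default_rng(3)
        x, y, g1, g2 = draw_module(rng, {gt: 0.4 for gt in JOINT_GENOTYPES}, 10)
        part = next(p for p in enumerate_partitions() if p.k == 4)
        rho = {1: -0.5, 2: 0.0, 3: 0.3, 4: 0.8}
        labels = np.array([part.class_of[(a, b)] for a, b in zip(g1, g2)])
        expected = sum(
            bvn_logpdf_oracle(x[i], y[i], rho[labels[i]], 0.97) for i in range(len(x))
        )
        got = log_likelihood(x, y, part, rho, 0.97, labels)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_invalid_rho_and_length_mismatch_raise(self):
        null = null_partition()
        with pytest.raises(ValueError, match="-1, 1"):
            log_likelihood([0.0], [0.0], null, {1: 1.0}, 1.0, [1])
        with pytest.raises(ValueError, match="length"):
            log_likelihood([0.0, 1.0], [0.0], null, {1: 0.0}, 1.0, [1, 1])


class TestCorrelationMLE:
    def test_symmetric_cross_data_gives_zero_rho(self):
        x = np.array([1.0, -1.0, 0.0, 0.0] * 5)
        y = np.array([0.0, 0.0, 1.0, -1.0] * 5)
        g = np.zeros(20, dtype=int)
        fit = fit_correlations(x, y, g, g, null_partition(), sd=1.0)
        assert fit.rho_hat[1] == pytest.approx(0.0, abs=1e-9)

    def test_consistency_at_large_n(self):
        rng = np.random.default_rng(7)
        x, y, g1, g2 = draw_module(rng, {gt: 0.6 for gt in JOINT_GENOTYPES},
                                   n_per_class=1250, sd=0.97)
        fit = fit_correlations(x, y, g1, g2, null_partition(), sd=0.97)
        assert fit.rho_hat[1] == pytest.approx(0.6, abs=0.03)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_grid_search_oracle_on_small_classes(self, seed):
        rng = np.random.default_rng(seed)
        part = epistatic_partitions()[seed % 12]
        rho = {gt: float(rng.uniform(-0.8, 0.8)) for gt in JOINT_GENOTYPES}
        x, y, g1, g2 = draw_module(rng, rho, n_per_class=int(rng.integers(5, 21)))
        fit = fit_correlations(x, y, g1, g2, part, sd=0.97)
        oracle_rho, oracle_ll = grid_search_rho_oracle(x, y, g1, g2, part, sd=0.97)
        for c in oracle_rho:
            assert fit.rho_hat[c] == pytest.approx(oracle_rho[c], abs=1e-3)
        assert fit.loglik == pytest.approx(oracle_ll, abs=1e-5)

    def test_rho_strictly_inside_unit_interval_even_for_tight_data(self):
        x = np.linspace(-1, 1, 12)
        g = np.zeros(12, dtype=int)
        fit = fit_correlations(x, x, g, g, null_partition(), sd=0.97)
        assert -1 < fit.rho_hat[1] < 1

    def test_sign_symmetry(self):
        rng = np.random.default_rng(11)
        rho = {(0, 0): 0.5, (0, 1): -0.2, (1, 0): 0.1, (1, 1): 0.7}
        x, y, g1, g2 = draw_module(rng, rho, 20)
        part = next(p for p in enumerate_partitions() if p.k == 4)
        fit = fit_correlations(x, y, g1, g2, part, sd=0.97)
        fit_neg = fit_correlations(-x, y, g1, g2, part, sd=0.97)
        for c in fit.rho_hat:
            assert fit_neg.rho_hat[c] == pytest.approx(-fit.rho_hat[c], abs=1e-9)
        assert fit_neg.loglik == pytest.approx(fit.loglik, abs=1e-8)

    def test_empty_class_raises(self):
        x = np.zeros(10)
        g1 = np.zeros(10, dtype=int)  # classes (1,*) empty
        part = marginal_partitions()[0]
        with pytest.raises(ValueError, match="fewer than 2"):
            fit_correlations(x, x + 1e-3, g1, g1, part, sd=0.97)


class TestLRTest:
    def test_identical_fits_give_zero_lr_p_one(self):
        rng = np.random.default_rng(0)
        x, y, g1, g2 = draw_module(rng, {gt: 0.3 for gt in JOINT_GENOTYPES}, 15)
        fit = fit_correlations(x, y, g1, g2, null_partition(), sd=0.97)
        res = lr_test(fit, fit)
        assert res.lr == 0.0 and res.p_value == 1.0

    def test_refinement_never_decreases_loglik(self):
        rng = np.random.default_rng(1)
        for seed in range(5):
            rng = np.random.default_rng(seed)
            rho = {gt: float(rng.uniform(-0.7, 0.7)) for gt in JOINT_GENOTYPES}
            x, y, g1, g2 = draw_module(rng, rho, 20)
            null = fit_correlations(x, y, g1, g2, null_partition(), sd=0.97)
            for part in enumerate_partitions():
                fit = fit_correlations(x, y, g1, g2, part, sd=0.97)
                assert fit.loglik >= null.loglik - 1e-9
                assert lr_test(fit, null).lr >= 0.0

    def test_non_nested_comparison_rejected(self):
        rng = np.random.default_rng(2)
        x, y, g1, g2 = draw_module(rng, {gt: 0.0 for gt in JOINT_GENOTYPES}, 10)
        m1, m2 = (fit_correlations(x, y, g1, g2, p, sd=0.97)
                  for p in marginal_partitions())
        with pytest.raises(ValueError, match="not nested"):
            lr_test(m1, m2)


class TestModelSelection:
    def test_p_value_is_min_over_epistatic_partitions(self):
        rng = np.random.default_rng(5)
        rho = {gt: (0.7 if gt == (1, 1) else 0.0) for gt in JOINT_GENOTYPES}
        x, y, g1, g2 = draw_module(rng, rho, 40)
        model = GenotypeCorrelationModel(x, y, g1, g2)
        res = model.fit()
        all_p = [t.p_value for _, t in res.per_partition]
        assert res.p_value == min(all_p)
        assert len(all_p) == 12

    def test_one_vs_rest_pattern_prefers_two_class_partition(self):
        hits = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            rho = {gt: (0.8 if gt == (1, 1) else 0.0) for gt in JOINT_GENOTYPES}
            x, y, g1, g2 = draw_module(rng, rho, 150)
            res = GenotypeCorrelationModel(x, y, g1, g2).fit()
            hits += res.partition.class_labels() == (1, 1, 1, 2)
        assert hits > 15

    def test_null_data_gives_roughly_uniform_p(self):
        ps = []
        for seed in range(60):
            rng = np.random.default_rng(100 + seed)
            x, y, g1, g2 = draw_module(rng, {gt: 0.3 for gt in JOINT_GENOTYPES}, 30)
            ps.append(GenotypeCorrelationModel(x, y, g1, g2).fit().p_value)
        # selection over 12 partitions inflates small p; just demand no collapse
        assert 0.001 < np.median(ps) < 0.9
        assert min(ps) > 1e-6

    def test_class_size_guard(self):
        rng = np.random.default_rng(0)
        x, y, g1, g2 = draw_module(rng, {gt: 0.0 for gt in JOINT_GENOTYPES},
                                   {(0, 0): 30, (0, 1): 30, (1, 0): 30, (1, 1): 5})
        with pytest.raises(ValueError, match="min_class_size"):
            GenotypeCorrelationModel(x, y, g1, g2).fit(min_class_size=15)


class TestEpistasisVsMarginal:
    def test_marginal_only_pattern_yields_nonsignificant_epistasis_p(self):
        removed = 0
        for seed in range(25):
            rng = np.random.default_rng(seed)
            rho = {gt: (0.6 if gt[0] == 1 else -0.1) for gt in JOINT_GENOTYPES}
            x, y, g1, g2 = draw_module(rng, rho, 35)
            res = GenotypeCorrelationModel(x, y, g1, g2).fit()
            removed += res.epistasis_p >= 0.05
        assert removed > 12  # majority not flagged epistatic

    def test_xor_pattern_yields_significant_epistasis_p(self):
        kept = 0
        for seed in range(25):
            rng = np.random.default_rng(1000 + seed)
            rho = {gt: (0.7 if gt[0] == gt[1] else -0.7) for gt in JOINT_GENOTYPES}
            x, y, g1, g2 = draw_module(rng, rho, 35)
            res = GenotypeCorrelationModel(x, y, g1, g2).fit()
            kept += res.epistasis_p < 0.05
        assert kept > 22

    def test_best_no_better_than_marginal_gives_p_one(self):
        # force the comparison partition to a 2-class epistatic split on
        # data with a pure marker-1 pattern: the marginal fit dominates,
        # the generalized LR clips at zero and p = 1 by construction
        from epicoex.model import epistasis_vs_marginal, select_best_model

        rng = np.random.default_rng(4)
        rho = {gt: (0.6 if gt[0] == 1 else 0.0) for gt in JOINT_GENOTYPES}
        x, y, g1, g2 = draw_module(rng, rho, 40)
        best = select_best_model(x, y, g1, g2, ScanConfig())
        weak = next(p for p in epistatic_partitions()
                    if p.class_labels() == (1, 1, 1, 2))
        best.selected_partition = weak.id
        best.df = 1
        _, _, epi_p = epistasis_vs_marginal(x, y, g1, g2, best, ScanConfig())
        assert epi_p == 1.0  # marginal fit dominates, LR clips at zero


class TestVarianceDependentVariants:
    def test_well_specified_equal_variances_recovered(self):
        rng = np.random.default_rng(9)
        x, y, g1, g2 = draw_module(rng, {gt: 0.4 for gt in JOINT_GENOTYPES},
                                   400, sd=0.8)
        part = next(p for p in enumerate_partitions() if p.k == 4)
        fit = fit_variance_dependent(x, y, g1, g2, part, "model6")
        sds = list(fit.sd_hat.values())
        assert max(sds) - min(sds) < 0.08
        assert all(abs(s - 0.8) < 0.06 for s in sds)

    @pytest.mark.parametrize("variant", ["model6", "model20"])
    def test_matches_two_d_grid_oracle_on_small_class(self, variant):
        rng = np.random.default_rng(13)
        x, y, g1, g2 = draw_module(
            rng, {gt: 0.5 for gt in JOINT_GENOTYPES}, 15, sd=1.1,
            mean_by_genotype={gt: (0.3, -0.2) for gt in JOINT_GENOTYPES},
        )
        null = null_partition()
        fit = fit_variance_dependent(x, y, g1, g2, null, variant)
        xv, yv = (x, y)
        if variant == "model20":
            xv = x - x.mean()
            yv = y - y.mean()
        # 2-D grid over (rho, sd)
        best = (-np.inf, None, None)
        for rho in np.arange(-0.99, 0.9951, 0.005):
            for sd in np.arange(0.5, 2.0, 0.005):
                ll = float(np.sum(bvn_logpdf_oracle(xv, yv, rho, sd)))
                if ll > best[0]:
                    best = (ll, rho, sd)
        assert fit.rho_hat[1] == pytest.approx(best[1], abs=1e-2)
        assert fit.sd_hat[1] == pytest.approx(best[2], abs=1e-2)

    def test_fixed_sd_model_has_more_power_when_variances_constant(self):
        # IMIVED-style data: correlation epistasis, means/variances constant
        alpha = 0.001
        wins_fixed = 0
        n_rep = 40
        part_full = next(p for p in enumerate_partitions() if p.k == 4)
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            rho = {gt: (0.55 if gt == (1, 1) else 0.0) for gt in JOINT_GENOTYPES}
            x, y, g1, g2 = draw_module(rng, rho, 25, sd=0.97)
            model = GenotypeCorrelationModel(x, y, g1, g2)
            fixed_alt = model.fit_partition(part_full)
            fixed_null = model.fit_partition(null_partition())
            p_fixed = lr_test(fixed_alt, fixed_null).p_value
            var_alt = model.fit_variance_dependent(part_full, "model6")
            var_null = model.fit_variance_dependent(null_partition(), "model6")
            lr = max(0.0, 2 * (var_alt.loglik - var_null.loglik))
            p_var = float(stats.chi2.sf(lr, 2 * 3))  # 2 params per extra class
            wins_fixed += p_fixed < p_var
        assert wins_fixed > n_rep // 2

    def test_small_class_rejected(self):
        rng = np.random.default_rng(1)
        x, y, g1, g2 = draw_module(rng, {gt: 0.0 for gt in JOINT_GENOTYPES}, 3)
        with pytest.raises(ValueError, match="fewer than 4"):
            fit_variance_dependent(x, y, g1, g2,
                                   next(p for p in enumerate_partitions() if p.k == 4))


def test_summary_contains_key_quantities():
    rng = np.random.default_rng(21)
    rho = {gt: (0.8 if gt == (1, 1) else 0.0) for gt in JOINT_GENOTYPES}
    x, y, g1, g2 = draw_module(rng, rho, 40)
    res = GenotypeCorrelationModel(x, y, g1, g2).fit()
    text = res.summary()
    assert "Selected partition" in text
    assert "epistasis vs best marginal" in text
    assert f"{res.model.nobs}" in text
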