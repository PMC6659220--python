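"""CTT descriptives, marginal-ML IRT fits, and CHull model selection."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

from gatedirt import (
    MarginalMLIrt,
    chull_select,
    compare_models,
    ctt_summary,
    fit_irt,
)


def simulate_irt(m, difficulties, discriminations, seed):
    rng = np.random.default_rng(seed)
    theta = rng.standard_normal(m)
    p = expit(np.asarray(discriminations) * (theta[:, None] - np.asarray(difficulties)))
    return (rng.random(p.shape) < p).astype(int)


class TestCttSummary:
    def test_parallel_items_alpha_one(self):
        col = np.array([1, 0, 1, 1, 0, 0, 1])
        summ = ctt_summary(np.c_[col, col])
        assert summ.cronbach_alpha == pytest.approx(1.0)

    def test_all_correct_item_easy_and_undefined_discrimination(self):
        rng = np.random.default_rng(1)
        Y = rng.integers(0, 2, (30, 4))
        Y[:, 0] = 1
        summ = ctt_summary(Y)
        assert summ.difficulty[0] == 1.0
        assert summ.difficulty_category[0] == "easy"
        assert np.isnan(summ.discrimination[0])
        assert summ.discrimination_category[0] == "undefined"

    def test_independent_coinflips_alpha_near_zero(self):
        Y = (np.random.default_rng(2).random((4000, 20)) < 0.5).astype(int)
        summ = ctt_summary(Y)
        assert abs(summ.cronbach_alpha) < 0.1
        assert np.nanmax(np.abs(summ.discrimination)) < 0.12

    def test_difficulty_category_boundaries_exact(self):
        # proportion-scale edges: [0, .30] difficult, (.30, .80] medium, else easy
        m = 10
        cols, expected = [], []
        for p, cat in ((0.30, "difficult"), (0.40, "medium"), (0.80, "medium"),
                       (0.90, "easy")):
            cols.append(np.r_[np.ones(int(p * m), int), np.zeros(m - int(p * m), int)])
            expected.append(cat)
        summ = ctt_summary(np.column_stack(cols))
        assert list(summ.difficulty_category) == expected

    def test_discrimination_category_boundaries_exact(self):
        from gatedirt.psychometrics import _discrimination_category

        assert _discrimination_category(-0.19) == "negative"
        assert _discrimination_category(-0.18) == "weak"
        assert _discrimination_category(0.19) == "weak"
        assert _discrimination_category(0.20) == "sufficient"
        assert _discrimination_category(0.29) == "sufficient"
        assert _discrimination_category(0.30) == "good"
        assert _discrimination_category(0.39) == "good"
        assert _discrimination_category(0.40) == "very_good"

    def test_invariance_to_orderings(self, rng):
        Y = (rng.random((50, 8)) < 0.6).astype(int)
        base = ctt_summary(Y)
        perm_students = ctt_summary(Y[rng.permutation(50)])
        assert base.difficulty == pytest.approx(perm_students.difficulty)
        assert base.cronbach_alpha == pytest.approx(perm_students.cronbach_alpha)
        perm = rng.permutation(8)
        perm_items = ctt_summary(Y[:, perm])
        assert perm_items.cronbach_alpha == pytest.approx(base.cronbach_alpha)
        assert perm_items.difficulty == pytest.approx(base.difficulty[perm])

    def test_minimum_size(self):
        with pytest.raises(ValueError):
            ctt_summary(np.zeros((2, 5), dtype=int))


class TestMarginalMLIrt:
    def test_one_pl_recovers_unit_discrimination(self):
        Y = simulate_irt(800, np.linspace(-1.5, 1.5, 15), 1.0, seed=3)
        fit = fit_irt(Y, "1pl")
        assert fit.discrimination == pytest.approx(1.0, abs=0.12)
        assert np.corrcoef(fit.difficulty, np.linspace(-1.5, 1.5, 15))[0, 1] > 0.98
        assert fit.converged

    def test_two_pl_nests_one_pl(self):
        Y = simulate_irt(300, np.linspace(-1, 1, 10), 1.0, seed=4)
        f1, f2 = fit_irt(Y, "1pl"), fit_irt(Y, "2pl")
        assert f2.log_likelihood >= f1.log_likelihood - 1e-6
        assert f1.n_parameters == 11 and f2.n_parameters == 20

    def test_information_criteria_formulas(self):
        Y = simulate_irt(100, [0.0, 0.5, -0.5, 1.0, 0.3], 1.0, seed=5)
        fit = fit_irt(Y, "1pl")
        assert fit.aic == pytest.approx(-2 * fit.log_likelihood + 2 * 6)
        assert fit.bic == pytest.approx(-2 * fit.log_likelihood + 6 * np.log(100))

    def test_em_matches_direct_optimisation(self):
        """EM optimum equals direct numerical maximum of the marginal
        likelihood on a 5-item, 50-student toy dataset."""
        Y = simulate_irt(50, [-1.0, -0.3, 0.0, 0.6, 1.2], 1.0, seed=6).astype(float)
        x, w = np.polynomial.hermite.hermgauss(61)
        x, logw = x * np.sqrt(2.0), np.log(w / np.sqrt(np.pi))

        def neg_marginal_ll(params):
            a, c = params[0], params[1:]
            z = np.outer(np.full(5, a), x) + c[:, None]
            logp = -np.logaddexp(0.0, -z)
            log1mp = -np.logaddexp(0.0, z)
            S = Y @ logp + (1 - Y) @ log1mp + logw
            return -logsumexp(S, axis=1).sum()

        direct = minimize(
            neg_marginal_ll, x0=np.r_[1.0, np.zeros(5)], method="Nelder-Mead",
            options={"maxiter": 20000, "xatol": 1e-8, "fatol": 1e-10},
        )
        em = fit_irt(Y.astype(int), "1pl")
        assert em.log_likelihood == pytest.approx(-direct.fun, abs=1e-3)

    def test_varying_discriminations_favour_two_pl(self):
        disc = np.tile([0.3, 2.0], 8)
        Y = simulate_irt(1500, np.zeros(16), disc, seed=7)
        table = compare_models(Y)
        sel = table.attrs["selected_by"]
        assert sel["aic"] == sel["bic"] == "2pl"
        f2 = fit_irt(Y, "2pl")
        assert np.corrcoef(f2.discrimination, disc)[0, 1] > 0.9

    def test_one_pl_data_bic_selects_one_pl(self):
        Y = simulate_irt(1200, np.linspace(-1, 1, 20), 1.0, seed=8)
        table = compare_models(Y)
        assert table.attrs["selected_by"]["bic"] == "1pl"

    def test_constant_column_flagged_for_2pl(self):
        Y = simulate_irt(60, np.zeros(5), 1.0, seed=9)
        Y[:, 2] = 1
        est = MarginalMLIrt(model="2pl").fit(Y)
        assert 2 in est.flagged_items_

    def test_invalid_model_name(self):
        with pytest.raises(ValueError):
            fit_irt(np.zeros((5, 3), dtype=int), "3pl")


class TestChull:
    def test_three_model_scree_ratio(self):
        ratios, sel = chull_select([(10, -100.0), (20, -50.0), (40, -49.0)])
        assert ratios[1] == pytest.approx((50 / 10) / (1 / 20))
        assert sel == 1
        assert np.isnan(ratios[0]) and np.isnan(ratios[2])

    def test_two_models_better_fitting_selected(self):
        ratios, sel = chull_select([(11, -120.0), (20, -100.0)])
        assert sel == 1 and np.isinf(ratios[1]) and ratios[0] == 0.0

    def test_two_models_no_gain_prefers_simpler(self):
        ratios, sel = chull_select([(11, -100.0), (20, -100.0)])
        assert sel == 0

    def test_collinear_fits_flat_scree(self):
        ratios, sel = chull_select([(10, -90.0), (20, -80.0), (30, -70.0)])
        assert ratios[1] == pytest.approx(1.0)

    def test_dominated_model_off_hull(self):
        ratios, _ = chull_select([(10, -50.0), (20, -60.0), (30, -40.0)])
        assert np.isnan(ratios[1])

    def test_needs_two_models(self):
        with pytest.raises(ValueError):
            chull_select([(10, -50.0)])
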