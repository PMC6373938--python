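import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from premcal.banks import equip_ph_bank
from premcal.data_io import Item, ItemBank
from premcal.pcm import (
    PCMModel,
    Quadrature,
    category_probabilities,
    eap_score,
    eap_scores,
    fit_pcm,
    fit_statistics,
    impute_missing,
    item_information,
    marginal_reliability,
    score_responses,
)
from premcal.pcm import test_information as total_information
from premcal.synthetic import SimulationDesign, simulate_responses

from conftest import make_matrix


class TestCategoryProbabilities:
    def test_equal_thresholds_at_their_location_give_uniform_categories(self):
        assert np.allclose(category_probabilities((0.0, 0.0), 0.0), [1 / 3] * 3)

    def test_published_first_item_probabilities_at_zero(self):
        # direct evaluation of the PCM formula for thresholds (-1.20, 0.12)
        p = category_probabilities((-1.20, 0.12), 0.0)
        assert np.allclose(p, [0.13765011, 0.45701444, 0.40533545], atol=1e-7)
        assert p.argmax() == 1  # theta sits between the two thresholds

    def test_extreme_theta_saturates_top_category(self):
        p = category_probabilities((-1.0, 1.0), 40.0)
        assert p[-1] == pytest.approx(1.0, abs=1e-12)
        p = category_probabilities((-1.0, 1.0), -40.0)
        assert p[0] == pytest.approx(1.0, abs=1e-12)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(
        deltas=st.lists(st.floats(-8, 8), min_size=1, max_size=5),
        theta=st.floats(-50, 50),
    )
    def test_probabilities_normalised_and_in_unit_interval(self, deltas, theta):
        p = category_probabilities(deltas, theta)
        assert p.sum() == pytest.approx(1.0, abs=1e-10)
        assert (p >= 0).all() and (p <= 1).all()


class TestInformation:
    def test_symmetric_item_peaks_at_zero_and_decays(self):
        grid = np.linspace(-4, 4, 41)
        info = item_information((0.0, 0.0), grid)
        assert info.argmax() == 20
        assert info[0] < info[20] and info[-1] < info[20]
        # symmetric in theta
        assert np.allclose(info, info[::-1], atol=1e-12)

    def test_information_equals_derivative_of_expected_score(self, published_bank):
        # Var(X|theta) = d/dtheta E[X|theta] for the PCM (finite-difference oracle)
        eps = 1e-5
        for theta in (-2.0, -0.5, 0.0, 0.9, 2.5):
            for it in published_bank.items[:5]:
                k = np.arange(len(it.deltas) + 1)
                e_hi = category_probabilities(it.deltas, theta + eps) @ k
                e_lo = category_probabilities(it.deltas, theta - eps) @ k
                fd = (e_hi - e_lo) / (2 * eps)
                assert item_information(it.deltas, theta) == pytest.approx(fd, abs=1e-4)

    def test_test_information_dominates_any_subset(self, published_bank):
        full = total_information(published_bank, 0.0)
        sub = ItemBank(published_bank.items[:10])
        assert full >= total_information(sub, 0.0)


class TestCalibration:
    def test_recovers_generating_thresholds(self, clean_study_matrix, fitted_clean_model,
                                            published_bank):
        true = np.concatenate([it.deltas for it in published_bank])
        est = np.concatenate([it.deltas for it in fitted_clean_model.bank])
        rmse = float(np.sqrt(((true - est) ** 2).mean()))
        assert rmse < 0.2  # n=500; the n=2000 bound is checked in the acceptance suite

    def test_estimates_latent_scale(self, fitted_clean_model):
        assert fitted_clean_model.prior_sd == pytest.approx(1.9, abs=0.25)

    def test_em_marginal_loglik_is_monotone(self, fitted_clean_model):
        trace = np.asarray(fitted_clean_model.loglik_trace)
        assert trace.size >= 2
        assert (np.diff(trace) > -1e-6).all()

    def test_balanced_dichotomous_items_centre_near_zero(self):
        # two dichotomous items, each split 50/50 -> thresholds at the prior centre
        rng = np.random.default_rng(1)
        a = rng.permutation([0, 1] * 100)
        b = rng.permutation([0, 1] * 100)
        m = make_matrix(np.column_stack([a, b]), max_cat=1)
        model = fit_pcm(m)
        for it in model.bank:
            assert abs(it.deltas[0]) < 0.15

    def test_unobserved_category_is_merged_and_logged(self):
        rng = np.random.default_rng(3)
        col_full = rng.integers(0, 3, 300)
        col_gap = rng.choice([0, 2], 300)  # category 1 never observed
        m = make_matrix(np.column_stack([col_full, col_gap]), max_cat=2)
        model = fit_pcm(m)
        assert model.merge_log and model.merge_log[0]["item_id"] == "i1"
        assert len(model.bank.items[1].deltas) == 1  # collapsed to two categories


class TestEAPScoring:
    def test_empty_response_returns_prior(self, published_model):
        est = eap_score(published_model, {})
        assert est.theta == pytest.approx(published_model.prior_mean, abs=1e-9)
        assert est.se == pytest.approx(published_model.prior_sd, abs=1e-6)
        assert est.n_items_used == 0

    def test_all_maximum_responses_exceed_largest_threshold(self, published_model):
        est = eap_score(published_model, {i: 2 for i in published_model.item_ids})
        assert est.theta > 1.51  # the bank's largest threshold

    def test_quadrature_refinement_changes_estimate_below_millitheta(self, published_bank):
        resp = {published_bank.item_ids[j]: (j % 3) for j in range(19)}
        coarse = PCMModel(published_bank, quadrature=Quadrature.gaussian(n_nodes=61))
        fine = PCMModel(published_bank, quadrature=Quadrature.gaussian(n_nodes=121))
        assert eap_score(coarse, resp).theta == pytest.approx(eap_score(fine, resp).theta, abs=1e-3)

    def test_eap_depends_only_on_total_score_and_increases_with_it(self, toy_bank):
        # Rasch sufficiency: exhaustive response patterns on a 3-item bank
        model = PCMModel.from_bank(toy_bank)
        by_total: dict[int, list[float]] = {}
        for pattern in itertools.product(range(3), repeat=3):
            est = eap_score(model, dict(zip(toy_bank.item_ids, pattern)))
            by_total.setdefault(sum(pattern), []).append(est.theta)
        totals = sorted(by_total)
        for t in totals:
            assert np.ptp(by_total[t]) < 1e-10
        means = [np.mean(by_total[t]) for t in totals]
        assert (np.diff(means) > 0).all()

    def test_out_of_range_category_rejected(self, published_model):
        with pytest.raises(ValueError, match="out of range"):
            eap_score(published_model, {published_model.item_ids[0]: 5})


class TestReliabilityAndFit:
    def test_reliability_grows_as_items_are_added(self, published_bank):
        rels = [
            marginal_reliability(ItemBank(published_bank.items[:k]))
            for k in (3, 7, 12, 19)
        ]
        assert all(b > a for a, b in zip(rels, rels[1:]))

    def test_single_item_scale_is_much_less_reliable_than_bank(self, published_bank):
        assert marginal_reliability(ItemBank(published_bank.items[:1])) < 0.5

    def test_item_fit_pvalues_roughly_uniform_under_the_model(
        self, clean_study_matrix, fitted_clean_model
    ):
        matrix, _ = clean_study_matrix
        report = fit_statistics(fitted_clean_model, matrix)
        ps = np.array([f["p"] for f in report.item_fit.values()])
        assert (ps < 0.05).mean() <= 3 / 19  # near-nominal rejection on null data
        assert report.rmsea < 0.05
        assert 0 < report.marginal_reliability < 1


class TestImputation:
    def test_complete_matrix_unchanged(self, published_model):
        design = SimulationDesign(bank=equip_ph_bank(), n_persons=50, missing_rate=0.0, seed=2)
        m, _ = simulate_responses(design)
        out = impute_missing(published_model, m)
        assert np.array_equal(out.responses, m.responses)

    def test_high_scorers_imputed_at_top(self, published_model):
        resp = np.full((4, 19), 2.0)
        resp[:, 5] = np.nan
        m = make_matrix(resp, max_cat=2)
        m.item_ids[:] = published_model.item_ids
        out = impute_missing(published_model, m)
        assert (out.responses[:, 5] == 2).all()

    def test_beats_marginal_mode_under_the_generating_model(self, published_bank):
        design = SimulationDesign(
            bank=published_bank, n_persons=800, theta_mean=-0.08, theta_sd=1.9,
            missing_rate=0.16, seed=9,
        )
        miss_m, theta = simulate_responses(design)
        complete_design = SimulationDesign(
            bank=published_bank, n_persons=800, theta_mean=-0.08, theta_sd=1.9,
            missing_rate=0.0, seed=9,
        )
        full_m, _ = simulate_responses(complete_design)
        model = fit_pcm(miss_m)
        imputed = impute_missing(model, miss_m)
        mask = np.isnan(miss_m.responses)
        truth = full_m.responses[mask]
        acc_model = (imputed.responses[mask] == truth).mean()
        # marginal-mode baseline per item
        mode_fill = np.zeros_like(full_m.responses)
        for j in range(19):
            col = miss_m.responses[:, j]
            col = col[~np.isnan(col)].astype(int)
            mode_fill[:, j] = np.bincount(col).argmax()
        acc_mode = (mode_fill[mask] == truth).mean()
        assert acc_model > acc_mode


class TestScoreResponses:
    def test_collapse_map_applied_and_missingness_kept(self, published_bank):
        resp = np.array([[0, 1, 2, 3, 4], [4, 3, 2, 1, 0]], dtype=float).T
        resp[2, 0] = np.nan
        m = make_matrix(resp, max_cat=4)
        bank = ItemBank(
            [
                Item("i0", "", (-1.0, 1.0), (0, 1, 1, 2, 2)),
                Item("i1", "", (-1.0, 1.0), (0, 1, 1, 2, 2)),
            ]
        )
        out = score_responses(bank, m)
        assert np.array_equal(out.responses[:, 1], [2, 2, 1, 1, 0])
        assert np.isnan(out.responses[2, 0])
        assert list(out.max_cat) == [2, 2]
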