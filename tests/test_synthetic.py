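import numpy as np
import pytest
from scipy import stats

from premcal.data_io import Item, ItemBank
from premcal.pcm import PCMModel, category_probabilities, eap_scores
from premcal.synthetic import (
    Pathology,
    RetestDesign,
    SimulationDesign,
    default_study_design,
    inject_dif,
    inject_local_dependency,
    random_bank,
    simulate_responses,
    simulate_retest,
)


class TestSimulateResponses:
    def test_same_seed_reproduces_matrix_exactly(self, published_bank):
        design = SimulationDesign(bank=published_bank, n_persons=100, seed=5)
        m1, t1 = simulate_responses(design)
        m2, t2 = simulate_responses(design)
        assert np.array_equal(m1.responses, m2.responses, equal_nan=True)
        assert np.array_equal(t1, t2)

    def test_equal_threshold_item_draws_uniform_categories(self):
        bank = ItemBank([Item("x", "", (0.0, 0.0), (0, 1, 2)), Item("y", "", (0.0, 0.0), (0, 1, 2))])
        design = SimulationDesign(bank=bank, n_persons=30000, theta_mean=0.0, theta_sd=1e-9,
                                  missing_rate=0.0, seed=1)
        m, _ = simulate_responses(design)
        counts = np.bincount(m.responses[:, 0].astype(int), minlength=3)
        # 3 SE of the multinomial count around n/3
        se = np.sqrt(30000 * (1 / 3) * (2 / 3))
        assert (np.abs(counts - 10000) < 3 * se).all()

    def test_missingness_rate_within_binomial_band(self, published_bank):
        design = SimulationDesign(bank=published_bank, n_persons=267, missing_rate=0.16, seed=3)
        m, _ = simulate_responses(design)
        n_cells = 267 * 19
        half_width = 2.576 * np.sqrt(0.16 * 0.84 / n_cells)
        assert abs(m.missing_fraction - 0.16) < half_width

    def test_category_frequencies_match_pcm_closed_form(self):
        # chi-square goodness of fit at fixed theta, n = 50000
        deltas = (-0.8, 0.3, 1.1)
        bank = ItemBank([Item("x", "", deltas, (0, 1, 2, 3)), Item("y", "", deltas, (0, 1, 2, 3))])
        theta0 = 0.4
        design = SimulationDesign(bank=bank, n_persons=50000, theta_mean=theta0, theta_sd=1e-12,
                                  missing_rate=0.0, seed=7)
        m, _ = simulate_responses(design)
        expected = category_probabilities(deltas, theta0) * 50000
        observed = np.bincount(m.responses[:, 0].astype(int), minlength=4)
        chi2 = ((observed - expected) ** 2 / expected).sum()
        assert stats.chi2.sf(chi2, df=3) > 0.01

    def test_group_mix_follows_design(self):
        design = default_study_design(seed=11)
        m, _ = simulate_responses(design)
        assert m.group is not None
        frac_su = (m.group == "service_user").mean()
        assert frac_su == pytest.approx(0.66, abs=0.1)


class TestPathologies:
    def test_local_dependency_strength_one_copies_column(self, published_bank):
        design = SimulationDesign(bank=published_bank, n_persons=400, missing_rate=0.1, seed=2)
        m, _ = simulate_responses(design)
        out = inject_local_dependency(m, (m.item_ids[0], m.item_ids[1]), 1.0,
                                      np.random.default_rng(0))
        both = m.mask[:, 0] & m.mask[:, 1]
        assert np.array_equal(out.responses[both, 0], out.responses[both, 1])

    def test_local_dependency_strength_zero_is_identity(self, published_bank):
        design = SimulationDesign(bank=published_bank, n_persons=200, missing_rate=0.0, seed=2)
        m, _ = simulate_responses(design)
        out = inject_local_dependency(m, (m.item_ids[0], m.item_ids[1]), 0.0,
                                      np.random.default_rng(0))
        assert np.array_equal(out.responses, m.responses)

    def test_unknown_item_in_pair_rejected(self, published_bank):
        design = SimulationDesign(bank=published_bank, n_persons=50, seed=1)
        m, _ = simulate_responses(design)
        with pytest.raises(KeyError):
            inject_local_dependency(m, ("nope", m.item_ids[0]), 0.5)

    def test_inject_dif_zero_shift_leaves_groups_exchangeable(self, published_bank):
        base = SimulationDesign(bank=published_bank, n_persons=4000, missing_rate=0.0,
                                group_probs={"service_user": 0.5, "carer": 0.5}, seed=6)
        target = published_bank.item_ids[0]
        shifted = inject_dif(base, target, 0.0, group="carer")
        m, _ = simulate_responses(shifted)
        su = m.group == "service_user"
        mean_su = np.nanmean(m.responses[su, 0])
        mean_ca = np.nanmean(m.responses[~su, 0])
        assert mean_su == pytest.approx(mean_ca, abs=0.1)

    def test_inject_dif_shift_moves_one_group_only(self, published_bank):
        base = SimulationDesign(bank=published_bank, n_persons=4000, missing_rate=0.0,
                                group_probs={"service_user": 0.5, "carer": 0.5}, seed=6)
        target = published_bank.item_ids[0]
        shifted = inject_dif(base, target, 1.5, group="carer")
        m, _ = simulate_responses(shifted)
        su = m.group == "service_user"
        assert np.nanmean(m.responses[su, 0]) > np.nanmean(m.responses[~su, 0]) + 0.2
        # other items unaffected beyond noise
        assert np.nanmean(m.responses[su, 5]) == pytest.approx(
            np.nanmean(m.responses[~su, 5]), abs=0.1
        )

    def test_inject_dif_requires_known_item_and_groups(self, published_bank):
        base = SimulationDesign(bank=published_bank, n_persons=100,
                                group_probs={"service_user": 0.5, "carer": 0.5}, seed=1)
        with pytest.raises(ValueError, match="not in bank"):
            inject_dif(base, "nope", 0.5)
        nogroups = SimulationDesign(bank=published_bank, n_persons=100, seed=1)
        with pytest.raises(ValueError, match="group"):
            inject_dif(nogroups, published_bank.item_ids[0], 0.5)

    def test_pathology_items_must_exist(self, published_bank):
        with pytest.raises(ValueError, match="not in bank"):
            SimulationDesign(
                bank=published_bank, n_persons=10, seed=0,
                pathologies=[Pathology("disordered_thresholds", ("ghost",), 1.0)],
            )


class TestRetestSimulation:
    def test_perfect_latent_correlation_reproduces_thetas(self, published_bank):
        design = SimulationDesign(bank=published_bank, n_persons=300, missing_rate=0.0,
                                  retest=RetestDesign(300, 1.0), seed=4)
        _, theta1 = simulate_responses(design)
        _, theta2 = simulate_retest(design, theta1)
        assert np.allclose(theta1, theta2)

    def test_near_zero_latent_correlation(self, published_bank):
        design = SimulationDesign(bank=published_bank, n_persons=5000, missing_rate=0.0,
                                  retest=RetestDesign(5000, 1e-9), seed=4)
        _, theta1 = simulate_responses(design)
        _, theta2 = simulate_retest(design, theta1)
        assert abs(np.corrcoef(theta1, theta2)[0, 1]) < 0.05

    def test_retest_larger_than_sample_rejected(self, published_bank):
        with pytest.raises(ValueError, match="n_retest"):
            SimulationDesign(bank=published_bank, n_persons=50,
                             retest=RetestDesign(60, 0.7), seed=0)

    def test_score_correlation_attenuated_toward_study_value(self, published_bank):
        # latent rho .75 with 19 scored items at n=67: the observed theta-hat
        # correlation lands in a band around .70 (Monte-Carlo replicates)
        model = PCMModel.from_bank(published_bank)
        rs = []
        for seed in range(20):
            design = SimulationDesign(bank=published_bank, n_persons=67, theta_mean=-0.08,
                                      theta_sd=1.9, missing_rate=0.16,
                                      retest=RetestDesign(67, 0.75), seed=seed)
            m1, theta1 = simulate_responses(design)
            m2, _ = simulate_retest(design, theta1)
            s1 = np.array([e.theta for e in eap_scores(model, m1)])
            s2 = np.array([e.theta for e in eap_scores(model, m2)])
            rs.append(np.corrcoef(s1, s2)[0, 1])
        assert np.mean(rs) == pytest.approx(0.70, abs=0.06)
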