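import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from premcal.data_io import Item, ItemBank, PurificationLedger
from premcal.pcm import PCMModel, fit_pcm
from premcal.purification import (
    LDReport,
    PurifyConfig,
    detect_threshold_disorder,
    q3_local_dependency,
    remove_misfitting_items,
    rescore_items,
    resolve_local_dependency,
    run_purification_pipeline,
)
from premcal.synthetic import Pathology, SimulationDesign, simulate_responses

from conftest import make_matrix


class TestThresholdDisorder:
    def test_ascending_thresholds_are_ordered(self):
        model = PCMModel.from_bank(ItemBank([Item("a", "", (-1.0, 1.0), (0, 1, 2))]))
        v = detect_threshold_disorder(model)["a"]
        assert not v["disordered"]
        assert v["never_modal_categories"] == []

    def test_reversed_thresholds_hide_the_middle_category(self):
        model = PCMModel.from_bank(ItemBank([Item("a", "", (1.0, -1.0), (0, 1, 2))]))
        v = detect_threshold_disorder(model)["a"]
        assert v["disordered"]
        assert v["never_modal_categories"] == [1]

    def test_published_bank_is_fully_ordered(self, published_model):
        verdicts = detect_threshold_disorder(published_model)
        assert not any(v["disordered"] for v in verdicts.values())


class TestRescoring:
    def test_study_collapse_map(self):
        m = make_matrix(np.array([[0, 1, 2, 3, 4]], dtype=float).T, max_cat=4)
        out = rescore_items(m, (0, 1, 1, 2, 2))
        assert list(out.responses[:, 0]) == [0, 1, 1, 2, 2]
        assert out.max_cat[0] == 2

    def test_identity_map_is_a_no_op(self):
        resp = np.array([[0, 2], [1, np.nan], [2, 0]], dtype=float)
        m = make_matrix(resp, max_cat=2)
        out = rescore_items(m, (0, 1, 2))
        assert np.array_equal(out.responses, resp, equal_nan=True)

    def test_extreme_only_column_collapses_to_two_categories(self):
        resp = np.array([[0, 4, 0, 4, 0]], dtype=float).T
        out = rescore_items(make_matrix(resp, max_cat=4), (0, 1, 1, 2, 2))
        assert set(out.responses[:, 0]) == {0.0, 2.0}  # middle scored category unobserved

    def test_category_outside_map_domain_rejected(self):
        m = make_matrix(np.array([[0, 5]], dtype=float).T, max_cat=5)
        with pytest.raises(ValueError, match="outside scoring map domain"):
            rescore_items(m, (0, 1, 1, 2, 2))

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 4), st.integers(0, 4)), min_size=2, max_size=20))
    def test_rescoring_preserves_total_score_order(self, raw):
        # non-decreasing map: person rank order by total never changes
        resp = np.array(raw, dtype=float)
        m = make_matrix(resp, max_cat=4)
        out = rescore_items(m, (0, 1, 1, 2, 2))
        t_raw = resp.sum(axis=1)
        t_new = out.responses.sum(axis=1)
        for a in range(len(t_raw)):
            for b in range(len(t_raw)):
                if t_raw[a] < t_raw[b]:
                    assert t_new[a] <= t_new[b]


class TestLocalDependency:
    def test_duplicated_item_column_is_flagged_with_q3_near_one(
        self, clean_study_matrix
    ):
        matrix, _ = clean_study_matrix
        dup = matrix.copy()
        dup.responses[:, 1] = dup.responses[:, 0]
        model = fit_pcm(dup)
        report = q3_local_dependency(model, dup)
        pair = tuple(sorted((dup.item_ids[0], dup.item_ids[1])))
        assert pair in [tuple(sorted(p)) for p in report.dependent_pairs]
        a, b = dup.item_ids.index(pair[0]), dup.item_ids.index(pair[1])
        assert report.q3[a, b] > 0.8

    def test_q3_matrix_symmetric_with_adaptive_threshold(
        self, clean_study_matrix, fitted_clean_model
    ):
        matrix, _ = clean_study_matrix
        report = q3_local_dependency(fitted_clean_model, matrix)
        off = report.q3[np.triu_indices(19, 1)]
        assert np.allclose(report.q3, report.q3.T, equal_nan=True)
        assert report.threshold == pytest.approx(0.2 + np.nanmean(off))
        # clean data: flagged pairs are rare
        assert len(report.dependent_pairs) <= 0.05 * len(off)

    def test_lower_offset_flags_superset_of_pairs(self, clean_study_matrix, fitted_clean_model):
        matrix, _ = clean_study_matrix
        strict = q3_local_dependency(fitted_clean_model, matrix, offset=0.2)
        loose = q3_local_dependency(fitted_clean_model, matrix, offset=0.0)
        assert set(strict.dependent_pairs) <= set(loose.dependent_pairs)


class TestResolveLocalDependency:
    def _model(self):
        items = [Item(i, "", (-1.0 + 0.2 * k, 1.0 + 0.4 * k), (0, 1, 2))
                 for k, i in enumerate("ABCDE")]
        return PCMModel.from_bank(ItemBank(items))

    def test_multi_partner_item_removed_first(self):
        model = self._model()
        report = LDReport(list("ABCDE"), np.full((5, 5), np.nan), 0.2, 0.0,
                          [("A", "B"), ("A", "C")])
        plan = resolve_local_dependency(report, model)
        assert [p["item_id"] for p in plan] == ["A"]

    def test_isolated_pair_loses_less_informative_member(self):
        model = self._model()
        # item E has wider-spread thresholds -> lower integrated information than D
        report = LDReport(list("ABCDE"), np.full((5, 5), np.nan), 0.2, 0.0, [("D", "E")])
        plan = resolve_local_dependency(report, model)
        assert len(plan) == 1
        from premcal.purification import _integrated_information

        worse = min("DE", key=lambda i: _integrated_information(model, i))
        assert plan[0]["item_id"] == worse

    def test_empty_report_gives_empty_plan(self):
        report = LDReport(list("ABCDE"), np.full((5, 5), np.nan), 0.2, 0.0, [])
        assert resolve_local_dependency(report, self._model()) == []

    def test_partner_counts_recomputed_after_each_removal(self):
        # chain A-B, B-C, C-D: B and C both have 2 partners, but removing one
        # leaves the other with a single partner (isolated-pair rule applies)
        model = self._model()
        report = LDReport(list("ABCDE"), np.full((5, 5), np.nan), 0.2, 0.0,
                          [("A", "B"), ("B", "C"), ("C", "D")])
        plan = resolve_local_dependency(report, model)
        multi = [p for p in plan if "multiple" in p["reason"]]
        assert len(multi) == 1  # only one of B/C removed for multi-partner


class TestMisfitRemoval:
    def test_alpha_zero_removes_nothing(self, clean_study_matrix, fitted_clean_model):
        matrix, _ = clean_study_matrix
        model, out = remove_misfitting_items(fitted_clean_model, matrix, alpha=0.0)
        assert out.item_ids == matrix.item_ids

    def test_null_data_survive_bonferroni_rule(self, clean_study_matrix, fitted_clean_model):
        matrix, _ = clean_study_matrix
        ledger = PurificationLedger()
        model, out = remove_misfitting_items(fitted_clean_model, matrix, ledger=ledger)
        assert len(out.item_ids) >= 18  # at most one chance removal

    def test_steeper_generating_slope_yields_worst_fit(self, published_bank):
        # one item generated with double discrimination among Rasch items
        design = SimulationDesign(bank=published_bank, n_persons=2000, theta_mean=0,
                                  theta_sd=1.5, missing_rate=0.0, seed=21,
                                  pathologies=[Pathology("low_scalability",
                                                         (published_bank.item_ids[0],), 2.0)])
        m, _ = simulate_responses(design)
        model = fit_pcm(m)
        from premcal.pcm import fit_statistics

        report = fit_statistics(model, m)
        ps = {i: f["p"] for i, f in report.item_fit.items()}
        assert min(ps, key=ps.get) == published_bank.item_ids[0]


class TestPipeline:
    def test_stages_run_in_study_order_and_clean_data_survive(self, published_bank):
        design = SimulationDesign(bank=published_bank, n_persons=400, theta_mean=-0.08,
                                  theta_sd=1.9, missing_rate=0.1,
                                  group_probs={"service_user": 0.6, "carer": 0.4}, seed=17)
        m, _ = simulate_responses(design)
        cfg = PurifyConfig(seed=17, pa_method="pearson", pa_n_reference=10)
        bank, ledger, model = run_purification_pipeline(m, cfg)
        stages = ledger.stages()
        order = ["mokken", "parallel_analysis", "rescore", "local_dependency", "dif", "final"]
        kept = [s for s in order if s in stages]
        assert [s for s in stages if s in order] == kept
        assert stages.index("parallel_analysis") < stages.index("local_dependency")
        assert len(bank) >= 17
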