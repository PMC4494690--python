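"""IHC scoring and the diagnostic panel: chi-square against the published
2x2 tables and the closed form, Mann-Whitney against full enumeration,
panel classification and Bayes-adjusted predictive values."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from basalmir.errors import AssumptionError, ValidationError
from basalmir.ihc import (
    NegativeMarkerPanel,
    case_positivity,
    chisq_2x2,
    compare_marker,
    composite_score,
    evaluate_panel,
    mannwhitney,
    marker_table,
    panel_classify,
    positivity,
    prevalence_adjusted_pv,
)
from basalmir.types import IHCRecord, PanelRule, PrevalenceAssumptions

# initial-cohort positive/negative counts per marker, BRCA1 vs sporadic,
# with the p-values the chi-square reproduces at printed precision
INITIAL_COHORT_TABLES = {
    "FOXP1": ((6, 14), (37, 12)),
    "CCND1": ((8, 14), (30, 16)),
    "NRP1": ((2, 18), (23, 23)),
    "CD99": ((17, 3), (7, 12)),
}


class TestScores:
    @pytest.mark.parametrize(
        "intensity,percent,total", [(3, 4, 7), (0, 0, 0), (2, 3, 5)]
    )
    def test_composite_score_is_sum(self, intensity, percent, total):
        assert composite_score(intensity, percent) == total

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            composite_score(4, 0)

    def test_positivity_is_any_staining(self):
        pos = IHCRecord("c", "initial", "brca1", "FOXP1", 1, 1)
        neg = IHCRecord("c", "initial", "brca1", "FOXP1", 0, 0)
        assert positivity(pos) and not positivity(neg)


class TestChiSquare:
    def test_cyclin_d1_initial_cohort_table(self):
        stat, p = chisq_2x2(8, 14, 30, 16)
        assert stat == pytest.approx(5.0256, abs=2e-3)
        assert round(p, 3) == 0.025

    def test_closed_form_identity(self, rng):
        for _ in range(20):
            a, b, c, d = rng.integers(1, 40, size=4)
            stat, _ = chisq_2x2(a, b, c, d)
            n = a + b + c + d
            closed = (a * d - b * c) ** 2 * n / ((a + b) * (c + d) * (a + c) * (b + d))
            assert stat == pytest.approx(closed, abs=1e-10)

    def test_no_association_gives_zero_statistic(self):
        stat, p = chisq_2x2(5, 5, 5, 5)
        assert stat == 0.0 and p == 1.0

    def test_invariant_under_row_and_column_swap(self):
        s1, p1 = chisq_2x2(6, 14, 37, 12)
        s2, p2 = chisq_2x2(12, 37, 14, 6)
        assert s1 == pytest.approx(s2) and p1 == pytest.approx(p2)

    def test_zero_margin_is_error(self):
        with pytest.raises(ValidationError):
            chisq_2x2(0, 0, 5, 5)


class TestMannWhitney:
    def test_complete_separation_exact_p(self):
        u, p = mannwhitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2 of C(6,3)=20 arrangements

    def test_identical_samples_p_one_on_approximation_path(self):
        u, p = mannwhitney([3, 3, 3, 3], [3, 3, 3, 3])
        assert p == 1.0

    def test_matches_full_permutation_oracle(self, rng):
        # tie-free samples exercise the exact path, which must equal the
        # full enumeration of rank splits
        for _ in range(5):
            pooled = rng.permutation(np.arange(1.0, 10.0))
            a, b = pooled[:5], pooled[5:]
            _, p = mannwhitney(a, b)
            ranks = sps.rankdata(pooled)
            obs = ranks[:5].sum() - 5 * 6 / 2
            mean_u = 5 * 4 / 2
            count = total = 0
            for combo in itertools.combinations(range(9), 5):
                u1 = ranks[list(combo)].sum() - 5 * 6 / 2
                total += 1
                if abs(u1 - mean_u) >= abs(obs - mean_u) - 1e-9:
                    count += 1
            assert p == pytest.approx(count / total, abs=1e-12)

    def test_tie_corrected_approximation_tracks_enumeration(self, rng):
        for _ in range(3):
            a = rng.integers(0, 8, size=6).astype(float)
            b = rng.integers(0, 8, size=6).astype(float)
            if len(np.unique(np.concatenate([a, b]))) == 12:
                continue  # want the tie path
            _, p = mannwhitney(a, b)
            pooled = np.concatenate([a, b])
            ranks = sps.rankdata(pooled)
            mean_u = 6 * 6 / 2
            obs = ranks[:6].sum() - 6 * 7 / 2
            count = total = 0
            for combo in itertools.combinations(range(12), 6):
                u1 = ranks[list(combo)].sum() - 6 * 7 / 2
                total += 1
                if abs(u1 - mean_u) >= abs(obs - mean_u) - 1e-9:
                    count += 1
            assert p == pytest.approx(count / total, abs=0.15)

    def test_agrees_with_scipy_exact_when_tie_free(self, rng):
        a = [1.5, 6.2, 3.3, 9.1]
        b = [2.2, 4.4, 8.8, 0.7, 5.5]
        u, p = mannwhitney(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert u == ref.statistic
        assert p == pytest.approx(ref.pvalue, abs=1e-12)


def _records(marker, brca1_pos, brca1_neg, spor_pos, spor_neg):
    out = []
    i = 0
    for group, n_pos, n_neg in (
        ("brca1", brca1_pos, brca1_neg),
        ("sporadic", spor_pos, spor_neg),
    ):
        for _ in range(n_pos):
            out.append(IHCRecord(f"c{i}", "initial", group, marker, 2, 3)); i += 1
        for _ in range(n_neg):
            out.append(IHCRecord(f"c{i}", "initial", group, marker, 0, 0)); i += 1
    return out


class TestCompareMarker:
    def test_nrp1_initial_cohort_chi_square(self):
        records = _records("NRP1", 2, 18, 23, 23)
        cmp = compare_marker(records, "NRP1")
        assert round(cmp.p_chi2, 3) == 0.002
        assert cmp.counts == ((2, 18), (23, 23))
        assert cmp.positivity_brca1 == pytest.approx(0.10)
        assert cmp.positivity_sporadic == pytest.approx(0.50)

    def test_non_evaluable_records_excluded(self):
        records = _records("NRP1", 2, 18, 23, 23)
        extra = IHCRecord("x1", "initial", "brca1", "NRP1", 3, 4, evaluable=False)
        cmp = compare_marker(records + [extra], "NRP1")
        assert cmp.counts == ((2, 18), (23, 23))

    def test_all_non_evaluable_is_error(self):
        records = [IHCRecord("c1", "initial", "brca1", "X", 1, 1, evaluable=False)]
        with pytest.raises(ValidationError):
            compare_marker(records, "X")

    def test_null_positivity_p_values_roughly_uniform(self):
        # planted equal positivity: chi-square p should not pile up near 0
        from basalmir.simulate import IHCCohortSimConfig, gen_ihc_cohort

        p_values = []
        for seed in range(40):
            cfg = IHCCohortSimConfig(
                n_brca1=60,
                n_sporadic=60,
                positivity={"M": {"brca1": 0.5, "sporadic": 0.5}},
                panel_negative_corr=0.0,
                p_evaluable=1.0,
                seed=seed,
            )
            records, _ = gen_ihc_cohort(cfg)
            p_values.append(compare_marker(records, "M").p_chi2)
        assert sps.kstest(p_values, "uniform").pvalue > 0.01


class TestPanelRule:
    def test_two_of_three_negative_predicts_brca1(self):
        assert panel_classify({"FOXP1": False, "CCND1": False, "NRP1": True}) == "brca1"

    def test_all_positive_predicts_sporadic(self):
        assert panel_classify({"FOXP1": True, "CCND1": True, "NRP1": True}) == "sporadic"

    def test_all_negative_predicts_brca1(self):
        assert panel_classify({"FOXP1": False, "CCND1": False, "NRP1": False}) == "brca1"

    def test_missing_marker_is_error(self):
        with pytest.raises(ValidationError, match="NRP1"):
            panel_classify({"FOXP1": False, "CCND1": False})

    def test_invalid_k_rejected(self):
        with pytest.raises(ValidationError):
            PanelRule(markers=("A", "B"), k=3)


class TestEvaluatePanel:
    def test_perfect_predictions(self):
        result = evaluate_panel(
            ["brca1", "sporadic"], ["brca1", "sporadic"]
        )
        assert result.sensitivity == result.specificity == 1.0
        assert result.adjusted_ppv == result.adjusted_npv == 1.0

    def test_all_brca1_calls(self):
        result = evaluate_panel(["brca1"] * 4, ["brca1", "brca1", "sporadic", "sporadic"])
        assert result.sensitivity == 1.0 and result.specificity == 0.0

    def test_counts_conserve(self):
        preds = ["brca1", "sporadic", "brca1", "sporadic", "brca1"]
        truth = ["brca1", "brca1", "sporadic", "sporadic", "brca1"]
        r = evaluate_panel(preds, truth)
        assert r.tp + r.fp + r.tn + r.fn == 5


class TestPrevalenceAdjustment:
    def test_derived_prevalence_from_stated_assumptions(self):
        # 0.02 * 0.69 / 0.15 = 0.092
        assert PrevalenceAssumptions().derived_prevalence == pytest.approx(0.092)

    def test_bayes_values_at_reported_rule_performance(self):
        ppv, npv, prev = prevalence_adjusted_pv(0.92, 0.44)
        assert prev == pytest.approx(0.092)
        assert ppv == pytest.approx(0.1427, abs=2e-3)
        assert npv == pytest.approx(0.9818, abs=2e-3)

    def test_ppv_monotone_in_prevalence_npv_anti(self):
        ppvs, npvs = [], []
        for p_mut in np.linspace(0.005, 0.1, 12):
            a = PrevalenceAssumptions(p_mutation_in_breast_cancer=p_mut)
            ppv, npv, _ = prevalence_adjusted_pv(0.9, 0.5, a)
            ppvs.append(ppv)
            npvs.append(npv)
        assert all(b > a for a, b in zip(ppvs, ppvs[1:]))
        assert all(b < a for a, b in zip(npvs, npvs[1:]))

    def test_impossible_assumptions_raise(self):
        bad = PrevalenceAssumptions(
            p_mutation_in_breast_cancer=0.5, p_basal_phenotype=0.1, p_basal_given_mutation=0.9
        )
        with pytest.raises(AssumptionError):
            prevalence_adjusted_pv(0.9, 0.5, bad)


class TestPanelEstimator:
    def test_excludes_cases_with_missing_markers(self):
        records = []
        for i, (f, c, n) in enumerate([(1, 1, 0), (0, 0, 0), (1, 0, 1)]):
            records.append(IHCRecord(f"b{i}", "validation", "brca1", "FOXP1", f, f))
            records.append(IHCRecord(f"b{i}", "validation", "brca1", "CCND1", c, c))
            records.append(
                IHCRecord(f"b{i}", "validation", "brca1", "NRP1", n, n, evaluable=(i != 2))
            )
        for i in range(3):
            for m in ("FOXP1", "CCND1", "NRP1"):
                records.append(IHCRecord(f"s{i}", "validation", "sporadic", m, 2, 2))
        grid = case_positivity(records)
        panel = NegativeMarkerPanel().fit(grid)
        result = panel.evaluate(grid, grid["truth_group"])
        assert result.n_excluded == 1
        assert result.tp + result.fp + result.tn + result.fn == 5

    def test_recovers_planted_rule_performance_with_closed_form_oracle(self):
        from basalmir.simulate import (
            IHCCohortSimConfig,
            gen_ihc_cohort,
            kofn_rule_performance,
        )

        # negativity 0.805 per marker makes 2-of-3 sensitivity ~0.9
        q_brca1, q_spor = 0.805, 0.25
        cfg = IHCCohortSimConfig(
            n_brca1=1000,
            n_sporadic=1000,
            positivity={
                m: {"brca1": 1 - q_brca1, "sporadic": 1 - q_spor}
                for m in ("FOXP1", "CCND1", "NRP1")
            },
            panel_negative_corr=0.0,
            p_evaluable=1.0,
            seed=17,
        )
        records, _ = gen_ihc_cohort(cfg)
        grid = case_positivity(records)
        panel = NegativeMarkerPanel().fit(grid)
        result = panel.evaluate(grid, grid["truth_group"])
        sens_expected = kofn_rule_performance([q_brca1] * 3, 2)
        spec_expected = 1 - kofn_rule_performance([q_spor] * 3, 2)
        se_sens = math.sqrt(sens_expected * (1 - sens_expected) / 1000)
        se_spec = math.sqrt(spec_expected * (1 - spec_expected) / 1000)
        assert abs(result.sensitivity - sens_expected) <= 3 * se_sens
        assert abs(result.specificity - spec_expected) <= 3 * se_spec

    def test_marker_table_shape(self):
        records = _records("NRP1", 2, 18, 23, 23) + _records("FOXP1", 6, 14, 37, 12)
        table = marker_table(records, ["NRP1", "FOXP1"])
        assert list(table.index) == ["NRP1", "FOXP1"]
        assert {"p_chi2", "p_mw", "positive_brca1"} <= set(table.columns)
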