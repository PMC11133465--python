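"""LMD classification, sensitivities, survival and association statistics."""

import numpy as np
import pytest
from lifelines.statistics import logrank_test as ll_logrank

from csftdna.clinical import (
    PatientClinical,
    classify_lmd,
    dichotomize_by_median,
    km_curve,
    km_logrank,
    mann_whitney,
    modality_sensitivity,
    penetration_rate,
    spearman_corr,
    vaf_percent_change,
)
from csftdna.containers import UndefinedResultError, ValidationError


def _record(cyt=False, pcr=False, mri=False, sym=False, **kw):
    return PatientClinical(patient_id="P", cytology_positive=cyt,
                           egfr_csf_pcr_positive=pcr, mri_unequivocal_lmd=mri,
                           progressive_symptoms=sym, **kw)


class TestLmdClassifier:
    def test_cytology_positive_is_definitive_confirmed(self):
        s = classify_lmd(_record(cyt=True))
        assert (s.study_category, s.eano_esmo) == ("definitive", "confirmed")

    def test_mri_plus_symptoms_is_definitive_probable(self):
        s = classify_lmd(_record(mri=True, sym=True))
        assert (s.study_category, s.eano_esmo) == ("definitive", "probable")

    def test_symptoms_only_is_possible_in_both_schemes(self):
        s = classify_lmd(_record(sym=True))
        assert (s.study_category, s.eano_esmo) == ("possible", "possible")

    def test_pcr_positive_is_definitive(self):
        s = classify_lmd(_record(pcr=True))
        assert s.study_category == "definitive"

    def test_unknowns_count_negative_and_flagged(self):
        s = classify_lmd(PatientClinical(patient_id="P"))
        assert s.study_category == "non_lmd"
        assert s.eano_esmo == "none"
        assert not s.data_complete


class TestSensitivity:
    def _cohort(self, n_pos, n_neg, n_missing=0):
        definitive = classify_lmd(_record(cyt=True))
        return ([(definitive, True)] * n_pos + [(definitive, False)] * n_neg
                + [(definitive, None)] * n_missing)

    def test_eleven_of_twelve(self):
        sens, num, den = modality_sensitivity(self._cohort(11, 1))
        assert 100 * sens == pytest.approx(91.7, abs=0.05)
        assert (num, den) == (11, 12)

    def test_nine_of_eleven(self):
        sens, _, _ = modality_sensitivity(self._cohort(9, 2))
        assert 100 * sens == pytest.approx(81.8, abs=0.05)

    def test_zero_of_n(self):
        assert modality_sensitivity(self._cohort(0, 5))[0] == 0.0

    def test_unevaluable_drop_from_denominator(self):
        sens, num, den = modality_sensitivity(self._cohort(3, 1, n_missing=2))
        assert (num, den) == (3, 4)

    def test_non_definitive_never_counted(self):
        possible = classify_lmd(_record(sym=True))
        with pytest.raises(UndefinedResultError):
            modality_sensitivity([(possible, True)] * 4)

    def test_adding_positive_case_never_decreases(self):
        base = modality_sensitivity(self._cohort(5, 3))[0]
        more = modality_sensitivity(self._cohort(6, 3))[0]
        assert more >= base


class TestLogrank:
    def test_hand_computed_oe_table(self):
        """Group A events at {1,2,3}, group B at {4,5,6}: O/E computed by hand.

        t=1: E_A += 3/6; t=2: += 2/5; t=3: += 1/4; later A is exhausted.
        So E_A = 1.15, O_A = 3, E_B = 4.85, O_B = 3; V = 0.25+0.24+0.1875.
        """
        times = [1, 2, 3, 4, 5, 6]
        events = [True] * 6
        groups = ["A", "A", "A", "B", "B", "B"]
        cmp_ = km_logrank(times, events, groups)
        e_a, o_a = 1.15, 3.0
        e_b, o_b = 4.85, 3.0
        v = 0.25 + 0.24 + 0.1875
        assert cmp_.hazard_ratio == pytest.approx((o_b / e_b) / (o_a / e_a))
        from scipy.stats import chi2
        assert cmp_.logrank_p == pytest.approx(chi2.sf((o_a - e_a) ** 2 / v, 1))

    def test_agrees_with_lifelines(self, rng):
        times = rng.exponential(100, size=40)
        events = rng.random(40) < 0.8
        groups = np.where(rng.random(40) < 0.5, "A", "B")
        if len(set(groups)) < 2:
            groups[0] = "A"
            groups[1] = "B"
        mine = km_logrank(times, events, groups)
        theirs = ll_logrank(times[groups == "A"], times[groups == "B"],
                            events[groups == "A"], events[groups == "B"])
        assert mine.logrank_p == pytest.approx(theirs.p_value, rel=1e-6)

    def test_identical_groups_give_null(self):
        times = [1, 2, 3, 1, 2, 3]
        events = [True] * 6
        groups = ["A"] * 3 + ["B"] * 3
        cmp_ = km_logrank(times, events, groups)
        assert cmp_.hazard_ratio == pytest.approx(1.0)
        assert cmp_.logrank_p == pytest.approx(1.0)

    def test_label_swap_inverts_hr(self, rng):
        times = rng.exponential(100, size=30)
        events = np.ones(30, bool)
        groups = ["A"] * 15 + ["B"] * 15
        a = km_logrank(times, events, groups)
        b = km_logrank(times, events, ["B" if g == "A" else "A" for g in groups])
        assert a.hazard_ratio == pytest.approx(1 / b.hazard_ratio)
        assert a.logrank_p == pytest.approx(b.logrank_p)

    def test_group_without_events_gives_no_hr_but_p(self):
        cmp_ = km_logrank([5, 6, 7, 8], [True, True, False, False],
                          ["A", "A", "B", "B"])
        assert cmp_.hazard_ratio is None
        assert 0 <= cmp_.logrank_p <= 1

    def test_ci_brackets_hr(self, rng):
        times = np.r_[rng.exponential(50, 20), rng.exponential(150, 20)]
        events = np.ones(40, bool)
        groups = ["fast"] * 20 + ["slow"] * 20
        cmp_ = km_logrank(times, events, groups)
        assert cmp_.hr_ci_low <= cmp_.hazard_ratio <= cmp_.hr_ci_high

    def test_needs_two_groups(self):
        with pytest.raises(ValidationError):
            km_logrank([1, 2], [True, True], ["A", "A"])


def test_km_curve_monotone_step_function(rng):
    times = rng.exponential(100, size=50)
    events = rng.random(50) < 0.7
    curve = km_curve(times, events)
    surv = curve["survival"].to_numpy()
    assert (np.diff(surv) <= 1e-12).all()
    assert (surv <= 1.0).all() and (surv >= 0).all()


def test_logrank_p_uniform_under_null():
    """With no survival difference between groups (hazard ratio 1), log-rank
    p-values over 200 simulated cohorts are approximately uniform."""
    from scipy.stats import kstest

    rng = np.random.default_rng(77)
    pvals = []
    for _ in range(200):
        times = rng.exponential(100, size=40)
        events = rng.random(40) < 0.8
        groups = np.r_[["A"] * 20, ["B"] * 20]
        pvals.append(km_logrank(times, events, groups).logrank_p)
    assert kstest(pvals, "uniform").pvalue > 0.01
    frac = np.mean(np.asarray(pvals) <= 0.05)
    assert 0.0 <= frac <= 0.10


class TestDichotomize:
    def test_median_threshold_recovered_from_simulated_vafs(self):
        """Splitting log-normal VAFs with configured median 4.8% puts the
        implied threshold within sampling error of 4.8%."""
        rng = np.random.default_rng(3)
        vafs = np.exp(rng.normal(np.log(0.048), 0.6, size=400))
        labels = dichotomize_by_median(vafs)
        threshold = float(np.median(vafs))
        assert threshold == pytest.approx(0.048, rel=0.15)
        above = vafs[[l == "above" for l in labels]]
        below = vafs[[l == "at_or_below" for l in labels]]
        assert above.min() > threshold >= below.max()

    def test_even_split_midpoint_median(self):
        labels = dichotomize_by_median([1, 2, 3, 4])
        assert labels == ["at_or_below", "at_or_below", "above", "above"]

    def test_tie_at_median_goes_low(self):
        labels = dichotomize_by_median([1, 2, 3])
        assert labels[1] == "at_or_below"

    def test_identical_values_undefined(self):
        with pytest.raises(UndefinedResultError):
            dichotomize_by_median([5, 5, 5])


class TestAssociations:
    def test_perfect_monotone(self):
        assert spearman_corr([1, 2, 3, 4], [10, 20, 30, 40]).statistic == 1.0
        assert spearman_corr([1, 2, 3, 4], [40, 30, 20, 10]).statistic == -1.0

    def test_matches_hand_ranked_oracle(self):
        """Spearman on six pairs equals the rank-correlation computed directly
        from hand-assigned average ranks."""
        x = [3.0, 1.0, 4.0, 1.0, 5.0, 9.0]
        y = [2.0, 7.0, 1.0, 8.0, 2.0, 8.0]

        def avg_ranks(v):
            v = np.asarray(v)
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v), float)
            i = 0
            sorted_v = v[order]
            while i < len(v):
                j = i
                while j < len(v) and sorted_v[j] == sorted_v[i]:
                    j += 1
                ranks[order[i:j]] = (i + j + 1) / 2  # average of 1-based ranks
                i = j
            return ranks

        rx, ry = avg_ranks(x), avg_ranks(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman_corr(x, y).statistic == pytest.approx(expected)

    def test_constant_vector_undefined(self):
        with pytest.raises(UndefinedResultError):
            spearman_corr([1, 1, 1], [1, 2, 3])

    def test_mann_whitney_matches_pair_count_oracle(self):
        a = [1.0, 4.0, 6.0, 9.0]
        b = [2.0, 3.0, 5.0]
        u_brute = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
        res = mann_whitney(a, b)
        assert res.statistic == pytest.approx(u_brute)
        assert 0 < res.p_value <= 1

    def test_mann_whitney_detects_shift(self, rng):
        a = rng.normal(0, 1, 50)
        b = rng.normal(2, 1, 50)
        assert mann_whitney(a, b).p_value < 1e-6


class TestDrugAndVafChange:
    @pytest.mark.parametrize("csf, plasma, expected", [
        (5.0, 100.0, 5.0), (100.0, 100.0, 100.0), (2.5, 250.0, 1.0)])
    def test_penetration(self, csf, plasma, expected):
        assert penetration_rate(csf, plasma) == pytest.approx(expected)

    def test_penetration_zero_plasma_undefined(self):
        with pytest.raises(UndefinedResultError):
            penetration_rate(5.0, 0.0)

    @pytest.mark.parametrize("pre, post, expected", [
        (0.10, 0.20, 100.0), (0.10, 0.10, 0.0), (0.04, 0.01, -75.0)])
    def test_vaf_change(self, pre, post, expected):
        assert vaf_percent_change(pre, post) == pytest.approx(expected)

    def test_new_detection_undefined(self):
        with pytest.raises(UndefinedResultError, match="new detection"):
            vaf_percent_change(0.0, 0.1)
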