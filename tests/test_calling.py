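"""Error model and tumor-naive caller: pooled rates, binomial test, filters."""

import math

import numpy as np
import pandas as pd
import pytest

from csftdna.calling import (
    binomial_tail,
    build_reporter_set,
    call_variants_tumor_naive,
    estimate_error_profile,
    exclude_germline,
    filter_coding,
)
from csftdna.containers import ValidationError
from csftdna.simulate import SimulationConfig, simulate_panel, simulate_sample_counts, true_error_profile

from conftest import make_counts


def _two_controls(alt_counts=(1, 3), depth=1000):
    recs = [[("chr1", 100, "A", "T", depth, a)] for a in alt_counts]
    return [make_counts(r, sample_id=f"C{i}") for i, r in enumerate(recs)]


def test_pooled_rate_no_pseudocounts():
    profile = estimate_error_profile(_two_controls(), pseudocounts=(0.0, 0.0))
    assert profile.rates["error_rate"].iloc[0] == pytest.approx(4 / 2000)
    assert profile.rates["total_control_depth"].iloc[0] == 2000
    assert profile.policy == "explicit"


def test_pseudocount_floor_on_all_zero_counts():
    controls = _two_controls(alt_counts=(0, 0), depth=5000)
    profile = estimate_error_profile(controls, pseudocounts=(0.5, 1.0))
    assert profile.rates["error_rate"].iloc[0] == pytest.approx(0.5 / 10001)


def test_zero_depth_position_flagged_unusable():
    controls = [make_counts([("chr1", 100, "A", "T", 0, 0)], sample_id=f"C{i}")
                for i in range(2)]
    profile = estimate_error_profile(controls, pseudocounts=(0.5, 1.0))
    assert not profile.rates["usable"].iloc[0]
    assert profile.lookup(profile.rates).isna().all()


def test_shrinkage_policy_preserves_mean_rate():
    """Fitted mean error rate matches the generating Beta mean within 3 SE."""
    cfg = SimulationConfig(panel_size=2000, seed=13)
    _, err = simulate_panel(cfg)
    profile_true = true_error_profile(err)
    controls = [simulate_sample_counts(None, 0.0, 1879.0, profile_true,
                                       seed=100 + j, sample_id=f"C{j}")
                for j in range(30)]
    fitted = estimate_error_profile(controls)
    est = fitted.rates["error_rate"].to_numpy()
    se = est.std(ddof=1) / math.sqrt(len(est))
    assert abs(est.mean() - 1e-4) < 3 * se + 2e-6


def test_requires_two_controls():
    with pytest.raises(ValidationError):
        estimate_error_profile(_two_controls()[:1])


def test_binomial_tail_matches_direct_summation():
    """Brute-force tail sum (log-space binomial pmf) agrees with the caller's."""
    n, k, p = 200, 5, 1e-3
    direct = sum(math.comb(n, j) * p ** j * (1 - p) ** (n - j)
                 for j in range(k, n + 1))
    assert binomial_tail(k, n, p) == pytest.approx(direct, rel=1e-9)


def _profile_for(panel, rate):
    rows = panel.positions[["chrom", "pos"]].copy()
    rows["ref"] = "A"
    rows["alt"] = "T"
    rows["error_rate"] = rate
    return true_error_profile(rows)


class TestCaller:
    def test_zero_alt_never_called(self, tiny_panel):
        profile = _profile_for(tiny_panel, 0.5)
        sample = make_counts([("chr1", 100, "A", "T", 1000, 0)])
        res = call_variants_tumor_naive(sample, profile, tiny_panel)
        assert len(res.calls) == 0

    def test_strong_signal_called_under_bonferroni(self, tiny_panel):
        # tail P(X >= 50 | n=1000, p=1e-4) is far below 0.05 / 1e5
        profile = _profile_for(tiny_panel, 1e-4)
        sample = make_counts([("chr1", 100, "A", "T", 1000, 50)])
        res = call_variants_tumor_naive(sample, profile, tiny_panel,
                                        alpha=0.05, n_tests=100_000)
        assert len(res.calls) == 1
        assert res.calls["p_value"].iloc[0] < 0.05 / 100_000

    def test_single_read_not_called(self, tiny_panel):
        # tail P(X >= 1 | n=1000, p=1e-3) = 1 - (1-p)^1000 ~ 0.63
        profile = _profile_for(tiny_panel, 1e-3)
        sample = make_counts([("chr1", 100, "A", "T", 1000, 1)])
        res = call_variants_tumor_naive(sample, profile, tiny_panel)
        assert len(res.calls) == 0

    def test_positions_outside_panel_and_profile_counted(self, tiny_panel):
        profile = _profile_for(tiny_panel, 1e-4)
        sample = make_counts([
            ("chr1", 100, "A", "T", 1000, 50),
            ("chr1", 100, "A", "G", 1000, 50),   # substitution not profiled
            ("chr9", 999, "A", "T", 1000, 50),   # outside panel
        ])
        res = call_variants_tumor_naive(sample, profile, tiny_panel)
        assert res.n_outside_panel == 1
        assert res.n_missing_profile == 1
        assert len(res.calls) == 1

    def test_sensitivity_monotone_in_depth_and_vaf(self, tiny_panel):
        """Tail p-value shrinks with depth and with alt fraction."""
        p1 = binomial_tail(5, 100, 1e-4)
        p2 = binomial_tail(10, 200, 1e-4)  # same VAF, double depth
        p3 = binomial_tail(10, 100, 1e-4)  # same depth, double VAF
        assert p2 < p1 and p3 < p1


class TestGermlineExclusion:
    def _cands(self):
        return pd.DataFrame([
            ("chr1", 100, "A", "T", "GENEA", True, 500, 40, 0.08, 1e-30),
            ("chr1", 101, "A", "T", "GENEA", True, 500, 35, 0.07, 1e-28),
        ], columns=["chrom", "pos", "ref", "alt", "gene", "coding",
                    "depth", "alt_count", "vaf", "p_value"])

    def test_heterozygous_snp_excluded(self):
        germ = make_counts([("chr1", 100, "A", "T", 1000, 490),
                            ("chr1", 101, "A", "T", 1000, 0)], sample_id="G")
        kept, removed = exclude_germline(self._cands(), germ)
        assert list(kept["pos"]) == [101]
        assert list(removed["pos"]) == [100]
        assert removed["reason"].iloc[0] == "germline_vaf"

    def test_boundary_vaf_inclusive(self):
        germ = make_counts([("chr1", 100, "A", "T", 1000, 5),
                            ("chr1", 101, "A", "T", 1000, 4)], sample_id="G")
        kept, removed = exclude_germline(self._cands(), germ,
                                         germline_vaf_threshold=0.005)
        assert list(removed["pos"]) == [100]  # VAF exactly 0.005 excluded
        assert list(kept["pos"]) == [101]

    def test_idempotent(self):
        germ = make_counts([("chr1", 100, "A", "T", 1000, 490),
                            ("chr1", 101, "A", "T", 1000, 0)], sample_id="G")
        once, _ = exclude_germline(self._cands(), germ)
        twice, _ = exclude_germline(once, germ)
        pd.testing.assert_frame_equal(once, twice)

    def test_missing_germline_policies(self):
        with pytest.raises(ValidationError):
            exclude_germline(self._cands(), None, missing_policy="fail")
        kept, removed = exclude_germline(self._cands(), None,
                                         missing_policy="warn")
        assert len(kept) == 2 and len(removed) == 0
        assert not kept["germline_checked"].any()


class TestCodingFilter:
    def test_mixed_list_keeps_coding_in_order(self, tiny_panel):
        cands = pd.DataFrame([
            ("chr1", 104, "A", "T"),  # non-coding
            ("chr1", 100, "A", "T"),  # coding
            ("chr2", 204, "A", "T"),  # non-coding
            ("chr2", 200, "A", "T"),  # coding
            ("chr3", 999, "A", "T"),  # unannotated -> treated non-coding
        ], columns=["chrom", "pos", "ref", "alt"])
        out = filter_coding(cands, tiny_panel)
        assert list(zip(out["chrom"], out["pos"])) == [("chr1", 100), ("chr2", 200)]

    def test_empty_input(self, tiny_panel):
        cands = pd.DataFrame(columns=["chrom", "pos", "ref", "alt"])
        assert len(filter_coding(cands, tiny_panel)) == 0


class TestReporterSet:
    @pytest.fixture()
    def setting(self, tiny_panel):
        profile = _profile_for(tiny_panel, 1e-4)
        tumor = make_counts([("chr1", 100, "A", "T", 1000, 300)],
                            sample_id="T", patient_id="P1", compartment="tumor",
                            timepoint_days=0.0, treatment_state="pre")
        csf = make_counts([("chr1", 100, "A", "T", 200, 60),
                           ("chr2", 200, "A", "T", 200, 50)],
                          sample_id="C", patient_id="P1", compartment="CSF",
                          timepoint_days=0.0, treatment_state="pre")
        germ = make_counts([("chr1", 100, "A", "T", 1000, 0),
                            ("chr2", 200, "A", "T", 1000, 0)],
                           sample_id="G", patient_id="P1", compartment="germline",
                           timepoint_days=0.0, treatment_state="pre")
        return profile, tumor, csf, germ

    def test_union_with_provenance(self, setting, tiny_panel):
        """Tumor {var1} + CSF {var1, var2} unite into two reporters."""
        profile, tumor, csf, germ = setting
        rs = build_reporter_set([tumor, csf, germ], profile, tiny_panel)
        assert len(rs) == 2
        shared = rs.variants.set_index("pos").loc[100, "sources"]
        assert shared == "C;T"  # called in both samples, recorded once

    def test_order_invariance(self, setting, tiny_panel):
        profile, tumor, csf, germ = setting
        a = build_reporter_set([tumor, csf, germ], profile, tiny_panel)
        b = build_reporter_set([germ, csf, tumor], profile, tiny_panel)
        pd.testing.assert_frame_equal(a.variants, b.variants)

    def test_disjoint_calls_sum(self, setting, tiny_panel):
        profile, tumor, csf, germ = setting
        csf2 = make_counts([("chr2", 200, "A", "T", 200, 50)],
                           sample_id="C2", patient_id="P1", compartment="CSF",
                           timepoint_days=0.0, treatment_state="pre")
        rs = build_reporter_set([tumor, csf2, germ], profile, tiny_panel)
        assert len(rs) == 2
        assert set(rs.variants["sources"]) == {"T", "C2"}

    def test_empty_union_is_valid(self, setting, tiny_panel):
        profile, _, _, germ = setting
        quiet = make_counts([("chr1", 100, "A", "T", 200, 0)],
                            sample_id="Q", patient_id="P1", compartment="CSF",
                            timepoint_days=0.0, treatment_state="pre")
        rs = build_reporter_set([quiet, germ], profile, tiny_panel)
        assert len(rs) == 0

    def test_germline_only_rejected(self, setting, tiny_panel):
        profile, _, _, germ = setting
        with pytest.raises(ValidationError):
            build_reporter_set([germ], profile, tiny_panel)

    def test_recovers_truth_reporters_in_simulation(self, small_cohort):
        """High-burden simulated patients recover exactly their truth reporters."""
        panel, samples, _, truth = small_cohort
        controls = [s for s in samples if s.patient_id.startswith("CTRL")]
        profile = estimate_error_profile(controls)
        pats = truth.patients.set_index("patient_id")
        pid = pats[pats["csf_tumor_fraction"] > 0.2].index[0]
        psamples = [s for s in samples if s.patient_id == pid]
        rs = build_reporter_set(psamples, profile, panel)
        want = truth.reporters[pid]
        got = rs.variants.merge(want, on=["chrom", "pos", "ref", "alt"])
        assert len(got) == len(want)  # every truth reporter recovered
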