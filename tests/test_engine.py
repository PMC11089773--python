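"""Curve assembly, AUPRC/AUROC, start conventions, and emulation profiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prcmethods import (
    PROFILES,
    METHODS,
    ScoredLabels,
    auroc,
    build_prc,
    evaluate_with_profile,
    fixture,
    get_profile,
)
from conftest import random_instance


class TestBuildPrc:
    @pytest.mark.parametrize("method", METHODS)
    def test_perfect_separation_gives_unit_area(self, method):
        curve = build_prc(fixture("perfect"), method=method)
        assert curve.auprc == pytest.approx(1.0)

    def test_all_tied_continuous_expectation_is_prevalence(self):
        # 32 positives, 42 negatives, one tie group -> 32/74, prints 0.432
        curve = build_prc(fixture("all_tied"), method="continuous_expectation")
        assert curve.auprc == pytest.approx(32 / 74, abs=1e-15)
        assert round(curve.auprc, 3) == 0.432

    def test_large_imbalanced_baseline_rounds_to_0014(self):
        data = ScoredLabels(
            [0.5] * (4012 + 274380), [1] * 4012 + [0] * 274380
        )
        curve = build_prc(data, method="continuous_expectation")
        assert curve.auprc == pytest.approx(4012 / 278392, abs=1e-15)
        assert round(curve.auprc, 3) == 0.014

    def test_start_convention_changes_linear_area_iff_first_precision_below_one(self):
        # first anchor precision 1: the two conventions coincide
        d_top_pos = ScoredLabels([0.9, 0.1], [1, 0])
        a = build_prc(d_top_pos, "linear", start_convention="derived").auprc
        b = build_prc(d_top_pos, "linear", start_convention="fixed_0_1").auprc
        assert a == pytest.approx(b)
        # first anchor precision 1/2: fixed (0,1) start adds a triangle
        d_tied_top = ScoredLabels([0.9, 0.9, 0.1], [1, 0, 0])
        a = build_prc(d_tied_top, "linear", start_convention="derived").auprc
        b = build_prc(d_tied_top, "linear", start_convention="fixed_0_1").auprc
        assert b > a
        # extra triangle: recall width 1, precision gap (1 - 0.5)
        assert b - a == pytest.approx(1.0 * (1 - 0.5) / 2)

    def test_derived_start_uses_method_limit_not_unity(self):
        # first tie group: 1 positive + 3 negatives -> expectation limit 0.25
        d = ScoredLabels([0.9] * 4 + [0.5, 0.5], [1, 0, 0, 0, 1, 0])
        for method in ("discrete_expectation", "continuous_expectation"):
            curve = build_prc(d, method, start_convention="derived")
            r0, p0 = curve.curve_points()[0]
            assert (r0, p0) == pytest.approx((0.0, 0.25))
        ap_curve = build_prc(d, "ap", start_convention="derived")
        assert ap_curve.curve_points()[0, 1] == pytest.approx(0.25)

    def test_fixed01_leaves_ap_and_continuous_area_unchanged(self):
        d = ScoredLabels([0.9] * 4 + [0.5, 0.5], [1, 0, 0, 0, 1, 0])
        for method in ("ap", "continuous_expectation"):
            derived = build_prc(d, method, start_convention="derived")
            fixed = build_prc(d, method, start_convention="fixed_0_1")
            assert fixed.auprc == pytest.approx(derived.auprc)
            assert fixed.curve_points()[0].tolist() == [0.0, 1.0]

    def test_auprc_agrees_with_trapezoid_of_sampled_points(self, rng):
        # exact segment areas vs numerical integration of the drawn curve
        for _ in range(15):
            d = random_instance(rng)
            for method in ("linear", "discrete_expectation", "ap"):
                curve = build_prc(d, method)
                pts = curve.curve_points()
                num = np.trapezoid(pts[:, 1], pts[:, 0])
                assert curve.auprc == pytest.approx(num, abs=1e-6)
            dense = build_prc(d, "continuous_expectation")
            pts = dense.curve_points()
            num = np.trapezoid(pts[:, 1], pts[:, 0])
            assert dense.auprc == pytest.approx(num, abs=1e-3)

    def test_no_negatives_warns_and_gives_unit_area(self):
        d = ScoredLabels([0.9, 0.5], [1, 1])
        with pytest.warns(UserWarning, match="no negative"):
            curve = build_prc(d, "continuous_expectation")
        assert curve.auprc == pytest.approx(1.0)

    def test_rectangle_curve_area(self):
        # one tie group covering recall 0->1 at precision 0.3
        d = ScoredLabels([1.0] * 10, [1] * 3 + [0] * 7)
        assert build_prc(d, "ap").auprc == pytest.approx(0.3)

    def test_three_entity_ap_hand_value(self):
        # scores 0.9(+), 0.8(-), 0.7(+): AP = 0.5*1 + 0.5*(2/3) = 5/6
        d = ScoredLabels([0.9, 0.8, 0.7], [1, 0, 1])
        assert build_prc(d, "ap").auprc == pytest.approx(5 / 6)


@settings(deadline=None, max_examples=50)
@given(n_pos=st.integers(1, 300), n_neg=st.integers(1, 300))
def test_all_tied_prevalence_identity(n_pos, n_neg):
    """Continuous-expectation AUPRC of an all-tied dataset = P/(P+N) exactly."""
    d = ScoredLabels([1.0] * (n_pos + n_neg), [1] * n_pos + [0] * n_neg)
    curve = build_prc(d, "continuous_expectation")
    assert curve.auprc == pytest.approx(n_pos / (n_pos + n_neg), abs=1e-12)


@settings(deadline=None, max_examples=40)
@given(n_pos=st.integers(1, 50), n_neg=st.integers(1, 50))
def test_linear_fixed01_dominates_on_single_tie_group(n_pos, n_neg):
    """The optimism ordering is exact on the degenerate all-tied case."""
    d = ScoredLabels([1.0] * (n_pos + n_neg), [1] * n_pos + [0] * n_neg)
    lin = build_prc(d, "linear", start_convention="fixed_0_1").auprc
    cont = build_prc(d, "continuous_expectation").auprc
    disc = build_prc(d, "discrete_expectation").auprc
    ap = build_prc(d, "ap").auprc
    assert cont == pytest.approx(disc, abs=1e-12)
    assert cont == pytest.approx(ap, abs=1e-12)
    if n_neg > 0:
        assert lin > cont  # prevalence < 1 -> strict optimism


class TestAuroc:
    def pair_counting(self, data):
        """Brute-force Mann-Whitney oracle with half credit for ties."""
        pos = data.scores[data.labels == 1]
        neg = data.scores[data.labels == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        return wins / (len(pos) * len(neg))

    def test_perfect_separation(self):
        assert auroc(fixture("perfect")) == pytest.approx(1.0)

    def test_all_tied_is_half(self):
        assert auroc(fixture("all_tied")) == pytest.approx(0.5)

    def test_equals_pair_counting_oracle_on_random_instances(self, rng):
        for _ in range(50):
            d = random_instance(rng, n_max=30)
            if d.n_neg == 0:
                continue
            assert auroc(d) == pytest.approx(self.pair_counting(d), abs=1e-12)


class TestProfiles:
    def test_catalogue_has_one_row_per_surveyed_tool_mode(self):
        expected = {
            "reference", "ROCR", "Weka", "scikit-learn-curve", "scikit-learn-ap",
            "PerfMeas", "PRROC-discrete", "PRROC-continuous", "TensorFlow",
            "precrec", "TorchEval", "MLeval", "yardstick-curve", "yardstick-ap",
        }
        assert set(PROFILES) == expected
        ref = PROFILES["reference"]
        assert ref.start_convention == "derived"
        assert ref.full_coverage and not ref.tie_order_sensitive
        assert not ref.drop_anchors and not ref.issues

    def test_reference_profile_equals_plain_build(self, rng):
        for _ in range(10):
            d = random_instance(rng)
            rep = evaluate_with_profile(d, "reference")
            assert rep.auprc == build_prc(d, "continuous_expectation").auprc
            assert rep.baseline == pytest.approx(d.prevalence)

    def test_unknown_profile_name(self):
        with pytest.raises(KeyError, match="unknown profile"):
            get_profile("nonexistent-tool")

    def test_perfmeas_depends_on_input_order_reference_does_not(self):
        # 6 tied entities; positives-first vs negatives-first input order
        pos_first = ScoredLabels([0.5] * 6, [1, 1, 1, 0, 0, 0])
        neg_first = ScoredLabels([0.5] * 6, [0, 0, 0, 1, 1, 1])
        pm_pf = evaluate_with_profile(pos_first, "PerfMeas").auprc
        pm_nf = evaluate_with_profile(neg_first, "PerfMeas").auprc
        assert pm_pf != pm_nf
        assert pm_pf > pm_nf  # positives-first flatters the classifier
        ref_pf = evaluate_with_profile(pos_first, "reference").auprc
        ref_nf = evaluate_with_profile(neg_first, "reference").auprc
        assert ref_pf == pytest.approx(ref_nf, abs=1e-15)

    def test_same_method_pair_profiles_agree_on_tie_free_data(self, rng):
        for _ in range(10):
            d = random_instance(rng, tie_prob=0.0)
            if d.n_neg == 0:
                continue
            a = evaluate_with_profile(d, "scikit-learn-ap").auprc
            b = evaluate_with_profile(d, "Weka").auprc
            assert a == b

    def test_order_insensitive_profiles_are_permutation_invariant(self, rng):
        d = random_instance(rng, tie_prob=1.0)
        perm = rng.permutation(d.n)
        d2 = ScoredLabels(d.scores[perm], d.labels[perm])
        for name, profile in PROFILES.items():
            if profile.tie_order_sensitive:
                continue
            assert (
                evaluate_with_profile(d, name).auprc
                == pytest.approx(evaluate_with_profile(d2, name).auprc, abs=1e-12)
            ), name

    def test_issue_flags(self):
        assert PROFILES["ROCR"].issues == (
            "fixed_start_point", "missing_anchors_on_prc",
        )
        assert PROFILES["scikit-learn-curve"].issues == (
            "tie_linear_optimism", "fixed_start_point",
        )
        assert PROFILES["PerfMeas"].issues == (
            "incomplete_recall_range", "input_order_ties",
        )
        assert PROFILES["MLeval"].issues == (
            "tie_linear_optimism", "incomplete_recall_range",
        )
        assert PROFILES["yardstick-curve"].issues == (
            "tie_linear_optimism", "fixed_start_point",
        )
        for clean in ("Weka", "scikit-learn-ap", "PRROC-discrete",
                      "PRROC-continuous", "precrec", "TorchEval",
                      "yardstick-ap", "TensorFlow", "reference"):
            assert PROFILES[clean].issues == ()

    def test_auroc_reported_identically_across_profiles(self, rng):
        d = random_instance(rng, tie_prob=1.0)
        vals = {
            evaluate_with_profile(d, name).auroc for name in PROFILES
        }
        assert len(vals) == 1

    def test_incomplete_coverage_truncates_drawn_curve_not_area(self):
        # MLeval-style defect: the drawn curve starts at the first
        # observed anchor instead of recall 0; the area integral is kept
        d = ScoredLabels([0.9, 0.9, 0.5, 0.5], [1, 0, 1, 0])
        full = build_prc(d, "linear", full_coverage=True)
        cut = build_prc(d, "linear", full_coverage=False)
        assert full.curve_points()[0, 0] == 0.0
        assert cut.curve_points()[0, 0] == pytest.approx(0.5)
        assert cut.auprc == full.auprc

    def test_drop_anchors_changes_drawn_points_not_area(self):
        d = ScoredLabels([0.9, 0.8, 0.7, 0.6], [1, 1, 0, 1])
        plain = build_prc(d, "discrete_expectation")
        dropped = build_prc(d, "discrete_expectation", drop_anchors=True)
        assert dropped.auprc == plain.auprc
        assert len(dropped.curve_points()) < len(plain.curve_points())


class TestSklearnCrossCheck:
    """scikit-learn as an independent oracle, never the implementation."""

    def test_ap_profile_matches_average_precision_score(self, rng):
        from sklearn.metrics import average_precision_score

        for _ in range(20):
            d = random_instance(rng)
            if d.n_neg == 0:
                continue
            ours = evaluate_with_profile(d, "scikit-learn-ap").auprc
            theirs = average_precision_score(d.labels, d.scores)
            assert ours == pytest.approx(theirs, abs=1e-12)

    def test_linear_fixed01_matches_trapezoid_of_sklearn_curve(self, rng):
        from sklearn.metrics import auc, precision_recall_curve

        for _ in range(20):
            d = random_instance(rng)
            if d.n_neg == 0:
                continue
            ours = evaluate_with_profile(d, "scikit-learn-curve").auprc
            prec, rec, _ = precision_recall_curve(d.labels, d.scores)
            theirs = auc(rec, prec)
            assert ours == pytest.approx(theirs, abs=1e-12)
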