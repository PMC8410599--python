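"""Lifetime sparseness, tuning-curve assembly, agonist counting, group tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from odortune import (
    ActivityCriterion,
    TuningProfile,
    build_tuning_curve,
    compare_to_wildtype,
    count_active,
    lifetime_sparseness,
)
from odortune.errors import (
    AlignmentError,
    ComparisonError,
    InvalidParameterError,
    UndefinedSparsenessError,
)


class TestLifetimeSparseness:
    @pytest.mark.parametrize(
        "responses, expected",
        [
            ((1, 1, 1, 1), 0.0),          # perfectly flat tuning
            ((1, 0), 1.0),                # single responder
            ((2, 1, 1, 0), 4 / 9),        # hand-evaluated formula
            ((1, -0.5), 1.0),             # inhibitory response zeroed first
        ],
    )
    def test_closed_forms(self, responses, expected):
        assert lifetime_sparseness(responses) == pytest.approx(expected, abs=1e-12)

    def test_all_zero_after_zeroing_is_undefined(self):
        with pytest.raises(UndefinedSparsenessError):
            lifetime_sparseness([0.0, -1.0, -2.0])

    def test_needs_two_responses(self):
        with pytest.raises(InvalidParameterError):
            lifetime_sparseness([1.0])

    @settings(max_examples=100, derandomize=True)
    @given(
        res=st.lists(st.floats(0, 100), min_size=2, max_size=30).filter(
            lambda r: sum(r) > 1e-6
        ),
        k=st.floats(1e-3, 1e3),
    )
    def test_scale_invariance_and_bounds(self, res, k):
        s = lifetime_sparseness(res)
        assert -1e-9 <= s <= 1 + 1e-9
        assert lifetime_sparseness(np.array(res) * k) == pytest.approx(s, abs=1e-9)

    def test_extremes_characterized(self):
        # S = 0 iff all zeroed responses equal; S = 1 iff exactly one nonzero
        assert lifetime_sparseness([3.3] * 7) == pytest.approx(0.0, abs=1e-12)
        assert lifetime_sparseness([0, 0, 5, 0]) == pytest.approx(1.0, abs=1e-12)
        assert 0 < lifetime_sparseness([2, 1, 0]) < 1

    def test_filling_a_zero_with_the_mean_weakly_decreases_sparseness(self):
        res = np.array([4.0, 2.0, 1.0, 0.0])
        filled = res.copy()
        filled[-1] = res.mean()
        assert lifetime_sparseness(filled) <= lifetime_sparseness(res) + 1e-12


class TestTuningCurve:
    def test_reference_ordering(self):
        wt = TuningProfile("WT", ["A", "B", "C"], [0.2, 0.9, 0.5])
        out = build_tuning_curve([wt], "WT")
        assert list(out["ligand_id"]) == ["B", "C", "A"]

    def test_ties_break_by_ligand_name(self):
        wt = TuningProfile("WT", ["B", "A", "C"], [0.5, 0.5, 0.5])
        out = build_tuning_curve([wt], "WT")
        assert list(out["ligand_id"]) == ["A", "B", "C"]

    def test_mutant_overlay_preserves_reference_order(self):
        wt = TuningProfile("WT", ["A", "B", "C"], [0.2, 0.9, 0.5])
        mut = TuningProfile("M1", ["A", "B", "C"], [1.0, 0.1, 0.2])
        out = build_tuning_curve([wt, mut], "WT")
        assert list(out["ligand_id"]) == ["B", "C", "A"]
        assert list(out["M1"]) == [0.1, 0.2, 1.0]
        # permutation: response multisets preserved
        assert sorted(out["M1"]) == sorted(mut.responses)

    def test_panel_mismatch_reports_difference(self):
        wt = TuningProfile("WT", ["A", "B"], [1, 2])
        mut = TuningProfile("M1", ["A", "C"], [1, 2])
        with pytest.raises(AlignmentError, match="B.*C|C.*B"):
            build_tuning_curve([wt, mut], "WT")


def _fits_frame(rows):
    return pd.DataFrame(rows, columns=["ligand_id", "censored", "activity_index"])


class TestCountActive:
    def test_all_censored_zero_efficacy(self):
        fits = _fits_frame([(f"l{i}", True, 0.0) for i in range(5)])
        assert count_active(fits)["fraction_active"] == 0.0

    def test_36_of_54(self):
        fits = _fits_frame(
            [(f"l{i}", False, 1.0) for i in range(36)]
            + [(f"m{i}", True, 0.0) for i in range(18)]
        )
        rec = count_active(fits)
        assert rec["fraction_active"] == pytest.approx(36 / 54)
        assert rec["fraction_active"] > 0.65

    def test_criterion_is_echoed_and_configurable(self):
        fits = _fits_frame([("a", True, 3.0), ("b", False, 1.0)])
        strict = count_active(fits)
        loose = count_active(fits, ActivityCriterion(require_uncensored=False,
                                                     min_activity_index=0.5))
        assert strict["n_active"] == 1 and loose["n_active"] == 2
        assert "non-censored" in strict["criterion"]
        assert strict["criterion"] != loose["criterion"]


class TestCompareToWildtype:
    def test_identical_groups_non_significant_anova_branch(self):
        base = np.array([-5.1, -5.0, -4.9, -5.0])
        res = compare_to_wildtype(
            {"WT": base, "M1": base.copy(), "M2": base.copy()}, "WT"
        )
        for r in res:
            assert r.test_used == "anova_dunnett"
            assert r.p_value > 0.9
            assert r.significance_label == "NS"

    def test_censored_heteroscedastic_mutant_uses_brown_forsythe(self, rng):
        wt = -5.0 + rng.normal(0, 0.15, 8)
        censored = np.full(8, -2.0)
        censored[0] = -2.0 + 1e-9  # pinned at the placeholder, near-zero variance
        res = compare_to_wildtype({"WT": wt, "Mcens": censored}, "WT")
        (r,) = res
        assert r.test_used == "brown_forsythe"
        assert r.bartlett_p < 0.05

    def test_uncensored_heteroscedastic_group_stays_with_dunnett(self, rng):
        wt = -5.0 + rng.normal(0, 0.1, 8)
        noisy = -5.0 + rng.normal(0, 2.0, 8)  # heteroscedastic but uncensored
        res = compare_to_wildtype({"WT": wt, "M1": noisy}, "WT")
        assert res[0].test_used == "anova_dunnett"

    def test_single_group_is_an_error(self):
        with pytest.raises(ComparisonError):
            compare_to_wildtype({"WT": np.array([-5.0, -5.1])}, "WT")

    def test_small_replicate_groups_rejected(self):
        with pytest.raises(ComparisonError):
            compare_to_wildtype(
                {"WT": np.array([-5.0, -5.1]), "M": np.array([-4.0])}, "WT"
            )

    def test_null_type_one_error_is_controlled(self):
        """Dunnett-adjusted family-wise false-positive rate <= 0.06 at
        nominal 0.05 when every group is drawn from the same distribution."""
        rng = np.random.default_rng(7)
        false_positives = 0
        n_sim = 400
        for _ in range(n_sim):
            groups = {
                name: rng.normal(-5.0, 0.3, 6) for name in ("WT", "M1", "M2", "M3")
            }
            res = compare_to_wildtype(groups, "WT")
            if any(r.p_value < 0.05 for r in res):
                false_positives += 1
        assert false_positives / n_sim <= 0.06
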