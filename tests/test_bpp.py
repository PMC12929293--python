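"""Posterior model probabilities, prior schemes, and sensitivity analysis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sembpp as s
from sembpp.bpp import bpp_at_target_prior

finite_bics = st.lists(
    st.floats(min_value=-1e4, max_value=1e4, allow_nan=False), min_size=2, max_size=8
)


class TestComputeBPP:
    def test_golden_unbiased(self, table1_bics):
        post = s.compute_bpp(table1_bics).bpp
        assert {k: round(v, 3) for k, v in post.items()} == {
            "A": 0.611, "B": 0.337, "C": 0.046, "D": 0.007,
        }

    def test_golden_informed_priors(self, table1_bics):
        priors = {"A": 0.20, "B": 0.40, "C": 0.20, "D": 0.20}
        post = s.compute_bpp(table1_bics, priors).bpp
        assert {k: round(v, 3) for k, v in post.items()} == {
            "A": 0.457, "B": 0.504, "C": 0.034, "D": 0.005,
        }

    def test_equal_bics_uniform_posterior(self):
        post = s.compute_bpp({f"M{i}": 10.0 for i in range(5)}).bpp
        assert all(v == pytest.approx(0.2) for v in post.values())

    def test_priors_must_sum_to_one(self, table1_bics):
        with pytest.raises(ValueError, match="sum"):
            s.compute_bpp(table1_bics, {"A": 0.5, "B": 0.5, "C": 0.5, "D": 0.5})

    def test_negative_prior_rejected(self, table1_bics):
        with pytest.raises(ValueError):
            s.compute_bpp(table1_bics, {"A": -0.1, "B": 0.6, "C": 0.3, "D": 0.2})

    def test_priors_must_cover_models(self, table1_bics):
        with pytest.raises(ValueError):
            s.compute_bpp(table1_bics, {"A": 0.5, "B": 0.5})

    def test_overflow_safe_for_huge_bic_gaps(self):
        post = s.compute_bpp({"a": 0.0, "b": 3000.0}).bpp
        assert post["a"] == pytest.approx(1.0)
        assert post["b"] >= 0.0

    @given(finite_bics)
    @settings(max_examples=50, deadline=None)
    def test_normalization_property(self, bics):
        names = [f"M{i}" for i in range(len(bics))]
        post = s.compute_bpp(dict(zip(names, bics))).bpp
        assert abs(sum(post.values()) - 1.0) < 1e-12
        assert all(0.0 <= v <= 1.0 for v in post.values())

    @given(finite_bics)
    @settings(max_examples=50, deadline=None)
    def test_reference_model_invariance(self, bics):
        names = [f"M{i}" for i in range(len(bics))]
        table = dict(zip(names, bics))
        base = s.compute_bpp(table, reference_model=names[0]).bpp
        for ref in names[1:]:
            other = s.compute_bpp(table, reference_model=ref).bpp
            for nm in names:
                assert other[nm] == pytest.approx(base[nm], abs=1e-12)

    @given(finite_bics, st.floats(min_value=-500, max_value=500, allow_nan=False))
    @settings(max_examples=50, deadline=None)
    def test_bic_shift_invariance(self, bics, shift):
        names = [f"M{i}" for i in range(len(bics))]
        base = s.compute_bpp(dict(zip(names, bics))).bpp
        shifted = s.compute_bpp({nm: b + shift for nm, b in zip(names, bics)}).bpp
        for nm in names:
            assert shifted[nm] == pytest.approx(base[nm], abs=1e-10)

    @given(finite_bics)
    @settings(max_examples=50, deadline=None)
    def test_rank_agreement_under_unbiased_priors(self, bics):
        names = [f"M{i}" for i in range(len(bics))]
        table = dict(zip(names, bics))
        post = s.compute_bpp(table).bpp
        by_bpp = sorted(names, key=lambda nm: (-post[nm], table[nm]))
        by_bic = sorted(names, key=lambda nm: table[nm])
        assert [table[nm] for nm in by_bpp] == [table[nm] for nm in by_bic]

    def test_zero_prior_equals_exclusion(self, table1_bics):
        # excluding D == giving D prior 0 and spreading its mass
        kept = {k: v for k, v in table1_bics.items() if k != "D"}
        excluded = s.compute_bpp(kept).bpp
        zeroed = s.compute_bpp(table1_bics, {"A": 1/3, "B": 1/3, "C": 1/3, "D": 0.0}).bpp
        for nm in kept:
            assert zeroed[nm] == pytest.approx(excluded[nm], abs=1e-12)
        assert zeroed["D"] == 0.0


class TestPriorSchemes:
    def test_single_target_thirteen_models(self):
        assert round(s.prior_single_target(13).p1, 3) == 0.094

    def test_single_target_degenerate(self):
        assert s.prior_single_target(1).p1 == pytest.approx(1.0)

    @pytest.mark.parametrize("m", [2, 5, 13, 40])
    def test_ratio_and_sum(self, m):
        scheme = s.prior_single_target(m)
        assert scheme.p1 == pytest.approx(1.25 * scheme.p2)
        assert scheme.p1 + (m - 1) * scheme.p2 == pytest.approx(1.0)

    def test_multiple_targets_fifteen_four(self):
        assert round(s.prior_multiple_targets(15, 4).p1, 3) == 0.078

    def test_all_favored_reduces_to_uniform(self):
        scheme = s.prior_multiple_targets(7, 7)
        assert scheme.p1 == pytest.approx(1 / 7)

    def test_single_target_consistency(self):
        assert s.prior_multiple_targets(13, 1).p1 == pytest.approx(
            s.prior_single_target(13).p1
        )

    @pytest.mark.parametrize("k, k1", [(10, 3), (15, 4), (6, 6)])
    def test_materialized_sums_to_one(self, k, k1):
        scheme = s.prior_multiple_targets(k, k1)
        names = [f"M{i}" for i in range(k)]
        bound = scheme.materialize(names, favored=names[:k1])
        assert sum(bound.priors.values()) == pytest.approx(1.0)

    def test_complete_partial_priors(self):
        spec = s.complete_priors({"a": 0.4}, ["a", "b", "c"])
        assert spec.priors == pytest.approx({"a": 0.4, "b": 0.3, "c": 0.3})


class TestMinPrior:
    def test_golden_target(self, table1_bics):
        sens = s.min_prior_for_target(table1_bics, "A", 0.80)
        assert sens.min_prior == pytest.approx(0.459, abs=5e-4)
        assert sens.achievable

    def test_self_consistency_with_unbiased_posterior(self, table1_bics):
        post = s.compute_bpp(table1_bics).bpp
        sens = s.min_prior_for_target(table1_bics, "B", post["B"])
        assert sens.min_prior == pytest.approx(0.25, abs=1e-9)

    def test_equal_bics_prior_equals_target(self):
        sens = s.min_prior_for_target({"a": 10.0, "b": 10.0}, "a", 0.75)
        assert sens.min_prior == pytest.approx(0.75)

    def test_closed_form_matches_bisection(self, table1_bics):
        for target in table1_bics:
            for b in (0.1, 0.5, 0.9):
                sens = s.min_prior_for_target(table1_bics, target, b)
                lo, hi = 0.0, 1.0
                for _ in range(80):
                    mid = 0.5 * (lo + hi)
                    if bpp_at_target_prior(table1_bics, target, mid) < b:
                        lo = mid
                    else:
                        hi = mid
                assert sens.min_prior == pytest.approx(0.5 * (lo + hi), abs=1e-9)

    def test_plugging_back_recovers_target(self, table1_bics):
        sens = s.min_prior_for_target(table1_bics, "C", 0.6)
        assert bpp_at_target_prior(table1_bics, "C", sens.min_prior) == pytest.approx(
            0.6, abs=1e-9
        )

    def test_posterior_strictly_increasing_in_prior(self, table1_bics):
        values = [bpp_at_target_prior(table1_bics, "D", pi)
                  for pi in np.linspace(0.01, 0.99, 25)]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_invalid_targets(self, table1_bics):
        with pytest.raises(ValueError):
            s.min_prior_for_target(table1_bics, "Z", 0.5)
        with pytest.raises(ValueError):
            s.min_prior_for_target(table1_bics, "A", 1.0)
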