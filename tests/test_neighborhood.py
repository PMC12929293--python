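"""Neighboring-model enumeration, fitting, naming, equivalence collapsing
and model-set combination."""

import numpy as np
import pytest

import sembpp as s
from sembpp import fixtures as fx
from sembpp.model_syntax import COVARIANCE, REGRESSION, MEASUREMENT, ParameterEntry
from sembpp.neighborhood import ModelModification, combine_model_sets

from .oracle_sem import brute_force_additions, brute_force_drops


def _keys(mods):
    return {m.parameter.key for m in mods}


class TestEnumerateAdditions:
    def test_fork_has_three_additions(self, fork_spec):
        adds = s.enumerate_additions(fork_spec)
        assert _keys(adds) == {
            ("y", REGRESSION, "m"), ("m", REGRESSION, "y"), ("y", COVARIANCE, "m"),
        }

    def test_chain_has_single_addition(self, chain_spec):
        adds = s.enumerate_additions(chain_spec)
        assert _keys(adds) == {("y", REGRESSION, "x")}

    def test_saturated_spec_has_none(self):
        spec = s.parse_model("y ~ x1 + x2\nx1 ~~ x2")
        assert s.enumerate_additions(spec) == []

    def test_xy_cov_reinclusion(self, chain_spec):
        options = s.NeighborhoodOptions(exclude_xy_cov=False)
        adds = _keys(s.enumerate_additions(chain_spec, options))
        # the precedence-excluded covariances come back
        assert ("m", COVARIANCE, "y") in adds
        assert ("m", COVARIANCE, "x") in adds or ("x", COVARIANCE, "m") in adds

    def test_cfa_cross_loadings_and_error_covs(self):
        spec = s.parse_model("f1 =~ a + b + c\nf2 =~ d + e + g")
        adds = _keys(s.enumerate_additions(spec))
        # 6 cross-loadings, no error covariances by default, and the
        # factor covariance already exists
        assert adds == {
            ("f1", MEASUREMENT, "d"), ("f1", MEASUREMENT, "e"), ("f1", MEASUREMENT, "g"),
            ("f2", MEASUREMENT, "a"), ("f2", MEASUREMENT, "b"), ("f2", MEASUREMENT, "c"),
        }
        options = s.NeighborhoodOptions(exclude_error_cov=False)
        with_err = _keys(s.enumerate_additions(spec, options))
        assert len(with_err) == 6 + 15  # all indicator pairs

    @pytest.mark.parametrize("syntax", [
        "y ~ x\nm ~ x",
        "m ~ x\ny ~ m",
        "m11 ~ x\nm12 ~ m11\nm2 ~ x\ny ~ m12 + m2",
        "y ~ x1 + x2",
        "f1 =~ a + b + c\nf2 =~ d + e + g",
        "a ~~ a\nb ~~ b\nc ~~ c\na ~~ 0*b\na ~~ 0*c\nb ~~ 0*c",
    ])
    def test_matches_brute_force(self, syntax):
        spec = s.parse_model(syntax)
        assert _keys(s.enumerate_additions(spec)) == brute_force_additions(spec)
        assert _keys(s.enumerate_drops(spec)) == brute_force_drops(spec)


class TestEnumerateDrops:
    def test_chain_drops(self, chain_spec):
        assert _keys(s.enumerate_drops(chain_spec)) == {
            ("m", REGRESSION, "x"), ("y", REGRESSION, "m"),
        }

    def test_independence_spec_no_drops(self):
        spec = s.parse_model("a ~~ a\nb ~~ b\na ~~ 0*b")
        assert s.enumerate_drops(spec) == []

    def test_one_factor_marker_protected(self):
        spec = s.parse_model("f =~ a + b + c")
        assert _keys(s.enumerate_drops(spec)) == {
            ("f", MEASUREMENT, "b"), ("f", MEASUREMENT, "c"),
        }


class TestNaming:
    def test_paper_style_labels(self):
        add = ModelModification("add", ParameterEntry("m12", REGRESSION, "x"), +1)
        drop = ModelModification("drop", ParameterEntry("y", REGRESSION, "m2"), -1)
        assert s.name_modification([add]) == "add: m12 x"
        assert s.name_modification([drop]) == "drop: y m2"
        assert s.name_modification([]) == "original"

    def test_multiple_changes_joined_deterministically(self):
        a = ModelModification("add", ParameterEntry("y", REGRESSION, "x"), +1)
        b = ModelModification("drop", ParameterEntry("m", REGRESSION, "x"), -1)
        assert s.name_modification([a, b]) == s.name_modification([b, a])
        assert "; " in s.name_modification([a, b])


class TestGenerateModelSet:
    def test_fork_radius_one(self, fork_spec, fork_sample_cov):
        cov, n = fork_sample_cov
        ms = s.generate_model_set(fork_spec, cov, n)
        assert len(ms.candidates) == 4  # original + 1 equivalent rep + 2 drops
        assert "original" in ms.names
        (rep, dups), = ms.merged.items()
        assert len(dups) == 2  # 3 equivalent saturated additions collapsed
        bpps = ms.bpp_result.bpp
        assert sum(bpps.values()) == pytest.approx(1.0)

    def test_radius_zero_add(self, chain_spec, chain_sigma):
        options = s.NeighborhoodOptions(df_change_add=0, df_change_drop=1)
        ms = s.generate_model_set(chain_spec, chain_sigma, 200, options)
        assert all(c.df_diff <= 0 for c in ms.candidates)
        assert all(m.kind == "drop" for c in ms.candidates for m in c.modifications)

    def test_radius_two_includes_paired_additions(self, serial_parallel):
        config = fx.analog("serial_parallel", seed=11, noise="sampled")
        cov = fx.sample_covariance(fx.sample_data(config))
        options = s.NeighborhoodOptions(df_change_add=2, df_change_drop=0)
        ms = s.generate_model_set(serial_parallel.spec, cov, config.n, options)
        two_adds = [c for c in ms.candidates if c.df_diff == 2]
        assert two_adds, "paired additions expected at radius 2"
        names = " | ".join(c.name for c in two_adds)
        assert "add: m12 x; add: y x" in names

    def test_nesting_monotonicity(self, fork_spec, fork_sample_cov):
        cov, n = fork_sample_cov
        ms = s.generate_model_set(fork_spec, cov, n)
        orig = ms.original.fit.chisq
        for cand in ms.candidates:
            if cand.df_diff == 1:
                assert cand.fit.chisq <= orig + 1e-6
            elif cand.df_diff == -1:
                assert cand.fit.chisq >= orig - 1e-6

    def test_cap_enforced(self, serial_parallel):
        sigma = fx.exact_covariance(serial_parallel)
        options = s.NeighborhoodOptions(df_change_add=2, df_change_drop=2, max_models=5)
        with pytest.raises(RuntimeError, match="cap"):
            s.generate_model_set(serial_parallel.spec, sigma, 200, options)

    def test_set_invariant_to_variable_ordering(self, fork_sample_cov):
        cov, n = fork_sample_cov
        spec_a = s.parse_model("y ~ x\nm ~ x")  # order y, x, m
        spec_b = s.parse_model("m ~ x\ny ~ x")  # order m, x, y
        perm = [spec_a.observed.index(v) for v in spec_b.observed]
        ms_a = s.generate_model_set(spec_a, cov, n)
        ms_b = s.generate_model_set(spec_b, cov[np.ix_(perm, perm)], n)
        assert len(ms_a.candidates) == len(ms_b.candidates)
        # the same chisq multiset up to optimizer tolerance
        ca = sorted(c.fit.chisq for c in ms_a.candidates)
        cb = sorted(c.fit.chisq for c in ms_b.candidates)
        assert ca == pytest.approx(cb, abs=1e-5)


class TestDetectEquivalent:
    def test_saturated_cluster_merged(self, fork_spec, fork_sample_cov):
        cov, n = fork_sample_cov
        ms = s.generate_model_set(fork_spec, cov, n)
        rep = next(iter(ms.merged))
        assert ms[rep].fit.df == 0

    def test_different_df_never_merged(self, fork_spec, fork_sample_cov):
        cov, n = fork_sample_cov
        ms = s.generate_model_set(fork_spec, cov, n)
        classes = {}
        for cand in ms.candidates:
            classes.setdefault(cand.equivalence_class, []).append(cand)
        for cls in classes.values():
            assert len({c.fit.df for c in cls}) == 1

    def test_collapsing_preserves_bpp(self, fork_spec, fork_sample_cov):
        """Merged duplicates have identical BICs, so the retained model's
        BPP equals what any duplicate would have received."""
        cov, n = fork_sample_cov
        ms = s.generate_model_set(fork_spec, cov, n)
        rep = next(iter(ms.merged))
        bics = ms.bics()
        direct = s.compute_bpp(bics).bpp
        assert ms.bpp_result.bpp[rep] == pytest.approx(direct[rep])


class TestCombine:
    def test_idempotent(self, fork_spec, fork_sample_cov):
        cov, n = fork_sample_cov
        ms = s.generate_model_set(fork_spec, cov, n)
        combined = combine_model_sets([ms])
        a = ms.bpp_result.bpp
        b = combined.bpp_result.bpp
        for nm, v in a.items():
            assert b[nm] == pytest.approx(v)

    def test_union_posterior_matches_direct_computation(self, fork_sample_cov):
        cov, n = fork_sample_cov
        spec_a = s.parse_model("y ~ x\nm ~ x")
        spec_b = s.parse_model("y ~ x\nm ~ x\ny ~ m")
        opts = s.NeighborhoodOptions(df_change_add=0, df_change_drop=1)
        ms_a = s.generate_model_set(spec_a, cov, n, opts)
        ms_b = s.generate_model_set(spec_b, cov, n, opts)
        combined = combine_model_sets([ms_a, ms_b])
        # every retained model's BPP equals compute_bpp on the union BICs
        direct = s.compute_bpp(combined.bics()).bpp
        for nm, v in combined.bpp_result.bpp.items():
            if not combined[nm].flagged:
                assert v == pytest.approx(direct[nm])

    def test_overlapping_models_are_merged(self, fork_sample_cov):
        cov, n = fork_sample_cov
        spec_a = s.parse_model("y ~ x\nm ~ x")
        # spec_b is spec_a with y~m added: it is a neighbor of spec_a
        spec_b = s.parse_model("y ~ x + m\nm ~ x")
        ms_a = s.generate_model_set(spec_a, cov, n)
        ms_b = s.generate_model_set(spec_b, cov, n)
        combined = combine_model_sets([ms_a, ms_b])
        total = len(ms_a.candidates) + len(ms_b.candidates)
        assert len(combined.candidates) < total
        assert combined.merged  # at least one equivalence across sets

    def test_mismatched_data_rejected(self, fork_spec, fork_sample_cov):
        cov, n = fork_sample_cov
        ms_a = s.generate_model_set(fork_spec, cov, n)
        ms_b = s.generate_model_set(fork_spec, cov * 1.5, n)
        with pytest.raises(ValueError, match="identical data"):
            combine_model_sets([ms_a, ms_b])


class TestResultsTable:
    def test_columns_and_sorting(self, fork_spec, fork_sample_cov):
        cov, n = fork_sample_cov
        frame = s.generate_model_set(fork_spec, cov, n).table()
        assert list(frame.columns) == [
            "model", "sep", "df_diff", "df", "chisq", "p", "Prior", "BIC",
            "BPP", "CFI", "RMSEA", "SRMR",
        ]
        assert list(frame["BPP"]) == sorted(frame["BPP"], reverse=True)
        assert frame["BPP"].sum() == pytest.approx(1.0)

    def test_csv_round_trip(self, tmp_path, fork_spec, fork_sample_cov):
        import pandas as pd

        cov, n = fork_sample_cov
        ms = s.generate_model_set(fork_spec, cov, n)
        path = tmp_path / "out.csv"
        ms.to_csv(path)
        frame = pd.read_csv(path)
        assert len(frame) == len(ms.candidates)
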