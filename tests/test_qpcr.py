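"""Matched-pair delta-delta-Ct analysis: examples, properties, brute-force oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mirchemo import qpcr
from mirchemo.qpcr import DifferentialMirnaAnalysis

from conftest import make_ct_long


class TestNormalizeSample:
    def test_mean_centering(self):
        dct = qpcr.normalize_sample(pd.Series([24.0, 26.0], index=["a", "b"]))
        assert dct.tolist() == [-1.0, 1.0]

    def test_undetected_excluded_from_mean(self):
        dct = qpcr.normalize_sample(pd.Series([20.0, 30.0, np.nan], index=list("abc")))
        assert dct["a"] == -5.0 and dct["b"] == 5.0 and np.isnan(dct["c"])

    def test_ct_at_detection_limit_is_undetected(self):
        dct = qpcr.normalize_sample(pd.Series([20.0, 30.0, 40.0], index=list("abc")))
        assert np.isnan(dct["c"]) and dct["a"] == -5.0

    def test_all_undetected_raises_with_sample_name(self):
        with pytest.raises(ValueError, match="s1"):
            qpcr.normalize_sample(pd.Series([np.nan, 41.0]), sample_name="s1")

    @given(shift=st.floats(-5, 5), cts=st.lists(st.floats(18, 35), min_size=2, max_size=8))
    def test_shift_invariance(self, shift, cts):
        base = pd.Series(cts)
        np.testing.assert_allclose(
            qpcr.normalize_sample(base + shift).values,
            qpcr.normalize_sample(base).values,
            atol=1e-9,
        )


class TestSignedFold:
    @pytest.mark.parametrize(
        "ratio,expected", [(0.5, -2.0), (1.0, 1.0), (3.46, 3.46), (0.25, -4.0)]
    )
    def test_examples(self, ratio, expected):
        assert qpcr.signed_fold(ratio) == pytest.approx(expected)

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError):
            qpcr.signed_fold(0.0)

    @given(r=st.floats(0.01, 100).filter(lambda r: abs(r - 1) > 1e-6))
    def test_reciprocal_antisymmetry_and_magnitude(self, r):
        f, finv = qpcr.signed_fold(r), qpcr.signed_fold(1 / r)
        assert abs(f) >= 1 and np.sign(f) == -np.sign(finv)
        assert qpcr.ratio_from_signed(f) == pytest.approx(r, rel=1e-9)


class TestPairFold:
    def test_known_folds(self, toy_ct_pair):
        folds = qpcr.fold_table(toy_ct_pair)
        by_id = folds.set_index("mirna_id")
        # ddCt = -1 -> ratio 2, +1 -> ratio 0.5 -> signed -2
        assert by_id.loc["miR-a", "signed_fold"] == pytest.approx(2.0)
        assert by_id.loc["miR-b", "signed_fold"] == pytest.approx(-2.0)
        assert not by_id["is_estimate"].any()

    def test_identity_when_unchanged(self):
        ct = make_ct_long(
            {"c": {"pre": {"a": 24, "b": 26}, "post": {"a": 25, "b": 27}}}
        )  # both shifted by +1: normalization absorbs it
        folds = qpcr.fold_table(ct)
        np.testing.assert_allclose(folds["signed_fold"], [1.0, 1.0])

    def test_single_undetected_imputed_and_flagged(self):
        ct = make_ct_long(
            {"c": {"pre": {"a": 24, "b": 26, "r": 30},
                   "post": {"a": 24, "b": None, "r": 30}}}
        )
        folds = qpcr.fold_table(ct).set_index("mirna_id")
        assert folds.loc["b", "is_estimate"]
        assert folds.loc["b", "signed_fold"] < -1  # bounded loss of expression
        assert not folds.loc["a", "is_estimate"]

    def test_double_undetected_marked_missing(self):
        ct = make_ct_long(
            {"c": {"pre": {"a": 24, "b": None, "r": 30},
                   "post": {"a": 24, "b": None, "r": 30}}}
        )
        folds = qpcr.fold_table(ct).set_index("mirna_id")
        assert folds.loc["b", "missing"] and np.isnan(folds.loc["b", "signed_fold"])

    def test_antisymmetry_pre_post_swap(self):
        rng = np.random.default_rng(7)
        cts = {m: rng.uniform(22, 34) for m in "abcdef"}
        cts_post = {m: rng.uniform(22, 34) for m in "abcdef"}
        fwd = qpcr.fold_table(make_ct_long({"c": {"pre": cts, "post": cts_post}}))
        rev = qpcr.fold_table(make_ct_long({"c": {"pre": cts_post, "post": cts}}))
        np.testing.assert_allclose(
            fwd.set_index("mirna_id")["ratio"],
            1.0 / rev.set_index("mirna_id")["ratio"],
            rtol=1e-9,
        )

    def test_brute_force_oracle_three_mirnas(self):
        """Folds match a from-first-principles recomputation on toy matrices."""
        rng = np.random.default_rng(11)
        for _ in range(5):
            pre = dict(zip("abc", rng.uniform(20, 34, 3)))
            post = dict(zip("abc", rng.uniform(20, 34, 3)))
            folds = qpcr.fold_table(make_ct_long({"c": {"pre": pre, "post": post}}))
            mpre = np.mean(list(pre.values()))
            mpost = np.mean(list(post.values()))
            for m in "abc":
                ddct = (post[m] - mpost) - (pre[m] - mpre)
                expected = 2.0 ** (-ddct)
                got = folds.set_index("mirna_id").loc[m, "ratio"]
                assert got == pytest.approx(expected, rel=1e-12)


class TestMeanSignedFold:
    def test_up_row(self):
        assert qpcr.mean_signed_fold([3.46, 1.84, 1.70, 1.33, 4.50]) == pytest.approx(2.57, abs=0.005)

    def test_down_row_ratio_scale(self):
        assert qpcr.mean_signed_fold([-2.33, -1.42, -14.4, -1.27, -1.36]) == pytest.approx(
            -1.83, abs=0.005
        )

    def test_estimates_excluded(self):
        val = qpcr.mean_signed_fold(
            [1.70, 1.32, 1.11, 1.82, 30.0], [False, False, False, False, True]
        )
        assert val == pytest.approx(1.49, abs=0.005)

    def test_all_estimates_rejected(self):
        with pytest.raises(ValueError):
            qpcr.mean_signed_fold([2.0, 3.0], [True, True])


class TestFilters:
    def _tidy(self, folds_by_mirna):
        rows = []
        for m, folds in folds_by_mirna.items():
            for i, f in enumerate(folds):
                rows.append(
                    {"mirna_id": m, "case_id": f"case{i+1}", "signed_fold": f,
                     "is_estimate": False, "missing": f is None}
                )
        return pd.DataFrame(rows)

    def test_consistency(self):
        t = self._tidy({"up": [2, 3, 1.1, 5, 1.5], "flip": [2, 3, -1.1, 5, 1.5]})
        assert qpcr.consistency_filter(t) == {"up"}

    def test_magnitude_worked_example(self, nac_folds):
        assert qpcr.magnitude_filter(nac_folds, 1.3) == {"miR-195", "miR-26b"}
        assert qpcr.magnitude_filter(nac_folds, 1.0) == set(nac_folds["mirna_id"])

    def test_min_fold_below_one_rejected(self, nac_folds):
        with pytest.raises(ValueError):
            qpcr.magnitude_filter(nac_folds, 0.9)

    @given(lo=st.floats(1.0, 3.0), hi=st.floats(1.0, 3.0))
    def test_monotone_in_min_fold(self, lo, hi):
        from mirchemo.datasets import load_nac_fold_table

        folds = load_nac_fold_table()
        lo, hi = sorted([lo, hi])
        assert qpcr.magnitude_filter(folds, hi) <= qpcr.magnitude_filter(folds, lo)

    def test_magnitude_subset_of_consistency(self, nac_folds):
        assert qpcr.magnitude_filter(nac_folds, 1.3) <= qpcr.consistency_filter(nac_folds)


class TestSummarize:
    def test_published_matrix_tallies(self, nac_folds):
        s = qpcr.summarize_signed_folds(nac_folds)
        assert len(s) == 12
        assert (s["direction"] == "up").sum() == 10
        assert (s["direction"] == "down").sum() == 2
        assert s["passes_filter"].sum() == 2

    def test_deterministic_ordering(self, nac_folds):
        s = qpcr.summarize_signed_folds(nac_folds)
        assert s["mean_fold"].abs().is_monotonic_decreasing
        assert s.loc[0, "mirna_id"] == "miR-483-5p"

    def test_planted_zero_noise_recovery(self):
        from mirchemo.simulate import SimulationConfig, gen_ct_arrays

        cfg = SimulationConfig(
            seed=5, n_mirnas=40, ct_noise_sd=0.0,
            planted_mirnas={"up": 1.5, "mid": 2.0, "big": 3.0},
        )
        est = DifferentialMirnaAnalysis().fit(gen_ct_arrays(cfg))
        assert est.selected_mirnas_ == {"up", "mid", "big"}

    def test_null_consistency_rate_matches_binomial(self):
        """With pure noise the expected survivor count is panel x 2 x 0.5^5."""
        from mirchemo.simulate import SimulationConfig, gen_ct_arrays

        cfg = SimulationConfig(seed=17, planted_mirnas={}, ct_noise_sd=0.15)
        est = DifferentialMirnaAnalysis().fit(gen_ct_arrays(cfg))
        expected = 377 * 2 * 0.5**5  # ~23.6, binomial SD ~4.7
        assert abs(len(est.consistent_mirnas_) - expected) < 3 * 4.7

    def test_sklearn_param_interface(self):
        est = DifferentialMirnaAnalysis(min_fold=1.5)
        assert est.get_params()["min_fold"] == 1.5
        est.set_params(min_fold=2.0)
        assert est.min_fold == 2.0


class TestSingleReferenceNormalizer:
    def test_reference_gene_centering(self):
        dct = qpcr.normalize_to_reference(
            pd.Series({"miR-195": 25.0, "RNU48": 22.0}), "RNU48"
        )
        assert dct["miR-195"] == 3.0 and dct["RNU48"] == 0.0

    def test_undetected_reference_rejected(self):
        with pytest.raises(ValueError, match="RNU48"):
            qpcr.normalize_to_reference(pd.Series({"a": 25.0, "RNU48": 40.0}), "RNU48")
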