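"""Band intensities, ratio statistics, ROC scan and the rank-sum test."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import mannwhitneyu, rankdata

import ramandx as rx
from ramandx.band_metrics import (
    _exact_two_sided_p,
    band_intensity,
    difference_spectrum,
    group_ratio_stats,
    intensity_ratio,
    mean_spectrum,
    rank_sum_test,
    roc_curve,
)
from ramandx.simulate import pseudo_voigt

from conftest import make_band_spectrum


class TestBandIntensity:
    def test_toy_window_max(self):
        axis = rx.WavenumberAxis(600, 1.0, 5)
        s = rx.Spectrum(axis=axis, intensities=[0.0, 0.1, 0.4, 0.3, 0.0], id="t")
        assert band_intensity(s, 602.0, 1.0) == pytest.approx(0.4)

    def test_single_gaussian_height(self, axis):
        s = make_band_spectrum(axis, [(1447.0, 5.0, 16.0, 1.0)])
        assert band_intensity(s, 1447.0, 8.0) == pytest.approx(5.0)

    def test_overlapping_bands_match_dense_grid_oracle(self, axis):
        """Window max on the 1 cm-1 grid ~ max on a 10x finer analytic grid."""
        bands = [(1447.0, 1.0, 16.0, 0.5), (1460.0, 0.9, 16.0, 0.5)]
        s = make_band_spectrum(axis, bands)
        fine = np.arange(1439.0, 1455.01, 0.1)
        dense = sum(h * pseudo_voigt(fine - c, w, e) for c, h, w, e in bands)
        coarse = band_intensity(s, 1447.0, 8.0)
        # interpolation bound: |f''| * step^2 / 8
        f2 = np.max(np.abs(np.diff(dense, 2))) / 0.1**2
        assert abs(coarse - dense.max()) <= f2 / 8 + 1e-12

    def test_window_outside_axis_rejected(self, axis):
        s = make_band_spectrum(axis, [(700.0, 1.0, 16.0, 0.5)])
        with pytest.raises(ValueError):
            band_intensity(s, 1795.0, 8.0)


class TestIntensityRatio:
    def test_known_heights(self, axis):
        s = make_band_spectrum(axis, [(785.0, 2.0, 16.0, 1.0), (1447.0, 3.2, 16.0, 1.0)])
        assert intensity_ratio(s) == pytest.approx(1.6, rel=1e-6)

    def test_scale_invariance(self, axis):
        s = make_band_spectrum(axis, [(785.0, 2.0, 16.0, 0.5), (1447.0, 3.2, 16.0, 0.5)])
        scaled = s.with_intensities(s.intensities * 17.3)
        assert intensity_ratio(scaled) == pytest.approx(intensity_ratio(s), rel=1e-12)

    def test_non_positive_denominator_rejected(self, axis):
        s = make_band_spectrum(axis, [(1447.0, 3.0, 16.0, 1.0)])
        bad = s.with_intensities(s.intensities - 1.0)
        with pytest.raises(ValueError):
            intensity_ratio(bad)


class TestGroupStats:
    def _set_with_ratios(self, ratios, label="REH"):
        axis = rx.WavenumberAxis()
        spectra = [
            make_band_spectrum(
                axis, [(785.0, 1.0, 16.0, 1.0), (1447.0, r, 16.0, 1.0)],
                sid=f"{label}{i}", label=label,
            )
            for i, r in enumerate(ratios)
        ]
        return rx.SpectrumSet(axis=axis, spectra=spectra)

    def test_hand_arithmetic(self):
        stats = group_ratio_stats(self._set_with_ratios([1.0, 2.0, 3.0]))
        assert stats.means[0] == pytest.approx(2.0, rel=1e-6)
        assert stats.sds[0] == pytest.approx(1.0, rel=1e-4)
        assert stats.ns[0] == 3

    def test_identical_spectra_have_zero_sd(self):
        stats = group_ratio_stats(self._set_with_ratios([2.0, 2.0]))
        assert stats.sds[0] == pytest.approx(0.0, abs=1e-12)

    def test_singleton_cohort_rejected_by_name(self):
        sset = self._set_with_ratios([2.0], label="Pt-1")
        with pytest.raises(ValueError, match="Pt-1"):
            group_ratio_stats(sset)


class TestMeanAndDifference:
    def test_mean_of_identical_is_itself(self, axis):
        s = make_band_spectrum(axis, [(785.0, 1.0, 16.0, 0.5)], label="B_normal")
        sset = rx.SpectrumSet(axis=axis, spectra=[
            rx.Spectrum(axis=axis, intensities=s.intensities, id=f"s{i}", label="B_normal")
            for i in range(3)
        ])
        np.testing.assert_allclose(
            mean_spectrum(sset, "B_normal").intensities, s.intensities
        )

    def test_two_point_mean(self):
        axis = rx.WavenumberAxis(600, 1.0, 2)
        sset = rx.SpectrumSet(axis=axis, spectra=[
            rx.Spectrum(axis=axis, intensities=[0, 2], id="a", label="x"),
            rx.Spectrum(axis=axis, intensities=[2, 0], id="b", label="x"),
        ])
        np.testing.assert_array_equal(mean_spectrum(sset, "x").intensities, [1, 1])
        with pytest.raises(ValueError):
            mean_spectrum(sset, "unknown")

    def test_difference_antisymmetry(self, axis):
        a = make_band_spectrum(axis, [(785.0, 1.0, 16.0, 0.5)], sid="a")
        b = make_band_spectrum(axis, [(1447.0, 1.0, 16.0, 0.5)], sid="b")
        d1 = difference_spectrum(a, b).intensities
        d2 = difference_spectrum(b, a).intensities
        np.testing.assert_allclose(d1, -d2)
        np.testing.assert_allclose(difference_spectrum(a, a).intensities, 0.0)


class TestRoc:
    def test_perfect_separation(self):
        r = roc_curve([2.5, 3.0, 3.5], [1.0, 1.5, 2.0])
        assert r.sensitivity == 1.0 and r.specificity == 1.0
        assert 2.0 < r.threshold < 2.5

    def test_interleaved_groups_by_enumeration(self):
        """positives {1,3}, negatives {2,4}: the scan agrees with exhaustive
        enumeration of all five candidate thresholds (max J = 0 here, attained
        first at the -inf threshold under the lowest-threshold tie rule)."""
        pos, neg = np.array([1.0, 3.0]), np.array([2.0, 4.0])
        r = roc_curve(pos, neg)
        # independent exhaustive scan
        best_j, best_t = -np.inf, None
        for t in [-np.inf, 1.5, 2.5, 3.5, np.inf]:
            j = (pos > t).mean() + (neg <= t).mean() - 1.0
            if j > best_j:
                best_j, best_t = j, t
        assert r.youden_j == pytest.approx(best_j) == pytest.approx(0.0)
        assert r.threshold == best_t == -np.inf
        assert r.sensitivity == 1.0 and r.specificity == 0.0

    def test_identical_groups_carry_no_information(self):
        r = roc_curve([2.0, 2.0], [2.0, 2.0])
        np.testing.assert_allclose(r.sensitivities + r.specificities, 1.0)

    @given(st.data())
    def test_monotonicity_invariant(self, data):
        pos = data.draw(st.lists(st.floats(-5, 5), min_size=1, max_size=12))
        neg = data.draw(st.lists(st.floats(-5, 5), min_size=1, max_size=12))
        r = roc_curve(pos, neg)
        assert np.all(np.diff(r.sensitivities) <= 1e-12)
        assert np.all(np.diff(r.specificities) >= -1e-12)

    def test_youden_beats_chance_for_separated_groups(self):
        rng = np.random.default_rng(3)
        neg = rng.normal(0.0, 1.0, 200)
        pos = rng.normal(3.0, 1.0, 200)  # > 2 pooled sd apart
        r = roc_curve(pos, neg)
        assert r.sensitivity > 0.5 and r.specificity > 0.5


class TestRankSum:
    def test_exact_p_for_fully_separated_triples(self):
        """{1,2,3} vs {4,5,6}: 2 of C(6,3)=20 assignments are as extreme."""
        res = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert res.method == "exact"
        assert res.u == 0.0
        assert res.p_value == pytest.approx(0.1)

    def test_complete_ties_give_p_one(self):
        res = rank_sum_test([5, 5, 5], [5, 5, 5])
        assert res.p_value == 1.0

    def test_u_range_invariant(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=6), rng.normal(size=7)
        res = rank_sum_test(a, b)
        assert 0 <= res.u <= len(a) * len(b)

    def test_normal_approximation_close_to_exact(self):
        """n1 = n2 = 8: the continuity-corrected normal p is within 0.02."""
        rng = np.random.default_rng(5)
        for _ in range(5):
            a = rng.normal(0.0, 1.0, 8)
            b = rng.normal(0.7, 1.0, 8)
            exact = rank_sum_test(a, b, method="exact")
            approx = rank_sum_test(a, b, method="normal_approx")
            assert abs(exact.p_value - approx.p_value) <= 0.02

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0.0, 1.0, 7)
        b = rng.normal(0.5, 1.0, 6)
        mine = rank_sum_test(a, b)
        ref = mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-9)

    @given(
        a=st.lists(st.integers(-3, 3), min_size=2, max_size=6),
        b=st.lists(st.integers(-3, 3), min_size=2, max_size=6),
    )
    def test_invariant_under_monotone_transform(self, a, b):
        a, b = np.array(a, dtype=float), np.array(b, dtype=float)
        base = rank_sum_test(a, b)
        transformed = rank_sum_test(np.exp(a), np.exp(b))
        assert transformed.u == pytest.approx(base.u)
        assert transformed.p_value == pytest.approx(base.p_value)

    def test_exact_enumeration_oracle_consistency(self):
        """The enumeration helper agrees with a from-scratch recount."""
        a, b = [1.0, 4.0, 2.5], [3.0, 5.0]
        pooled = np.array(a + b)
        ranks = rankdata(pooled)
        u_obs = ranks[:3].sum() - 6.0
        mean_u = 3 * 2 / 2.0
        count = sum(
            1
            for idx in combinations(range(5), 3)
            if abs(ranks[list(idx)].sum() - 6.0 - mean_u) >= abs(u_obs - mean_u) - 1e-12
        )
        assert _exact_two_sided_p(ranks, 3, float(u_obs)) == pytest.approx(count / 10.0)
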