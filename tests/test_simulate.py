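"""Generator: band catalog, cohort profiles, calibration and draw statistics."""

from dataclasses import replace

import numpy as np
import pytest

import ramandx as rx
from ramandx.band_metrics import intensity_ratio, difference_spectrum
from ramandx.preprocess import preprocess_set
from ramandx.simulate import (
    Band,
    ClassProfile,
    _generate_matrix,
    calibrate_profile,
    profile_spectrum,
    pseudo_voigt,
)

from conftest import SEED


EXPECTED_CENTERS = {743, 785, 1004, 1120, 1310, 1337, 1370, 1447, 1485, 1577, 1617, 1659}


class TestBandCatalog:
    def test_centers_and_key_assignments(self):
        catalog = rx.default_band_catalog()
        by_center = {b.center: b for b in catalog}
        assert set(by_center) == EXPECTED_CENTERS
        assert "DNA" in by_center[785.0].assignment
        assert "amide I" in by_center[1659.0].assignment
        assert all(b.fwhm == 16.0 and b.gauss_fraction == 0.5 for b in catalog)

    def test_band_spacing_exceeds_linewidth(self):
        """Neighboring centers are well separated relative to the 16 cm-1
        linewidth: every gap is at least 27 cm-1 (the amide III / CH pair at
        1310/1337), i.e. > 1.5 fwhm, and all but three gaps exceed 2 fwhm."""
        centers = sorted(b.center for b in rx.default_band_catalog())
        gaps = np.diff(centers)
        assert gaps.min() == 27.0
        assert gaps.min() > 1.5 * 16.0
        assert sum(g <= 2 * 16.0 for g in gaps) == 1  # only the 1310/1337 pair


class TestDefaultProfiles:
    def test_cohort_variability_levels(self, profiles):
        assert profiles["B_normal"].global_cv == 0.20
        assert profiles["REH"].global_cv == 0.075
        assert profiles["Pt-3"].global_cv == 0.11

    def test_ratio_targets(self):
        profs = rx.default_profiles()
        for name, target in [("B_normal", 1.6), ("RS4;11", 1.98), ("REH", 2.59),
                             ("MN60", 3.45), ("Pt-1", 2.56), ("Pt-2", 2.45), ("Pt-3", 2.93)]:
            assert profs[name].target_ratio == pytest.approx(target)

    def test_atra_variant_identical_to_parent(self, profiles):
        for line in ("RS4;11", "REH", "MN60"):
            assert profiles[f"{line}_ATRA"].band_amplitudes == profiles[line].band_amplitudes

    def test_antimetabolite_band_reduction(self, profiles):
        """MTX/6MP suppress nucleic-acid + Phe + CH2 bands by a fixed factor."""
        for line in ("RS4;11", "REH", "MN60"):
            parent = profiles[line].band_amplitudes
            for treated in (f"{line}_MTX", f"{line}_6MP"):
                amps = profiles[treated].band_amplitudes
                for c in (785.0, 1120.0, 1370.0, 1577.0, 1004.0, 1447.0):
                    assert amps[c] == pytest.approx(0.7 * parent[c])
                for c in (1310.0, 1337.0, 1485.0, 1617.0, 1659.0):
                    assert amps[c] == pytest.approx(parent[c])

    def test_leukemia_band_pattern_monotone(self, profiles):
        """Nucleic bands fall and protein bands rise along RS4;11 < REH < MN60."""
        b = profiles["B_normal"].band_amplitudes
        series = [profiles[n].band_amplitudes for n in ("RS4;11", "REH", "MN60")]
        for c in (785.0, 1120.0, 1370.0, 1577.0):
            values = [b[c]] + [a[c] for a in series]
            assert all(x > y for x, y in zip(values, values[1:]))
        for c in (1310.0, 1337.0, 1485.0, 1617.0):
            values = [b[c]] + [a[c] for a in series]
            assert all(x < y for x, y in zip(values, values[1:]))

    def test_profile_dict_round_trip(self, profiles):
        p = profiles["REH"]
        assert ClassProfile.from_dict(p.to_dict()) == p


class TestGeneration:
    def test_pure_gaussian_band_has_exact_unit_height(self, axis):
        """A single eta=1 band of amplitude 5 reaches exactly 5 at its center."""
        bands = (Band(center=1004.0, fwhm=12.0, gauss_fraction=1.0),)
        prof = ClassProfile(
            name="one", band_amplitudes={1004.0: 5.0}, global_cv=0.0,
            cohort_kind="cell_line", default_band_rel_sd=0.0,
            baseline_ranges=((0, 0),) * 4, drift_sd=0.0, noise_sd=0.0, bands=bands,
        )
        s = rx.generate_spectrum(prof, axis, np.random.default_rng(0))
        assert s.intensities[404] == pytest.approx(5.0, abs=1e-12)

    def test_degenerate_parameters_give_deterministic_band_sum(self, axis, profiles):
        """cv = noise = drift = baseline = 0 reproduces the analytic profile."""
        p = replace(
            profiles["REH"],
            global_cv=0.0, default_band_rel_sd=0.0, band_rel_sd={},
            baseline_ranges=((0, 0),) * 4, drift_sd=0.0, noise_sd=0.0,
        )
        s1 = rx.generate_spectrum(p, axis, np.random.default_rng(1))
        s2 = rx.generate_spectrum(p, axis, np.random.default_rng(99))
        np.testing.assert_array_equal(s1.intensities, s2.intensities)
        np.testing.assert_allclose(
            s1.intensities, profile_spectrum(p, axis).intensities, atol=1e-12
        )
        # at an isolated band center: amplitude plus neighbor tails only
        i785 = 185
        tails = sum(
            p.band_amplitudes[b.center] * pseudo_voigt(785.0 - b.center, b.fwhm, b.gauss_fraction)
            for b in p.bands if b.center != 785.0
        )
        assert s1.intensities[i785] == pytest.approx(p.band_amplitudes[785.0] + tails)

    def test_monte_carlo_mean_matches_noiseless_value(self, axis, profiles):
        """Mean amide I intensity over 1000 draws ~ deterministic value (3 SE)."""
        p = profiles["REH"]
        y, _, _ = _generate_matrix(p, axis, np.random.default_rng(SEED), 1000)
        i1659 = 1059
        det = profile_spectrum(p, axis).intensities[i1659]
        baseline_mean = sum(
            (lo + hi) / 2 * (1059 / 1199) ** k for k, (lo, hi) in enumerate(p.baseline_ranges)
        )
        vals = y[:, i1659]
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - (det + baseline_mean)) < 3 * se + 0.01 * det

    def test_seeded_determinism_is_bitwise(self, profiles):
        a = rx.generate_dataset({"B_normal": 2}, seed=7, profiles=profiles)
        b = rx.generate_dataset({"B_normal": 2}, seed=7, profiles=profiles)
        np.testing.assert_array_equal(a.matrix(), b.matrix())
        assert a.ids == b.ids

    def test_plan_counts_and_labels(self, profiles):
        sset = rx.generate_dataset({"B_normal": 4, "REH": 3}, seed=1, profiles=profiles)
        assert len(sset) == 7
        assert sset.labels.count("B_normal") == 4
        assert sset.labels.count("REH") == 3
        assert sset.spectra[0].cohort_kind == "normal"

    def test_unknown_cohort_rejected(self, profiles):
        with pytest.raises(KeyError):
            rx.generate_dataset({"HL60": 3}, seed=1, profiles=profiles)

    def test_integrated_intensity_cv_matches_study_condition(self, axis, profiles):
        """Raw integrated intensity CV of B_normal ~ 20% within 3 sigma."""
        p = replace(profiles["B_normal"], baseline_ranges=((0, 0),) * 4, noise_sd=0.0)
        y, _, _ = _generate_matrix(p, axis, np.random.default_rng(SEED), 400)
        areas = np.trapezoid(y, axis.values(), axis=1)
        cv = areas.std(ddof=1) / areas.mean()
        sigma_cv = 0.20 * np.sqrt((1 + 2 * 0.20**2) / (2 * 400))
        assert abs(cv - 0.20) < 3 * sigma_cv + 0.01


class TestCalibration:
    def test_fixed_point_returns_profile_unchanged(self, profiles):
        """A calibrated profile is already at the fixed point."""
        p = profiles["REH"]
        again = calibrate_profile(p)
        assert again.band_amplitudes[1447.0] == pytest.approx(
            p.band_amplitudes[1447.0], abs=1e-9
        )

    def test_calibrated_noiseless_ratio_hits_target(self, axis, profiles):
        for name in ("B_normal", "REH", "MN60"):
            p = profiles[name]
            sset = rx.SpectrumSet(axis=axis, spectra=[profile_spectrum(p, axis)])
            ratio = intensity_ratio(preprocess_set(sset).spectra[0])
            assert ratio == pytest.approx(p.target_ratio, abs=1e-4)

    def test_isolated_pair_calibrates_to_amplitude_ratio(self, axis):
        """With negligible cross-talk, the calibrated 1447 amplitude is
        target_ratio x the 785 amplitude."""
        bands = (Band(center=785.0, fwhm=8.0, gauss_fraction=1.0),
                 Band(center=1447.0, fwhm=8.0, gauss_fraction=1.0),
                 Band(center=1659.0, fwhm=8.0, gauss_fraction=1.0))
        prof = ClassProfile(
            name="pair", band_amplitudes={785.0: 2.0, 1447.0: 1.0, 1659.0: 3.0},
            global_cv=0.0, cohort_kind="cell_line", default_band_rel_sd=0.0,
            baseline_ranges=((0, 0),) * 4, drift_sd=0.0, noise_sd=0.0,
            target_ratio=2.5, bands=bands,
        )
        cal = calibrate_profile(prof, axis)
        assert cal.band_amplitudes[1447.0] == pytest.approx(2.5 * 2.0, rel=5e-3)

    def test_zero_denominator_amplitude_rejected(self, axis):
        prof = rx.default_profiles()["REH"]
        prof.band_amplitudes[785.0] = 0.0
        from ramandx.simulate import CalibrationError
        with pytest.raises(CalibrationError):
            calibrate_profile(prof, axis)

    def test_cohort_mean_ratio_converges_to_target(self, axis, profiles):
        """|empirical mean - target| shrinks as the cohort grows."""
        p = profiles["REH"]
        errors = []
        for n, seed in ((40, SEED), (640, SEED)):
            y, _, _ = _generate_matrix(p, axis, np.random.default_rng(seed), n)
            sset = rx.SpectrumSet(
                axis=axis,
                spectra=[rx.Spectrum(axis=axis, intensities=row, id=f"r{i}", label="REH")
                         for i, row in enumerate(y)],
            )
            ratios = [intensity_ratio(s) for s in preprocess_set(sset)]
            errors.append(abs(np.mean(ratios) - p.target_ratio))
        assert errors[1] < max(errors[0], 0.02)


class TestDifferenceSignPattern:
    def test_leukemia_minus_normal_signs(self, axis, profiles):
        """Every leukemia profile: negative at 785/1120/1370/1577, positive at 1447."""
        def noiseless_pre(name):
            sset = rx.SpectrumSet(axis=axis, spectra=[profile_spectrum(profiles[name], axis)])
            return preprocess_set(sset).spectra[0]

        b = noiseless_pre("B_normal")
        for name in ("RS4;11", "REH", "MN60", "Pt-1", "Pt-2", "Pt-3"):
            d = difference_spectrum(noiseless_pre(name), b).intensities
            for c in (785, 1120, 1370, 1577):
                assert d[c - 600] < 0, f"{name} not reduced at {c}"
            assert d[1447 - 600] > 0, f"{name} not elevated at 1447"
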