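"""Synthetic single-cell Raman spectra with class-structured band patterns.

The generator emulates the statistical structure of fingerprint-region
(600-1800 cm^-1) spectra of normal B-lymphocytes, three B-ALL cell lines of
increasing maturation (RS4;11 < REH < MN60), their drug-treated variants,
and clinical B-ALL cohorts:

* twelve pseudo-Voigt bands at the canonical positions (DNA/RNA ring
  breathing, PO2- backbone, phenylalanine, amide III/I, CH/CH2 protein
  modes);
* class-dependent band amplitudes — leukemia cohorts have the nucleic-acid
  bands (785/1120/1370/1577 cm^-1) suppressed and the protein bands raised,
  with magnitude increasing along the maturation series; MTX/6MP treatment
  lowers the nucleic-acid and protein bands, ATRA changes nothing;
* per-cell multiplicative intensity scatter (lognormal, CV 20% for normal B
  cells, 7.5% for cell lines, 11% for clinical cohorts), per-band lognormal
  amplitude scatter, a random cubic fluorescence baseline, a rigid
  wavenumber drift per spectrum, and additive Gaussian noise.

Each cohort carries a target post-preprocessing I_1447/I_785 intensity
ratio; :func:`calibrate_profile` pins the 1447 cm^-1 amplitude so the
noiseless pipeline reproduces it exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .io import Spectrum, SpectrumSet, WavenumberAxis
from .preprocess import PreprocessConfig, preprocess_set

__all__ = [
    "Band",
    "ClassProfile",
    "pseudo_voigt",
    "default_band_catalog",
    "default_profiles",
    "calibrate_profile",
    "calibrated_default_profiles",
    "profile_spectrum",
    "generate_spectrum",
    "generate_dataset",
    "CalibrationError",
]

#: Hard cap on the per-spectrum rigid wavenumber shift, cm^-1.
DRIFT_CAP = 5.0

#: Bands suppressed by antimetabolite (MTX / 6MP) treatment: the four
#: nucleic-acid bands plus the phenylalanine and CH2-protein bands.
TREATMENT_REDUCED_BANDS = (785.0, 1120.0, 1370.0, 1577.0, 1004.0, 1447.0)
TREATMENT_REDUCTION = 0.7


class CalibrationError(RuntimeError):
    """Raised when the amplitude calibration fixed point does not converge."""


@dataclass(frozen=True)
class Band:
    """One Raman band: a unit-height pseudo-Voigt line."""

    center: float
    fwhm: float = 16.0
    gauss_fraction: float = 0.5
    assignment: str = ""

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("band fwhm must be positive")
        if not 0 <= self.gauss_fraction <= 1:
            raise ValueError("gauss_fraction must be within [0, 1]")


def pseudo_voigt(x: np.ndarray, fwhm: float, gauss_fraction: float) -> np.ndarray:
    """Unit-peak-height pseudo-Voigt profile (Gaussian/Lorentzian mixture)."""
    x = np.asarray(x, dtype=float)
    g = np.exp(-4.0 * math.log(2.0) * (x / fwhm) ** 2)
    l = 1.0 / (1.0 + (2.0 * x / fwhm) ** 2)
    return gauss_fraction * g + (1.0 - gauss_fraction) * l


def default_band_catalog() -> list[Band]:
    """The twelve fingerprint-region bands used by every default cohort."""
    assignments = {
        743.0: "RNA bases (ring breathing)",
        785.0: "DNA bases U/T/C ring breathing + backbone",
        1004.0: "phenylalanine sym ring breathing",
        1120.0: "PO2- sym str, DNA backbone",
        1310.0: "amide III",
        1337.0: "CH def, proteins / nucleic acids",
        1370.0: "DNA bases T/A/G",
        1447.0: "CH2 def, proteins",
        1485.0: "CH/CH2 def, proteins / lipids",
        1577.0: "DNA bases G/A ring",
        1617.0: "C=C str, Tyr/Trp",
        1659.0: "amide I",
    }
    return [Band(center=c, assignment=a) for c, a in assignments.items()]


@dataclass
class ClassProfile:
    """Generative parameters of one cohort.

    band_amplitudes
        Mean peak height per band center (arbitrary units).
    band_rel_sd
        Per-band relative sd of the lognormal amplitude factor; bands not
        listed use ``default_band_rel_sd``. The 785/1447 pair carries the
        cohort's ratio variance (the global factor cancels in the ratio).
    global_cv
        sd/mean of the per-cell multiplicative intensity factor.
    baseline_ranges
        Uniform ranges (lo, hi) for the four coefficients of the random
        cubic background, on wavenumbers rescaled to [0, 1].
    drift_sd
        sd (cm^-1) of the per-spectrum rigid wavenumber shift (capped at
        ``+-DRIFT_CAP``).
    noise_sd
        sd of the additive white noise, in raw amplitude units.
    target_ratio
        Intended post-preprocessing mean I_1447/I_785 (None = uncalibrated).
    """

    name: str
    band_amplitudes: dict[float, float]
    global_cv: float
    cohort_kind: str
    treatment: str = "none"
    band_rel_sd: dict[float, float] = field(default_factory=dict)
    default_band_rel_sd: float = 0.05
    baseline_ranges: tuple[tuple[float, float], ...] = (
        (0.25, 0.70),
        (-0.40, 0.10),
        (-0.25, 0.25),
        (-0.20, 0.20),
    )
    drift_sd: float = 1.0
    noise_sd: float = 0.004
    target_ratio: float | None = None
    bands: tuple[Band, ...] = field(default_factory=lambda: tuple(default_band_catalog()))

    def __post_init__(self) -> None:
        centers = {b.center for b in self.bands}
        if set(self.band_amplitudes) != centers:
            raise ValueError(f"profile {self.name!r}: amplitudes do not match the band catalog")
        if any(a < 0 for a in self.band_amplitudes.values()):
            raise ValueError(f"profile {self.name!r}: negative band amplitude")
        if self.global_cv < 0:
            raise ValueError(f"profile {self.name!r}: global_cv must be >= 0")
        if self.target_ratio is not None and self.target_ratio <= 0:
            raise ValueError(f"profile {self.name!r}: target_ratio must be positive")
        if len(self.baseline_ranges) != 4:
            raise ValueError("baseline_ranges must give 4 coefficient ranges")

    def rel_sd(self, center: float) -> float:
        return self.band_rel_sd.get(center, self.default_band_rel_sd)

    def amplitude_vector(self) -> np.ndarray:
        return np.array([self.band_amplitudes[b.center] for b in self.bands])

    # -- serialization (config-file schema) --------------------------------

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "band_amplitudes": {str(k): v for k, v in self.band_amplitudes.items()},
            "global_cv": self.global_cv,
            "cohort_kind": self.cohort_kind,
            "treatment": self.treatment,
            "band_rel_sd": {str(k): v for k, v in self.band_rel_sd.items()},
            "default_band_rel_sd": self.default_band_rel_sd,
            "baseline_ranges": [list(r) for r in self.baseline_ranges],
            "drift_sd": self.drift_sd,
            "noise_sd": self.noise_sd,
            "target_ratio": self.target_ratio,
            "bands": [
                {
                    "center": b.center,
                    "fwhm": b.fwhm,
                    "gauss_fraction": b.gauss_fraction,
                    "assignment": b.assignment,
                }
                for b in self.bands
            ],
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ClassProfile":
        return cls(
            name=d["name"],
            band_amplitudes={float(k): float(v) for k, v in d["band_amplitudes"].items()},
            global_cv=float(d["global_cv"]),
            cohort_kind=d["cohort_kind"],
            treatment=d.get("treatment", "none"),
            band_rel_sd={float(k): float(v) for k, v in d.get("band_rel_sd", {}).items()},
            default_band_rel_sd=float(d.get("default_band_rel_sd", 0.05)),
            baseline_ranges=tuple(tuple(r) for r in d["baseline_ranges"]) if "baseline_ranges" in d else ClassProfile.__dataclass_fields__["baseline_ranges"].default,
            drift_sd=float(d.get("drift_sd", 1.0)),
            noise_sd=float(d.get("noise_sd", 0.004)),
            target_ratio=None if d.get("target_ratio") is None else float(d["target_ratio"]),
            bands=tuple(
                Band(
                    center=float(b["center"]),
                    fwhm=float(b.get("fwhm", 16.0)),
                    gauss_fraction=float(b.get("gauss_fraction", 0.5)),
                    assignment=b.get("assignment", ""),
                )
                for b in d["bands"]
            )
            if "bands" in d
            else tuple(default_band_catalog()),
        )


# ---------------------------------------------------------------------------
# default cohort profiles
# ---------------------------------------------------------------------------

# Normal B-lymphocyte mean band heights (arbitrary units; amide I = 1).
_B_NORMAL_AMPLITUDES = {
    743.0: 0.28,
    785.0: 0.60,
    1004.0: 0.45,
    1120.0: 0.34,
    1310.0: 0.50,
    1337.0: 0.56,
    1370.0: 0.33,
    1447.0: 0.90,
    1485.0: 0.46,
    1577.0: 0.40,
    1617.0: 0.42,
    1659.0: 1.00,
}

# Leukemia-vs-normal shape change per maturation step: the DNA ring-breathing
# band at 785 cm^-1 drops 15% per step (bounded by the requirement that the
# printed ratio targets keep the 1447 difference positive after calibration),
# the remaining nucleic-acid bands drop 28%, protein/CH bands rise 16%, and
# the amide I reference rises only 2% so protein bands stay elevated after
# normalization. Step magnitudes are calibrated once so that the cohorts
# reproduce the reported PCA separability (leave-one-out efficiencies) while
# preserving the qualitative difference-spectrum pattern.
_NUCLEIC_BANDS = (785.0, 1120.0, 1370.0, 1577.0)
_PROTEIN_UP_BANDS = (1310.0, 1337.0, 1447.0, 1485.0, 1617.0)
_NUCLEIC_785_STEP = 0.15
_NUCLEIC_OTHER_STEP = 0.28
_PROTEIN_STEP = 0.16
_AMIDE_I_STEP = 0.02

# Maturation step per cohort: REH sits slightly past the linear midpoint,
# which matches both its printed ratio (2.59 of the 1.98-3.45 line span)
# and the reported distinctness of the three lines.
_LINE_STEPS = {"RS4;11": 1.0, "REH": 2.2, "MN60": 3.0}
_PATIENT_STEPS = {"Pt-1": 2.0, "Pt-2": 2.0, "Pt-3": 2.5}
# RNA 743 cm^-1 elevation of the L3-type MN60 line (abundant ribosomal RNA);
# Pt-3 is intermediate between the L2 lines and MN60.
_RNA_743_FACTORS = {"MN60": 2.5, "Pt-3": 1.3}

# Printed per-cohort I_1447/I_785 statistics (mean, sd) that anchor the
# calibration targets and the 785/1447 band-level variance allocation.
_RATIO_STATS = {
    "B_normal": (1.6, 0.3),
    "RS4;11": (1.98, 0.17),
    "REH": (2.59, 0.18),
    "MN60": (3.45, 0.20),
    "Pt-1": (2.56, 0.27),
    "Pt-2": (2.45, 0.25),
    "Pt-3": (2.93, 0.27),
}


def _leukemia_amplitudes(step: float, rna_743_factor: float = 1.0) -> dict[float, float]:
    amps = dict(_B_NORMAL_AMPLITUDES)
    amps[785.0] *= 1.0 - _NUCLEIC_785_STEP * step
    for c in _NUCLEIC_BANDS[1:]:
        amps[c] *= 1.0 - _NUCLEIC_OTHER_STEP * step
    for c in _PROTEIN_UP_BANDS:
        amps[c] *= 1.0 + _PROTEIN_STEP * step
    amps[1659.0] *= 1.0 + _AMIDE_I_STEP * step
    amps[743.0] *= rna_743_factor
    return amps


def _ratio_pair_sd(name: str) -> dict[float, float]:
    """Allocate the cohort's relative ratio sd to the 785/1447 amplitudes.

    The per-cell ratio of two independent lognormal factors has relative sd
    ~ sqrt(2) x the per-band relative sd, so each band gets rel_sd / sqrt(2).
    """
    mean, sd = _RATIO_STATS[name]
    s = (sd / mean) / math.sqrt(2.0)
    return {785.0: s, 1447.0: s}


def default_profiles() -> dict[str, ClassProfile]:
    """Uncalibrated generative profiles for every default cohort.

    Cohorts: B_normal; the RS4;11 / REH / MN60 lines; their MTX-, 6MP- and
    ATRA-treated variants; clinical patients Pt-1..3. Treated variants derive
    from the untreated line (MTX/6MP: nucleic-acid + protein bands x0.7;
    ATRA: identical amplitudes) and carry no ratio target of their own.
    """
    profiles: dict[str, ClassProfile] = {}
    profiles["B_normal"] = ClassProfile(
        name="B_normal",
        band_amplitudes=dict(_B_NORMAL_AMPLITUDES),
        global_cv=0.20,
        cohort_kind="normal",
        band_rel_sd=_ratio_pair_sd("B_normal"),
        target_ratio=_RATIO_STATS["B_normal"][0],
    )
    for name, step in _LINE_STEPS.items():
        profiles[name] = ClassProfile(
            name=name,
            band_amplitudes=_leukemia_amplitudes(step, _RNA_743_FACTORS.get(name, 1.0)),
            global_cv=0.075,
            cohort_kind="cell_line",
            band_rel_sd=_ratio_pair_sd(name),
            target_ratio=_RATIO_STATS[name][0],
        )
    for name in _LINE_STEPS:
        for treatment in ("MTX", "6MP", "ATRA"):
            profiles[f"{name}_{treatment}"] = _treated_variant(profiles[name], treatment)
    for name, step in _PATIENT_STEPS.items():
        profiles[name] = ClassProfile(
            name=name,
            band_amplitudes=_leukemia_amplitudes(step, _RNA_743_FACTORS.get(name, 1.0)),
            global_cv=0.11,
            cohort_kind="clinical",
            band_rel_sd=_ratio_pair_sd(name),
            target_ratio=_RATIO_STATS[name][0],
        )
    return profiles


def _treated_variant(parent: ClassProfile, treatment: str) -> ClassProfile:
    amps = dict(parent.band_amplitudes)
    if treatment in ("MTX", "6MP"):
        for c in TREATMENT_REDUCED_BANDS:
            amps[c] *= TREATMENT_REDUCTION
    elif treatment != "ATRA":
        raise ValueError(f"unknown treatment {treatment!r}")
    return replace(
        parent,
        name=f"{parent.name}_{treatment}",
        band_amplitudes=amps,
        band_rel_sd=dict(parent.band_rel_sd),
        treatment=treatment,
        target_ratio=None,
    )


# ---------------------------------------------------------------------------
# deterministic spectrum and calibration
# ---------------------------------------------------------------------------

def profile_spectrum(
    profile: ClassProfile, axis: WavenumberAxis | None = None
) -> Spectrum:
    """Noiseless, drift-free, baseline-free spectrum of a profile."""
    axis = axis or WavenumberAxis()
    v = axis.values()
    y = np.zeros(axis.n_points)
    for band in profile.bands:
        y += profile.band_amplitudes[band.center] * pseudo_voigt(
            v - band.center, band.fwhm, band.gauss_fraction
        )
    return Spectrum(
        axis=axis,
        intensities=y,
        id=f"{profile.name}-noiseless",
        label=profile.name,
        treatment=profile.treatment,
        cohort_kind=profile.cohort_kind,
    )


def _noiseless_pipeline_ratio(
    profile: ClassProfile, axis: WavenumberAxis, config: PreprocessConfig
) -> float:
    from .band_metrics import intensity_ratio

    raw = profile_spectrum(profile, axis)
    sset = SpectrumSet(axis=axis, spectra=[raw])
    pre = preprocess_set(sset, config)
    return intensity_ratio(pre.spectra[0], halfwidth=config.band_halfwidth)


def calibrate_profile(
    profile: ClassProfile,
    axis: WavenumberAxis | None = None,
    config: PreprocessConfig | None = None,
    *,
    max_iters: int = 20,
    tol: float = 1e-6,
) -> ClassProfile:
    """Rescale the 1447 cm^-1 amplitude so the noiseless preprocessed
    I_1447/I_785 ratio equals ``profile.target_ratio``.

    Fixed-point iteration: measure the ratio through the full preprocessing
    chain, multiply the amplitude by target/measured, repeat. The cross-talk
    from neighboring band tails is small, so convergence takes a few steps.
    """
    axis = axis or WavenumberAxis()
    config = config or PreprocessConfig()
    if profile.target_ratio is None:
        raise ValueError(f"profile {profile.name!r} has no target_ratio to calibrate to")
    if profile.band_amplitudes.get(785.0, 0.0) <= 0:
        raise CalibrationError(f"profile {profile.name!r}: zero 785 cm-1 amplitude")
    target = profile.target_ratio
    current = replace(profile, band_amplitudes=dict(profile.band_amplitudes))
    for _ in range(max_iters):
        measured = _noiseless_pipeline_ratio(current, axis, config)
        if measured <= 0:
            raise CalibrationError(f"profile {profile.name!r}: non-positive measured ratio")
        if abs(measured - target) <= tol * max(1.0, target):
            return current
        amps = dict(current.band_amplitudes)
        amps[1447.0] *= target / measured
        current = replace(current, band_amplitudes=amps)
    raise CalibrationError(
        f"profile {profile.name!r}: ratio calibration did not converge in {max_iters} iterations"
    )


def calibrated_default_profiles(
    axis: WavenumberAxis | None = None, config: PreprocessConfig | None = None
) -> dict[str, ClassProfile]:
    """Default profiles with every ratio target calibrated.

    Profiles with a target are calibrated directly; drug-treated variants are
    re-derived from their calibrated parent so the treatment factors act on
    the calibrated amplitudes.
    """
    profiles = default_profiles()
    out: dict[str, ClassProfile] = {}
    for name, prof in profiles.items():
        if prof.target_ratio is not None:
            out[name] = calibrate_profile(prof, axis, config)
    for name, prof in profiles.items():
        if prof.target_ratio is None:
            parent = name.rsplit("_", 1)[0]
            out[name] = _treated_variant(out[parent], prof.treatment)
    return {name: out[name] for name in profiles}  # preserve original order


# ---------------------------------------------------------------------------
# stochastic generation
# ---------------------------------------------------------------------------

def _lognormal_factors(
    rng: np.random.Generator, cv: float, size, *, unit_inverse_mean: bool = False
) -> np.ndarray:
    """Lognormal factors with sd/mean = cv.

    By default the factors have mean 1. With ``unit_inverse_mean`` the
    *reciprocal* has mean 1 instead (the mean shifts up by a factor
    ``1 + cv^2``): used for the 785 cm^-1 ratio-denominator band so the
    per-cell I_1447/I_785 ratio is unbiased and its cohort mean converges
    to the calibrated target.
    """
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log(1.0 + cv * cv)
    mu = sigma2 / 2.0 if unit_inverse_mean else -sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=size)


def _generate_matrix(
    profile: ClassProfile, axis: WavenumberAxis, rng: np.random.Generator, n: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw ``n`` spectra; returns (intensities (n, p), drifts (n,), g (n,))."""
    v = axis.values()
    p = axis.n_points
    g = _lognormal_factors(rng, profile.global_cv, n)
    eps = np.column_stack(
        [
            _lognormal_factors(
                rng,
                profile.rel_sd(b.center),
                n,
                unit_inverse_mean=(b.center == 785.0),
            )
            for b in profile.bands
        ]
    )
    if profile.drift_sd > 0:
        drifts = np.clip(rng.normal(0.0, profile.drift_sd, n), -DRIFT_CAP, DRIFT_CAP)
    else:
        drifts = np.zeros(n)
    coeffs = np.column_stack(
        [rng.uniform(lo, hi, n) for lo, hi in profile.baseline_ranges]
    )
    noise = rng.normal(0.0, profile.noise_sd, (n, p)) if profile.noise_sd > 0 else 0.0

    y = np.zeros((n, p))
    for j, band in enumerate(profile.bands):
        amp = profile.band_amplitudes[band.center]
        if amp == 0:
            continue
        x = v[None, :] - band.center - drifts[:, None]
        y += (amp * eps[:, j])[:, None] * pseudo_voigt(x, band.fwhm, band.gauss_fraction)
    y *= g[:, None]
    u = (v - v[0]) / (v[-1] - v[0])
    baseline = coeffs @ np.vander(u, 4, increasing=True).T
    y += baseline + noise
    return y, drifts, g


def generate_spectrum(
    profile: ClassProfile,
    axis: WavenumberAxis | None = None,
    rng: np.random.Generator | None = None,
    spectrum_id: str | None = None,
) -> Spectrum:
    """Draw a single spectrum from a cohort profile."""
    axis = axis or WavenumberAxis()
    rng = rng if rng is not None else np.random.default_rng()
    y, drifts, g = _generate_matrix(profile, axis, rng, 1)
    return Spectrum(
        axis=axis,
        intensities=y[0],
        id=spectrum_id or f"{profile.name}-0",
        label=profile.name,
        treatment=profile.treatment,
        cohort_kind=profile.cohort_kind,
        meta={"drift": float(drifts[0]), "global_factor": float(g[0])},
    )


def generate_dataset(
    class_plan: Mapping[str, int],
    seed: int,
    profiles: Mapping[str, ClassProfile] | None = None,
    axis: WavenumberAxis | None = None,
) -> SpectrumSet:
    """Deterministically generate a labeled multi-cohort dataset.

    ``class_plan`` maps cohort name -> number of spectra; cohorts are drawn
    in plan order from a single seeded stream, so a fixed (plan, seed) pair
    always yields a bitwise-identical set. With ``profiles=None`` the
    calibrated default profiles are used.
    """
    axis = axis or WavenumberAxis()
    if profiles is None:
        profiles = calibrated_default_profiles(axis)
    unknown = [name for name in class_plan if name not in profiles]
    if unknown:
        raise KeyError(f"unknown cohort name(s): {unknown}")
    rng = np.random.default_rng(seed)
    spectra: list[Spectrum] = []
    for name, n in class_plan.items():
        prof = profiles[name]
        y, drifts, g = _generate_matrix(prof, axis, rng, int(n))
        for i in range(int(n)):
            spectra.append(
                Spectrum(
                    axis=axis,
                    intensities=y[i],
                    id=f"{name}-{i:04d}",
                    label=name,
                    treatment=prof.treatment,
                    cohort_kind=prof.cohort_kind,
                    meta={"drift": float(drifts[i]), "global_factor": float(g[i])},
                )
            )
    plan_str = ",".join(f"{k}:{v}" for k, v in class_plan.items())
    return SpectrumSet(
        axis=axis, spectra=spectra, provenance=f"synthetic seed={seed} plan={plan_str}"
    )
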