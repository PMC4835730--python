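"""Spectral preprocessing: drift alignment, baseline removal, normalization.

The chain mirrors standard single-cell Raman practice for this kind of
dataset: (1) rigid alignment of each spectrum to a common reference to
compensate small laser-wavelength drift, (2) fluorescence background removal
by an iterative peak-suppressing third-order polynomial fit ("modified
polyfit"), and (3) normalization of every spectrum to the maximum of the
amide I band at 1659 cm^-1 so that only spectral *shape* enters downstream
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .io import Spectrum, SpectrumSet, WavenumberAxis

__all__ = [
    "PreprocessConfig",
    "estimate_shift",
    "apply_shift",
    "subtract_baseline",
    "normalize",
    "preprocess_set",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    poly_order
        Order of the background polynomial (3 = cubic fluorescence model).
    max_baseline_iters / baseline_tol
        Stopping rule of the iterative peak-suppressing fit; with
        ``max_baseline_iters=1`` the fit degenerates to a single naive
        least-squares polynomial through the whole trace.
    align_max_shift
        Largest rigid shift (cm^-1) searched for / accepted during alignment.
    norm_center / band_halfwidth
        Window (center +- halfwidth, cm^-1) whose maximum defines both the
        normalization constant and band intensities downstream.
    """

    poly_order: int = 3
    max_baseline_iters: int = 100
    baseline_tol: float = 1e-6
    align_max_shift: float = 5.0
    norm_center: float = 1659.0
    band_halfwidth: float = 8.0

    def __post_init__(self) -> None:
        if self.poly_order < 0:
            raise ValueError("poly_order must be >= 0")
        if self.band_halfwidth <= 0:
            raise ValueError("band_halfwidth must be positive")


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def estimate_shift(
    spectrum: Spectrum,
    reference: Spectrum,
    config: PreprocessConfig | None = None,
) -> float:
    """Rigid wavenumber shift of ``spectrum`` relative to ``reference``.

    Returns the shift ``s`` (cm^-1) maximizing the cross-correlation between
    the two traces over integer lags within ``+-align_max_shift``, refined to
    sub-sample precision by parabolic interpolation of the correlation peak.
    Sign convention: ``spectrum(v) ~ reference(v + s)``, so
    ``apply_shift(spectrum, -s)`` aligns the spectrum onto the reference.
    """
    config = config or PreprocessConfig()
    if spectrum.axis != reference.axis:
        raise ValueError("spectrum and reference must share an axis")
    axis = spectrum.axis
    # detrend both traces with a coarse cubic so broad fluorescence
    # backgrounds do not dominate the correlation
    if np.ptp(spectrum.intensities) == 0 or np.ptp(reference.intensities) == 0:
        raise ValueError("cannot align a flat (zero-variance) spectrum")
    s = _detrend(axis, spectrum.intensities)
    r = _detrend(axis, reference.intensities)
    scale = max(np.max(np.abs(spectrum.intensities)), np.max(np.abs(reference.intensities)))
    if np.ptp(s) <= 1e-12 * scale or np.ptp(r) <= 1e-12 * scale:
        raise ValueError("cannot align a featureless (pure-baseline) spectrum")

    max_lag = max(1, int(round(config.align_max_shift / axis.step)))
    lags = np.arange(-max_lag, max_lag + 1)
    corr = np.empty(lags.size)
    n = axis.n_points
    for j, lag in enumerate(lags):
        if lag >= 0:
            a, b = s[lag:], r[: n - lag]
        else:
            a, b = s[: n + lag], r[-lag:]
        corr[j] = a @ b / a.size
    best = int(np.argmax(corr))
    lag = float(lags[best])
    # parabolic refinement on the three points around the peak
    if 0 < best < lags.size - 1:
        c_m, c_0, c_p = corr[best - 1], corr[best], corr[best + 1]
        denom = c_m - 2 * c_0 + c_p
        if denom < 0:
            lag += 0.5 * (c_m - c_p) / denom
    shift = -lag * axis.step  # spectrum[i] ~ reference[i + lag] <=> s = -lag*step
    return float(np.clip(shift, -config.align_max_shift, config.align_max_shift))


def apply_shift(
    spectrum: Spectrum, shift: float, max_shift: float = 5.0
) -> Spectrum:
    """Resample the spectrum at ``v + shift`` (linear interpolation, edge fill)."""
    if abs(shift) > max_shift + 1e-12:
        raise ValueError(f"|shift| = {abs(shift):g} exceeds the allowed {max_shift:g} cm-1")
    if shift == 0:
        return spectrum.with_intensities(spectrum.intensities.copy())
    v = spectrum.axis.values()
    return spectrum.with_intensities(np.interp(v + shift, v, spectrum.intensities))


def _detrend(axis: WavenumberAxis, y: np.ndarray, order: int = 3) -> np.ndarray:
    design, pinv = _design(axis, order)
    return y - design @ (pinv @ y)


# ---------------------------------------------------------------------------
# baseline
# ---------------------------------------------------------------------------

@lru_cache(maxsize=32)
def _design(axis: WavenumberAxis, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Polynomial design matrix on [0, 1]-scaled wavenumbers and its pseudo-inverse."""
    v = axis.values()
    u = (v - v[0]) / (v[-1] - v[0])
    design = np.vander(u, order + 1, increasing=True)
    return design, np.linalg.pinv(design)


def fit_baseline(spectrum: Spectrum, config: PreprocessConfig | None = None) -> np.ndarray:
    """Iterative peak-suppressing polynomial baseline of a spectrum.

    Fits an order-``poly_order`` least-squares polynomial to a working copy of
    the trace, clips the working copy to the fit wherever it lies above it,
    and repeats until the largest relative change of the working copy drops
    below ``baseline_tol`` (or ``max_baseline_iters`` is reached). Peaks are
    thereby progressively excluded, and the fit settles onto the smooth
    background under them.
    """
    config = config or PreprocessConfig()
    y = spectrum.intensities
    if not np.all(np.isfinite(y)):
        raise ValueError(f"spectrum {spectrum.id!r}: non-finite intensities")
    if spectrum.axis.n_points <= config.poly_order + 1:
        raise ValueError("axis too short for the requested polynomial order")
    design, pinv = _design(spectrum.axis, config.poly_order)
    scale = max(float(np.max(np.abs(y))), 1e-300)
    work = y.astype(float).copy()
    fit = np.zeros_like(work)
    for _ in range(config.max_baseline_iters):
        fit = design @ (pinv @ work)
        clipped = np.minimum(work, fit)
        change = float(np.max(np.abs(clipped - work))) / scale
        work = clipped
        if change < config.baseline_tol:
            break
    return fit


def subtract_baseline(spectrum: Spectrum, config: PreprocessConfig | None = None) -> Spectrum:
    """Remove the fluorescence background (see :func:`fit_baseline`)."""
    fit = fit_baseline(spectrum, config)
    return spectrum.with_intensities(spectrum.intensities - fit)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize(spectrum: Spectrum, config: PreprocessConfig | None = None) -> Spectrum:
    """Divide by the maximum intensity within the amide I window.

    After this step the window maximum is exactly 1, and every intensity
    ratio within the spectrum is unchanged.
    """
    config = config or PreprocessConfig()
    mask = spectrum.axis.window(config.norm_center, config.band_halfwidth)
    if not mask.any():
        raise ValueError("normalization window lies outside the axis")
    peak = float(np.max(spectrum.intensities[mask]))
    if peak <= 0:
        raise ValueError(
            f"spectrum {spectrum.id!r}: non-positive intensity in the "
            f"{config.norm_center:g} cm-1 window (failed baseline correction?)"
        )
    return spectrum.with_intensities(spectrum.intensities / peak)


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------

def median_reference(sset: SpectrumSet) -> Spectrum:
    """Pointwise median spectrum of a set (the alignment reference)."""
    med = np.median(sset.matrix(), axis=0)
    return Spectrum(axis=sset.axis, intensities=med, id="__median_reference__")


def preprocess_set(sset: SpectrumSet, config: PreprocessConfig | None = None) -> SpectrumSet:
    """Align (to the set median), baseline-subtract and normalize every spectrum."""
    config = config or PreprocessConfig()
    if len(sset) == 0:
        raise ValueError("cannot preprocess an empty spectrum set")
    reference = median_reference(sset)
    out = []
    for s in sset:
        try:
            shift = estimate_shift(s, reference, config)
            aligned = apply_shift(s, -shift, max_shift=config.align_max_shift)
            corrected = subtract_baseline(aligned, config)
            result = normalize(corrected, config)
        except ValueError as exc:
            raise ValueError(f"preprocessing failed for spectrum {s.id!r}: {exc}") from exc
        result.meta["applied_shift"] = -shift
        out.append(result)
    return SpectrumSet(axis=sset.axis, spectra=out, provenance=sset.provenance)
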