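"""Shared fixtures: calibrated cohort profiles and the (expensive) default
300-cell datasets, computed once per session and reused across tests."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import ramandx as rx
from ramandx.preprocess import PreprocessConfig, preprocess_set

settings.register_profile("suite", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("suite")

#: Base seed for every stochastic fixture in the suite.
SEED = 1234


@pytest.fixture(scope="session")
def axis() -> rx.WavenumberAxis:
    return rx.WavenumberAxis()


@pytest.fixture(scope="session")
def profiles():
    """Calibrated default cohort profiles (ratio targets pinned)."""
    return rx.calibrated_default_profiles()


@pytest.fixture(scope="session")
def cohort_sets(profiles):
    """Lazily generated, preprocessed 300-spectrum single-cohort datasets.

    Returned as a callable ``get(name) -> (raw_set, preprocessed_set)``; each
    cohort is drawn with a seed derived from the suite base seed and cached.
    """
    cache: dict[str, tuple] = {}

    def get(name: str):
        if name not in cache:
            offset = sum(ord(c) for c in name) % 1000
            raw = rx.generate_dataset({name: 300}, seed=SEED + offset, profiles=profiles)
            cache[name] = (raw, preprocess_set(raw))
        return cache[name]

    return get


@pytest.fixture(scope="session")
def four_cohort_pre(profiles):
    """Preprocessed default 4-cohort dataset (300 spectra per cohort)."""
    plan = {name: 300 for name in ("B_normal", "RS4;11", "REH", "MN60")}
    return preprocess_set(rx.generate_dataset(plan, seed=SEED, profiles=profiles))


@pytest.fixture(scope="session")
def mtx_cohort_pre(profiles):
    """Preprocessed normal-B + three MTX-treated cohorts (300 each)."""
    plan = {name: 300 for name in ("B_normal", "RS4;11_MTX", "REH_MTX", "MN60_MTX")}
    return preprocess_set(rx.generate_dataset(plan, seed=SEED + 1, profiles=profiles))


def make_band_spectrum(axis, bands, sid="s", label=""):
    """Deterministic sum-of-pseudo-Voigt spectrum for small oracles.

    ``bands`` is a list of (center, height, fwhm, gauss_fraction) tuples.
    """
    from ramandx.simulate import pseudo_voigt

    v = axis.values()
    y = np.zeros(axis.n_points)
    for center, height, fwhm, eta in bands:
        y += height * pseudo_voigt(v - center, fwhm, eta)
    return rx.Spectrum(axis=axis, intensities=y, id=sid, label=label)
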