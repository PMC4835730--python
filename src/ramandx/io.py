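"""Spectral data containers and file I/O.

The on-disk convention is a pair of CSV files: a *matrix* file whose first
column is ``wavenumber_cm1`` followed by one column of intensities per
spectrum, and an optional *labels* file with columns
``id,label,treatment,cohort_kind`` joined to the matrix by column name.
A minimal read-only JCAMP-DX importer is provided for interoperability
with the common spectroscopy exchange format.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WavenumberAxis",
    "Spectrum",
    "SpectrumSet",
    "SpectralFormatError",
    "read_spectra_csv",
    "write_spectra_csv",
    "read_jcampdx",
]

#: Allowed values of ``Spectrum.treatment``.
TREATMENTS = ("none", "MTX", "6MP", "ATRA")
#: Allowed values of ``Spectrum.cohort_kind`` (empty string = unknown).
COHORT_KINDS = ("normal", "cell_line", "clinical", "")

_AXIS_RTOL = 1e-6


class SpectralFormatError(ValueError):
    """Raised when a spectral file violates the expected format."""


@dataclass(frozen=True)
class WavenumberAxis:
    """Uniform wavenumber grid, in cm^-1.

    The default covers the fingerprint region 600-1799 cm^-1 at 1 cm^-1
    spacing: exactly 1200 points (the half-open interval [600, 1800)).
    """

    start: float = 600.0
    step: float = 1.0
    n_points: int = 1200

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("axis step must be positive")
        if self.n_points < 2:
            raise ValueError("axis needs at least 2 points")

    def values(self) -> np.ndarray:
        """The grid as a float array of shape ``(n_points,)``."""
        return self.start + self.step * np.arange(self.n_points, dtype=float)

    @property
    def stop(self) -> float:
        """Last grid point (inclusive)."""
        return self.start + self.step * (self.n_points - 1)

    def contains(self, wavenumber: float) -> bool:
        return self.start <= wavenumber <= self.stop

    def window(self, center: float, halfwidth: float) -> np.ndarray:
        """Boolean mask of points within ``center +- halfwidth``."""
        v = self.values()
        return (v >= center - halfwidth) & (v <= center + halfwidth)

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "WavenumberAxis":
        """Build an axis from explicit grid values, validating uniformity."""
        v = np.asarray(values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise SpectralFormatError("axis must be a 1-D array of >= 2 points")
        steps = np.diff(v)
        if np.any(steps <= 0):
            raise SpectralFormatError("wavenumber axis must be strictly increasing")
        step = steps.mean()
        if not np.allclose(steps, step, rtol=_AXIS_RTOL, atol=_AXIS_RTOL * max(1.0, step)):
            raise SpectralFormatError("wavenumber axis is not uniformly spaced")
        return cls(start=float(v[0]), step=float(step), n_points=int(v.size))


@dataclass
class Spectrum:
    """One cell's intensity trace on a shared wavenumber axis."""

    axis: WavenumberAxis
    intensities: np.ndarray
    id: str
    label: str = ""
    treatment: str = "none"
    cohort_kind: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (self.axis.n_points,):
            raise ValueError(
                f"spectrum {self.id!r}: {self.intensities.shape[0] if self.intensities.ndim == 1 else self.intensities.shape} "
                f"intensities for a {self.axis.n_points}-point axis"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError(f"spectrum {self.id!r}: non-finite intensities")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"spectrum {self.id!r}: unknown treatment {self.treatment!r}")
        if self.cohort_kind not in COHORT_KINDS:
            raise ValueError(f"spectrum {self.id!r}: unknown cohort_kind {self.cohort_kind!r}")

    def with_intensities(self, intensities: np.ndarray) -> "Spectrum":
        """Copy of this spectrum with replaced intensities (metadata kept)."""
        return replace(self, intensities=np.asarray(intensities, dtype=float), meta=dict(self.meta))


@dataclass
class SpectrumSet:
    """Ordered collection of spectra sharing one axis."""

    axis: WavenumberAxis
    spectra: list[Spectrum]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [s.id for s in self.spectra]
        if len(set(ids)) != len(ids):
            raise ValueError("spectrum ids are not unique")
        for s in self.spectra:
            if s.axis != self.axis:
                raise ValueError(f"spectrum {s.id!r} does not share the set axis")

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra)

    def matrix(self) -> np.ndarray:
        """Intensities stacked as a ``(n_spectra, n_points)`` array."""
        return np.vstack([s.intensities for s in self.spectra])

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.spectra]

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.spectra]

    def subset(self, labels: Iterable[str]) -> "SpectrumSet":
        """Spectra whose label is in ``labels``, order preserved."""
        wanted = set(labels)
        return SpectrumSet(
            axis=self.axis,
            spectra=[s for s in self.spectra if s.label in wanted],
            provenance=self.provenance,
        )

    def with_matrix(self, matrix: np.ndarray) -> "SpectrumSet":
        """Copy with per-spectrum intensities replaced row-by-row."""
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (len(self.spectra), self.axis.n_points):
            raise ValueError("matrix shape does not match the set")
        return SpectrumSet(
            axis=self.axis,
            spectra=[s.with_intensities(row) for s, row in zip(self.spectra, matrix)],
            provenance=self.provenance,
        )


# ---------------------------------------------------------------------------
# CSV matrix + labels files
# ---------------------------------------------------------------------------

def read_spectra_csv(matrix_path: str | Path, labels_path: str | Path | None = None) -> SpectrumSet:
    """Read a spectra matrix CSV (and optional labels CSV) into a SpectrumSet.

    The matrix file must have a ``wavenumber_cm1`` first column; every other
    column becomes one spectrum, in file order. Labels are joined by spectrum
    id; ids present in the labels file but absent from the matrix produce a
    warning, not an error.
    """
    df = pd.read_csv(matrix_path)
    if df.shape[1] < 2:
        raise SpectralFormatError(f"{matrix_path}: need a wavenumber column plus >= 1 spectrum")
    if df.columns[0] != "wavenumber_cm1":
        raise SpectralFormatError(f"{matrix_path}: first column must be 'wavenumber_cm1'")
    if df.isna().any().any():
        raise SpectralFormatError(f"{matrix_path}: ragged or missing values")
    axis = WavenumberAxis.from_values(df.iloc[:, 0].to_numpy())

    labels: Mapping[str, Mapping[str, str]] = {}
    if labels_path is not None:
        ldf = pd.read_csv(labels_path, dtype=str).fillna("")
        required = {"id", "label", "treatment", "cohort_kind"}
        if not required.issubset(ldf.columns):
            raise SpectralFormatError(
                f"{labels_path}: labels file needs columns {sorted(required)}"
            )
        labels = {row["id"]: row for _, row in ldf.iterrows()}
        missing = set(labels) - set(df.columns[1:])
        if missing:
            warnings.warn(
                f"{labels_path}: ids not present in matrix: {sorted(missing)}",
                stacklevel=2,
            )

    spectra = []
    for col in df.columns[1:]:
        row = labels.get(col, {})
        spectra.append(
            Spectrum(
                axis=axis,
                intensities=df[col].to_numpy(dtype=float),
                id=str(col),
                label=str(row.get("label", "")),
                treatment=str(row.get("treatment", "") or "none"),
                cohort_kind=str(row.get("cohort_kind", "")),
            )
        )
    return SpectrumSet(axis=axis, spectra=spectra, provenance=f"read from {matrix_path}")


def write_spectra_csv(
    sset: SpectrumSet, matrix_path: str | Path, labels_path: str | Path | None = None
) -> None:
    """Write a SpectrumSet as matrix (+ optional labels) CSV, preserving order."""
    if len(sset) == 0:
        raise ValueError("refusing to write an empty spectrum set")
    data: dict[str, np.ndarray] = {"wavenumber_cm1": sset.axis.values()}
    for s in sset:
        data[s.id] = s.intensities
    pd.DataFrame(data).to_csv(matrix_path, index=False)
    if labels_path is not None:
        pd.DataFrame(
            {
                "id": sset.ids,
                "label": sset.labels,
                "treatment": [s.treatment for s in sset],
                "cohort_kind": [s.cohort_kind for s in sset],
            }
        ).to_csv(labels_path, index=False)


# ---------------------------------------------------------------------------
# JCAMP-DX (read-only, single spectrum)
# ---------------------------------------------------------------------------

def _jcamp_records(text: str) -> dict[str, str]:
    """Split a JCAMP-DX block into LABEL -> content records."""
    records: dict[str, str] = {}
    label = None
    for line in text.splitlines():
        line = line.split("$$")[0].rstrip()  # strip comments
        if line.startswith("##"):
            name, _, rest = line[2:].partition("=")
            label = name.strip().upper().replace(" ", "").replace("-", "").replace("_", "")
            records[label] = rest.strip()
        elif label is not None and line.strip():
            records[label] += "\n" + line.strip()
    return records


def read_jcampdx(path: str | Path, axis: WavenumberAxis | None = None) -> Spectrum:
    """Read a single-block JCAMP-DX file onto ``axis`` (default axis if None).

    Supports ``##XYDATA=(X++(Y..Y))`` and ``##XYPOINTS=(XY..XY)`` records with
    ``XUNITS`` of 1/CM. Spectra on a different grid are linearly interpolated
    onto the target axis; the file must cover the full axis range.
    """
    axis = axis or WavenumberAxis()
    text = Path(path).read_text()
    if "##END" not in text.upper():
        raise SpectralFormatError(f"{path}: missing ##END record")
    if text.upper().count("##TITLE") > 1:
        raise SpectralFormatError(f"{path}: multi-block JCAMP files are not supported")
    records = _jcamp_records(text)
    if "TITLE" not in records:
        raise SpectralFormatError(f"{path}: missing ##TITLE record")
    xunits = records.get("XUNITS", "").upper()
    if xunits not in ("1/CM", "CM-1", "CM^-1"):
        raise SpectralFormatError(f"{path}: XUNITS must be 1/CM, got {xunits or 'nothing'!r}")

    if "XYDATA" in records:
        x, y = _parse_xydata(records, path)
    elif "XYPOINTS" in records:
        x, y = _parse_xypoints(records["XYPOINTS"], path)
    else:
        raise SpectralFormatError(f"{path}: need an ##XYDATA or ##XYPOINTS record")

    order = np.argsort(x)
    x, y = x[order], y[order]
    if x[0] > axis.start or x[-1] < axis.stop:
        raise SpectralFormatError(
            f"{path}: data cover {x[0]:g}-{x[-1]:g} cm-1 but the target axis "
            f"needs {axis.start:g}-{axis.stop:g} cm-1"
        )
    intensities = np.interp(axis.values(), x, y)
    return Spectrum(axis=axis, intensities=intensities, id=records.get("TITLE", Path(path).stem))


def _parse_xydata(records: dict[str, str], path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    body = records["XYDATA"]
    lines = body.splitlines()
    if not lines or "X++" not in lines[0].replace(" ", ""):
        raise SpectralFormatError(f"{path}: only (X++(Y..Y)) XYDATA is supported")
    yfac = float(records.get("YFACTOR", "1") or 1)
    try:
        firstx = float(records["FIRSTX"])
        lastx = float(records["LASTX"])
    except KeyError as exc:
        raise SpectralFormatError(f"{path}: XYDATA needs ##FIRSTX and ##LASTX") from exc
    ys: list[float] = []
    for line in lines[1:]:
        vals = [float(tok) for tok in line.replace(",", " ").split()]
        if not vals:
            continue
        # first value on each line is the X of its first Y; Ys are equidistant,
        # so the full X grid is reconstructed from FIRSTX/LASTX and the count
        ys.extend(v * yfac for v in vals[1:])
    if not ys:
        raise SpectralFormatError(f"{path}: empty XYDATA block")
    n = len(ys)
    x = np.array([firstx * 1.0]) if n == 1 else np.linspace(firstx, lastx, n)
    return x, np.array(ys)


def _parse_xypoints(body: str, path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    pairs: list[tuple[float, float]] = []
    for line in body.splitlines()[1:] if body.splitlines() and "XY" in body.splitlines()[0].upper() else body.splitlines():
        toks = line.replace(";", " ").replace(",", " ").split()
        for i in range(0, len(toks) - 1, 2):
            pairs.append((float(toks[i]), float(toks[i + 1])))
    if not pairs:
        raise SpectralFormatError(f"{path}: empty XYPOINTS block")
    arr = np.array(pairs, dtype=float)
    return arr[:, 0], arr[:, 1]
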