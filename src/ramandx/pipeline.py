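"""End-to-end driver: simulate -> preprocess -> PCA/LOOCV -> ratio diagnostics.

The pipeline is a chain of file-based stages, each of which writes both its
CSV artifacts and a JSON fragment; the final report merges the fragments.
Running the stages individually (the CLI subcommands) therefore produces
bit-identical output to :func:`run_pipeline`. All randomness flows from the
single config seed through a per-stage derivation, so each stage is
independently reproducible.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import band_metrics, chemometrics
from .io import SpectrumSet, WavenumberAxis, read_spectra_csv, write_spectra_csv
from .preprocess import PreprocessConfig, preprocess_set
from .simulate import ClassProfile, calibrated_default_profiles, generate_dataset

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed", "SCHEMA_VERSION"]

SCHEMA_VERSION = 1


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed (< 2^31) from the config seed."""
    return (int(seed) ^ zlib.crc32(stage.encode())) % (2**31)


def _pct(x: float) -> float:
    return round(100.0 * x, 1)


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one end-to-end run."""

    seed: int
    class_plan: dict[str, int]
    axis: WavenumberAxis = field(default_factory=WavenumberAxis)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    k: int = 3
    roc_pairs: list[tuple[str, str]] = field(default_factory=list)  # (positive, negative)
    profile_overrides: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cohorts = set(self.class_plan)
        for pos, neg in self.roc_pairs:
            if pos not in cohorts or neg not in cohorts:
                raise ValueError(f"roc pair ({pos!r}, {neg!r}) references unknown cohorts")

    @classmethod
    def default_study_plan(cls, seed: int = 0, n_per_cohort: int = 300) -> "PipelineConfig":
        """The four untreated cohorts, n spectra each, REH-vs-normal ROC."""
        return cls(
            seed=seed,
            class_plan={name: n_per_cohort for name in ("B_normal", "RS4;11", "REH", "MN60")},
            roc_pairs=[("REH", "B_normal")],
        )

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        axis = WavenumberAxis(**d.get("axis", {}))
        pp = PreprocessConfig(**d.get("preprocess", {}))
        return cls(
            seed=int(d["seed"]),
            class_plan={str(k): int(v) for k, v in d["class_plan"].items()},
            axis=axis,
            preprocess=pp,
            k=int(d.get("k", 3)),
            roc_pairs=[tuple(p) for p in d.get("roc_pairs", [])],
            profile_overrides={str(k): dict(v) for k, v in d.get("profiles", {}).items()},
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "class_plan": dict(self.class_plan),
            "axis": asdict(self.axis),
            "preprocess": asdict(self.preprocess),
            "k": self.k,
            "roc_pairs": [list(p) for p in self.roc_pairs],
            "profiles": self.profile_overrides,
        }

    def resolve_profiles(self) -> dict[str, ClassProfile]:
        """Calibrated default profiles with any config overrides applied."""
        profiles = calibrated_default_profiles(self.axis, self.preprocess)
        for name, overrides in self.profile_overrides.items():
            base = profiles[name].to_dict()
            base.update(overrides)
            profiles[name] = ClassProfile.from_dict(base)
        return profiles


# ---------------------------------------------------------------------------
# stages (each file-based: read CSVs, write CSVs + a JSON fragment)
# ---------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig, outdir: Path) -> SpectrumSet:
    sset = generate_dataset(
        config.class_plan,
        stage_seed(config.seed, "simulate"),
        profiles=config.resolve_profiles(),
        axis=config.axis,
    )
    write_spectra_csv(sset, outdir / "raw_spectra.csv", outdir / "labels.csv")
    return sset


def stage_preprocess(config: PipelineConfig, outdir: Path) -> SpectrumSet:
    raw = read_spectra_csv(outdir / "raw_spectra.csv", outdir / "labels.csv")
    pre = preprocess_set(raw, config.preprocess)
    write_spectra_csv(pre, outdir / "preprocessed_spectra.csv")
    return pre


def stage_pca(config: PipelineConfig, outdir: Path) -> dict:
    pre = read_spectra_csv(outdir / "preprocessed_spectra.csv", outdir / "labels.csv")
    model = chemometrics.fit_pca(pre, config.k)
    scores = chemometrics.project(model, pre)
    pd.DataFrame(
        scores, columns=[f"PC{i + 1}" for i in range(config.k)], index=pre.ids
    ).rename_axis("id").to_csv(outdir / "pca_scores.csv")
    loadings = pd.DataFrame(
        model.loadings.T,
        columns=[f"PC{i + 1}" for i in range(config.k)],
    )
    loadings.insert(0, "wavenumber_cm1", pre.axis.values())
    loadings.to_csv(outdir / "pca_loadings.csv", index=False)

    cm = chemometrics.loocv_classify(pre, k=config.k)
    eff = chemometrics.efficiency(cm)
    cm_df = pd.DataFrame(cm.counts, index=list(cm.labels), columns=list(cm.labels))
    cm_df.rename_axis("true\\predicted").to_csv(outdir / "confusion_matrix.csv")

    fragment = {
        "k": config.k,
        "explained_variance_fractions": [float(f) for f in model.explained_variance_fractions],
        "explained_variance_pct": [_pct(float(f)) for f in model.explained_variance_fractions],
        "loocv": {
            "labels": list(cm.labels),
            "counts": cm.counts.tolist(),
            "n_correct": int(np.trace(cm.counts)),
            "n_total": cm.total,
            "efficiency": eff,
            "efficiency_pct": _pct(eff),
        },
    }
    _write_json(outdir / "pca.json", fragment)
    return fragment


def stage_ratio(config: PipelineConfig, outdir: Path) -> dict:
    pre = read_spectra_csv(outdir / "preprocessed_spectra.csv", outdir / "labels.csv")
    hw = config.preprocess.band_halfwidth
    ratios = band_metrics.per_spectrum_ratios(pre, hw)
    stats = band_metrics.group_ratio_stats(pre, hw)
    pd.DataFrame(
        {
            "cohort": stats.cohorts,
            "mean_ratio": stats.means,
            "sd_ratio": stats.sds,
            "n": stats.ns,
        }
    ).to_csv(outdir / "ratio_table.csv", index=False)

    diagnostics = []
    roc_rows = []
    for pos, neg in config.roc_pairs:
        roc = band_metrics.roc_curve(ratios[pos], ratios[neg])
        rs = band_metrics.rank_sum_test(ratios[pos], ratios[neg])
        diagnostics.append(
            {
                "positive": pos,
                "negative": neg,
                "threshold": roc.threshold if np.isfinite(roc.threshold) else None,
                "sensitivity": roc.sensitivity,
                "sensitivity_pct": _pct(roc.sensitivity),
                "specificity": roc.specificity,
                "specificity_pct": _pct(roc.specificity),
                "youden_j": roc.youden_j,
                "rank_sum_u": rs.u,
                "p_value": rs.p_value,
                "p_method": rs.method,
            }
        )
        for t, se, sp in zip(roc.thresholds, roc.sensitivities, roc.specificities):
            roc_rows.append(
                {"positive": pos, "negative": neg, "threshold": t, "sensitivity": se, "specificity": sp}
            )
    if roc_rows:
        pd.DataFrame(roc_rows).to_csv(outdir / "roc_curve.csv", index=False)

    fragment = {"ratio_stats": stats.as_dict(), "diagnostics": diagnostics}
    _write_json(outdir / "ratio.json", fragment)
    return fragment


def stage_report(config: PipelineConfig, outdir: Path) -> dict:
    """Merge the stage fragments into the final machine-readable report."""
    report = {
        "schema_version": SCHEMA_VERSION,
        "config": config.to_dict(),
        "n_spectra": int(sum(config.class_plan.values())),
        "pca": _read_json(outdir / "pca.json"),
        "ratio": _read_json(outdir / "ratio.json"),
    }
    _write_json(outdir / "report.json", report)
    return report


_STAGES = ("simulate", "preprocess", "pca", "ratio", "report")


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run all stages in order; identical config + seed => identical report.

    On a stage failure, the partial outputs written during this run are
    removed and the error is re-raised with the stage name attached.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    before = set(outdir.iterdir())
    stages = (
        ("simulate", stage_simulate),
        ("preprocess", stage_preprocess),
        ("pca", stage_pca),
        ("ratio", stage_ratio),
        ("report", stage_report),
    )
    result: dict = {}
    for name, fn in stages:
        try:
            result = fn(config, outdir)
        except Exception as exc:
            for path in set(outdir.iterdir()) - before:
                if path.is_file():
                    path.unlink()
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
    return result


def _write_json(path: Path, obj: dict) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _read_json(path: Path) -> dict:
    return json.loads(path.read_text())
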