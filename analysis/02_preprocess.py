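#!/usr/bin/env python
"""Preprocess the simulated cohorts: align to the set median, remove the
fluorescence baseline with the iterative cubic fit, normalize at amide I.

Reads results/cohorts/raw_spectra.csv, writes preprocessed_spectra.csv and the
per-cohort mean spectra (the inputs to the difference-spectrum comparison).
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

import ramandx as rx
from ramandx.band_metrics import mean_spectrum
from ramandx.preprocess import preprocess_set

OUT = Path(__file__).resolve().parent.parent / "results" / "cohorts"


def main() -> None:
    raw = rx.read_spectra_csv(OUT / "raw_spectra.csv", OUT / "labels.csv")
    pre = preprocess_set(raw)
    rx.write_spectra_csv(pre, OUT / "preprocessed_spectra.csv")

    cohorts = sorted(set(pre.labels))
    means = {"wavenumber_cm1": pre.axis.values()}
    for name in cohorts:
        means[name] = mean_spectrum(pre, name).intensities
    b = means.get("B_normal")
    diffs = {"wavenumber_cm1": pre.axis.values()}
    for name in cohorts:
        if name != "B_normal" and b is not None:
            diffs[f"{name}-B_normal"] = means[name] - b
    pd.DataFrame(means).to_csv(OUT / "mean_spectra.csv", index=False)
    pd.DataFrame(diffs).to_csv(OUT / "difference_spectra.csv", index=False)
    print(f"preprocessed {len(pre)} spectra; wrote mean and difference spectra "
          f"for {len(cohorts)} cohorts")


if __name__ == "__main__":
    main()
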