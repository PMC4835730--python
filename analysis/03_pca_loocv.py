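#!/usr/bin/env python
"""PCA of the preprocessed cohorts and leave-one-out classification.

Reports the PC1-3 explained variance, writes scores/loadings, and runs the
per-fold-refit leave-one-out nearest-centroid classification whose confusion
matrix and efficiency are the study's main diagnostic readout.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

import ramandx as rx

OUT = Path(__file__).resolve().parent.parent / "results" / "cohorts"


def main() -> None:
    pre = rx.read_spectra_csv(OUT / "preprocessed_spectra.csv", OUT / "labels.csv")
    model = rx.fit_pca(pre, 3)
    evf = model.explained_variance_fractions
    print("explained variance: " + ", ".join(
        f"PC{i + 1} {100 * f:.1f}%" for i, f in enumerate(evf)
    ) + f" (PC1-3 total {100 * evf.sum():.1f}%)")

    scores = rx.project(model, pre)
    df = pd.DataFrame(scores, columns=["PC1", "PC2", "PC3"])
    df.insert(0, "id", pre.ids)
    df.insert(1, "label", pre.labels)
    df.to_csv(OUT / "pca_scores.csv", index=False)
    loadings = pd.DataFrame(model.loadings.T, columns=["PC1", "PC2", "PC3"])
    loadings.insert(0, "wavenumber_cm1", pre.axis.values())
    loadings.to_csv(OUT / "pca_loadings.csv", index=False)

    cm = rx.loocv_classify(pre, k=3)
    eff = rx.efficiency(cm)
    pd.DataFrame(cm.counts, index=list(cm.labels), columns=list(cm.labels)) \
        .rename_axis("true\\predicted").to_csv(OUT / "confusion_matrix.csv")
    print(f"LOOCV: {int(np.trace(cm.counts))}/{cm.total} correct "
          f"-> efficiency {100 * eff:.1f}%")


if __name__ == "__main__":
    main()
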