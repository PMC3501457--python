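"""Project the four wavelet attributes spanning the Cat2 -> Max3 region
(w5coef24 ... w5coef27) into the plane with RadViz and quantify how
line-like each tissue's point cloud is.

An optional scatter plot is written to scratch/ when matplotlib rendering
is wanted; the per-tissue collinearity table goes to results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from voltfp.classify import build_feature_table
from voltfp.extremes import clean_dataset
from voltfp.radviz import project_wavelet_subset
from voltfp.synthetic import (DEFAULT_OUTLIER_FLAGS, DatasetSpec,
                              generate_dataset, make_tissue_profiles)

SEED = 1
ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"


def main():
    OUT.mkdir(exist_ok=True)
    spec = DatasetSpec(outlier_flags=list(DEFAULT_OUTLIER_FLAGS), seed=SEED)
    dataset = generate_dataset(spec, make_tissue_profiles(SEED))
    cleaned, _ = clean_dataset(dataset, manual_flags=list(DEFAULT_OUTLIER_FLAGS))
    table = build_feature_table(cleaned, "wavelet32")
    pts = project_wavelet_subset(table)
    print(f"projected {len(pts)} curves onto 4 anchors")

    rows = []
    for tissue, sub in pts.groupby("tissue"):
        xy = sub[["u1", "u2"]].to_numpy()
        xy = xy - xy.mean(axis=0)
        ev = np.linalg.svd(xy, compute_uv=False) ** 2
        rows.append({"tissue": tissue, "n": len(sub),
                     "pc1_variance_fraction": round(float(ev[0] / ev.sum()), 4)})
    frame = pd.DataFrame(rows).sort_values("tissue")
    frame.to_csv(OUT / "radviz_collinearity.csv", index=False)
    print(frame.to_string(index=False))

    scratch = ROOT / "scratch"
    scratch.mkdir(exist_ok=True)
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(6, 6))
        for tissue, sub in pts.groupby("tissue"):
            ax.scatter(sub["u1"], sub["u2"], s=8, label=tissue)
        ax.set_aspect("equal")
        ax.legend(fontsize=7)
        fig.savefig(scratch / "radviz.png", dpi=150)
        print(f"scatter -> {scratch / 'radviz.png'}")
    except Exception as exc:          # plotting is best-effort
        print(f"plot skipped: {exc}")


if __name__ == "__main__":
    main()
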