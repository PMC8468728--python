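"""Unsupervised exploration: PCA, metabolite clustering, biomarker correlations.

Writes PCA scores/loadings (group separation shows on PC1), the Ward leaf
order of the differential metabolites, and Spearman screens of every
metabolite against LysoGb3 and residual enzyme activity in patients.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from fabrynet import hierarchical_cluster, run_pca
from fabrynet.core_data import read_matrix, read_metadata
from fabrynet.multivariate import spearman_biomarker_screen


def main(
    cohort_dir: str = "results/cohort",
    processed_dir: str = "results/processed",
    out_dir: str = "results/explore",
) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix = read_matrix(Path(processed_dir) / "matrix_processed.csv", scale="log-pareto")
    meta = read_metadata(Path(cohort_dir) / "metadata.csv")

    pca = run_pca(matrix, n_components=5)
    pca.scores.join(meta.table[["group", "sex", "phenotype"]]).to_csv(out / "pca_scores.csv")
    pca.loadings.to_csv(out / "pca_loadings.csv")
    pc1 = float(pca.explained_ratio[0]) * 100
    (out / "pca_explained.json").write_text(
        json.dumps({"explained_pct": [float(r) * 100 for r in pca.explained_ratio[:10]]})
    )

    # cluster metabolites on their processed profiles (Euclidean/Ward)
    _, leaf_order = hierarchical_cluster(matrix.data.T)
    (out / "metabolite_dendrogram_order.json").write_text(json.dumps(list(leaf_order)))

    screens = spearman_biomarker_screen(matrix, meta)
    for name, scr in screens.items():
        scr.to_csv(out / f"spearman_{name}.csv")
        top = scr[scr["p_adjusted"] < 0.05]
        print(f"{name}: {len(top)} metabolites with adjusted p < 0.05")
    print(f"PC1 explains {pc1:.1f}% of the variance")
    return out


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", default="results/cohort")
    ap.add_argument("--processed", default="results/processed")
    ap.add_argument("--out", default="results/explore")
    args = ap.parse_args()
    main(args.cohort, args.processed, args.out)
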