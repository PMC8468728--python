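"""Preprocess the cohort matrix: KNN-impute, log2, pareto-scale.

Reads results/cohort/, writes the processed matrix and an imputation report
under results/processed/.
"""

import argparse
import json
from pathlib import Path

from fabrynet import preprocess
from fabrynet.core_data import read_matrix, write_matrix


def main(in_dir: str = "results/cohort", out_dir: str = "results/processed") -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix = read_matrix(Path(in_dir) / "matrix.csv")
    processed, report = preprocess(matrix)
    write_matrix(processed, out / "matrix_processed.csv")
    (out / "report.json").write_text(
        json.dumps(
            {
                "n_imputed": report.n_imputed,
                "n_row_fallbacks": report.n_row_fallbacks,
                "zero_variance_columns": report.zero_variance_columns,
            },
            indent=1,
        )
    )
    print(f"imputed {report.n_imputed} cells; matrix now {processed.scale} -> {out}")
    return out


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--in", dest="in_dir", default="results/cohort")
    ap.add_argument("--out", default="results/processed")
    args = ap.parse_args()
    main(args.in_dir, args.out)
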