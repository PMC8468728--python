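"""Generate the synthetic study cohort.

Emulates the study conditions: 60 control and 66 Fabry plasma samples on a
188-metabolite p180-style panel, 86 planted differential metabolites at
1.5 SD, a 13-metabolite disease module with disease-only partial-correlation
edges, sex/age covariate effects, 2% sporadic missingness, and patient
LysoGb3 / residual-enzyme-activity biomarkers coupled to a planted
metabolite.  Writes the cohort tables and the ground truth under
results/cohort/.
"""

import argparse
from pathlib import Path

from fabrynet import SimulationConfig, attach_biomarkers, simulate_cohort
from fabrynet.core_data import write_annotation, write_matrix, write_metadata


def main(seed: int = 0, out_dir: str = "results/cohort") -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, meta, anno, truth = simulate_cohort(SimulationConfig(seed=seed))
    meta = attach_biomarkers(meta, matrix, truth, seed=seed + 1, rho_lysogb3=0.6, rho_rea=-0.5)
    write_matrix(matrix, out / "matrix.csv")
    write_metadata(meta, out / "metadata.csv")
    write_annotation(anno, out / "annotation.csv")
    truth.to_json(out / "truth.json")
    counts = meta.group_counts()
    print(
        f"cohort: {counts['control']} controls + {counts['fabry']} patients, "
        f"{matrix.shape[1]} metabolites, {matrix.n_missing} missing cells -> {out}"
    )
    return out


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", default="results/cohort")
    args = ap.parse_args()
    main(args.seed, args.out)
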