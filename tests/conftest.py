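import numpy as np
import pandas as pd
import pytest

from fabrynet import SimulationConfig, simulate_cohort, attach_biomarkers, preprocess
from fabrynet.core_data import MetaboliteMatrix, SampleMetadata, MetaboliteAnnotation


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (60 controls + 66 patients, 188 metabolites)."""
    matrix, meta, anno, truth = simulate_cohort(SimulationConfig(seed=11))
    meta = attach_biomarkers(meta, matrix, truth, seed=12, rho_lysogb3=0.6, rho_rea=-0.5)
    return matrix, meta, anno, truth


@pytest.fixture(scope="session")
def processed_cohort(default_cohort):
    matrix, meta, anno, truth = default_cohort
    processed, _ = preprocess(matrix)
    return processed, meta, anno, truth


def tiny_matrix(values, sample_ids=None, metabolite_ids=None, scale="raw"):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    sample_ids = sample_ids or [f"S{i+1}" for i in range(n)]
    metabolite_ids = metabolite_ids or [f"m{j+1}" for j in range(p)]
    return MetaboliteMatrix(
        pd.DataFrame(values, index=pd.Index(sample_ids, name="sample_id"), columns=metabolite_ids),
        scale=scale,
    )


def tiny_metadata(groups, sexes=None, ages=None, sample_ids=None):
    n = len(groups)
    sample_ids = sample_ids or [f"S{i+1}" for i in range(n)]
    return SampleMetadata(
        pd.DataFrame(
            {
                "group": groups,
                "sex": sexes or (["F", "M"] * ((n + 1) // 2))[:n],
                "age": ages or [30.0 + i for i in range(n)],
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )


def tiny_annotation(metabolite_ids, cls="amino_acid"):
    return MetaboliteAnnotation(
        pd.DataFrame({"class": [cls] * len(metabolite_ids)}, index=pd.Index(metabolite_ids, name="metabolite_id"))
    )
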