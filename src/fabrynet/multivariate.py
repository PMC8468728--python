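"""Unsupervised structure: PCA, Spearman biomarker screens, hierarchical clustering."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .core_data import MetaboliteMatrix, SampleMetadata
from .differential import adjust_benjamini_yekutieli


@dataclass
class PcaResult:
    scores: pd.DataFrame        # samples x components
    loadings: pd.DataFrame      # metabolites x components
    explained_ratio: np.ndarray  # over all min(n-1, p) components


def run_pca(matrix: MetaboliteMatrix, n_components: int | None = None) -> PcaResult:
    """Column-centered SVD PCA.

    ``explained_ratio`` spans all components (sums to 1); ``scores`` and
    ``loadings`` keep the first ``n_components``.  Component signs are fixed
    so each loading vector's largest-magnitude entry is positive.
    """
    x = matrix.values()
    if np.isnan(x).any():
        raise ValueError("PCA requires a fully observed matrix")
    n, p = x.shape
    max_rank = min(n - 1, p)
    if n_components is None:
        n_components = max_rank
    if n_components > max_rank:
        raise ValueError(f"n_components={n_components} exceeds min(n-1, p)={max_rank}")
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    s = s[:max_rank]
    u = u[:, :max_rank]
    vt = vt[:max_rank]
    var = s**2
    explained = var / var.sum() if var.sum() > 0 else var
    # deterministic sign: largest-|entry| of each loading vector positive
    for k in range(n_components):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    comp_names = [f"PC{k+1}" for k in range(n_components)]
    scores = pd.DataFrame(
        (u[:, :n_components] * s[:n_components]), index=matrix.data.index, columns=comp_names
    )
    loadings = pd.DataFrame(vt[:n_components].T, index=matrix.data.columns, columns=comp_names)
    return PcaResult(scores=scores, loadings=loadings, explained_ratio=explained)


def spearman_screen(
    matrix: MetaboliteMatrix,
    targets: pd.Series,
    sample_ids: list[str] | None = None,
    adjust: str = "bh",
) -> pd.DataFrame:
    """Spearman rho of every metabolite against a biomarker, with FDR.

    ``targets`` is a per-sample biomarker (e.g. LysoGb3 or residual enzyme
    activity), typically restricted to the patient samples via
    ``sample_ids``.  Ties are handled by midranks; p-values come from the
    t approximation and are adjusted across the whole screen.
    """
    ids = list(targets.index) if sample_ids is None else list(sample_ids)
    ids = [s for s in ids if s in matrix.data.index and pd.notna(targets.get(s))]
    if len(ids) < 5:
        raise ValueError("need at least 5 samples with observed biomarker values")
    y = targets.loc[ids].to_numpy(dtype=float)
    rows = []
    for met in matrix.metabolite_ids:
        x = matrix.data.loc[ids, met].to_numpy(dtype=float)
        ok = ~np.isnan(x)
        if ok.sum() < 5:
            rows.append((met, np.nan, np.nan))
            continue
        rho, p = stats.spearmanr(x[ok], y[ok])
        rows.append((met, float(rho), float(p)))
    out = pd.DataFrame(rows, columns=["metabolite_id", "rho", "p"]).set_index("metabolite_id")
    valid = out["p"].notna()
    q = np.full(len(out), np.nan)
    if valid.any():
        q[valid.to_numpy()] = adjust_benjamini_yekutieli(out.loc[valid, "p"].to_numpy(), method=adjust)
    out["p_adjusted"] = q
    return out.sort_values("p", kind="stable")


def spearman_biomarker_screen(
    matrix: MetaboliteMatrix, meta: SampleMetadata, adjust: str = "bh"
) -> dict[str, pd.DataFrame]:
    """Screen all metabolites against LysoGb3 and residual enzyme activity
    on the Fabry samples (controls lack these biomarkers)."""
    fabry = meta.ids_of("fabry")
    out = {}
    for biomarker in ("lysoGb3", "residual_enzyme_activity"):
        values = meta.table[biomarker]
        out[biomarker] = spearman_screen(matrix, values, sample_ids=fabry, adjust=adjust)
    return out


def hierarchical_cluster(
    data: pd.DataFrame, linkage_method: str = "ward"
) -> tuple[np.ndarray, list]:
    """Agglomerative clustering of rows on Euclidean distances.

    Returns the scipy linkage matrix and the deterministic leaf order
    (ties broken by lower original index, scipy's stable convention).
    """
    if len(data) < 2:
        raise ValueError("need at least 2 items to cluster")
    x = data.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("clustering requires fully observed data")
    z = hierarchy.linkage(pdist(x, metric="euclidean"), method=linkage_method)
    order = hierarchy.leaves_list(z)
    return z, [data.index[i] for i in order]
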