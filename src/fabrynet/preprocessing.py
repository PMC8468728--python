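"""Concentration-matrix preprocessing: KNN imputation, log transform, pareto scaling.

The chain is fixed as impute -> log -> pareto.  Imputing raw concentrations
by nearest-neighbour averaging keeps imputed values positive, so the log is
always defined; pareto scaling, (x - mean)/sqrt(sd), then centres each
metabolite while down-weighting high-variance metabolites less aggressively
than unit-variance scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import MetaboliteMatrix


@dataclass
class PreprocessConfig:
    log_base: float = 2.0
    knn_k: int = 10
    impute_axis: str = "metabolites"  # rows used as neighbours
    scaling: str = "pareto"           # "pareto" or "none"

    def validate(self) -> None:
        if self.log_base <= 1:
            raise ValueError("log_base must be > 1")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")
        if self.impute_axis not in ("metabolites", "samples"):
            raise ValueError("impute_axis must be 'metabolites' or 'samples'")
        if self.scaling not in ("pareto", "none"):
            raise ValueError("scaling must be 'pareto' or 'none'")


@dataclass
class PreprocessReport:
    n_imputed: int = 0
    n_row_fallbacks: int = 0
    zero_variance_columns: list = field(default_factory=list)


def _knn_impute_rows(values: np.ndarray, k: int, max_row_missing: float = 0.5):
    """Impute missing cells row-wise by averaging the k nearest rows.

    Distance between two rows is the Euclidean distance over their mutually
    observed columns (unscaled, as in nearest-neighbour averaging of
    expression rows).  Rows missing more than ``max_row_missing`` of their
    cells fall back to the per-column mean, as do cells whose candidate
    neighbours are all unobserved in that column.
    """
    x = values.copy()
    n_rows, n_cols = x.shape
    obs = ~np.isnan(x)
    if not obs.any(axis=0).all():
        bad = np.where(~obs.any(axis=0))[0]
        raise ValueError(f"columns with all values missing: {list(bad)}")
    col_means = np.nanmean(x, axis=0)

    out = x.copy()
    n_imputed = 0
    n_fallback = 0
    row_missing_frac = (~obs).mean(axis=1)
    for i in range(n_rows):
        miss_cols = np.where(~obs[i])[0]
        if miss_cols.size == 0:
            continue
        if row_missing_frac[i] > max_row_missing:
            out[i, miss_cols] = col_means[miss_cols]
            n_fallback += 1
            n_imputed += miss_cols.size
            continue
        # distances from row i to all other rows over shared observed columns
        shared = obs[i] & obs  # (n_rows, n_cols)
        diff = x[i] - x
        diff = np.where(shared, diff, 0.0)
        n_shared = shared.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            dist = np.sqrt((diff**2).sum(axis=1))
        dist[i] = np.inf
        dist[n_shared == 0] = np.inf
        order = np.argsort(dist, kind="stable")
        for j in miss_cols:
            donors = [r for r in order if np.isfinite(dist[r]) and obs[r, j]][:k]
            if donors:
                out[i, j] = x[donors, j].mean()
            else:
                out[i, j] = col_means[j]
            n_imputed += 1
    return out, n_imputed, n_fallback


def knn_impute(
    matrix: MetaboliteMatrix, k: int = 10, axis: str = "metabolites"
) -> tuple[MetaboliteMatrix, PreprocessReport]:
    """Nearest-neighbour-averaging imputation.

    With ``axis='metabolites'`` (default, the convention for omics matrices)
    metabolites are the rows being matched to their nearest neighbours;
    ``axis='samples'`` matches samples instead.
    """
    if axis not in ("metabolites", "samples"):
        raise ValueError("axis must be 'metabolites' or 'samples'")
    values = matrix.values()
    if axis == "metabolites":
        filled, n_imp, n_fb = _knn_impute_rows(values.T, k)
        filled = filled.T
    else:
        filled, n_imp, n_fb = _knn_impute_rows(values, k)
    report = PreprocessReport(n_imputed=n_imp, n_row_fallbacks=n_fb)
    out = matrix.with_data(pd.DataFrame(filled, index=matrix.data.index, columns=matrix.data.columns))
    return out, report


def log_transform(matrix: MetaboliteMatrix, base: float = 2.0) -> MetaboliteMatrix:
    """Elementwise logarithm; requires strictly positive values."""
    if base <= 1:
        raise ValueError("log base must be > 1")
    values = matrix.values()
    bad = np.argwhere(np.nan_to_num(values, nan=1.0) <= 0)
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"non-positive value at sample {matrix.data.index[r]!r}, "
            f"metabolite {matrix.data.columns[c]!r}; cannot log-transform"
        )
    out = np.log(values) / np.log(base)
    return matrix.with_data(
        pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns), scale="log"
    )


def pareto_scale(matrix: MetaboliteMatrix) -> tuple[MetaboliteMatrix, PreprocessReport]:
    """Per-metabolite (x - mean) / sqrt(sd), sd with the n-1 denominator.

    Zero-variance metabolites map to all-zero columns (flagged in the
    report) rather than NaN.
    """
    values = matrix.values()
    if np.isnan(values).any():
        raise ValueError("pareto scaling requires a fully observed matrix; impute first")
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    zero_var = sd == 0
    denom = np.where(zero_var, 1.0, np.sqrt(sd))
    out = (values - mean) / denom
    out[:, zero_var] = 0.0
    report = PreprocessReport(
        zero_variance_columns=[matrix.data.columns[j] for j in np.where(zero_var)[0]]
    )
    scaled = matrix.with_data(
        pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns),
        scale="log-pareto",
    )
    return scaled, report


def preprocess(
    matrix: MetaboliteMatrix, cfg: PreprocessConfig | None = None
) -> tuple[MetaboliteMatrix, PreprocessReport]:
    """Full chain: impute -> log -> pareto (or log only with scaling='none')."""
    cfg = cfg or PreprocessConfig()
    cfg.validate()
    report = PreprocessReport()
    if matrix.n_missing:
        matrix, rep_imp = knn_impute(matrix, k=cfg.knn_k, axis=cfg.impute_axis)
        report.n_imputed = rep_imp.n_imputed
        report.n_row_fallbacks = rep_imp.n_row_fallbacks
    matrix = log_transform(matrix, base=cfg.log_base)
    if cfg.scaling == "pareto":
        matrix, rep_scale = pareto_scale(matrix)
        report.zero_variance_columns = rep_scale.zero_variance_columns
    return matrix, report
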