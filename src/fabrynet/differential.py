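"""Covariate-adjusted differential analysis with empirical-Bayes moderation.

Per metabolite g, an ordinary least-squares fit of the processed abundance
on [intercept, group, sex, age] yields the group coefficient ("logFC" on the
processed scale), the residual variance s_g^2 and its degrees of freedom
d_g.  Variances are then shrunk toward a common prior by empirical Bayes:

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

with the prior (d0, s0^2) estimated by moment-matching of log s_g^2 through
digamma/trigamma relations, exploiting that d*s^2/sigma^2 is chi-squared
and that sigma^2 is inverse-gamma across metabolites.  The moderated
statistic t_g = beta_g / (s~_g * sqrt(v_g)) is referred to a Student t with
d0 + d_g degrees of freedom.  False discovery rates default to the
Benjamini–Yekutieli step-up, which is valid under arbitrary dependency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .core_data import MetaboliteMatrix, SampleMetadata, MetaboliteAnnotation


@dataclass
class ModerationPrior:
    d0: float      # prior degrees of freedom (may be inf)
    s0_sq: float   # prior variance

    def __post_init__(self) -> None:
        if not (self.d0 >= 0):
            raise ValueError("prior degrees of freedom must be non-negative")
        if not (self.s0_sq > 0):
            raise ValueError("prior variance must be positive")


def build_design(meta: SampleMetadata) -> tuple[np.ndarray, list[str]]:
    """Design matrix [intercept, group(fabry=1), sex(M=1), age centered]."""
    t = meta.table
    x = np.column_stack(
        [
            np.ones(len(t)),
            (t["group"] == "fabry").to_numpy(dtype=float),
            (t["sex"] == "M").to_numpy(dtype=float),
            t["age"].to_numpy(dtype=float) - t["age"].to_numpy(dtype=float).mean(),
        ]
    )
    names = ["intercept", "group", "sex", "age"]
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify collinear columns by checking each against the rest
        collinear = []
        for j in range(x.shape[1]):
            rest = np.delete(x, j, axis=1)
            if np.linalg.matrix_rank(rest) == rank:
                collinear.append(names[j])
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")
    return x, names


def fit_linear_models(matrix: MetaboliteMatrix, meta: SampleMetadata) -> pd.DataFrame:
    """Per-metabolite OLS; returns beta (group), s2, df, and the design-based
    variance factor v of the group coefficient."""
    y = matrix.values()
    if np.isnan(y).any():
        raise ValueError("matrix must be fully observed; run preprocessing first")
    x, _ = build_design(meta)
    n, k = x.shape
    if list(matrix.sample_ids) != list(meta.sample_ids):
        raise ValueError("matrix and metadata sample order differ; align first")
    xtx_inv = np.linalg.inv(x.T @ x)
    beta_all = xtx_inv @ x.T @ y                     # (k, p)
    resid = y - x @ beta_all
    df = n - k
    s2 = (resid**2).sum(axis=0) / df
    v_group = xtx_inv[1, 1]
    return pd.DataFrame(
        {
            "logFC": beta_all[1],
            "s2": s2,
            "df": float(df),
            "v": v_group,
        },
        index=pd.Index(matrix.metabolite_ids, name="metabolite_id"),
    )


def _trigamma_inverse(y: float, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone, convex)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif / x) < 1e-8:
            break
    return x


def estimate_prior(s2: np.ndarray, df: np.ndarray) -> ModerationPrior:
    """Moment-match the scaled-F distribution of the residual variances.

    Works on z = log s^2: its mean and excess variance relative to the
    chi-squared theory give s0^2 and d0 via digamma/trigamma identities.
    If the empirical dispersion is at or below theory, d0 is infinite and
    s0^2 is the plain mean of the variances.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    pos = s2 > 0
    if pos.sum() == 0:
        raise ValueError("all residual variances are zero; cannot moderate")
    if pos.sum() < 10:
        raise ValueError("need at least 10 positive residual variances")
    z = np.log(s2[pos])
    d = df[pos]
    e = z - special.digamma(d / 2) + np.log(d / 2)
    emean = e.mean()
    evar = ((e - emean) ** 2).sum() / (e.size - 1)
    evar -= float(np.mean(special.polygamma(1, d / 2)))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2) - np.log(d0 / 2)))
    else:
        d0 = np.inf
        s0_sq = float(s2[pos].mean())
    return ModerationPrior(d0=d0, s0_sq=s0_sq)


def apply_moderation(fits: pd.DataFrame, prior: ModerationPrior) -> pd.DataFrame:
    """Compute moderated variances, t-statistics and p-values under a prior.

    With d0 = 0 this reduces to the ordinary per-metabolite t-test; with
    d0 = inf every variance collapses to s0^2 and t is referred to a normal.
    """
    s2 = fits["s2"].to_numpy(dtype=float)
    df = fits["df"].to_numpy(dtype=float)
    if np.isinf(prior.d0):
        s2_mod = np.full_like(s2, prior.s0_sq)
        df_total = np.full_like(df, np.inf)
    else:
        s2_mod = (prior.d0 * prior.s0_sq + df * s2) / (prior.d0 + df)
        df_total = prior.d0 + df
    t = fits["logFC"].to_numpy() / np.sqrt(s2_mod * fits["v"].to_numpy())
    finite = np.isfinite(df_total)
    p = np.empty_like(t)
    p[finite] = 2 * stats.t.sf(np.abs(t[finite]), df_total[finite])
    p[~finite] = 2 * stats.norm.sf(np.abs(t[~finite]))
    out = fits.copy()
    out["s2_moderated"] = s2_mod
    out["t"] = t
    out["df_total"] = df_total
    out["p"] = p
    return out


def ebayes_moderate(fits: pd.DataFrame) -> tuple[ModerationPrior, pd.DataFrame]:
    """Estimate the variance prior and moderate every metabolite's statistics."""
    prior = estimate_prior(fits["s2"].to_numpy(), fits["df"].to_numpy())
    return prior, apply_moderation(fits, prior)


def adjust_benjamini_yekutieli(p: np.ndarray, method: str = "by") -> np.ndarray:
    """Step-up FDR adjustment; ``method`` is 'by' (default) or 'bh'.

    BY inflates by the harmonic factor c(m) = sum 1/k, giving control under
    arbitrary dependency among the tests.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if method not in ("by", "bh"):
        raise ValueError("method must be 'by' or 'bh'")
    if p.size == 0:
        return p.copy()
    _, q, _, _ = multipletests(p, method={"by": "fdr_by", "bh": "fdr_bh"}[method])
    return q


def differential_pipeline(
    matrix: MetaboliteMatrix,
    meta: SampleMetadata,
    anno: MetaboliteAnnotation,
    alpha: float = 0.05,
    fdr_method: str = "by",
) -> tuple[pd.DataFrame, dict]:
    """Full differential analysis on an aligned, processed cohort.

    Returns the per-metabolite table (sorted by raw p) and a summary with
    the number of significant metabolites and their class composition
    (lysophosphatidylcholines folded into glycerophospholipids).
    """
    fits = fit_linear_models(matrix, meta)
    prior, table = ebayes_moderate(fits)
    table["p_adjusted"] = adjust_benjamini_yekutieli(table["p"].to_numpy(), method=fdr_method)
    # alpha >= 1 is an everything-passes boundary (adjusted p is capped at 1)
    table["significant"] = table["p_adjusted"] < alpha if alpha < 1 else True
    table = table.sort_values("p", kind="stable")
    sig_ids = list(table.index[table["significant"]])
    summary = {
        "n_significant": len(sig_ids),
        "alpha": alpha,
        "fdr_method": fdr_method,
        "prior_d0": prior.d0,
        "prior_s0_sq": prior.s0_sq,
        "composition": anno.composition(sig_ids) if sig_ids else {},
    }
    return table, summary
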