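"""Exhaustive random-forest evaluation of consensus-metabolite subsets.

Every non-empty subset of the consensus signature is scored by repeated
stratified cross-validation: per repeat, out-of-fold class probabilities
are pooled over the folds and summarized as an ROC AUC; the subset's AUC is
the mean over repeats.  The 95% CI comes from a percentile bootstrap over
samples of the per-sample mean out-of-fold probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .core_data import MetaboliteMatrix, SampleMetadata

MAX_CONSENSUS = 20  # guard against combinatorial blowup (2^20 subsets)


@dataclass
class CvConfig:
    folds: int = 5
    repeats: int = 50
    n_trees: int = 500
    max_features: str | float = "sqrt"
    class_weight: str = "balanced_subsample"
    n_bootstrap: int = 2000


@dataclass
class ModelEvaluation:
    subset: tuple
    auc: float
    ci_low: float
    ci_high: float
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    mean_oof_prob: pd.Series  # per-sample probability of the disease class
    repeats: int
    seed: int


def enumerate_subsets(members: list, max_size: int | None = None) -> list[tuple]:
    """All non-empty subsets in deterministic order (size, then lexicographic)."""
    members = sorted(members)
    if not 1 <= len(members) <= MAX_CONSENSUS:
        raise ValueError(
            f"consensus size {len(members)} outside [1, {MAX_CONSENSUS}]; "
            "reduce it via the consensus frequency threshold"
        )
    top = len(members) if max_size is None else min(max_size, len(members))
    out: list[tuple] = []
    for size in range(1, top + 1):
        out.extend(combinations(members, size))
    return out


def subset_seed(master_seed: int, index: int) -> int:
    """Deterministic per-subset seed below 2^31."""
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0] % (2**31 - 1))


def _bootstrap_auc_ci(
    y: np.ndarray, prob: np.ndarray, n_boot: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Percentile bootstrap over samples; rank-based AUC, vectorized."""
    from scipy.stats import rankdata

    n = len(y)
    take = rng.integers(0, n, size=(n_boot, n))
    yb = y[take]
    pb = prob[take]
    npos = yb.sum(axis=1)
    valid = (npos > 0) & (npos < n)
    ranks = rankdata(pb, axis=1)
    rank_pos = (ranks * yb).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        auc = (rank_pos - npos * (npos + 1) / 2) / (npos * (n - npos))
    auc[~valid] = np.nan
    lo, hi = np.nanpercentile(auc, [2.5, 97.5])
    return float(lo), float(hi)


def evaluate_subset(
    matrix: MetaboliteMatrix,
    meta: SampleMetadata,
    subset,
    cv: CvConfig | None = None,
    seed: int = 0,
) -> ModelEvaluation:
    """Repeated stratified CV of a random forest on the given metabolite subset."""
    cv = cv or CvConfig()
    subset = tuple(subset)
    x = matrix.data.loc[:, list(subset)].to_numpy(dtype=float)
    y = (meta.table.loc[matrix.sample_ids, "group"] == "fabry").to_numpy(dtype=int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both classes must be present")
    min_class = min(y.sum(), len(y) - y.sum())
    if min_class < cv.folds:
        raise ValueError(
            f"smallest class has {min_class} samples; cannot stratify into {cv.folds} folds"
        )
    rng = np.random.default_rng(seed)
    aucs = np.empty(cv.repeats)
    prob_sum = np.zeros(len(y))
    for r in range(cv.repeats):
        skf = StratifiedKFold(n_splits=cv.folds, shuffle=True, random_state=int(rng.integers(2**31 - 1)))
        oof = np.empty(len(y))
        for train, test in skf.split(x, y):
            clf = RandomForestClassifier(
                n_estimators=cv.n_trees,
                max_features=cv.max_features,
                class_weight=cv.class_weight,
                random_state=int(rng.integers(2**31 - 1)),
                n_jobs=1,
            )
            clf.fit(x[train], y[train])
            oof[test] = clf.predict_proba(x[test])[:, list(clf.classes_).index(1)]
        aucs[r] = roc_auc_score(y, oof)
        prob_sum += oof
    mean_prob = prob_sum / cv.repeats
    fpr, tpr, _ = roc_curve(y, mean_prob)
    lo, hi = _bootstrap_auc_ci(y, mean_prob, cv.n_bootstrap, rng)
    return ModelEvaluation(
        subset=subset,
        auc=float(aucs.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        roc_fpr=fpr,
        roc_tpr=tpr,
        mean_oof_prob=pd.Series(mean_prob, index=matrix.data.index),
        repeats=cv.repeats,
        seed=seed,
    )


def evaluate_all_subsets(
    matrix: MetaboliteMatrix,
    meta: SampleMetadata,
    members: list,
    cv: CvConfig | None = None,
    seed: int = 0,
    max_size: int | None = None,
) -> list[ModelEvaluation]:
    """Evaluate every non-empty subset with deterministically derived seeds."""
    subsets = enumerate_subsets(members, max_size=max_size)
    return [
        evaluate_subset(matrix, meta, s, cv=cv, seed=subset_seed(seed, i))
        for i, s in enumerate(subsets)
    ]


def rank_models(evaluations: list[ModelEvaluation]) -> pd.DataFrame:
    """Leaderboard sorted by AUC descending; ties -> smaller subset, then
    lexicographic."""
    if not evaluations:
        raise ValueError("no evaluations to rank")
    rows = [
        {
            "subset": "+".join(e.subset),
            "size": len(e.subset),
            "auc": e.auc,
            "ci_low": e.ci_low,
            "ci_high": e.ci_high,
            "repeats": e.repeats,
        }
        for e in evaluations
    ]
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["auc", "size", "subset"], ascending=[False, True, True], kind="stable"
    ).reset_index(drop=True)
    return df


def mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC via concordant-pair counting (ties count half)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes required")
    greater = (pos[:, None] > neg[None, :]).sum()
    equal = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * equal) / (pos.size * neg.size))
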