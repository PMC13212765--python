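"""Predictive evaluation: AUROC and Monte Carlo cross-validation.

Nested feature sets (clinical-radiological variables, plus cluster labels,
plus the dispersion range) are compared by the mean test AUROC over repeated
stratified random train/test splits ("Monte Carlo cross-validation").  All
feature sets share one split sequence, so per-split AUROC differences are
paired; the 95% CI is the empirical 2.5/97.5 percentile interval over splits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression

logger = logging.getLogger(__name__)


@dataclass
class MCCVResult:
    feature_set: str
    aurocs: np.ndarray
    mean_auroc: float
    ci_low: float
    ci_high: float
    n_splits: int
    test_fraction: float
    seed: int


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) area under the ROC curve with midrank ties.

    Equals P(score_pos > score_neg) + 0.5 P(score_pos = score_neg).
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    n1 = labels.sum()
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _stratified_split(
    y: np.ndarray, test_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    test_idx = []
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        n_test = max(1, int(round(test_fraction * idx.size)))
        test_idx.append(rng.choice(idx, size=n_test, replace=False))
    test = np.concatenate(test_idx)
    mask = np.ones(y.size, bool)
    mask[test] = False
    return np.flatnonzero(mask), test


def mccv(
    data: pd.DataFrame,
    outcome: str,
    feature_sets: dict[str, list[str]],
    n_splits: int = 1000,
    test_fraction: float = 0.3,
    seed: int = 0,
) -> dict[str, MCCVResult]:
    """Monte Carlo cross-validated AUROC per feature set.

    Per split: a stratified random train/test partition (identical across
    feature sets for paired comparison), an unpenalized logistic model fit on
    the training portion, and the rank-based AUROC on the held-out test
    portion.  Splits where either portion lacks a class are redrawn (logged).
    Deterministic given the seed.
    """
    for name, cols in feature_sets.items():
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise ValueError(f"feature set {name!r} references missing columns {missing}")
    y = data[outcome].astype(int).to_numpy()
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("outcome must be binary with both classes present")

    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    splits = []
    while len(splits) < n_splits:
        train, test = _stratified_split(y, test_fraction, rng)
        if len(np.unique(y[train])) < 2 or len(np.unique(y[test])) < 2:
            logger.info("redrawing split: a class is missing")
            continue
        splits.append((train, test))

    results: dict[str, MCCVResult] = {}
    for name, cols in feature_sets.items():
        X = data[cols].astype(float).to_numpy()
        aucs = np.empty(n_splits)
        for s, (train, test) in enumerate(splits):
            clf = LogisticRegression(C=np.inf, max_iter=500)  # unpenalized MLE
            clf.fit(X[train], y[train])
            scores = clf.decision_function(X[test])
            aucs[s] = auroc(scores, y[test])
        lo, hi = np.percentile(aucs, [2.5, 97.5])
        results[name] = MCCVResult(
            feature_set=name,
            aurocs=aucs,
            mean_auroc=float(aucs.mean()),
            ci_low=float(lo),
            ci_high=float(hi),
            n_splits=n_splits,
            test_fraction=test_fraction,
            seed=seed,
        )
    return results


def compare_feature_sets(results: dict[str, MCCVResult]) -> pd.DataFrame:
    """Summary and paired differences between feature sets.

    One row per feature set (mean AUROC, percentile CI) followed by one row
    per ordered pair with the paired per-split AUROC difference and its
    percentile CI.  All results must share the split sequence.
    """
    names = list(results)
    ref = results[names[0]]
    for r in results.values():
        if (r.n_splits, r.test_fraction, r.seed) != (
            ref.n_splits,
            ref.test_fraction,
            ref.seed,
        ):
            raise ValueError("results do not share a split sequence")
    rows = []
    for name in names:
        r = results[name]
        rows.append(
            {
                "comparison": name,
                "mean_auroc": r.mean_auroc,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "mean_diff": np.nan,
                "diff_ci_low": np.nan,
                "diff_ci_high": np.nan,
            }
        )
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            diff = results[b].aurocs - results[a].aurocs
            lo, hi = np.percentile(diff, [2.5, 97.5])
            rows.append(
                {
                    "comparison": f"{b} - {a}",
                    "mean_auroc": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "mean_diff": float(diff.mean()),
                    "diff_ci_low": float(lo),
                    "diff_ci_high": float(hi),
                }
            )
    return pd.DataFrame(rows)
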