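"""Reproducibility filtering and normalization of lesion-level radiomic features.

Features are retained when their inter-segmentation intraclass correlation
coefficient exceeds a threshold (default 0.85, strict) AND they do not have
near-zero variance.  Retained features are then center-scaled over the pooled
lesion population and Yeo-Johnson transformed with a per-feature maximum
likelihood lambda; the fitted constants are stored so the exact transform can
be replayed on new lesions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .synthdata import feature_columns

DEFAULT_ICC_THRESHOLD = 0.85
DEFAULT_FREQ_RATIO = 19.0
DEFAULT_UNIQUE_FRAC = 0.10


class FilterError(ValueError):
    """Raised when feature filtering leaves nothing usable."""


@dataclass
class FeatureFilterReport:
    """Fate of every feature through filtering and normalization.

    ``icc`` maps feature -> ICC(2,1) (NaN when not computable), ``nzv`` maps
    feature -> near-zero-variance flag, ``retained`` lists survivors, and
    ``center`` / ``scale`` / ``lam`` hold the replayable transform constants
    for each retained feature.
    """

    icc: dict[str, float] = field(default_factory=dict)
    nzv: dict[str, bool] = field(default_factory=dict)
    retained: list[str] = field(default_factory=list)
    icc_threshold: float = DEFAULT_ICC_THRESHOLD
    center: dict[str, float] = field(default_factory=dict)
    scale: dict[str, float] = field(default_factory=dict)
    lam: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "icc": self.icc,
            "nzv": self.nzv,
            "retained": self.retained,
            "icc_threshold": self.icc_threshold,
            "center": self.center,
            "scale": self.scale,
            "lambda": self.lam,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def icc_2_1(first: np.ndarray, second: np.ndarray) -> float:
    """Two-way random effects, absolute agreement, single-measurement ICC.

    With n targets (lesions) and k = 2 raters (segmentations):

        ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    where MSR, MSC, MSE are the rows (targets), columns (raters) and residual
    mean squares of the two-way ANOVA without replication.
    """
    x = np.column_stack([np.asarray(first, float), np.asarray(second, float)])
    n, k = x.shape
    if n < 3:
        raise ValueError("ICC needs at least 3 targets")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        return 1.0 if msr == mse else np.nan
    return float((msr - mse) / denom)


def compute_icc(first: pd.DataFrame, second: pd.DataFrame) -> pd.Series:
    """Per-feature ICC(2,1) between two segmentation tables.

    The tables must contain identical ``(patient_id, lesion_id)`` keys; order
    is aligned on those keys before the ANOVA.
    """
    keys = ["patient_id", "lesion_id"]
    a = first.set_index(keys).sort_index()
    b = second.set_index(keys).sort_index()
    if not a.index.equals(b.index):
        raise ValueError("duplicate table keys do not match the original table")
    feats = feature_columns(first)
    n = len(a)
    out = {}
    for col in feats:
        if n < 3:
            warnings.warn(f"ICC undefined for {col}: fewer than 3 lesions")
            out[col] = np.nan
            continue
        out[col] = icc_2_1(a[col].to_numpy(), b[col].to_numpy())
    return pd.Series(out, name="icc")


def near_zero_variance(
    values: np.ndarray,
    freq_ratio_threshold: float = DEFAULT_FREQ_RATIO,
    unique_frac_threshold: float = DEFAULT_UNIQUE_FRAC,
) -> bool:
    """Near-zero-variance flag.

    Flagged iff the ratio of the most common value's frequency to the second
    most common exceeds ``freq_ratio_threshold`` AND the fraction of distinct
    values is below ``unique_frac_threshold``.  Constant vectors are always
    flagged.
    """
    v = np.asarray(values)
    if v.size == 0:
        raise ValueError("empty input")
    uniq, counts = np.unique(v, return_counts=True)
    if uniq.size == 1:
        return True
    counts = np.sort(counts)[::-1]
    freq_ratio = counts[0] / counts[1]
    unique_frac = uniq.size / v.size
    return bool(freq_ratio > freq_ratio_threshold and unique_frac < unique_frac_threshold)


def filter_features(
    table: pd.DataFrame,
    icc: pd.Series,
    icc_threshold: float = DEFAULT_ICC_THRESHOLD,
    freq_ratio_threshold: float = DEFAULT_FREQ_RATIO,
    unique_frac_threshold: float = DEFAULT_UNIQUE_FRAC,
) -> tuple[pd.DataFrame, FeatureFilterReport]:
    """Drop features failing the ICC (> threshold, strict) or NZV rule.

    Features absent from ``icc`` (no duplicate segmentation available) pass
    the ICC rule by default, mirroring a duplicate subsample smaller than the
    cohort.
    """
    feats = feature_columns(table)
    report = FeatureFilterReport(icc_threshold=icc_threshold)
    retained = []
    for col in feats:
        icc_val = float(icc[col]) if col in icc.index else np.nan
        nzv = near_zero_variance(
            table[col].to_numpy(), freq_ratio_threshold, unique_frac_threshold
        )
        report.icc[col] = icc_val
        report.nzv[col] = nzv
        passes_icc = np.isnan(icc_val) or icc_val > icc_threshold
        if passes_icc and not nzv:
            retained.append(col)
    if not retained:
        raise FilterError(f"no features retained; report: {report.icc}")
    report.retained = retained
    meta = [c for c in table.columns if c not in feats]
    return table[meta + retained].copy(), report


def yeo_johnson(values: np.ndarray, lam: float) -> np.ndarray:
    """Yeo-Johnson power transform at a fixed lambda.

    psi(x, lam) = ((x+1)^lam - 1)/lam            x >= 0, lam != 0
                  log(x+1)                        x >= 0, lam == 0
                  -((1-x)^(2-lam) - 1)/(2-lam)    x < 0,  lam != 2
                  -log(1-x)                       x < 0,  lam == 2
    """
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite inputs")
    return stats.yeojohnson(v, lmbda=lam)


def fit_lambda(values: np.ndarray, bounds: tuple[float, float] = (-5.0, 5.0)) -> float:
    """Maximum-likelihood lambda for the Yeo-Johnson transform.

    Maximizes the Gaussian profile log-likelihood of the transformed sample
    (including the Jacobian term) over a bounded interval.
    """
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite inputs")
    res = optimize.minimize_scalar(
        lambda lam: -stats.yeojohnson_llf(lam, v),
        bounds=bounds,
        method="bounded",
        options={"xatol": 1e-6},
    )
    return float(res.x)


def transform_features(
    table: pd.DataFrame, report: FeatureFilterReport | None = None
) -> tuple[pd.DataFrame, FeatureFilterReport]:
    """Center-scale (pooled over all lesions) then Yeo-Johnson each feature.

    When ``report`` already holds transform constants the stored transform is
    replayed verbatim (no re-fitting) — this is how held-out lesions must be
    normalized.  Otherwise constants are fitted on ``table`` and recorded.
    """
    feats = feature_columns(table)
    out = table.copy()
    if report is not None and report.center:
        for col in feats:
            z = (out[col].to_numpy() - report.center[col]) / report.scale[col]
            out[col] = yeo_johnson(z, report.lam[col])
        return out, report
    if report is None:
        report = FeatureFilterReport()
        report.retained = list(feats)
    for col in feats:
        v = out[col].to_numpy(dtype=float)
        mu = float(v.mean())
        sd = float(v.std(ddof=1))
        if sd == 0:
            raise ValueError(f"zero variance in {col}: should have been NZV-filtered")
        z = (v - mu) / sd
        lam = fit_lambda(z)
        out[col] = yeo_johnson(z, lam)
        report.center[col] = mu
        report.scale[col] = sd
        report.lam[col] = lam
    return out, report
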