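"""Association and outcome statistics.

Implements the analysis battery used to relate patient-level radiomic
representations to molecular groups and outcomes: contingency odds ratios
with Wald confidence intervals, automatic group-comparison tests (chi-square
or Fisher for categorical variables; t, Mann-Whitney or Kruskal-Wallis for
numeric variables after a Shapiro-Wilk normality gate), univariable logistic
screening, backward stepwise multivariable logistic regression, Kaplan-Meier
curves with log-rank tests, and Cox proportional-hazards models (Efron ties,
via lifelines).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

logger = logging.getLogger(__name__)

Z_95 = 1.959964  # two-sided 95% normal quantile


@dataclass
class EffectEstimate:
    """Odds or hazard ratio with Wald 95% CI.

    ``undefined`` marks degenerate estimates (zero cell, perfect separation,
    constant covariate); then ``estimate`` is 0 or inf by direction and the
    CI bounds are NaN.
    """

    term: str
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    model: str = "univariable"
    level: str | None = None
    undefined: bool = False

    def as_row(self) -> dict:
        return {
            "term": self.term,
            "level": self.level,
            "model": self.model,
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "undefined": self.undefined,
        }


def odds_ratio_wald(
    a: int, b: int, c: int, d: int, alpha: float = 0.05, term: str = "exposure"
) -> EffectEstimate:
    """Odds ratio for a 2x2 table with a Wald CI on the log scale.

    Table layout: exposed cases ``a``, exposed references ``b``, unexposed
    cases ``c``, unexposed references ``d``; OR = (a*d)/(b*c).  A zero cell
    yields a flagged degenerate estimate (0 or inf by direction) instead of
    an error, matching how such rows are reported in practice ("0 (-)").
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("cell counts must be nonnegative")
    if a + b + c + d == 0:
        raise ValueError("empty table")
    z = sps.norm.ppf(1 - alpha / 2)
    if min(a, b, c, d) == 0:
        est = 0.0 if (a == 0 or d == 0) else np.inf
        return EffectEstimate(term, est, np.nan, np.nan, np.nan, undefined=True)
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = np.exp(np.log(or_) + np.array([-1, 1]) * z * se)
    p = 2 * sps.norm.sf(abs(np.log(or_)) / se)
    return EffectEstimate(term, float(or_), float(lo), float(hi), float(p))


@dataclass
class GroupComparison:
    test: str
    statistic: float
    p_value: float
    detail: str = ""


def group_compare(
    values_by_group: dict[str, np.ndarray], kind: str, alpha_normal: float = 0.05
) -> GroupComparison:
    """Compare a variable across groups with the conventional test choice.

    ``kind='categorical'``: chi-square on the contingency table, falling back
    to Fisher's exact test (2x2 only) when any expected cell is below 5.
    ``kind='numeric'``: with two groups, Shapiro-Wilk gates between Student t
    (both p > alpha_normal) and Mann-Whitney; with more groups,
    Kruskal-Wallis.  The chosen test is reported for audit.
    """
    groups = list(values_by_group)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    samples = [np.asarray(values_by_group[g]) for g in groups]
    if any(s.size < 2 for s in samples):
        raise ValueError("each group needs at least 2 observations")

    if kind == "categorical":
        cats = np.unique(np.concatenate(samples))
        table = np.array([[np.sum(s == c) for c in cats] for s in samples])
        chi2, p, _, expected = sps.chi2_contingency(table)
        if (expected < 5).any() and table.shape == (2, 2):
            _, p = sps.fisher_exact(table)
            logger.info("expected cell < 5: Fisher fallback")
            return GroupComparison("fisher", np.nan, float(p), "expected cell < 5")
        return GroupComparison("chi2", float(chi2), float(p))

    if kind != "numeric":
        raise ValueError("kind must be 'categorical' or 'numeric'")
    if len(samples) == 2:
        normal = all(sps.shapiro(s).pvalue > alpha_normal for s in samples)
        if normal:
            t = sps.ttest_ind(*samples)
            return GroupComparison("t", float(t.statistic), float(t.pvalue))
        u = sps.mannwhitneyu(*samples, alternative="two-sided")
        return GroupComparison("mannwhitney", float(u.statistic), float(u.pvalue))
    kw = sps.kruskal(*samples)
    return GroupComparison("kruskal", float(kw.statistic), float(kw.pvalue))


# ---------------------------------------------------------------------------
# logistic regression helpers


def _design(
    data: pd.DataFrame, terms: list[str], references: dict[str, str]
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Design matrix with dummy coding against declared reference levels.

    Returns the matrix (no intercept column) and a map term -> its columns.
    """
    cols: dict[str, list[str]] = {}
    blocks = []
    for t in terms:
        s = data[t]
        if t in references or s.dtype == object or isinstance(
            s.dtype, pd.CategoricalDtype
        ):
            levels = [str(v) for v in pd.unique(s.dropna())]
            ref = str(references.get(t, sorted(levels)[0]))
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} absent from {t}")
            others = [l for l in sorted(levels) if l != ref]
            block = pd.DataFrame(
                {f"{t}[{l}]": (s.astype(str) == l).astype(float) for l in others},
                index=data.index,
            )
            cols[t] = list(block.columns)
            blocks.append(block)
        else:
            blocks.append(s.astype(float).to_frame(t))
            cols[t] = [t]
    X = pd.concat(blocks, axis=1) if blocks else pd.DataFrame(index=data.index)
    return X, cols


def _fit_logit(y: np.ndarray, X: pd.DataFrame):
    Xc = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, Xc)
        try:
            res = model.fit(disp=0, maxiter=200)
        except Exception:
            return None
    if not res.mle_retvals.get("converged", False):
        return None
    # absurd standard errors signal quasi-separation
    if np.any(np.asarray(res.bse) > 50):
        return None
    return res


def univariable_screen(
    data: pd.DataFrame,
    outcome: str,
    candidates: list[str],
    references: dict[str, str] | None = None,
    alpha: float = 0.05,
) -> list[EffectEstimate]:
    """One single-covariate logistic fit per candidate.

    Categorical candidates expand against their declared reference level, one
    EffectEstimate per non-reference level.  Perfect separation yields a
    flagged estimate rather than a crash.  Complete cases per candidate.
    """
    references = references or {}
    out: list[EffectEstimate] = []
    for cand in candidates:
        sub = data[[outcome, cand]].dropna()
        y = sub[outcome].astype(float).to_numpy()
        X, cols = _design(sub, [cand], references)
        res = _fit_logit(y, X)
        for col in cols[cand]:
            level = col[len(cand) + 1 : -1] if col != cand else None
            if res is None:
                out.append(
                    EffectEstimate(cand, np.nan, np.nan, np.nan, np.nan,
                                   level=level, undefined=True)
                )
                continue
            beta = res.params[col]
            se = res.bse[col]
            out.append(
                EffectEstimate(
                    term=cand,
                    level=level,
                    estimate=float(np.exp(beta)),
                    ci_low=float(np.exp(beta - Z_95 * se)),
                    ci_high=float(np.exp(beta + Z_95 * se)),
                    p_value=float(res.pvalues[col]),
                )
            )
    return out


def screened_terms(estimates: list[EffectEstimate], alpha: float = 0.05) -> list[str]:
    """Terms with any level significant at ``alpha`` in univariable screening."""
    keep = []
    for e in estimates:
        if not e.undefined and e.p_value < alpha and e.term not in keep:
            keep.append(e.term)
    return keep


@dataclass
class StepwiseResult:
    estimates: list[EffectEstimate]
    retained: list[str]
    trace: list[tuple[int, str, float]] = field(default_factory=list)  # (step, term, p)


def stepwise_logistic(
    data: pd.DataFrame,
    outcome: str,
    candidates: list[str],
    references: dict[str, str] | None = None,
    p_remove: float = 0.05,
) -> StepwiseResult:
    """Backward elimination from the screened candidate set.

    At each step the term with the largest removal p-value above ``p_remove``
    is dropped (ties broken by name): Wald p for single-column terms, a
    likelihood-ratio test for whole categorical blocks.  Perfectly collinear
    columns are dropped up front with a logged warning.  Complete cases only.
    """
    references = references or {}
    sub = data[[outcome] + candidates].dropna()
    y = sub[outcome].astype(float).to_numpy()
    X, cols = _design(sub, candidates, references)

    # rank-deficiency guard: greedily drop columns that add no rank
    keep_cols: list[str] = []
    for col in X.columns:
        trial = X[keep_cols + [col]].to_numpy()
        if np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), trial])) == (
            len(keep_cols) + 2
        ):
            keep_cols.append(col)
        else:
            logger.warning("dropping collinear column %s", col)
    dropped_collinear = [c for c in X.columns if c not in keep_cols]
    terms = [
        t for t in candidates if any(c in keep_cols for c in cols[t])
    ]
    cols = {t: [c for c in cols[t] if c in keep_cols] for t in terms}

    trace: list[tuple[int, str, float]] = []
    step = 0
    while terms:
        X_cur = X[[c for t in terms for c in cols[t]]]
        res = _fit_logit(y, X_cur)
        if res is None:
            # drop the term whose columns have the worst conditioning
            bad = terms[-1]
            logger.warning("fit degenerate; removing term %s", bad)
            step += 1
            trace.append((step, bad, np.nan))
            terms = [t for t in terms if t != bad]
            continue
        pvals: dict[str, float] = {}
        for t in terms:
            if len(cols[t]) == 1:
                pvals[t] = float(res.pvalues[cols[t][0]])
            else:  # LR test for the categorical block
                X_red = X_cur.drop(columns=cols[t])
                res_red = _fit_logit(y, X_red)
                if res_red is None:
                    pvals[t] = 0.0
                else:
                    lr = 2 * (res.llf - res_red.llf)
                    pvals[t] = float(sps.chi2.sf(max(lr, 0.0), df=len(cols[t])))
        worst = max(terms, key=lambda t: (pvals[t], t))
        if pvals[worst] > p_remove:
            step += 1
            trace.append((step, worst, pvals[worst]))
            terms = [t for t in terms if t != worst]
            continue
        break

    estimates: list[EffectEstimate] = []
    if terms:
        X_fin = X[[c for t in terms for c in cols[t]]]
        res = _fit_logit(y, X_fin)
        if res is not None:
            for t in terms:
                for col in cols[t]:
                    level = col[len(t) + 1 : -1] if col != t else None
                    beta, se = res.params[col], res.bse[col]
                    estimates.append(
                        EffectEstimate(
                            term=t,
                            level=level,
                            estimate=float(np.exp(beta)),
                            ci_low=float(np.exp(beta - Z_95 * se)),
                            ci_high=float(np.exp(beta + Z_95 * se)),
                            p_value=float(res.pvalues[col]),
                            model="multivariable",
                        )
                    )
    for col in dropped_collinear:
        trace.append((0, f"collinear:{col}", np.nan))
    return StepwiseResult(estimates=estimates, retained=terms, trace=trace)


# ---------------------------------------------------------------------------
# survival


@dataclass
class KMLogrankResult:
    curves: dict[str, pd.DataFrame]  # group -> timeline/survival columns
    statistic: float
    p_value: float


def km_logrank(
    time: np.ndarray, event: np.ndarray, group: np.ndarray
) -> KMLogrankResult:
    """Kaplan-Meier curves per group plus the log-rank test across groups.

    With no events anywhere the survival functions are identically 1 and the
    test is undefined (NaN statistic and p)."""
    time = np.asarray(time, float)
    event = np.asarray(event).astype(int)
    group = np.asarray(group)
    if np.any(time <= 0):
        raise ValueError("survival times must be positive")
    curves = {}
    for g in np.unique(group):
        mask = group == g
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask], label=str(g))
        curves[str(g)] = kmf.survival_function_.reset_index().rename(
            columns={"timeline": "time", str(g): "survival"}
        )
    if event.sum() == 0:
        return KMLogrankResult(curves, np.nan, np.nan)
    lr = multivariate_logrank_test(time, group, event)
    return KMLogrankResult(curves, float(lr.test_statistic), float(lr.p_value))


def cox_fit(
    data: pd.DataFrame,
    time_col: str,
    event_col: str,
    covariates: list[str],
) -> list[EffectEstimate]:
    """Cox proportional-hazards fit (Efron tie handling) on complete cases.

    Returns a hazard ratio with Wald 95% CI per covariate; constant
    covariates and non-converging fits produce flagged estimates.
    """
    sub = data[[time_col, event_col] + covariates].dropna()
    out: list[EffectEstimate] = []
    degenerate = [c for c in covariates if sub[c].nunique() <= 1]
    usable = [c for c in covariates if c not in degenerate]
    for c in degenerate:
        out.append(
            EffectEstimate(c, np.nan, np.nan, np.nan, np.nan,
                           model="cox", undefined=True)
        )
    if not usable:
        return out
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(
                sub[[time_col, event_col] + usable].astype(float),
                duration_col=time_col,
                event_col=event_col,
            )
    except Exception as exc:  # monotone likelihood / non-convergence
        logger.warning("Cox fit failed: %s", exc)
        for c in usable:
            out.append(
                EffectEstimate(c, np.nan, np.nan, np.nan, np.nan,
                               model="cox", undefined=True)
            )
        return out
    for c in usable:
        beta = float(cph.params_[c])
        se = float(cph.standard_errors_[c])
        out.append(
            EffectEstimate(
                term=c,
                estimate=float(np.exp(beta)),
                ci_low=float(np.exp(beta - Z_95 * se)),
                ci_high=float(np.exp(beta + Z_95 * se)),
                p_value=float(cph.summary.loc[c, "p"]),
                model="cox",
            )
        )
    return out


def estimates_frame(estimates: list[EffectEstimate]) -> pd.DataFrame:
    """Tidy frame of effect estimates (one row per term/level)."""
    return pd.DataFrame([e.as_row() for e in estimates])
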