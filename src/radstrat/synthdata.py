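"""Synthetic multi-lesion radiomics cohorts.

Real cohorts of this kind — metastatic lung adenocarcinoma patients with
several segmented CT lesions each, a molecular label (wild-type, smoker-related
oncogenic alteration, non-smoker-related oncogenic alteration), and clinical
outcomes — are not publicly depositable.  This module generates cohorts with
the same statistical skeleton so that every downstream stage (feature
filtering, patient-level integration, consensus clustering, association and
outcome models) can be exercised and tested end to end.

The generative model:

* each patient belongs to one of ``n_clusters`` latent radiophenotypes;
  cluster means sit ``cluster_separation`` within-cluster standard deviations
  apart in feature space;
* a patient's lesions scatter around a patient-specific point as isotropic
  Gaussian noise whose standard deviation is scaled by a molecular-group
  dispersion multiplier (lower multiplier = radiologically more homogeneous
  lesions, as observed for non-smoker oncogenic alterations);
* lesion counts follow 2 + Poisson(lambda) — every patient has at least the
  two segmentable lesions the study design requires;
* objective response is Bernoulli under a logistic model on the dispersion
  range and the latent cluster; survival is exponential with a log-hazard
  term on the dispersion range and independent uniform censoring;
* duplicate segmentations add Gaussian measurement noise calibrated to a
  target intraclass correlation coefficient.

All randomness flows from a single root seed through named
``numpy.random.SeedSequence`` children, so identical configurations produce
byte-identical tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

MOLECULAR_GROUPS = ("WT", "sOA", "nsOA")

# stream names -> child index of the root SeedSequence (documented splitting
# scheme; adding a stream must not renumber existing ones)
_STREAMS = {
    "cluster": 0,
    "lesion_counts": 1,
    "features": 2,
    "labels": 3,
    "volumes": 4,
    "biopsy": 5,
    "outcomes": 6,
    "duplicates": 7,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(_STREAMS))
    return np.random.Generator(np.random.PCG64(children[_STREAMS[stream]]))


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort.

    Defaults emulate the published cohort: 361 patients, at least two lesions
    each with a median of 4 per patient, roughly half the patients with an
    identifiable biopsied lesion, and lower lesion dispersion in the nsOA
    group.
    """

    n_patients: int = 361
    n_features: int = 20
    n_clusters: int = 3
    cluster_separation: float = 3.0
    lesion_poisson_mean: float = 2.4  # counts are 2 + Poisson(mean); median 4
    patient_sd: float = 1.0  # within-cluster scatter of patient-level means
    lesion_sd: float = 1.0  # baseline lesion scatter around the patient mean
    dispersion_by_group: Mapping[str, float] = field(
        default_factory=lambda: {"WT": 1.0, "sOA": 1.0, "nsOA": 0.6}
    )
    # P(molecular group | latent cluster); rows index clusters cyclically
    label_probs: Sequence[Sequence[float]] = field(
        default_factory=lambda: (
            (0.15, 0.55, 0.30),
            (0.45, 0.45, 0.10),
            (0.25, 0.70, 0.05),
        )
    )
    biopsy_fraction: float = 0.5  # fraction of patients with a biopsied lesion
    biopsy_largest_prob: float = 0.611  # biopsied lesion is the largest one
    # objective-response logistic model
    orr_intercept: float = -0.5
    orr_beta_dispersion_range: float = -0.4
    orr_beta_cluster: Sequence[float] = (0.0, 0.8, -0.3)
    # overall survival: exponential hazard, uniform censoring
    os_baseline_hazard: float = 1.0 / 24.0  # events per month
    os_log_hr_dispersion_range: float = 0.10
    censor_low: float = 6.0
    censor_high: float = 72.0
    duplicate_icc: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0 or self.n_features <= 0 or self.n_clusters <= 0:
            raise ValueError("n_patients, n_features, n_clusters must be positive")
        if self.n_clusters > self.n_features:
            raise ValueError("need n_features >= n_clusters to place cluster means")
        if self.cluster_separation < 0:
            raise ValueError("cluster_separation must be nonnegative")
        if not 0 < self.duplicate_icc <= 1:
            raise ValueError("duplicate_icc must lie in (0, 1]")
        probs = np.asarray(self.label_probs, dtype=float)
        if probs.shape[1] != len(MOLECULAR_GROUPS):
            raise ValueError("label_probs rows must have one entry per molecular group")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each label_probs row must sum to 1")
        if (probs < 0).any():
            raise ValueError("label_probs must be nonnegative")
        for g in MOLECULAR_GROUPS:
            if g not in self.dispersion_by_group:
                raise ValueError(f"dispersion_by_group missing group {g!r}")


@dataclass
class CohortTruth:
    """Ground truth of a generated cohort, for parameter-recovery tests."""

    true_cluster: pd.Series  # per patient
    true_dispersion_scale: pd.Series  # per patient
    config: SyntheticConfig

    def to_json(self, path: str | Path) -> None:
        payload = {
            "true_cluster": self.true_cluster.to_dict(),
            "true_dispersion_scale": self.true_dispersion_scale.to_dict(),
            "config": _config_dict(self.config),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _config_dict(config: SyntheticConfig) -> dict:
    d = asdict(config)
    d["dispersion_by_group"] = dict(config.dispersion_by_group)
    d["label_probs"] = [list(row) for row in config.label_probs]
    d["orr_beta_cluster"] = list(config.orr_beta_cluster)
    return d


def _cluster_means(config: SyntheticConfig) -> np.ndarray:
    """Cluster means on scaled coordinate axes: pairwise distance equals
    ``cluster_separation`` in units of the patient-level SD."""
    means = np.zeros((config.n_clusters, config.n_features))
    scale = config.cluster_separation * config.patient_sd / np.sqrt(2.0)
    for c in range(config.n_clusters):
        means[c, c] = scale
    return means


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, CohortTruth]:
    """Generate (lesion table, patient table, truth) for one synthetic cohort.

    The lesion table has one row per segmented lesion: ``patient_id``,
    ``lesion_id``, ``volume_cm3``, ``is_largest``, ``is_biopsied`` and
    ``n_features`` numeric columns ``f000``.. .  The patient table carries the
    molecular group, clinical covariates, objective response and survival.
    """
    n = config.n_patients
    patient_ids = [f"P{i:04d}" for i in range(n)]

    clusters = _rng(config.seed, "cluster").integers(0, config.n_clusters, size=n)
    counts = 2 + _rng(config.seed, "lesion_counts").poisson(
        config.lesion_poisson_mean, size=n
    )

    probs = np.asarray(config.label_probs, dtype=float)
    rng_lab = _rng(config.seed, "labels")
    group_idx = np.array(
        [rng_lab.choice(len(MOLECULAR_GROUPS), p=probs[c % probs.shape[0]]) for c in clusters]
    )
    groups = np.array(MOLECULAR_GROUPS)[group_idx]
    disp_scale = np.array([config.dispersion_by_group[g] for g in groups])

    means = _cluster_means(config)
    rng_feat = _rng(config.seed, "features")
    rng_vol = _rng(config.seed, "volumes")

    lesion_rows = []
    true_disp = []
    for i, pid in enumerate(patient_ids):
        m = counts[i]
        patient_mean = means[clusters[i]] + config.patient_sd * rng_feat.standard_normal(
            config.n_features
        )
        sd = config.lesion_sd * disp_scale[i]
        true_disp.append(sd)
        lesions = patient_mean + sd * rng_feat.standard_normal((m, config.n_features))
        # log-normal volumes shifted above the 1 cm^3 inclusion threshold
        volumes = 1.0 + rng_vol.lognormal(mean=1.0, sigma=0.8, size=m)
        largest = np.argmax(volumes)
        for j in range(m):
            row = {
                "patient_id": pid,
                "lesion_id": f"L{j:02d}",
                "volume_cm3": volumes[j],
                "is_largest": j == largest,
                "is_biopsied": False,
            }
            row.update({f"f{k:03d}": lesions[j, k] for k in range(config.n_features)})
            lesion_rows.append(row)

    lesion_table = pd.DataFrame(lesion_rows)

    # biopsied lesion: present for ~biopsy_fraction of patients; it is the
    # largest lesion with probability biopsy_largest_prob, else uniform among
    # the others
    rng_biopsy = _rng(config.seed, "biopsy")
    has_biopsy = rng_biopsy.random(n) < config.biopsy_fraction
    for i, pid in enumerate(patient_ids):
        if not has_biopsy[i]:
            continue
        mask = lesion_table["patient_id"] == pid
        idx = lesion_table.index[mask]
        largest_pos = int(np.flatnonzero(lesion_table.loc[idx, "is_largest"].to_numpy())[0])
        if counts[i] == 1 or rng_biopsy.random() < config.biopsy_largest_prob:
            chosen = idx[largest_pos]
        else:
            others = [p for p in range(counts[i]) if p != largest_pos]
            chosen = idx[rng_biopsy.choice(others)]
        lesion_table.loc[chosen, "is_biopsied"] = True

    # dispersion range on the raw generated features drives the outcome model
    feat_cols = [f"f{k:03d}" for k in range(config.n_features)]
    disp_range = np.empty(n)
    for i, pid in enumerate(patient_ids):
        X = lesion_table.loc[lesion_table["patient_id"] == pid, feat_cols].to_numpy()
        d = np.linalg.norm(X - X.mean(axis=0), axis=1)
        disp_range[i] = d.max() - d.min()

    rng_out = _rng(config.seed, "outcomes")
    beta_c = np.asarray(config.orr_beta_cluster, dtype=float)
    logit = (
        config.orr_intercept
        + config.orr_beta_dispersion_range * disp_range
        + beta_c[clusters % len(beta_c)]
    )
    response = rng_out.random(n) < 1.0 / (1.0 + np.exp(-logit))

    hazard = config.os_baseline_hazard * np.exp(
        config.os_log_hr_dispersion_range * disp_range
    )
    event_time = rng_out.exponential(1.0 / hazard)
    censor_time = rng_out.uniform(config.censor_low, config.censor_high, size=n)
    os_time = np.minimum(event_time, censor_time)
    os_event = event_time <= censor_time

    # simple clinical covariates (independent; marginals loosely follow the
    # published Table 1 frequencies)
    sex_female = rng_out.random(n) < 0.413
    never_smoker = rng_out.random(n) < 0.115
    who_ps = rng_out.choice([0, 1, 2], size=n, p=[0.269, 0.526, 0.205])
    stage_ivb = rng_out.random(n) < 0.773
    age = rng_out.normal(63.0, 9.0, size=n).round(1)

    patient_table = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "molecular_group": groups,
            "any_oa": groups != "WT",
            "sex_female": sex_female,
            "never_smoker": never_smoker,
            "who_ps": who_ps,
            "stage_ivb": stage_ivb,
            "age": age,
            "n_lesions": counts,
            "response": response,
            "os_months": os_time,
            "os_event": os_event,
        }
    )

    truth = CohortTruth(
        true_cluster=pd.Series(clusters, index=patient_ids, name="true_cluster"),
        true_dispersion_scale=pd.Series(
            true_disp, index=patient_ids, name="true_dispersion_scale"
        ),
        config=config,
    )
    return lesion_table, patient_table, truth


def generate_duplicate_segmentations(
    lesions: pd.DataFrame, duplicate_icc: float, seed: int
) -> pd.DataFrame:
    """Second-segmentation table for ICC estimation.

    Adds zero-mean Gaussian noise per feature to the duplicate only.  In the
    two-way ANOVA behind ICC(2,1) a disagreement variance split evenly over
    the two raters contributes half of itself to the residual mean square, so
    noise carried entirely by the duplicate must have variance

        sigma_e^2 = 2 * sigma_b^2 * (1 - ICC) / ICC,

    with ``sigma_b^2`` the observed between-lesion variance of the feature,
    for the empirical ICC(2,1) of (original, duplicate) pairs to converge to
    ``duplicate_icc``.
    """
    if not 0 < duplicate_icc <= 1:
        raise ValueError("duplicate_icc must lie in (0, 1]")
    out = lesions.copy()
    if duplicate_icc == 1.0:
        return out
    feat_cols = [c for c in lesions.columns if c.startswith("f") and c[1:].isdigit()]
    rng = _rng(seed, "duplicates")
    for col in feat_cols:
        sigma_b2 = float(np.var(lesions[col].to_numpy(), ddof=1))
        sigma_e2 = 2.0 * sigma_b2 * (1.0 - duplicate_icc) / duplicate_icc
        out[col] = lesions[col].to_numpy() + rng.normal(
            0.0, np.sqrt(sigma_e2), size=len(lesions)
        )
    return out


def write_cohort(
    outdir: str | Path,
    lesions: pd.DataFrame,
    patients: pd.DataFrame,
    truth: CohortTruth,
    duplicates: pd.DataFrame | None = None,
) -> None:
    """Write the cohort as CSV tables plus a JSON truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lesions.to_csv(outdir / "lesions.csv", index=False)
    patients.to_csv(outdir / "patients.csv", index=False)
    truth.to_json(outdir / "truth.json")
    if duplicates is not None:
        duplicates.to_csv(outdir / "lesions_duplicate.csv", index=False)


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Names of the numeric feature columns of a lesion table."""
    reserved = {"patient_id", "lesion_id", "volume_cm3", "is_largest", "is_biopsied"}
    return [c for c in table.columns if c not in reserved]
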