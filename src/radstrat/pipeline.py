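"""End-to-end orchestration.

Runs the full stratification analysis on a synthetic (or user-supplied)
cohort: duplicate-segmentation ICC filtering and normalization, patient-level
integration, consensus clustering of the three representations, cluster
merging, ARI comparisons, descriptive group statistics, univariable +
stepwise logistic association models, Kaplan-Meier / Cox survival analysis,
and Monte Carlo cross-validated AUROC comparisons of nested feature sets.
All outputs are plain CSV/JSON under one output directory, with a manifest
recording every parameter and seed; a re-run with the same configuration
reproduces the outputs byte-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import cluster as cl
from . import evaluate as ev
from . import features as ft
from . import integrate as it
from . import stats as st
from . import synthdata as sd

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    outdir: str = "radstrat_out"
    # either paths to existing tables ...
    lesions_csv: str | None = None
    patients_csv: str | None = None
    duplicates_csv: str | None = None
    # ... or parameters of a synthetic cohort
    synth: dict = field(default_factory=dict)
    icc_threshold: float = ft.DEFAULT_ICC_THRESHOLD
    freq_ratio_threshold: float = ft.DEFAULT_FREQ_RATIO
    unique_frac_threshold: float = ft.DEFAULT_UNIQUE_FRAC
    k_min: int = 2
    k_max: int = 6
    n_resamples: int = 200
    item_fraction: float = 0.8
    min_cluster_frac: float = 0.05
    mccv_splits: int = 200
    mccv_test_fraction: float = 0.3
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the report bundle; returns the manifest.

    A stage failure aborts with the stage name and leaves a partial-results
    manifest (``manifest.partial.json``) in the output directory.
    """
    try:
        return _run(config)
    except StageError as err:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "manifest.partial.json").write_text(
            json.dumps({"failed_stage": err.stage, "error": str(err)}, indent=2)
        )
        raise


def _run(config: PipelineConfig) -> dict:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config": {k: v for k, v in vars(config).items()},
        "stages": [],
        "synthetic_inputs": config.lesions_csv is None,
    }

    def _stage(name):
        manifest["stages"].append(name)
        logger.info("stage: %s", name)

    try:
        _stage("inputs")
        if config.lesions_csv is not None:
            lesions = pd.read_csv(config.lesions_csv)
            patients = pd.read_csv(config.patients_csv)
            duplicates = (
                pd.read_csv(config.duplicates_csv) if config.duplicates_csv else None
            )
        else:
            synth_cfg = sd.SyntheticConfig(seed=config.seed, **config.synth)
            lesions, patients, truth = sd.generate_cohort(synth_cfg)
            duplicates = sd.generate_duplicate_segmentations(
                lesions, synth_cfg.duplicate_icc, seed=config.seed + 1
            )
            sd.write_cohort(out / "cohort", lesions, patients, truth, duplicates)
        manifest["n_patients"] = int(patients.shape[0])
        manifest["n_lesions"] = int(lesions.shape[0])
    except Exception as exc:
        raise StageError("inputs", exc) from exc

    try:
        _stage("feature_filtering")
        n_before = len(sd.feature_columns(lesions))
        if duplicates is not None:
            icc = ft.compute_icc(lesions, duplicates)
        else:
            icc = pd.Series(dtype=float)
        filtered, report = ft.filter_features(
            lesions,
            icc,
            icc_threshold=config.icc_threshold,
            freq_ratio_threshold=config.freq_ratio_threshold,
            unique_frac_threshold=config.unique_frac_threshold,
        )
        transformed, report = ft.transform_features(filtered, report)
        report.to_json(out / "feature_report.json")
        manifest["features_in"] = n_before
        manifest["features_retained"] = len(report.retained)
    except Exception as exc:
        raise StageError("feature_filtering", exc) from exc

    try:
        _stage("integration")
        reps = it.build_representations(transformed)
        rep_table = it.representation_table(reps)
        rep_table.to_csv(out / "patient_representations.csv", index=False)
    except Exception as exc:
        raise StageError("integration", exc) from exc

    try:
        _stage("clustering")
        assign = pd.DataFrame({"patient_id": sorted(reps)}).set_index("patient_id")
        consensus_results = {}
        for stream, (which, colname) in enumerate(
            (("centroid", "cluster_C"), ("largest", "cluster_M"),
             ("biopsied", "cluster_B"))
        ):
            X, ids = it.feature_matrix(reps, which)
            res = cl.consensus_cluster(
                X,
                k_range=range(config.k_min, config.k_max + 1),
                n_resamples=config.n_resamples,
                item_fraction=config.item_fraction,
                seed=config.seed * 10 + stream,
            )
            consensus_results[which] = res
            labels = res.assignments[res.chosen_k]
            merged, merge_map = cl.merge_small_clusters(
                labels, res.consensus[res.chosen_k], min_frac=config.min_cluster_frac
            )
            assign.loc[ids, colname] = labels
            assign.loc[ids, colname + "_merged"] = merged
            manifest[f"chosen_k_{colname}"] = int(res.chosen_k)
            manifest[f"merge_map_{colname}"] = {str(k): int(v) for k, v in merge_map.items()}
        assign.reset_index().to_csv(out / "cluster_assignments.csv", index=False)

        aris = {}
        for a, b in (("cluster_C", "cluster_M"), ("cluster_C", "cluster_B"),
                     ("cluster_M", "cluster_B")):
            common = assign[[a, b]].dropna()
            aris[f"{a}_vs_{b}"] = cl.adjusted_rand_index(
                common[a].to_numpy(), common[b].to_numpy()
            )
        manifest["ari"] = aris
    except Exception as exc:
        raise StageError("clustering", exc) from exc

    try:
        _stage("association")
        ptab = patients.merge(
            rep_table[["patient_id", "dispersion_mean", "dispersion_range"]],
            on="patient_id",
        ).merge(assign.reset_index(), on="patient_id")
        ptab["cluster_C_merged"] = ptab["cluster_C_merged"].map(
            lambda v: f"C{int(v)}" if pd.notna(v) else np.nan
        )
        disp_by_group = {
            g: grp["dispersion_range"].to_numpy()
            for g, grp in ptab.groupby("molecular_group")
        }
        disp_cmp = st.group_compare(disp_by_group, kind="numeric")
        manifest["dispersion_test"] = {
            "test": disp_cmp.test,
            "statistic": disp_cmp.statistic,
            "p_value": disp_cmp.p_value,
        }

        candidates = ["sex_female", "never_smoker", "dispersion_range",
                      "cluster_C_merged"]
        refs = {"cluster_C_merged": sorted(ptab["cluster_C_merged"].dropna().unique())[0]}
        uni = st.univariable_screen(ptab, "any_oa", candidates, refs)
        screened = st.screened_terms(uni)
        steps = (
            st.stepwise_logistic(ptab, "any_oa", screened, refs)
            if screened
            else st.StepwiseResult([], [])
        )
        st.estimates_frame(uni + steps.estimates).to_csv(
            out / "association_models.csv", index=False
        )
        manifest["screened_terms"] = screened
        manifest["stepwise_retained"] = steps.retained
        manifest["stepwise_trace"] = [
            [s, t, None if np.isnan(p) else p] for s, t, p in steps.trace
        ]
    except Exception as exc:
        raise StageError("association", exc) from exc

    try:
        _stage("survival")
        km = st.km_logrank(
            ptab["os_months"], ptab["os_event"], ptab["cluster_C_merged"].fillna("NA")
        )
        manifest["logrank"] = {"statistic": km.statistic, "p_value": km.p_value}
        cox = st.cox_fit(
            ptab.assign(
                any_oa=ptab["any_oa"].astype(float),
                sex_female=ptab["sex_female"].astype(float),
            ),
            "os_months",
            "os_event",
            ["dispersion_range", "age", "sex_female", "who_ps", "stage_ivb"],
        )
        st.estimates_frame(cox).to_csv(out / "cox_models.csv", index=False)
    except Exception as exc:
        raise StageError("survival", exc) from exc

    try:
        _stage("evaluation")
        eval_data = ptab.dropna(subset=["cluster_C_merged"]).copy()
        for lvl in sorted(eval_data["cluster_C_merged"].unique())[1:]:
            eval_data[f"clusterC_{lvl}"] = (
                eval_data["cluster_C_merged"] == lvl
            ).astype(float)
        cluster_cols = [c for c in eval_data.columns if c.startswith("clusterC_")]
        sets = {
            "CR": ["sex_female", "never_smoker", "age"],
            "CR+C": ["sex_female", "never_smoker", "age"] + cluster_cols,
            "CR+C+D": ["sex_female", "never_smoker", "age"]
            + cluster_cols
            + ["dispersion_range"],
        }
        mccv_res = ev.mccv(
            eval_data,
            "any_oa",
            sets,
            n_splits=config.mccv_splits,
            test_fraction=config.mccv_test_fraction,
            seed=config.seed + 7,
        )
        ev.compare_feature_sets(mccv_res).to_csv(out / "mccv_comparison.csv", index=False)
        manifest["mccv"] = {
            name: {"mean_auroc": r.mean_auroc, "ci": [r.ci_low, r.ci_high]}
            for name, r in mccv_res.items()
        }
    except Exception as exc:
        raise StageError("evaluation", exc) from exc

    _stage("manifest")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
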