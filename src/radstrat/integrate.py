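"""Patient-level integration of lesion-level radiomic features.

Three representations per patient:

* **centroid** — coordinate-wise mean of all lesion feature vectors
  (feeds centroid-based clustering, Cluster-C);
* **largest lesion** — features of the lesion with maximal segmented volume
  (Cluster-M);
* **biopsied lesion** — features of the flagged biopsied lesion when one
  exists (Cluster-B); patients without one are excluded from Cluster-B.

From the centroid, the Euclidean distance of every lesion is computed; the
mean and the range (max - min) of those distances are per-patient proxies for
the spatial dispersion of the radiophenotype across lesions.  A patient with
exactly two lesions has two equal distances, hence range exactly 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthdata import feature_columns

logger = logging.getLogger(__name__)


@dataclass
class PatientRepresentation:
    patient_id: str
    centroid: np.ndarray
    lesion_distances: np.ndarray
    dispersion_mean: float
    dispersion_range: float
    largest_features: np.ndarray
    biopsied_features: np.ndarray | None


def patient_centroid(lesions: pd.DataFrame) -> np.ndarray:
    """Coordinate-wise mean of one patient's lesion feature vectors."""
    if len(lesions) < 2:
        raise ValueError("patient must have at least 2 lesions")
    feats = feature_columns(lesions)
    return lesions[feats].to_numpy(dtype=float).mean(axis=0)


def dispersion_stats(
    lesions: pd.DataFrame, centroid: np.ndarray
) -> tuple[np.ndarray, float, float]:
    """Lesion-to-centroid Euclidean distances with their mean and range."""
    feats = feature_columns(lesions)
    X = lesions[feats].to_numpy(dtype=float)
    if X.shape[1] != centroid.shape[0]:
        raise ValueError("centroid dimension does not match feature count")
    d = np.linalg.norm(X - centroid, axis=1)
    if len(d) == 2:
        # the two distances are mathematically identical; make the range an
        # exact zero instead of rounding noise
        return d, float(d.mean()), 0.0
    return d, float(d.mean()), float(d.max() - d.min())


def select_largest(lesions: pd.DataFrame) -> np.ndarray:
    """Features of the lesion with maximal volume; volume ties broken by the
    lexicographically smallest lesion_id (tie logged)."""
    if lesions["volume_cm3"].isna().any():
        raise ValueError("missing volumes")
    vols = lesions["volume_cm3"].to_numpy(dtype=float)
    vmax = vols.max()
    tied = lesions.loc[vols == vmax]
    if len(tied) > 1:
        logger.info(
            "volume tie for patient %s at %.4g cm3; choosing lesion %s",
            lesions["patient_id"].iloc[0],
            vmax,
            tied["lesion_id"].min(),
        )
        tied = tied.sort_values("lesion_id")
    feats = feature_columns(lesions)
    return tied.iloc[0][feats].to_numpy(dtype=float)


def select_biopsied(lesions: pd.DataFrame) -> np.ndarray | None:
    """Features of the flagged biopsied lesion, or None if no flag."""
    flagged = lesions.loc[lesions["is_biopsied"].astype(bool)]
    if len(flagged) > 1:
        raise ValueError(
            f"patient {lesions['patient_id'].iloc[0]} has multiple biopsied lesions"
        )
    if flagged.empty:
        return None
    feats = feature_columns(lesions)
    return flagged.iloc[0][feats].to_numpy(dtype=float)


def build_representations(table: pd.DataFrame) -> dict[str, PatientRepresentation]:
    """All patient representations for a (transformed) lesion table."""
    reps: dict[str, PatientRepresentation] = {}
    for pid, grp in table.groupby("patient_id", sort=True):
        c = patient_centroid(grp)
        d, dmean, drange = dispersion_stats(grp, c)
        reps[pid] = PatientRepresentation(
            patient_id=pid,
            centroid=c,
            lesion_distances=d,
            dispersion_mean=dmean,
            dispersion_range=drange,
            largest_features=select_largest(grp),
            biopsied_features=select_biopsied(grp),
        )
    return reps


def representation_table(reps: dict[str, PatientRepresentation]) -> pd.DataFrame:
    """Patient-level frame: dispersion stats + centroid / largest / biopsied
    feature blocks (biopsied columns NaN when unavailable)."""
    rows = []
    for pid, r in sorted(reps.items()):
        row: dict = {
            "patient_id": pid,
            "dispersion_mean": r.dispersion_mean,
            "dispersion_range": r.dispersion_range,
        }
        row.update({f"centroid_{i}": v for i, v in enumerate(r.centroid)})
        row.update({f"largest_{i}": v for i, v in enumerate(r.largest_features)})
        if r.biopsied_features is not None:
            row.update({f"biopsied_{i}": v for i, v in enumerate(r.biopsied_features)})
        rows.append(row)
    return pd.DataFrame(rows)


def feature_matrix(
    reps: dict[str, PatientRepresentation], which: str
) -> tuple[np.ndarray, list[str]]:
    """Stacked patient x feature matrix for one representation.

    ``which`` is one of ``centroid``, ``largest``, ``biopsied``; for
    ``biopsied``, patients without a biopsied lesion are dropped.
    """
    ids, vecs = [], []
    for pid, r in sorted(reps.items()):
        v = {
            "centroid": r.centroid,
            "largest": r.largest_features,
            "biopsied": r.biopsied_features,
        }[which]
        if v is None:
            continue
        ids.append(pid)
        vecs.append(v)
    return np.vstack(vecs), ids
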