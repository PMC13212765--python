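"""Worked-example data: published contingency counts.

A published cohort of 361 metastatic lung adenocarcinoma patients reports,
per molecular group (wild-type WT, smoker-related oncogenic alteration sOA,
non-smoker-related nsOA, and "any OA" = sOA or nsOA or other), the counts of
patients with each clinical/radiological characteristic and each radiomic
cluster label.  Those printed counts are sufficient inputs for the
univariable odds-ratio analyses, so they serve as a worked example whose
results can be checked against the corresponding published table.

Each 2x2 entry is ``(a, b, c, d)``: exposed cases, exposed references,
unexposed cases, unexposed references; the case group is named in the key and
the reference group is WT unless the key says otherwise.
"""

from __future__ import annotations

# exposure | case group vs reference group -> (a, b, c, d)
CONTINGENCY_2X2: dict[str, tuple[int, int, int, int]] = {
    # any OA (n=233) vs WT (n=92)
    "sex_women|any_oa_vs_wt": (108, 29, 125, 63),
    "pleural|any_oa_vs_wt": (53, 11, 180, 81),
    # sOA (n=174) vs WT
    "pleural|soa_vs_wt": (40, 11, 134, 81),
    # nsOA (n=47) vs WT (smoking status known for 90 WT)
    "never_smoker|nsoa_vs_wt": (25, 7, 22, 83),
    "brain|nsoa_vs_wt": (23, 26, 24, 66),
    "bone|nsoa_vs_wt": (32, 42, 15, 50),
    "sex_women|nsoa_vs_wt": (31, 29, 16, 63),
    # nsOA vs sOA (smoking known for 172 sOA)
    "never_smoker|nsoa_vs_soa": (25, 6, 22, 166),
    "sex_women|nsoa_vs_soa": (31, 68, 16, 106),
    "peritoneal|nsoa_vs_soa": (0, 21, 47, 153),
}

# merged largest-lesion cluster label -> (cases, references); reference level
# is the M3+M4 class
CLUSTER_M_COUNTS: dict[str, dict[str, tuple[int, int]]] = {
    "any_oa_vs_wt": {"M1": (39, 6), "M2+M5": (93, 22), "M3+M4": (101, 64)},
    "soa_vs_wt": {"M1": (34, 6), "M2+M5": (63, 22), "M3+M4": (77, 64)},
}


def cluster_m_long(comparison: str):
    """Expand the per-level cluster counts to one row per patient
    (outcome flag + cluster level), ready for logistic screening."""
    import pandas as pd

    rows = []
    for level, (cases, refs) in CLUSTER_M_COUNTS[comparison].items():
        rows += [{"case": True, "cluster_m": level}] * cases
        rows += [{"case": False, "cluster_m": level}] * refs
    return pd.DataFrame(rows)
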