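"""Whole-cohort analysis: every headline quantity of the study pipeline.

:func:`run_study_analysis` takes a cohort and recomputes the group-level
results from scratch — risk-score diagnostics, outcome classes, fMRI
added-risk and lateralization-pattern counts, the Spearman correlations
between the laterality indices and the psychometric change scores (per side
of surgery and pooled), volumetry summaries, and the univariate logistic
odds ratios of the candidate predictors of verbal decline.
"""

from __future__ import annotations

from dataclasses import asdict
from typing import Dict, Optional

import numpy as np

from .cohort import Cohort
from .risk import assess_cohort
from .stats import (
    median_range,
    sens_spec,
    spearman,
    univariate_logistic_or,
)

__all__ = ["run_study_analysis"]

#: (x column, y column, group) of the correlations examined by the pipeline
CORRELATION_PANEL = (
    ("li_broca_verbal", "cd_list_change", "LTLE"),
    ("li_mtl_verbal", "cd_list_change", "LTLE"),
    ("li_broca_verbal", "cd_list_change", "RTLE"),
    ("li_mtl_verbal", "cd_list_change", "RTLE"),
    ("li_mtl_visuospatial", "rcft_change", "LTLE"),
    ("li_mtl_visuospatial", "rcft_change", "RTLE"),
    ("li_mtl_visuospatial", "rcft_change", "all"),
)

#: candidate predictors entered one at a time into the logistic model
LOGISTIC_PREDICTORS = (
    "age_onset",
    "duration",
    "resected_volume",
    "remaining_hc_volume",
    "cd_list_baseline",
    "li_broca_verbal",
    "li_mtl_verbal",
    "li_mtl_visuospatial",
)


def _group_frame(df, cohort_df, group: str):
    if group == "all":
        return cohort_df
    side = "L" if group == "LTLE" else "R"
    return cohort_df[cohort_df["side"] == side]


def run_study_analysis(cohort: Cohort) -> Dict:
    """Recompute the full analysis for a cohort; returns a nested dict."""
    table = assess_cohort(cohort)
    df = cohort.to_dataframe().set_index("patient_id")

    # --- risk score vs decline -------------------------------------------
    highrisk = (table["risk_band"] == "medium_high").to_numpy()
    declined = table["verbal_significant_decline"].to_numpy()
    diag = sens_spec(highrisk, declined)

    outcome_counts = table["outcome_class"].value_counts().to_dict()
    unexpected_ids = sorted(
        table.index[table["outcome_class"] == "unexpected"].tolist()
    )

    grade_counts = {
        g: int((table["fmri_added_risk"] == g).sum()) for g in ("0", "+", "++")
    }

    # patients whose verbal-task LIs both match the side-specific
    # expectation (i.e. graded "0")
    pattern = {}
    for group, side in (("RTLE", "R"), ("LTLE", "L")):
        sub = table[table["side"] == side]
        pattern[group] = {
            "predicted_pattern": int((sub["fmri_added_risk"] == "0").sum()),
            "n": int(len(sub)),
        }

    vis_counts = table["visuospatial_class"].value_counts().to_dict()

    # --- correlations -----------------------------------------------------
    correlations = []
    for x_col, y_col, group in CORRELATION_PANEL:
        sub = _group_frame(table, df, group)
        try:
            res = spearman(
                sub[x_col].tolist(), sub[y_col].tolist(),
                x_name=x_col, y_name=y_col, group=group,
            )
            correlations.append(asdict(res))
        except ValueError:
            continue

    # --- univariate logistic odds ratios ---------------------------------
    odds_ratios = {}
    y = declined.astype(bool)
    for col in LOGISTIC_PREDICTORS:
        x = df[col].to_numpy(dtype=float)
        keep = ~np.isnan(x)
        if keep.sum() < 4 or len(set(y[keep])) < 2:
            continue
        odds_ratios[col] = asdict(univariate_logistic_or(x[keep], y[keep]))

    # --- volumetry --------------------------------------------------------
    res_med, res_min, res_max = median_range(df["resected_volume"].tolist())
    rem = df["remaining_hc_volume"].tolist()
    rem_med, rem_min, rem_max = median_range(rem)

    sens_rounded, spec_rounded = diag.rounded()
    return {
        "n_patients": len(cohort),
        "n_left": int((df["side"] == "L").sum()),
        "n_right": int((df["side"] == "R").sum()),
        "per_patient": table.reset_index().to_dict(orient="records"),
        "ras_diagnostics": {
            **asdict(diag),
            "sensitivity_rounded": sens_rounded,
            "specificity_rounded": spec_rounded,
        },
        "outcome": {
            "expected": int(outcome_counts.get("expected", 0)),
            "unexpected": int(outcome_counts.get("unexpected", 0)),
            "unexpected_ids": unexpected_ids,
        },
        "fmri_added_risk_counts": grade_counts,
        "predicted_pattern": pattern,
        "visuospatial_lateralization": {
            "left": int(vis_counts.get("left", 0)),
            "right": int(vis_counts.get("right", 0)),
            "bilateral": int(vis_counts.get("bilateral", 0)),
        },
        "correlations": correlations,
        "odds_ratios": odds_ratios,
        "volumetry": {
            "resected_volume": {
                "median": res_med, "min": res_min, "max": res_max,
                "n": int(df["resected_volume"].notna().sum()),
            },
            "remaining_hc_volume": {
                "median": rem_med, "min": rem_min, "max": rem_max,
                "n": int(df["remaining_hc_volume"].notna().sum()),
            },
        },
    }


def find_correlation(result: Dict, x_name: str, y_name: str, group: str
                     ) -> Optional[Dict]:
    """Pull one correlation entry out of a :func:`run_study_analysis` dict."""
    for c in result["correlations"]:
        if (c["x_name"], c["y_name"], c["group"]) == (x_name, y_name, group):
            return c
    return None
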