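"""Clinical Risk Assessment Score (RAS), fMRI added-risk grading and
expected/unexpected outcome classification.

The RAS sums three binary risk points for post-operative verbal memory
decline:

* dominant-hemisphere resection (1) vs non-dominant (0),
* MRI-negative, i.e. no structural pathology (1) vs MRI-positive (0) —
  a normal scan in an operable epilepsy implies functionally intact,
  and therefore vulnerable, tissue,
* good baseline verbal memory, CD list learning >= -1 SD (1) vs poor (0).

Totals of 0-1 mean low risk; 2-3 mean medium-high risk.

Independently of the RAS, the fMRI laterality indices are graded against
the pattern expected for the side of surgery: language should lateralize
left in both groups; verbal encoding should lateralize away from the
epileptogenic medial temporal lobe (right for left-sided foci, left for
right-sided foci). A deviating language LI in the Broca ROI grades "++"
(added risk); an expected language LI with a deviating encoding LI in the
MTL ROI grades "+" (possible added risk); otherwise "0". The visuospatial
LI is expected contralateral to the focus but is excluded from the verbal
grading.

An outcome is *expected* when a medium-high score is followed by
significant verbal decline or a low score by intact verbal memory, and
*unexpected* otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Tuple

import pandas as pd

from .change_scores import classify_rcft_change, classify_verbal_change
from .cohort import Cohort, PatientRecord
from .laterality import classify_li

__all__ = [
    "RiskAssessment",
    "ras_score",
    "expected_pattern",
    "fmri_added_risk",
    "outcome_class",
    "assess_patient",
    "assess_cohort",
]

GOOD_BASELINE_SD = -1.0   # CD list learning at or above this = good baseline

ADDED_RISK_NONE = "0"
ADDED_RISK_POSSIBLE = "+"
ADDED_RISK_SIGNIFICANT = "++"


@dataclass(frozen=True)
class RiskAssessment:
    """Per-patient risk breakdown; fMRI/outcome fields filled when known."""

    dominance_point: int
    mri_point: int
    baseline_point: int
    ras_total: int
    risk_band: str                            # {"low", "medium_high"}
    fmri_added_risk: Optional[str] = None     # {"0", "+", "++"}
    expected_language: Optional[str] = None
    expected_encoding: Optional[str] = None
    outcome_class: Optional[str] = None       # {"expected", "unexpected"}

    def __post_init__(self) -> None:
        if self.ras_total != (
            self.dominance_point + self.mri_point + self.baseline_point
        ):
            raise ValueError("ras_total must equal the sum of the three points")
        expected_band = "low" if self.ras_total <= 1 else "medium_high"
        if self.risk_band != expected_band:
            raise ValueError(
                f"risk_band {self.risk_band!r} inconsistent with total "
                f"{self.ras_total}"
            )


def ras_score(
    dominant_resection: bool, mri_positive: bool, cd_list_baseline: float
) -> RiskAssessment:
    """Three-point clinical risk score and its band.

    ``cd_list_baseline`` is the pre-operative CD list-learning score in SD
    units; scores at or above -1.0 SD count as good baseline memory.
    """
    if cd_list_baseline is None:
        raise ValueError("RAS requires a baseline CD list-learning score")
    dominance_point = 1 if dominant_resection else 0
    mri_point = 0 if mri_positive else 1
    baseline_point = 1 if cd_list_baseline >= GOOD_BASELINE_SD else 0
    total = dominance_point + mri_point + baseline_point
    return RiskAssessment(
        dominance_point=dominance_point,
        mri_point=mri_point,
        baseline_point=baseline_point,
        ras_total=total,
        risk_band="low" if total <= 1 else "medium_high",
    )


def expected_pattern(side: str) -> Tuple[str, str, str]:
    """Expected (language, verbal-encoding, visuospatial) lateralization.

    Language is expected left for either side of surgery. Verbal encoding
    and visuospatial activity are expected contralateral to the
    epileptogenic focus. The visuospatial expectation is reported but not
    used in the added-risk grading.
    """
    if side == "L":
        return ("left", "right", "right")
    if side == "R":
        return ("left", "left", "left")
    raise ValueError(f"side must be 'L' or 'R', got {side!r}")


def fmri_added_risk(side: str, li_broca: float, li_mtl_verbal: float) -> str:
    """Grade the added risk signalled by the two verbal-task LIs.

    A deviation is any classified category (left/right/bilateral, +/-0.1
    cutoffs) differing from the expected one — bilateral counts as a
    deviation from a lateralized expectation. A language deviation grades
    '++' regardless of the encoding LI; an encoding deviation alone grades
    '+'.
    """
    exp_language, exp_encoding, _ = expected_pattern(side)
    if classify_li(li_broca) != exp_language:
        return ADDED_RISK_SIGNIFICANT
    if classify_li(li_mtl_verbal) != exp_encoding:
        return ADDED_RISK_POSSIBLE
    return ADDED_RISK_NONE


def outcome_class(risk_band: str, verbal_significant_decline: bool) -> str:
    """'expected' iff the decline matches the risk band's prediction."""
    if risk_band not in ("low", "medium_high"):
        raise ValueError(f"unknown risk band {risk_band!r}")
    if verbal_significant_decline is None:
        raise ValueError("outcome classification requires a decline label")
    predicted_decline = risk_band == "medium_high"
    return "expected" if predicted_decline == verbal_significant_decline else "unexpected"


def assess_patient(record: PatientRecord) -> RiskAssessment:
    """Full assessment of one patient: RAS, fMRI grade and outcome class."""
    base = ras_score(
        record.dominant_resection, record.mri_positive, record.cd_list_baseline
    )
    decline = classify_verbal_change(
        record.cd_list_change, record.cd_delayed_change
    ).verbal_significant_decline
    exp_language, exp_encoding, _ = expected_pattern(record.side)
    return replace(
        base,
        fmri_added_risk=fmri_added_risk(
            record.side, record.li_broca_verbal, record.li_mtl_verbal
        ),
        expected_language=exp_language,
        expected_encoding=exp_encoding,
        outcome_class=outcome_class(base.risk_band, decline),
    )


def assess_cohort(cohort: Cohort) -> pd.DataFrame:
    """Per-patient assessment table for a whole cohort.

    Columns: the RAS point breakdown and band, the fMRI added-risk grade,
    the three observed LI classes, the verbal and visuospatial decline
    labels, and the expected/unexpected outcome class.
    """
    rows = []
    for r in cohort:
        a = assess_patient(r)
        verbal = classify_verbal_change(r.cd_list_change, r.cd_delayed_change)
        rows.append(
            {
                "patient_id": r.patient_id,
                "side": r.side,
                "dominance_point": a.dominance_point,
                "mri_point": a.mri_point,
                "baseline_point": a.baseline_point,
                "ras_total": a.ras_total,
                "risk_band": a.risk_band,
                "language_class": classify_li(r.li_broca_verbal),
                "encoding_class": classify_li(r.li_mtl_verbal),
                "visuospatial_class": classify_li(r.li_mtl_visuospatial),
                "fmri_added_risk": a.fmri_added_risk,
                "verbal_significant_decline": verbal.verbal_significant_decline,
                "rcft_significant_decline": classify_rcft_change(r.rcft_change),
                "outcome_class": a.outcome_class,
            }
        )
    return pd.DataFrame(rows).set_index("patient_id")
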