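"""Pre/post psychometric change-score classification.

Change scores are post-operative minus pre-operative test scores in SD
units. A verbal change of at least 1.0 SD counts as significant; changes of
0.5-0.9 SD count as minor. A minor deterioration in list learning that is
accompanied by a significant deterioration in delayed recall also counts as
a significant verbal-memory decline, because encoding and retention losses
compound clinically. Visuospatial retention (RCFT delayed recall) uses the
same -1.0 SD significance criterion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .cohort import Cohort

__all__ = [
    "ChangeClassification",
    "classify_verbal_change",
    "classify_rcft_change",
    "verbal_decline_ids",
]

# decision thresholds, in SD units of the age/education-corrected norms
SIGNIFICANT_SD = 1.0
MINOR_SD = 0.5

_BANDS = (
    "significant_decline",
    "minor_deterioration",
    "stable",
    "minor_improvement",
    "significant_improvement",
)


@dataclass(frozen=True)
class ChangeClassification:
    """Outcome of the verbal change-score rules for one patient."""

    cd_list_class: str                       # one of the five change bands
    verbal_significant_decline: bool
    rcft_significant_decline: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.cd_list_class not in _BANDS:
            raise ValueError(f"unknown change band {self.cd_list_class!r}")


def _band(delta: float) -> str:
    if delta <= -SIGNIFICANT_SD:
        return "significant_decline"
    if delta <= -MINOR_SD:
        return "minor_deterioration"
    if delta >= SIGNIFICANT_SD:
        return "significant_improvement"
    if delta >= MINOR_SD:
        return "minor_improvement"
    return "stable"


def classify_verbal_change(
    cd_list_change: float, cd_delayed_change: float
) -> ChangeClassification:
    """Classify a verbal memory change score pair.

    Significant verbal decline holds iff

    * list learning dropped by >= 1.0 SD, or
    * list learning dropped by 0.5-0.9 SD (minor deterioration) *and*
      delayed recall dropped by >= 1.0 SD.

    Boundaries are inclusive: a change of exactly -1.0 is significant and
    exactly -0.5 is minor.
    """
    if cd_list_change is None or cd_delayed_change is None:
        raise ValueError("verbal change classification requires both CD change scores")
    band = _band(cd_list_change)
    decline = band == "significant_decline" or (
        band == "minor_deterioration" and cd_delayed_change <= -SIGNIFICANT_SD
    )
    return ChangeClassification(cd_list_class=band, verbal_significant_decline=decline)


def classify_rcft_change(rcft_change: Optional[float]) -> Optional[bool]:
    """True iff visuospatial retention dropped by >= 1.0 SD; None propagates."""
    if rcft_change is None:
        return None
    return rcft_change <= -SIGNIFICANT_SD


def verbal_decline_ids(cohort: Cohort) -> set[int]:
    """Ids of patients with significant post-operative verbal memory decline."""
    return {
        r.patient_id
        for r in cohort
        if classify_verbal_change(
            r.cd_list_change, r.cd_delayed_change
        ).verbal_significant_decline
    }
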