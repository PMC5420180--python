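"""Typed cohort container and delimited-file I/O.

A :class:`Cohort` is an ordered collection of :class:`PatientRecord`, one per
surgical candidate, holding the clinical variables used by the risk model:
side of the epileptogenic (to-be-resected) temporal lobe, hemisphere
dominance, structural-MRI status, baseline and change scores of the
psychometric battery (in age/education-corrected SD units), the three fMRI
laterality indices, and resection volumetry.

The built-in 14-patient study cohort is shipped as a plain CSV and loaded
with :func:`builtin_cohort`. Missing cells (one patient lacks the
visuospatial retention score, one lacks a remaining-hippocampus volume) are
empty strings on disk and ``None`` in memory — never zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping, Optional, Union

import pandas as pd
import yaml

__all__ = [
    "PatientRecord",
    "Cohort",
    "CohortError",
    "load_cohort",
    "write_cohort",
    "builtin_cohort",
]


class CohortError(ValueError):
    """Raised for malformed or invalid cohort files/records."""


#: fields that may legitimately be missing (visuospatial retention was not
#: obtained for one patient; one resection cavity precluded hippocampal
#: volumetry)
_OPTIONAL_FIELDS = frozenset({"rcft_baseline", "rcft_change", "remaining_hc_volume"})

_LI_FIELDS = ("li_broca_verbal", "li_mtl_verbal", "li_mtl_visuospatial")

_BOOL_FIELDS = ("mri_positive", "seizure_free")


@dataclass(frozen=True)
class PatientRecord:
    """One surgical candidate.

    Change scores are signed post-minus-pre deltas in SD units (negative =
    deterioration). Laterality indices lie in [-1, 1], positive = left.
    """

    patient_id: int
    sex: str                          # {M, F}
    age_onset: float                  # years
    duration: float                   # years of epilepsy
    side: str                         # {L, R}: epileptogenic / resected lobe
    dominant_hemisphere: str          # {left, right, unknown}
    mri_positive: bool                # structural pathology on MRI
    cd_list_baseline: float           # CD list learning, SD units
    cd_delayed_baseline: float        # CD delayed recall, SD units
    rcft_baseline: Optional[float]    # RCFT delayed recall, SD units
    cd_list_change: float
    cd_delayed_change: float
    rcft_change: Optional[float]
    li_broca_verbal: float            # language LI, Broca ROI
    li_mtl_verbal: float              # verbal-encoding LI, MTL ROI
    li_mtl_visuospatial: float        # visuospatial LI, MTL ROI
    resected_volume: float            # cm^3
    remaining_hc_volume: Optional[float]  # cm^3
    seizure_free: bool
    intertest_interval: float         # months between pre/post testing

    def __post_init__(self) -> None:
        if self.side not in ("L", "R"):
            raise CohortError(
                f"patient {self.patient_id}: side must be 'L' or 'R', got {self.side!r}"
            )
        if self.sex not in ("M", "F"):
            raise CohortError(
                f"patient {self.patient_id}: sex must be 'M' or 'F', got {self.sex!r}"
            )
        if self.dominant_hemisphere not in ("left", "right", "unknown"):
            raise CohortError(
                f"patient {self.patient_id}: dominant_hemisphere must be "
                f"left/right/unknown, got {self.dominant_hemisphere!r}"
            )
        for name in _LI_FIELDS:
            v = getattr(self, name)
            if v is None or not -1.0 <= v <= 1.0:
                raise CohortError(
                    f"patient {self.patient_id}: {name}={v!r} outside [-1, 1]"
                )
        for f in fields(self):
            if getattr(self, f.name) is None and f.name not in _OPTIONAL_FIELDS:
                raise CohortError(
                    f"patient {self.patient_id}: required field {f.name} is missing"
                )

    @property
    def dominant_resection(self) -> bool:
        """True when the resected lobe is on the dominant hemisphere."""
        return (self.side == "L") == (self.dominant_hemisphere == "left")


class Cohort:
    """Ordered, id-unique collection of patient records."""

    def __init__(self, records, provenance: str = "") -> None:
        records = list(records)
        if not records:
            raise CohortError("a cohort must contain at least one patient")
        ids = [r.patient_id for r in records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortError(f"duplicate patient ids: {dupes}")
        self.records: list[PatientRecord] = records
        self.provenance = provenance

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def __getitem__(self, patient_id: int) -> PatientRecord:
        for r in self.records:
            if r.patient_id == patient_id:
                return r
        raise KeyError(patient_id)

    def subset(self, side: Optional[str] = None) -> "Cohort":
        """Restrict to one epileptogenic side ('L' or 'R')."""
        recs = [r for r in self.records if side is None or r.side == side]
        return Cohort(recs, provenance=f"{self.provenance} [side={side}]")

    def to_dataframe(self) -> pd.DataFrame:
        """One row per patient; missing values become NaN."""
        return pd.DataFrame([vars(r) for r in self.records])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n_l = sum(r.side == "L" for r in self.records)
        return f"Cohort(n={len(self)}, left={n_l}, right={len(self) - n_l})"


def _coerce(name: str, raw, row_label) -> object:
    """Convert one CSV cell to its field type; '' / NaN -> None."""
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    if isinstance(raw, str):
        s = raw.strip()
        # table transcriptions use '--' or '*' for unavailable measurements
        if s in ("", "--", "*", "--*", "NA", "NaN"):
            return None
        raw = s
    try:
        if name == "patient_id":
            return int(raw)
        if name in _BOOL_FIELDS:
            if isinstance(raw, str):
                low = raw.lower()
                if low in ("true", "yes", "1"):
                    return True
                if low in ("false", "no", "0"):
                    return False
                raise ValueError(raw)
            return bool(raw)
        if name in ("sex", "side", "dominant_hemisphere"):
            return str(raw)
        return float(raw)
    except (TypeError, ValueError) as exc:
        raise CohortError(
            f"row {row_label}, column {name!r}: cannot parse value {raw!r}"
        ) from exc


def _load_column_map(dialect) -> Mapping[str, str]:
    """dialect: None, a mapping {file column -> field}, or a YAML/JSON path."""
    if dialect is None:
        return {}
    if isinstance(dialect, Mapping):
        return dict(dialect)
    with open(dialect) as fh:
        loaded = yaml.safe_load(fh)
    if not isinstance(loaded, Mapping):
        raise CohortError(f"column-map config {dialect} must hold a mapping")
    return dict(loaded)


def load_cohort(
    path: Union[str, Path],
    dialect: Union[None, Mapping[str, str], str, Path] = None,
) -> Cohort:
    """Read a delimited cohort file (CSV or TSV, header row, UTF-8).

    Parameters
    ----------
    path
        Cohort file, one patient per row.
    dialect
        Optional column mapping (file column name -> :class:`PatientRecord`
        field name), given inline or as a YAML/JSON file.

    Raises
    ------
    CohortError
        Empty file, unknown/missing columns, unparsable cells, or field
        values violating the record invariants (e.g. an LI outside [-1, 1]).
    """
    import csv

    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    except (pd.errors.EmptyDataError, csv.Error) as exc:
        raise CohortError(f"{path}: empty or undelimited cohort file") from exc
    if df.empty:
        raise CohortError(f"{path}: cohort file has a header but no rows")
    df = df.rename(columns=_load_column_map(dialect))

    field_names = [f.name for f in fields(PatientRecord)]
    missing_cols = sorted(set(field_names) - set(df.columns))
    if missing_cols:
        raise CohortError(f"{path}: missing columns {missing_cols}")

    records = []
    for i, row in df.iterrows():
        kwargs = {name: _coerce(name, row[name], i + 2) for name in field_names}
        records.append(PatientRecord(**kwargs))
    return Cohort(records, provenance=str(path))


def write_cohort(cohort: Cohort, path: Union[str, Path]) -> None:
    """Write a cohort as CSV; missing values become empty cells."""
    df = cohort.to_dataframe()
    df.to_csv(path, index=False)


def builtin_cohort() -> Cohort:
    """The packaged 14-patient study cohort (8 left, 6 right resections).

    Values transcribe the published per-patient tables: clinical baseline
    data, the three laterality indices, post-operative change scores and
    volumetry. Hemisphere dominance is recorded as operationalized by the
    clinical risk score (left-dominant for all 14; the one non-dexterous
    patient was lateralized left by word-generation fMRI).
    """
    src = resources.files("memrisk.data").joinpath("cohort.csv")
    with resources.as_file(src) as p:
        cohort = load_cohort(p)
    cohort.provenance = "builtin 14-patient surgical cohort"
    return cohort


def builtin_cohort_path() -> Path:
    """Filesystem path of the packaged cohort CSV (for round-trip checks)."""
    with resources.as_file(
        resources.files("memrisk.data").joinpath("cohort.csv")
    ) as p:
        return Path(p)
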