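"""Synthetic statistic maps and cohorts for end-to-end testing.

No imaging or tabular data were deposited by the study this package
re-implements, so validation runs on simulated inputs with the same
structure:

* :func:`make_stat_map` builds a 3D "t-map" with two mirrored spherical
  ROIs. Gaussian signal blobs are placed at the ROI centres with left/right
  amplitudes proportional to (1+a)/2 and (1-a)/2, so the value-weighted LI
  of the noise-free map at threshold zero equals the asymmetry parameter
  ``a`` exactly. I.i.d. Gaussian noise and optional Gaussian smoothing are
  applied on top.

* :func:`make_cohort` draws cohorts with the statistical structure of the
  study tables: per-side risk-band frequencies, decline probabilities
  conditional on the risk band, categorical LI patterns per ROI, and change
  scores generated so that the change-score rules reproduce the drawn
  decline label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Tuple

import numpy as np
from scipy import ndimage

from .change_scores import classify_verbal_change
from .cohort import Cohort, PatientRecord
from .laterality import StatMapWithMasks

__all__ = ["MapSimParams", "CohortSimParams", "make_stat_map", "make_cohort"]


# --------------------------------------------------------------------------
# statistic maps
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MapSimParams:
    """Geometry and signal parameters of a simulated lateralized t-map.

    ``asymmetry`` is the target LI of the noise-free map: +1 puts all signal
    in the left ROI, 0 splits it evenly, -1 mirrors +1.
    """

    grid_shape: Tuple[int, int, int] = (36, 36, 36)
    roi_radius: float = 6.0          # voxels
    asymmetry: float = 0.0           # a in [-1, 1]
    signal_amplitude: float = 6.0    # peak t-value of the summed blobs
    noise_sd: float = 0.5            # t-units
    smoothing_fwhm: float = 0.0      # voxels; 0 disables smoothing
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 <= self.asymmetry <= 1.0:
            raise ValueError("asymmetry must lie in [-1, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.roi_radius <= 0:
            raise ValueError("roi_radius must be positive")


def _roi_centres(shape: Tuple[int, int, int]) -> Tuple[np.ndarray, np.ndarray]:
    nx, ny, nz = shape
    cy, cz = (ny - 1) / 2.0, (nz - 1) / 2.0
    # mirror-symmetric about the x midline (x = (nx-1)/2)
    left = np.array([(nx - 1) * 0.25, cy, cz])
    right = np.array([(nx - 1) * 0.75, cy, cz])
    return left, right


def make_stat_map(p: MapSimParams) -> StatMapWithMasks:
    """Simulate a lateralized statistic map with mirrored spherical ROIs.

    Deterministic for a given ``p.seed``. Raises ``ValueError`` when the
    grid cannot hold two disjoint ROIs of the requested radius.
    """
    left_c, right_c = _roi_centres(p.grid_shape)
    if np.linalg.norm(left_c - right_c) <= 2 * p.roi_radius:
        raise ValueError(
            "grid too small: the two spherical ROIs would overlap "
            f"(centres {np.linalg.norm(left_c - right_c):.1f} voxels apart, "
            f"radius {p.roi_radius})"
        )

    grid = np.indices(p.grid_shape, dtype=float)
    d_left = np.sqrt(((grid - left_c[:, None, None, None]) ** 2).sum(axis=0))
    d_right = np.sqrt(((grid - right_c[:, None, None, None]) ** 2).sum(axis=0))

    mask_left = d_left <= p.roi_radius
    mask_right = d_right <= p.roi_radius

    sigma_blob = p.roi_radius / 2.0
    amp_left = p.signal_amplitude * (1.0 + p.asymmetry) / 2.0
    amp_right = p.signal_amplitude * (1.0 - p.asymmetry) / 2.0
    values = amp_left * np.exp(-(d_left**2) / (2 * sigma_blob**2))
    values += amp_right * np.exp(-(d_right**2) / (2 * sigma_blob**2))

    if p.noise_sd > 0:
        rng = np.random.default_rng(p.seed)
        values = values + rng.normal(0.0, p.noise_sd, size=p.grid_shape)
    if p.smoothing_fwhm > 0:
        values = ndimage.gaussian_filter(
            values, sigma=p.smoothing_fwhm / 2.3548200450309493
        )
    return StatMapWithMasks(
        values=values, mask_left=mask_left, mask_right=mask_right
    )


def noise_free_map(p: MapSimParams) -> StatMapWithMasks:
    """The same geometry and asymmetry with noise and smoothing switched off.

    Used as the ground-truth reference ("what would the LI be without
    measurement noise?") when checking recovery on noisy simulations.
    """
    from dataclasses import replace

    return make_stat_map(replace(p, noise_sd=0.0, smoothing_fwhm=0.0))


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------

# per-side categorical LI-class frequencies matching the study cohort
_DEFAULT_LI_PROBS: Dict[str, Dict[str, Dict[str, float]]] = {
    "R": {
        "broca": {"left": 3 / 6, "right": 1 / 6, "bilateral": 2 / 6},
        "mtl_verbal": {"left": 3 / 6, "right": 2 / 6, "bilateral": 1 / 6},
        "mtl_visuospatial": {"left": 1.0, "right": 0.0, "bilateral": 0.0},
    },
    "L": {
        "broca": {"left": 7 / 8, "right": 1 / 8, "bilateral": 0.0},
        "mtl_verbal": {"left": 0.0, "right": 6 / 8, "bilateral": 2 / 8},
        "mtl_visuospatial": {"left": 5 / 8, "right": 2 / 8, "bilateral": 1 / 8},
    },
}


@dataclass(frozen=True)
class CohortSimParams:
    """Generative parameters of a synthetic surgical cohort.

    Defaults reproduce the observed study frequencies: risk-band rates of
    5/8 (left resections) and 3/6 (right), decline probabilities of 0.75
    given a medium-high clinical risk score and 1/3 given a low score, the
    per-side LI-pattern frequencies of the published tables, and one missing
    visuospatial score in fourteen.
    """

    n_left: int = 8
    n_right: int = 6
    decline_rate_given_highrisk: float = 0.75
    decline_rate_given_lowrisk: float = 1.0 / 3.0
    highrisk_rate_left: float = 5.0 / 8.0
    highrisk_rate_right: float = 3.0 / 6.0
    li_class_probs: Mapping[str, Mapping[str, Mapping[str, float]]] = field(
        default_factory=lambda: _DEFAULT_LI_PROBS
    )
    missing_rcft_rate: float = 1.0 / 14.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "decline_rate_given_highrisk",
            "decline_rate_given_lowrisk",
            "highrisk_rate_left",
            "highrisk_rate_right",
            "missing_rcft_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_left < 0 or self.n_right < 0:
            raise ValueError("cohort sizes must be non-negative")


def _draw_li(rng: np.random.Generator, probs: Mapping[str, float]) -> float:
    cls = rng.choice(["left", "right", "bilateral"],
                     p=[probs["left"], probs["right"], probs["bilateral"]])
    if cls == "left":
        return float(rng.uniform(0.15, 0.85))
    if cls == "right":
        return float(rng.uniform(-0.85, -0.15))
    return float(rng.uniform(-0.095, 0.095))


def _trunc_normal(
    rng: np.random.Generator, mu: float, sd: float,
    lo: float = -np.inf, hi: float = np.inf,
) -> float:
    for _ in range(200):
        v = rng.normal(mu, sd)
        if lo <= v <= hi:
            return float(v)
    return float(np.clip(mu, lo, hi))


def _draw_changes(rng: np.random.Generator, decline: bool) -> Tuple[float, float]:
    """CD list / delayed change scores realizing the intended decline label."""
    if decline:
        if rng.uniform() < 0.8:
            # outright significant drop in list learning
            cd_list = _trunc_normal(rng, -1.8, 0.6, hi=-1.0)
            cd_delayed = rng.normal(-0.8, 0.9)
        else:
            # combination route: minor list drop + significant delayed drop
            cd_list = float(rng.uniform(-0.99, -0.5))
            cd_delayed = _trunc_normal(rng, -1.8, 0.5, hi=-1.0)
    else:
        if rng.uniform() < 0.2:
            # minor deterioration that stays below the combination criterion
            cd_list = float(rng.uniform(-0.99, -0.5))
            cd_delayed = _trunc_normal(rng, 0.0, 0.7, lo=-0.99)
        else:
            cd_list = _trunc_normal(rng, 0.1, 0.7, lo=-0.49)
            cd_delayed = rng.normal(-0.2, 0.9)
    return float(cd_list), float(cd_delayed)


def _draw_ras_inputs(
    rng: np.random.Generator, side: str, highrisk: bool
) -> Tuple[bool, float]:
    """(mri_positive, cd_list_baseline) consistent with the drawn risk band.

    All simulated patients are left-hemisphere dominant (as in the study),
    so a left-sided resection contributes one risk point by itself.
    """
    dominance_point = 1 if side == "L" else 0
    if highrisk:                     # total must reach 2
        need = 2 - dominance_point
        if need >= 2:
            mri_point, baseline_point = 1, 1
        else:
            mri_point = int(rng.uniform() < 0.5)
            baseline_point = 1 if mri_point == 0 else int(rng.uniform() < 0.7)
    else:                            # total must stay <= 1
        allowed = 1 - dominance_point
        if allowed == 0:
            mri_point, baseline_point = 0, 0
        else:
            mri_point = int(rng.uniform() < 0.3)
            baseline_point = 0 if mri_point == 1 else int(rng.uniform() < 0.5)
    mri_positive = mri_point == 0
    if baseline_point == 1:
        baseline = _trunc_normal(rng, 0.0, 0.8, lo=-0.99)
    else:
        baseline = _trunc_normal(rng, -1.9, 0.7, hi=-1.01)
    return mri_positive, baseline


def make_cohort(p: CohortSimParams) -> Cohort:
    """Simulate a cohort with the study's tabular structure.

    Deterministic for a given ``p.seed``; raises ``CohortError`` (via the
    :class:`Cohort` constructor) when both group sizes are zero.
    """
    rng = np.random.default_rng(p.seed)
    records = []
    pid = 0
    for side, n, hr_rate in (
        ("R", p.n_right, p.highrisk_rate_right),
        ("L", p.n_left, p.highrisk_rate_left),
    ):
        for _ in range(n):
            pid += 1
            highrisk = rng.uniform() < hr_rate
            decline_rate = (
                p.decline_rate_given_highrisk if highrisk
                else p.decline_rate_given_lowrisk
            )
            decline = rng.uniform() < decline_rate
            mri_positive, baseline = _draw_ras_inputs(rng, side, highrisk)
            cd_list_change, cd_delayed_change = _draw_changes(rng, decline)
            # store at table precision; the draws keep a margin so rounding
            # cannot flip the realized decline label
            cd_list_change = round(cd_list_change, 2)
            cd_delayed_change = round(cd_delayed_change, 2)
            assert (
                classify_verbal_change(cd_list_change, cd_delayed_change)
                .verbal_significant_decline
                == decline
            )
            probs = p.li_class_probs[side]
            rcft_missing = rng.uniform() < p.missing_rcft_rate
            records.append(
                PatientRecord(
                    patient_id=pid,
                    sex="F" if rng.uniform() < 0.6 else "M",
                    age_onset=float(np.round(rng.uniform(1, 47), 1)),
                    duration=float(np.round(rng.uniform(3, 33), 1)),
                    side=side,
                    dominant_hemisphere="left",
                    mri_positive=mri_positive,
                    cd_list_baseline=round(baseline, 2),
                    cd_delayed_baseline=round(float(rng.normal(-0.7, 1.4)), 2),
                    rcft_baseline=None if rcft_missing
                    else round(float(rng.normal(-1.0, 1.1)), 2),
                    cd_list_change=cd_list_change,
                    cd_delayed_change=cd_delayed_change,
                    rcft_change=None if rcft_missing
                    else round(float(rng.normal(-0.1, 1.0)), 2),
                    li_broca_verbal=round(_draw_li(rng, probs["broca"]), 3),
                    li_mtl_verbal=round(_draw_li(rng, probs["mtl_verbal"]), 3),
                    li_mtl_visuospatial=round(
                        _draw_li(rng, probs["mtl_visuospatial"]), 3
                    ),
                    resected_volume=round(float(_trunc_normal(
                        rng, 25.0, 9.0, lo=5.0, hi=60.0)), 1),
                    remaining_hc_volume=round(float(_trunc_normal(
                        rng, 0.5, 0.7, lo=0.0, hi=3.0)), 1),
                    seizure_free=bool(rng.uniform() < 10 / 14),
                    intertest_interval=float(np.round(rng.uniform(3, 24), 1)),
                )
            )
    return Cohort(records, provenance=f"simulated cohort (seed={p.seed})")
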