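"""Cohort statistics: tie-corrected Spearman correlation with exact
small-sample p-values, diagnostic sensitivity/specificity, median/range
summaries, and univariate logistic odds ratios.

At the sample sizes of a single-centre surgical series (n = 6-14) the
asymptotic null of the rank correlation is unreliable, so for n <= 9 the
two-sided p-value is computed by full enumeration of the n! permutations of
one variable's ranks; larger samples use the usual t approximation with
n - 2 degrees of freedom. The coefficient itself is the Pearson correlation
of mid-ranks, which corrects for ties (the classical 6*sum(d^2) formula
does not).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "DiagnosticResult",
    "OddsRatioResult",
    "spearman",
    "sens_spec",
    "univariate_logistic_or",
    "median_range",
]

EXACT_PERMUTATION_MAX_N = 9   # 9! = 362,880 permutations, still instant


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int
    x_name: str = "x"
    y_name: str = "y"
    group: str = "all"
    method: str = "exact"     # p-value method: {"exact", "t-approx"}

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"|r|={abs(self.r)} exceeds 1")


def _complete_pairs(x, y) -> Tuple[np.ndarray, np.ndarray]:
    x = np.asarray(
        [np.nan if v is None else float(v) for v in x], dtype=float
    )
    y = np.asarray(
        [np.nan if v is None else float(v) for v in y], dtype=float
    )
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    return x[keep], y[keep]


def _rank_r(rx: np.ndarray, ry: np.ndarray) -> float:
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt((rxc**2).sum() * (ryc**2).sum())
    return float((rxc * ryc).sum() / denom)


def _exact_p(rx: np.ndarray, ry: np.ndarray, r_obs: float) -> float:
    """Two-sided permutation p: share of the n! rank permutations with
    |r| >= |r_obs| (to within floating slack)."""
    perms = np.array(list(itertools.permutations(ry)))
    rxc = rx - rx.mean()
    pc = perms - perms.mean(axis=1, keepdims=True)
    denom = np.sqrt((pc**2).sum(axis=1) * (rxc**2).sum())
    rs = pc @ rxc / denom
    return float(np.mean(np.abs(rs) >= abs(r_obs) - 1e-12))


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    *,
    x_name: str = "x",
    y_name: str = "y",
    group: str = "all",
) -> CorrelationResult:
    """Tie-corrected Spearman correlation with pairwise deletion.

    Pairs with a missing value in either variable are dropped; at least 3
    complete pairs are required. r is Pearson on mid-ranks. The two-sided
    p-value is exact (full permutation enumeration) for n <= 9 and a
    t-approximation otherwise.
    """
    xv, yv = _complete_pairs(x, y)
    n = xv.size
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    rx = sps.rankdata(xv)
    ry = sps.rankdata(yv)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("zero variance in ranks: correlation undefined")
    r = _rank_r(rx, ry)
    if n <= EXACT_PERMUTATION_MAX_N:
        p = _exact_p(rx, ry, r)
        method = "exact"
    else:
        # t = r * sqrt((n-2)/(1-r^2)), df = n-2
        r_clip = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
        t = r_clip * math.sqrt((n - 2) / (1.0 - r_clip**2))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
        method = "t-approx"
    return CorrelationResult(
        r=r, p=p, n=int(n), x_name=x_name, y_name=y_name, group=group,
        method=method,
    )


@dataclass(frozen=True)
class DiagnosticResult:
    """2x2 diagnostic counts of a binary predictor against a binary outcome.

    ``sensitivity``/``specificity`` are percentages (0-100), kept unrounded;
    ``None`` marks an undefined metric (no positives / no negatives).
    """

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: Optional[float]
    specificity: Optional[float]

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def rounded(self) -> Tuple[Optional[int], Optional[int]]:
        """(sensitivity, specificity) rounded to whole percent for display."""
        rnd = lambda v: None if v is None else int(round(v))
        return rnd(self.sensitivity), rnd(self.specificity)


def sens_spec(
    predicted_positive: Sequence[bool], condition_positive: Sequence[bool]
) -> DiagnosticResult:
    """Sensitivity and specificity of a binary prediction.

    Here the prediction is typically "medium-high clinical risk" and the
    condition "significant post-operative verbal memory decline".
    """
    pred = np.asarray(predicted_positive, dtype=bool)
    cond = np.asarray(condition_positive, dtype=bool)
    if pred.shape != cond.shape:
        raise ValueError("prediction and condition must have equal length")
    if pred.size == 0:
        raise ValueError("empty input")
    tp = int(np.sum(pred & cond))
    fp = int(np.sum(pred & ~cond))
    tn = int(np.sum(~pred & ~cond))
    fn = int(np.sum(~pred & cond))
    sens = 100.0 * tp / (tp + fn) if (tp + fn) > 0 else None
    spec = 100.0 * tn / (tn + fp) if (tn + fp) > 0 else None
    return DiagnosticResult(
        tp=tp, fp=fp, tn=tn, fn=fn, sensitivity=sens, specificity=spec
    )


@dataclass(frozen=True)
class OddsRatioResult:
    """Univariate logistic odds ratio per unit of the predictor.

    ``estimable`` is False under complete/quasi-separation or a degenerate
    predictor, in which case the numeric fields are None.
    """

    odds_ratio: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    p: Optional[float]
    n: int
    estimable: bool
    reason: str = ""


def univariate_logistic_or(
    x: Sequence[float], y: Sequence[bool]
) -> OddsRatioResult:
    """Odds ratio from a univariate logistic regression (Wald 95% CI).

    Fits outcome ~ intercept + x by maximum likelihood via statsmodels.
    Complete or quasi-separation, a constant predictor, or a non-converged
    fit are reported as non-estimable rather than returning a diverged
    estimate.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    xv, yv = _complete_pairs(x, [float(v) for v in y])
    n = xv.size
    if n < 2 or len(np.unique(yv)) < 2:
        raise ValueError("logistic regression needs both outcome classes")
    if np.ptp(xv) == 0:
        return OddsRatioResult(
            None, None, None, None, int(n), False, "constant predictor"
        )
    design = sm.add_constant(xv)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(yv, design).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        return OddsRatioResult(None, None, None, None, int(n), False, str(exc))
    beta = fit.params[1]
    se = fit.bse[1]
    # quasi-separation drives |beta| and its SE to absurd magnitudes
    if not np.isfinite(beta) or not np.isfinite(se) or abs(beta) > 15 or se > 50:
        return OddsRatioResult(
            None, None, None, None, int(n), False, "separation detected"
        )
    z = sps.norm.ppf(0.975)
    return OddsRatioResult(
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - z * se)),
        ci_high=float(np.exp(beta + z * se)),
        p=float(fit.pvalues[1]),
        n=int(n),
        estimable=True,
    )


def median_range(values: Sequence[Optional[float]]) -> Tuple[float, float, float]:
    """(median, min, max) of the non-missing values.

    Uses the average-of-the-middle-two convention for even counts. Raises
    ``ValueError`` when every value is missing.
    """
    arr = np.asarray(
        [np.nan if v is None else float(v) for v in values], dtype=float
    )
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("median of an all-missing sample is undefined")
    return float(np.median(arr)), float(arr.min()), float(arr.max())
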