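# Methods

## The clinical model

The pipeline targets one question: before an anterior temporal lobe
resection (ATLR), how likely is this patient to suffer a significant
post-operative verbal-memory decline, and does task-fMRI lateralization add
information beyond the standard clinical predictors?

Three binary clinical predictors form the Risk Assessment Score (RAS):
resection of the dominant hemisphere (1 point), a normal ("MRI-negative")
structural scan (1 point — in an operable epilepsy a normal scan implies
functionally adequate, and therefore vulnerable, tissue), and good baseline
verbal memory, operationalized as a CD list-learning score of at least
−1 SD of the age/education-corrected norms (1 point). Totals of 0–1 are a
low risk band, 2–3 medium–high. An outcome is *expected* when the band's
prediction (decline for medium–high, no decline for low) matches the
observed change-score label, *unexpected* otherwise.

Decline labels come from fixed rules on signed SD change scores (post minus
pre): list-learning change ≤ −1.0 SD is significant; changes of 0.5–0.9 SD
are minor; a minor list-learning deterioration combined with a delayed
recall change ≤ −1.0 SD also counts as significant verbal decline. All
boundaries are inclusive (−1.0 is significant, −0.5 is minor); this is
forced by the cohort itself — the patient with changes (−0.5, −1.1) carries
a decline label, which only the inclusive reading reproduces. The
visuospatial measure (RCFT delayed recall) uses the same −1.0 SD cutoff; the
rule reproduces the two visuospatial decliners of the cohort. Boundary
conventions matter at n = 14 and are pinned by tests.

The fMRI grading compares each patient's classified laterality pattern with
the side-specific expectation: language left-lateralized for either side of
surgery; verbal encoding contralateral to the epileptogenic focus (right
for left-sided foci, left for right-sided). A deviation of the language LI
(Broca ROI) grades `++` regardless of the encoding LI; an encoding
deviation (MTL ROI) alone grades `+`. "Deviation" means the classified
category differs from the expected one, so a bilateral index deviates from
any lateralized expectation — the only reading that reproduces all 14
published grades. The visuospatial LI is expected contralateral to the
focus but is excluded from the verbal grading, since the task probes
recollection rather than verbal encoding.

## Laterality-index engine

`LI(t) = (S_L − S_R)/(S_L + S_R)`, with `S_side` the sum of statistic
values above threshold `t` inside that side's mask. Values are summed
rather than voxels counted: the value-weighted index changes smoothly as
voxels cross a cutoff and is the convention of the clinical laterality
toolchains this engine mirrors. Left and right are defined solely by the
two mask images; the engine never infers hemisphere from the affine, and
the CLI only warns when the mask centroids do not straddle the volume's
x midline.

The bootstrap sweep (`LiConfig` defaults, all configurable):

* 20 equally spaced thresholds from `threshold_min = 0` to the in-mask
  maximum;
* at each usable threshold, 100 resamples per side, each drawing 25% of
  that side's suprathreshold voxels with replacement;
* all 100 × 100 left/right resample combinations, trimmed by 25% at each
  tail, averaged (scipy `trim_mean`);
* overall LI = threshold-value-weighted mean of the per-threshold trimmed
  means (`weighting="unweighted"` gives the plain mean; which of the two a
  given historical analysis used is usually unstated, so both are exposed).

Numerical and degenerate-input choices:

* A threshold is *usable* when the combined suprathreshold count of both
  masks reaches `min_voxels` (default 10). The rule is deliberately joint
  rather than per-side: a strictly one-sided map has zero surviving voxels
  on the silent side at every threshold, yet its laterality is maximally
  determined, not indeterminate. An empty side contributes a sum of 0, so
  such maps yield LI = ±1. Only when *no* threshold is usable does the
  engine raise `IndeterminateLateralityError`.
* Suprathreshold voxel values are sorted before resampling, and both sides
  restart an identical RNG substream keyed on (seed, threshold index).
  Mirrored masks of equal size therefore draw identical resample indices,
  which makes the LI of a left/right-mirrored map the exact negation of the
  original and makes a mirror-symmetric map return exactly 0 — the
  estimator's antisymmetry holds to machine precision instead of Monte
  Carlo tolerance.
* The degenerate configuration `resample_fraction=1, n_boot=1,
  trim_fraction=0` is defined as the identity resample (the full
  suprathreshold set, no random draw), so it coincides exactly with the
  deterministic threshold-sweep mean `threshold_sweep_mean`, which serves
  as the no-resampling reference throughout the tests.
* The overall LI is clipped to [−1, 1] against floating-point overshoot;
  per-threshold LIs of unusable thresholds are reported as missing, not 0.
* `seed` defaults to 0 and fully determines the estimate.

## Synthetic data

No imaging or per-voxel data accompany the packaged cohort, so the engine
is validated on simulated maps. `make_stat_map` places two mirrored
spherical ROIs (radius 6 voxels on a 36³ grid by default) and adds Gaussian
signal blobs at their centres with amplitudes proportional to (1+a)/2 and
(1−a)/2, so the value-weighted LI of the noise-free map at threshold 0
equals the asymmetry parameter `a` exactly; i.i.d. Gaussian noise
(default SD 0.5 against a peak amplitude of 6) and optional Gaussian
smoothing are applied on top. The geometry is deliberately abstract:
spherical ROIs on a mirrored grid, not anatomy — mask shape is irrelevant
to the correctness of a mask-defined index. What the simulation does *not*
emulate: spatially correlated physiological noise, BOLD time-series
structure, inter-subject anatomical variability, and hand-drawn ROI
asymmetries. Passing recovery tests therefore show estimator correctness,
not clinical accuracy on real maps.

Note that with threshold-value weighting the overall LI of a blob pair is
generally larger in magnitude than `a` (high thresholds retain only the
stronger peak); recovery tests therefore compare the noisy estimate against
the *noise-free sweep of the same geometry*, not against `a` itself.

`make_cohort` draws cohorts with the tabular structure of the study: side
of surgery, a risk band drawn per side (defaults 5/8 for left, 3/6 for
right — the packaged cohort's frequencies), RAS inputs generated consistent
with the drawn band, a decline label drawn conditional on the band
(defaults 0.75 | medium–high and 1/3 | low), change scores drawn so the
rule-based classification reproduces the label exactly (with margins so
that rounding to table precision cannot flip it), LI values drawn from
per-side categorical class frequencies matching the published tables, and
one missing RCFT score in fourteen. With the default rates and an 8:6 side
ratio the implied sensitivity/specificity are exactly 75%/67%, so parameter
recovery at n ≈ 2000 is a sharp end-to-end check of the whole
score→label→diagnostics chain (binomial SE ≈ 1.3 points at that n).
Demographics and volumetry are drawn from plausible ranges and carry no
signal.

## Statistics

*Spearman correlation* is the Pearson correlation of mid-ranks, which
handles ties (the classical 6Σd² formula does not and fails to reproduce
the published coefficients for these data, which contain tied LIs). Pairs
with a missing value are deleted pairwise. For n ≤ 9 the two-sided p-value
is exact — the share of all n! rank permutations with |r| at least as
extreme — computed by vectorized enumeration (9! = 362,880, instant); for
larger n the usual t-approximation with n − 2 df is used. At these sample
sizes exact and asymptotic p can differ a lot (r = 0.714 at n = 6: exact
two-sided 0.136 vs one-sided t-approx 0.055), so the correlation
coefficient, not p, is the reproducibility anchor; `CorrelationResult`
records which method produced its p.

*Sensitivity/specificity* are plain 2×2 ratios kept unrounded, with
`None` marking an undefined metric (no positives or no negatives) and a
`rounded()` display helper.

*Univariate logistic odds ratios* delegate the maximum-likelihood fit to
statsmodels `Logit` (one predictor at a time, Wald 95% CI). Complete or
quasi-separation — a real hazard at n = 14 with binary-ish predictors — is
reported as `estimable=False` (detected via the fitter's separation error
or a diverged |coefficient| > 15 / SE > 50) instead of returning an
absurd estimate. No multivariate model is fitted: fourteen observations
cannot support one.

*median_range* uses the average-of-the-middle-two convention for even
counts and excludes missing values. On the packaged cohort this yields a
resected-volume median of 24.5 cm³ over 14 patients (24 at integer display
precision) and a remaining-hippocampus median of 0.2 cm³ over the 13
patients with a measurable remnant.

## Cohort conventions

Missing table cells are empty strings on disk and `None` in memory, never
zeros; only the RCFT scores and the remaining-hippocampus volume may be
missing. Hemisphere dominance is recorded as the risk score operationalizes
it — left for all fourteen patients (thirteen dexterous, one lateralized
left by word-generation fMRI) — so "dominant resection" reduces to
left-sided surgery in this cohort, while the record type supports
right/unknown dominance for other data. Change scores are stored exactly as
printed, signed (negative = deterioration).

## Problem sizes

The packaged analysis is 14 rows and runs in milliseconds. Test simulations
use 36³ grids (≈ 900 voxels per ROI) for the laterality engine and cohorts
of 2,000–5,000 for parameter-recovery and law-of-large-numbers checks —
sizes at which binomial error is well below the asserted tolerances while
the whole suite stays in the seconds range.

## Known limitations

* The ROI masks of the original clinical setting are hand-drawn and not
  distributed; the engine accepts any user-supplied NIfTI masks but ships
  none.
* The 3-point score and the grading rules are transcriptions of a clinical
  convention, not fitted models; no calibration or uncertainty is attached
  to the risk bands.
* Exact permutation p-values treat the observations as exchangeable under
  the null; with n ≤ 9 they are the honest choice but remain tied to that
  assumption.
* The cohort simulator reproduces marginal and conditional frequencies,
  not the joint dependence structure of real clinical variables; recovery
  results validate the pipeline's arithmetic, not its clinical validity.
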