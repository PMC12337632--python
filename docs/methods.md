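# Methods

This note records the scientific and numerical choices behind `afstrat`:
what each stage assumes, which constants are fixed by the platform's
design and which were open choices, and what the synthetic validation does
and does not demonstrate about clinical data.

## Signal model and preprocessing

Body-surface recordings are modelled as channels × samples matrices in mV
at a single sampling rate (1 kHz in the clinical acquisition; simulations
default to 250–500 Hz, which satisfies the same band constraints at lower
cost). Preprocessing assumes the atrial component of interest lies in
2–20 Hz.

* **QRS removal.** The ventricular deflection is blanked in a window of
  −60/+100 ms around each R peak and bridged by a cubic spline fitted to
  flanking samples (≥ 4 support samples per side; overlapping windows are
  merged; windows clipped at recording edges fall back to nearest-value
  fill). R peaks are supplied externally (the simulator returns ground
  truth) or found by a simple amplitude detector (60 % of the lead maximum,
  300 ms refractory). This is a declared stand-in: the clinical platform's
  cancellation algorithm is unpublished, and template/PCA QRST-cancellation
  research methods are out of scope. Samples outside blanking windows are
  returned bit-identical.
* **Band filtering.** 4th-order Butterworth band-pass (2–20 Hz), applied
  forward–backward (`sosfiltfilt`) so that no phase distortion is
  introduced before Hilbert phase analysis. Order and cutoffs are
  configurable; the defaults reproduce the platform's stated cutoffs. The
  filter is idempotent in band to < 1 % RMS.
* **Window plan.** Three non-overlapping ≥ 4 s windows per recording for
  spectral analysis, placed deterministically at starts 0, (D−w)/2, D−w
  (D = duration, w = window length) — for a 20 s recording, [0,4), [8,12),
  [16,20). A 1 s rotor window is centred in each. Recordings shorter than
  3·w raise an error stating the deficit. Per-window biomarkers are
  averaged arithmetically.

## Forward model and inverse problem

The synthetic forward operator uses current monopoles in an unbounded
homogeneous conductor of unit conductivity: an electrode at `e` sees
`1/(4π·|e−s|)` per unit source at `s`. This keeps every entry analytic
(testable against closed-form evaluation) while reproducing the smoothing
that makes the inverse problem ill-posed. Realistic torso BEM assembly is
deliberately out of scope; the inverse machinery is agnostic to how the
transfer matrix was produced.

Zero-order Tikhonov inversion is solved by one SVD with filter factors
σ/(σ²+λ²), reused across the λ grid; λ = 0 gives the minimum-norm
least-squares solution with relative rank truncation 10⁻¹². One λ is
chosen per recording window on its stacked columns (not per sample), at
the maximum-curvature corner of the L-curve (log residual norm vs log
solution norm over a log-spaced grid). Two numerical guards matter in
practice: points where the curve's speed is ~0 (λ far below the smallest
singular value) and points on the vertical limb where the residual does
not yet respond to λ are excluded as corner candidates — both otherwise
attract spurious curvature maxima. Perfectly consistent data short-circuit
to the smallest grid value; a flat L-curve warns and returns the grid
median.

## Spectral biomarkers

Dominant frequency is the in-band maximum of a Welch periodogram: 2 s Hann
windows, 50 % overlap, zero-padded so the grid spacing never exceeds
0.01 Hz regardless of window length. The analysis band defaults to
3–15 Hz, inside the filtered band. Power ties resolve toward the lower
frequency. HDF is the map maximum by default; because a strict maximum is
sensitive to single-vertex outliers on reconstructed maps, a percentile
variant (e.g. 98th) is available. MedianDF is the map median; HDF ≥
MedianDF holds by construction.

## Rotor detection

Phase maps are instantaneous phases of the Hilbert analytic signal of
band-filtered, zero-mean electrograms. Singularities are detected by the
three-circle criterion around each vertex:

* circles of radius 1×, 2×, 3× the mesh mean edge length, sampled at
  6/9/12 points inner→outer (the counts and radii are configurable; the
  platform's exact radii are unpublished);
* phase at each circle point interpolated from the 4 nearest vertices with
  weights ∝ d⁻². Interpolation acts on the unit phasor e^{iφ}, not on the
  wrapped angle — a weighted mean of angles is undefined across the ±π
  branch cut. The literal d² weighting (which would upweight *distant*
  nodes and is almost surely a typographical inversion in the platform's
  description) is selectable for comparison;
* a circle "winds" when its wrapped phase increments sum to ±2π and are
  monotone, allowing one backward step of ≤ π/6 (a strict mode allows
  none); a vertex is a singularity iff ≥ 2 of its 3 circles wind with the
  same sign, which is the chirality;
* vertices whose outer circle would leave the mesh (distance to the
  boundary below the outer radius) are skipped — detection is undefined
  there, so cores within ~3.5 edge lengths of the boundary are invisible
  by design;
* same-chirality hits within 1.5 mean edges merge into one singularity at
  their centroid (the criterion fires on every vertex within ~2 edges of a
  true core).

Tracking links singularities of equal chirality between consecutive
frames greedily by distance, strictly below 1 cm (electrogram modes) or
5 cm (surface ECG); a distance equal to the threshold does not link.
Rotation count is the unwrapped phase accumulated over the trajectory's
lifetime at the vertex nearest its mean position, divided by 2π; only
trajectories with ≥ 1 full rotation count as rotors. Mean Rotor Time is
the mean rotor duration in seconds within the 1 s window, with 0 s for a
window with no rotors — the alternative reading (total rotor time per
window) is exposed in the extras (`total_rotor_time_s`) rather than chosen
silently, since the original definition is ambiguous; seconds are used as
the unit throughout. The histogram map splits each trajectory segment's
duration between the vertices nearest its endpoints, so total map mass
equals total rotor duration exactly.

## Score, stratification, evaluation

The complexity score is a logistic model with published coefficients
(−0.11, +0.40, −0.39, −0.04) for (intercept, HDF, MedianDF,
MeanRotorTime); calibration refits them by maximum likelihood
(`statsmodels` Logit) and reports standard errors; perfect separation
raises an error naming the separating direction (difference of class
means, normalised). Feature ranking uses univariate AUC folded about 0.5
— chosen for transparency; the platform's extraction method and its full
12-biomarker list are unpublished, so the extras set (rotor count, max
rotor time, total rotor time) is a documented stand-in.

Stratification: paroxysmal patients split at score 0.4/0.6 (closed
interval for the intermediate band), persistent at 0.5 — the persistent
threshold is not published and 0.5 is the score's natural midpoint; both
are configurable. The k-NN predictor (k = 5) encodes AF type and treatment
class as one-hot columns and z-standardizes the score on the training
cohort, Euclidean metric; with odd k on a binary outcome votes cannot tie,
and the configurable-k tie rule falls pessimistically to AF recurrence.

Evaluation: the 80/20 split is outcome-stratified with the test arm sized
by nearest-integer rounding (204 → 163/41) and allocated across classes by
largest remainder, so class proportions match within one patient. AUCs use
midrank placements; variances, CIs and the paired test are the standard
DeLong estimators. Confusion metrics are evaluated at Youden's J threshold
with Wilson 95 % intervals (the CI method for these is not published; Wilson
was chosen for coverage at small n). χ² is Pearson without continuity
correction, the two-proportion test is the pooled z (satisfying z² = χ² on
any 2×2), the t-test defaults to Welch. No multiple-testing correction is
applied, matching the platform's analysis. Multivariate one-way ANOVA is
deliberately replaced by the multivariable logistic association from the
calibration step.

## Synthetic data: what it shows and what it does not

The generators provide exact ground truth: spiral fields have precisely
one phase singularity at a known (possibly drifting) core — the spatial
phase is χ·θ(x; core) − 2πr/λ with an Archimedean term whose wavelength
defaults to the mesh diameter (any field with one singularity suffices for
validating the detector; no physiological wave model is claimed); planar
and focal fields have none. Cohort biomarkers are drawn as MedianDF ~
U(4, 9) Hz, HDF = MedianDF + Exp(mean 1.5 Hz), MeanRotorTime ~
U(0.2, 3) s — ranges spanning realistic AF activation rates — and outcomes
are Bernoulli with the score's own probability, making coefficient
recovery a well-posed check. Under these defaults the implied scores
concentrate in roughly [0.45, 0.95]: the generated biomarkers populate the
intermediate and high bands densely but the paroxysmal low band only
rarely, so structural tests of the five-group partition draw scores
uniformly on [0.1, 0.9] instead. AF type and treatment are drawn at the
study's observed mix (37.5 % paroxysmal; 30/29/8/33 % across PVI, PVI +
drivers, pharmacological rhythm control, rate control) independently of
the biomarkers, so synthetic cohorts carry no AF-type–outcome association
by default.

Passing on this synthetic data demonstrates algorithmic correctness —
detector fidelity to the winding-number definition, solver optimality,
estimator calibration — not clinical performance: real fibrillatory
electrograms are broadband and nonstationary, real rotors meander and
fragment, real torso conduction is inhomogeneous, and the real
biomarker–outcome relationship is not exactly logistic. The platform's
clinical endpoint figures (test-set accuracy, cohort AUC) depend on the
unavailable patient data and are out of scope here.

## Problem sizes

Default validation sizes were picked so the whole suite runs comfortably
on one core: ~300–650-vertex meshes (mean edge 0.3–0.4 cm on a 4 cm
disk), 2 s simulations at 500 Hz with detection every 2 samples, cohorts
of 5 000–50 000 for estimator checks, 1 000 bootstrap resamples. All are
parameters, not limits.
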