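# Methods

This note documents the statistical procedures, the synthetic data model,
the numerical choices, and the known limitations of `pepdiscover`.

## The workflow being modelled

A case/control serum-peptidome study acquires one profile-mode MALDI-TOF
spectrum per subject over *m/z* 1,000–10,000, reduces each spectrum to a
peak list, aligns peaks across subjects into a common reference panel,
screens the per-peak intensities univariately, and combines the
significant peaks into a multivariate logistic "diagnostic panel" whose
frozen coefficients are then evaluated on a second, independent cohort.
The package implements each of those stages behind an explicit contract
so that every intermediate object (spectrum, peak list, peak matrix,
panel model, performance report) can be inspected, serialised and tested.

## Preprocessing chain

Applied per spectrum in a fixed, logged order:
crop → smooth → baseline → noise → TIC-normalise → detect.

- **Smoothing**: centered moving average, default window 5 points.
  Windows shrink at the spectrum edges instead of reflecting or
  zero-padding, so no invented data enter the signal. Smoothing is
  linear (property-tested).
- **Baseline**: the spectrum is partitioned into windows of
  `baseline_mass_window` (default 100 Th). In each window the dominant
  local maxima — prominence above 3 × the window's robust noise scale —
  are located, and the minimum between each pair of consecutive dominant
  maxima becomes a baseline anchor. Windows with no peak structure
  contribute their *median* rather than their minimum: the minimum of a
  signal-free window sits roughly two noise standard deviations below
  the true background, and anchoring there would shift every residual
  upward — at an S/N 5 cut-off that artificial offset materialises as
  dozens of spurious "peaks" per spectrum. The median is the unbiased
  location of a flat noisy stretch. Anchors are linearly interpolated
  (constant-extrapolated at the ends) and subtracted with a zero clamp.
- **Noise**: 1.4826 × median absolute deviation over sliding windows
  (default 100 Th, half-window step), interpolated to every grid point.
  The MAD is computed on the *pre-clamp* residual (smoothed − baseline):
  after the zero clamp roughly half the residuals in empty regions are
  exactly zero, which would collapse the MAD and make S/N meaningless.
- **TIC normalisation**: every intensity divided by the spectrum's total
  intensity sum (sums to 1 afterwards; idempotent).
- **Peak detection**: strict local maxima (plateaus count once, at their
  leftmost point) whose apex intensity over the local noise level reaches
  `snr_cutoff` (default 5.0, boundary inclusive). The centroid *m/z* is
  the intensity-weighted mean over the contiguous run above half the apex
  height. S/N is invariant under the global TIC division, so detection is
  unaffected by where normalisation sits in the chain; reported peak
  intensities are on the normalised scale.

## Alignment and the peak matrix

All detected peaks are pooled in ascending *m/z* and clustered by single
linkage: a cluster breaks wherever the gap to the next peak exceeds
`tol_rel` (default 0.001, i.e. 0.1 %) times the running cluster mean.
This respects the instrument's bounded per-spectrum mass shift without
imposing fixed bin edges. Each sample contributes at most one member per
cluster (most intense wins); the reference *m/z* is the member mean.
Cells of the samples × peaks matrix hold the member intensity or **0 when
the peak was not detected** — absences are informative (a peptide below
the detection limit), and zero-filling keeps rows complete for the
logistic model. Reference peaks present in fewer than
`presence_min_frac` (default 50 %) of samples are dropped before any
statistics.

## Univariate screening

For each retained peak, a Shapiro–Wilk test (α = 0.05) on *both* groups
gates the two-sample test: Student's pooled-variance *t* if both pass,
Mann–Whitney U otherwise (requiring both normal is the conservative
reading; constant groups fall to the rank test). The Mann–Whitney P is
exact — full enumeration of group assignments, valid under ties, with
two-tailed P = min(1, 2·min(P(U≤u), P(U≥u))) — for pooled n ≤ 12, and a
tie-corrected normal approximation otherwise. Each peak also gets a raw
ROC AUC (cases scored high; computed from average ranks, hence exactly
U/n₁n₂) with a Hanley–McNeil 95 % interval clipped to [0, 1]. Peaks with
P < α (default 0.05) become candidates, deliberately **without**
multiple-testing adjustment — the plain P < 0.05 screen is how such
discovery studies operate; a Benjamini–Hochberg option exists but is off
by default. Demographic helpers cover published-summary pooled *t* tests
and Pearson's 2×2 chi-square without continuity correction.

## Panel model

`fit_logistic` is a hand-rolled Newton-Raphson/IRLS maximum-likelihood
fit (intercept added internally; convergence when max |score| < 1e-8,
cap 100 iterations, halving-damped steps far from the optimum). Standard
errors come from the inverse observed information. Complete or
quasi-complete separation is detected by monitoring standardized
coefficient magnitudes (> 20) and raised as an explicit error.
Independent cross-checks in the test suite (a BFGS optimiser on the same
likelihood; statsmodels `Logit`) agree to 1e-6 in log-likelihood.

`stepwise_select` is forward stepwise with backward elimination: at each
step the candidate whose likelihood-ratio test against the current model
has the smallest P enters if P < `p_enter` (0.05; ties broken by
ascending *m/z*), then included peaks with Wald P > `p_remove` (0.10)
are removed worst-first with refitting. The procedure is deterministic,
terminates when the included set stabilises (with a visited-set guard
against entry/removal cycles), and skips candidates whose addition makes
the fit separable. A model never retains a coefficient with Wald
P > `p_remove` (invariant-tested).

Predicted probabilities use the frozen coefficients; classification
thresholds at `cutoff` = 0.5, the standard classification-table
convention. Performance is a confusion matrix (case = positive) with
accuracy, sensitivity and specificity, Wald 95 % binomial intervals
p̂ ± 1.96·√(p̂(1−p̂)/n) clipped to [0, 1], and the panel ROC AUC.
External validation matches the model's peaks to the validation matrix
columns by nearest reference *m/z* within the 0.1 % alignment tolerance
(missing peaks warn and contribute zeros) and never refits.

**Feature scale.** Coefficient magnitudes in logistic regression depend
on the intensity unit, which profiling studies rarely state. Selection,
P-values and performance are invariant to any global rescaling, so the
pipeline exposes `feature_scale` (default 10⁴: TIC-normalised heights
expressed as parts-per-10,000 of total ion current), chosen so panel
coefficients land in the conventional 0.01–1 range. The scale is stored
on the model and applied identically at prediction time.

## Synthetic cohorts

`generate_cohort` emulates the two-cohort colorectal-cancer study design
the package is built around. Each spectrum on a 1 Th grid over
1,000–10,000 Th is

TIC × ( Σ present peaks + baseline + noise ),

with per-spectrum TIC factor log-normal (unit mean, cv 0.1), baseline
A·exp(−(mz−1000)/τ) (A = 300, τ = 2000 Th), Gaussian detector noise
(sd 10), and a per-spectrum relative mass miscalibration uniform in
±0.1 % (matching the alignment tolerance). A planted peak appears with a
per-class Bernoulli presence probability and a log-normal height around
its class mean; its profile is Gaussian with σ = max(5·10⁻⁴·m/z, 1 Th) —
the resolution-like scaling with a floor at the digitizer step, since
linear-mode TOF peaks narrower than the grid are unphysical (and would
be destroyed by 5-point smoothing).

The default peak population:

- **10 discriminative markers** at the *m/z* values and class-mean
  intensities of the motivating study design (three elevated in cases,
  seven reduced). Group means alone don't fix how separable two
  log-normals are, so each marker's cv is calibrated from its published
  single-peak AUC via AUC = Φ(Δμ/(σ√2)) (capped at cv = 3 where a weak
  AUC combined with a large mean ratio would imply an implausible
  spread).
- **12 abundant nuisance peaks** with equal class means (presence 0.9) —
  the nulls a candidate screen must reject.
- **190 sparse peaks** (presence 0.15, log-spaced like real peptide
  density, kept ≥ 0.4–0.8 % away from other peaks) — these exercise the
  detection→presence-filter funnel: typical runs detect ~450 reference
  peaks of which ~22 survive the 50 % filter.

Ground truth (per-sample presence, drawn height, jittered apex position,
planted S/N) is returned alongside the spectra for recovery tests.

`generate_panel_features` is a matrix-level shortcut for panel-recovery
experiments: five informative features (the panel markers' control-group
log-normal marginals) and five null features, with the case/control
outcome drawn from a *true logistic model* linear in the standardized
intensities. Informative coefficients are proportional to each marker's
signed probit separation √2·Φ⁻¹(AUC) and jointly scaled so the combined
score discriminates at the panel's training AUC (0.982). This is the
only construction under which "k features carry independent effects and
the rest none" is well defined — under class-conditional sampling with
independent features, *every* shifted feature has an independent effect.
Class sizes are prospective (random, ≈ n/2 each).

**What the generator does not model**: isotopic envelopes, detector
saturation, replicate spot acquisition, correlated peptide abundances,
batch/plate effects, and heavy-tailed or drifting baselines. Passing
tests therefore demonstrate that the pipeline recovers structure it is
designed for under idealised noise — not that it is robust to every
artefact of real serum profiling.

## Numerical choices and degenerate inputs

- Smoothing requires an odd window ≥ 1; window 1 is the identity.
- A baseline mass window wider than the spectrum span degrades to a flat
  global-minimum baseline with a warning.
- A spectrum with no variation yields zero noise (warning); S/N of a
  positive apex over zero noise is +∞, so such peaks are kept.
- All-zero spectra cannot be TIC-normalised (error).
- Detection plateau ties resolve to the leftmost point.
- Mann–Whitney exact enumeration bounds: pooled n ≤ 12 (C(12,6) = 924
  assignments).
- The stepwise entry test is likelihood-ratio and the removal test Wald,
  mirroring the behaviour of mainstream stepwise logistic
  implementations; both thresholds are exposed.
- Wald intervals for proportions can touch 0/1 and are clipped; at
  p̂ ∈ {0, 1} they are degenerate points, which is the documented
  behaviour of the plain Wald method.

## Problem sizes in the test suite

End-to-end tests run the full spectral pipeline at the study's own
cohort sizes (100/100 discovery, 91/91 validation; ~10⁴ grid points per
spectrum) plus a reduced 50/50 cohort for cross-module checks; the
panel-recovery simulation uses n = 200 training / 500 validation
samples at the matrix level. These sizes keep the whole suite around
half a minute while leaving every statistical check at realistic power.

## Known limitations

- The per-peak cv calibration treats the published AUCs as exact
  population quantities and assumes equal log-scale spread in both
  groups.
- Zero-filled absences make group means mixture means; the univariate
  screen sees presence and intensity effects jointly, as the original
  workflow does, but the two are not separated.
- Stepwise selection inherits the classic optimism of apparent training
  performance (≈ 3–5 accuracy points at n = 200 with ~6 parameters);
  external validation is the honest estimate.
- The baseline/noise estimators assume peaks occupy a minority of each
  mass window; pathologically peak-dense spectra would bias both.
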