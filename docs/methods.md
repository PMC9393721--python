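# Methods

This note records the models, conventions and design choices behind
`hipporad`, in the spirit of a statistical software methods appendix. It
states no empirical number that the test suite or `scripts/acceptance.py`
does not itself compute.

## ALFF in the slow-5 band

A voxel's BOLD series is processed as: discard the first `n_discard = 10`
volumes; voxelwise ordinary least squares against an intercept, a linear
trend, the Friston-24 motion expansion `[R(t), R(t−1), R(t)², R(t−1)²]`
(lagged row zero-filled), and optional precomputed white-matter/CSF mean
series; then the single-sided amplitude spectrum `2|X(f)|/N` of the
residual. ALFF is the arithmetic mean of the amplitude over the discrete
FFT bins inside the closed band `[0.01, 0.027]` Hz. Conventions that are
fixed and documented rather than universal:

* **Amplitude, not power, band mean, not sum.** Any fixed convention is
  equivalent downstream because every signature step is scale-invariant
  after z-normalization; the mean-amplitude form makes the analytic test
  value exact (a unit bin-aligned sinusoid with 7 in-band bins gives
  ALFF = 1/7).
* **Band edges closed, no interpolation.** A bin is in-band iff
  `low ≤ f ≤ high`. The DC bin is always excluded, and the series is
  demeaned before the FFT so a constant series yields exactly 0.
* **No division by the global-mean ALFF** (mALFF) by default; the map is
  used within-ROI only.
* Rank-deficient nuisance designs drop collinear columns greedily (QR-style
  rank test) with a warning.

Motion QC: framewise displacement is the Power form
`FD[t] = Σ|Δd| + 50·Σ|Δθ|` (translations mm, rotations rad on a 50 mm
sphere), `FD[0] = 0`. Exclusion when max |translation| > 3 mm, max
|rotation| > 3°, or **mean** FD > 0.5 mm. Mean (rather than maximum) FD is
the default because it is the common toolchain behavior; the threshold
object is configurable.

## Radiomic features

Extraction is deterministic and purely in 3D within a binary ROI.

**Discretization.** Fixed bin number, default `N_g = 32`, within the ROI's
own min–max range: `level = 1 + floor(N_g·(x−min)/(max−min))`, maximum
mapped to `N_g`. This makes all texture features invariant under monotone
affine intensity transforms, which matters because structural and ALFF
intensities are on incomparable scales.

**First-order (13).** mean, median, min, max, range, variance, standard
deviation, skewness, excess kurtosis, energy, histogram entropy (on the
discretized levels), 10th and 90th percentiles — on raw intensities.
Constant ROIs get variance/skewness/kurtosis 0 by convention.

**Texture (88).** Five standard matrix families with their full rosters:

| family | count | matrix |
| --- | --- | --- |
| GLCM | 25 | co-occurrence at distance 1, 13 directions summed, symmetrized (26-neighborhood) |
| GLRLM | 16 | run lengths along the 13 directions, matrices summed |
| GLSZM | 16 | 26-connected equal-level zones by size |
| GLDZM | 16 | the same zones by minimum city-block distance to the ROI border |
| NGLDM | 15 | per-voxel count of equal-level 26-neighbors (α = 0) |

Totals: 13 + 88 = 101 features per modality per ROI; a combined
structural+ALFF extraction yields 202 candidates. The roster necessarily
includes the features that hippocampal radiomics reports typically single
out (GLCM Correlation and Entropy, GLRLM RLN and RLV, GLSZM GLN). Matrices
are aggregated (summed over directions) before features are computed, not
averaged per-direction. Degenerate conventions: GLCM correlation of a
constant ROI is 1 (zero marginal variance); `0·log 0 = 0` throughout; the
NGLDM dependence column index is `1 + (number of matching neighbors)` so
emphasis weights are defined at zero dependence. Every GLCM/GLRLM/GLSZM
feature is checked against an explicit-loop enumeration oracle on random
4×4×4 ROIs to 1e-10 relative; GLDZM and NGLDM matrices are checked against
flood-fill/neighbor-count oracles.

## Signature construction

Training order on training rows only: z-normalize (sample, n−1, standard
deviation; zero-variance features map to 0 with a warning) → SMOTE to exact
class balance (synthetic rows interpolate a minority row toward one of its
k = 5 nearest minority neighbors, u ~ U[0,1]; k shrinks with a warning when
the minority is small) → greedy mRMR with the mutual-information difference
criterion, features discretized to 3 states at mean ± sd, exactly 20 kept,
ties broken by column name (MIQ and pure-relevance variants available) →
L1 logistic regression over a 30-point descending λ grid
(λ_max·[1, …, 1e-3]), λ chosen at minimum mean 10-fold CV binomial
deviance, zero-coefficient features dropped. The stored model (JSON) holds
the normalization statistics, selected names, coefficients, intercept and
λ, so external cohorts are scored frozen, with nothing re-fitted.

Implementation notes: the logistic fits use liblinear with a large
`intercept_scaling` (intercept effectively unpenalized) and a pinned
internal random state; normalization statistics are computed on a
C-contiguous copy so the fitted model is bit-identical regardless of how
the caller's DataFrame was assembled — this is what the leakage-sentinel
test asserts. Minimum-deviance λ (not 1-SE) is the default because it gives
the more stable selected sets at these sample sizes.

## Evaluation

Stratified splits put `round(0.7·n_class)` subjects of each class in
training; repetitions are seeded per (scheme seed, repetition) and shared
across ROIs and modalities so that DeLong comparisons are paired. AUC is
the tie-corrected Mann–Whitney statistic; its 95% CI uses the DeLong
placement-value variance with a normal interval truncated to [0, 1].
Accuracy is reported at the Youden threshold of the training ROC, applied
unchanged to the test set (the threshold rule is a documented choice).
DeLong comparisons (combined vs structural, structural vs ALFF) default to
training-set scores; Wilcoxon is the two-independent-sample rank-sum test
(exact for ≤10 per group without ties, tie-corrected normal otherwise);
Spearman uses midranks with the t-approximation p. The reported cell AUC is
exactly the arithmetic mean of the per-repetition AUCs. No multiple-testing
correction is applied (α = 0.05 per test). Feature–score correlations are
computed for features retained in at least half the repetitions of the
combined model, on case-group subjects.

## Synthetic cohorts

The generator emulates a three-group clinical cohort (default sizes
84/50/44 with an MMSE-like score: 17.512 ± 5.084, 26.200 ± 0.881,
29.023 ± 0.902) with two independently tunable, per-group-scalable effects:

* **Structural texture**: within the ellipsoidal ROIs the image is a
  Gaussian random field smoothed with kernel width
  `σ = 0.6·(1 + texture_effect·scale_g)·exp(ε)`, `ε ~ N(0, 0.25)`,
  re-standardized to sd 10 after smoothing so first-order statistics are
  group-matched and only spatial correlation differs.
* **ALFF amplitude**: functional ROI series are baseline 1000 + drift
  (0.02 units/s) + three sinusoids at {0.0125, 0.02, 0.025} Hz — inside the
  slow-5 band and bin-aligned at TR = 2 s with 200 retained volumes — with
  subject amplitude `1·(1 + alff_effect·scale_g)·exp(ε)`,
  `ε ~ N(0, 0.35)`, a smooth ±15% per-voxel modulation field (giving the
  ALFF map its own texture), random phases per voxel, and white noise
  (sd 1.0). The lognormal subject factor is what makes group separation
  finite; without it the spectral estimate is nearly noiseless and any
  planted effect would saturate the AUC.

Motion traces are 6-parameter random walks (steps 0.02 mm / 4e-4 rad per
volume) with optional per-subject planted pathologies: a mid-series
translation/rotation jump, or a step-scale factor that drives mean FD over
threshold. The clinical score is linear in group (group mean + Gaussian
noise), so feature–score correlations are recoverable by construction.
Reproducibility: one master seed; per-subject generators come from
`SeedSequence([master, subject_index])`, so any subject regenerates
bit-identically in isolation.

What the generator does **not** emulate: brain anatomy, scanner artifacts,
slice-timing effects, spatial normalization, partial-volume boundaries, or
realistic BOLD autocorrelation outside the planted band. Passing tests
therefore demonstrate correctness and calibration of the *procedure*, not
clinical performance on real data.

## Simulation sizes and null calibration

The recovery experiments run at scaled-down sizes chosen as this package's
own test conditions: two groups of 20 subjects on a 16×16×12 voxel grid
(two ≈80-voxel ROIs), 210 volumes at TR = 2 s, bilateral ROI, 5 repetitions
of the 70/30 split per cohort; 20 cohorts for the null study, 10 per grid
point for effect monotonicity and modality ordering. The statistical null
calibrations use 5000 replicates (2000 in the acceptance script).

One property of the specified procedure deserves note: under the null,
held-out AUC from repeated 70/30 splits of a small finite cohort sits
slightly **below** 0.5, because sampling train and test without replacement
from the same 40 subjects anti-correlates whatever the selection step
favored in training with the complementary test subjects. The effect is
reproduced by a minimal independent simulation with a plain mean-difference
classifier and grows with selection intensity. The null-calibration test
therefore asserts (a) no positive discrimination and (b) agreement with the
label-permutation null of the identical procedure on the same cohorts,
which is the correctly centered Monte-Carlo reference.

## Known limitations

* The texture roster is a documented stand-in: real clinical studies vary
  in their exact 88-feature split across families; the roster here is fixed
  (and overridable) but not a reconstruction of any particular toolbox.
* GLCM MCC (maximal correlation coefficient) is omitted as numerically
  fragile on small ROIs.
* `resample_mask` consumes precomputed affines; no registration is
  estimated.
* The 3-class problem (AD vs aMCI vs NC jointly) is out of scope; all
  signatures are binary contrasts.
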