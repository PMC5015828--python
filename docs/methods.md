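# Methods

This note documents the models, parameters and numerical choices behind
`decnef`, in the order data flows through the pipeline.  Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Synthetic subjects

The generator emulates the *statistical structure* the analysis assumes,
not fMRI physics.

**Grid and regions.** Voxels live on a 3-D grid (default voxel size
3 × 3 × 3.5 mm, matching a typical EPI acquisition; configurable isotropic
3 mm).  Named ROIs are disjoint cubic blocks; `make_ground_truth` places a
target region "CC" plus any number of other regions, with a configurable
inter-block gap so searchlight spheres need not straddle two regions.

**Faces and ratings.** Each of 400 faces carries a latent preference drawn
uniformly on [1, 10].  An observed Likert rating is
`clip(round(latent + N(0, σ_r)), 1, 10)` with σ_r = 0.5 by default (the
observation model is a modeling choice; only its ordinal structure
matters).  Face selection follows the design: the 100 highest- and 100
lowest-rated faces plus the 40 mid-ranked ("neutral") faces, from which 15
induction and 15 disjoint baseline faces are drawn.  Rating ties at a quota
boundary are broken by a seeded random key; without a seed they are an
error, because the selection would be arbitrary.

**Encoding model.** A decoder-construction trial with observed rating `r`
deposits the pattern

```
( linearize(r) − mean(linearize(r_session)) ) · w / ‖w‖²
```

into the target ROI at the lag-shifted volumes of its 6 s rating period,
on top of i.i.d. `N(0, noise_sd²)` voxel noise (noise_sd = 1 by default).
`w` (the ground-truth weights) is a fixed random signed vector scaled to
unit norm, so the pattern's magnitude equals the linearized rating
deviation regardless of ROI size and an ideal read-out `wᵀA` returns that
deviation exactly.  Amplitudes are centered on the *artanh-domain session
mean* — the same center the decoder bias uses (see below) — which makes
the noiseless round trip exact.  At the default signal-to-noise this
yields leave-one-run-out decoding of r ≈ 0.8 (Fisher z ≈ 1.1), deliberately
above what real BOLD achieves so that the desk-scale sample sizes used in
the tests retain power; passing tests therefore demonstrate correctness of
the machinery, not attainable real-data effect sizes.

**Timing.** TR = 2 s throughout.  Decoder-construction runs: 10 s lead-in
fixation + 20 trials × 12 s (face 0.5 s, rating 6 s, report/inter-trial
5.5 s) + 2 s tail = 252 s = 126 volumes; 12 runs = 240 trials.  Induction
runs: 30 s fixation + 15 trials × 20 s (face 0.5, induction 6, fixation 6,
feedback 2, inter-trial 5.5) = 330 s = 165 volumes.  No hemodynamic
response function is modeled: the analysis only ever averages lag-shifted
volumes, so trial responses are embedded directly at the volumes the
4 s-shifted extraction will read.  Period onsets that fall mid-volume are
mapped to the nearest volume; a period must span an integer number of
volumes (the 5.5 s inter-trial period is read with an explicit 2-volume
window).  The lag-shifted inter-trial window of a run's *final* trial
extends past the acquired volumes and is dropped from the period analyses.

**Cross-region coupling.** Each off-target ROI owns a fixed random linear
map `M` (drawn once per ground-truth seed), and a coupled region receives
`c · M·pattern` per trial (sample-level form:
`c · M·pattern + (1 − c) · noise`), so leakage is pattern-level, not
voxel-identity-level.  `M` is scaled so the leaked image's per-voxel
amplitude is twice the source pattern's; full coupling is then comfortably
detectable at desk-scale sample sizes, while `c = 0` regions are exactly
independent noise.

**Subject policies.** The experiment never observes how subjects regulate
their activity, so policies are explicit generative stand-ins, not claims
about mechanism.  `non_adaptive` emits a null pattern (the negative
control).  `hill_climb` is a (1+1) keep-if-improved perturbation scheme —
it uses only the scalar feedback history, which is all a subject could
exploit.  `oracle` moves along the ground-truth weight direction: its
first 10 trials probe both signs at full amplitude and keep the sign whose
mean disk was larger (the group assignment is never disclosed, so even the
oracle must *learn* the feedback direction), then its amplitude ramps from
0.15 to 0.6 × noise_sd over 60 trials.  The cap holds the asymptotic
induced shift near +1–2 rating points (mirroring a plausible learning
outcome) instead of pinning the decoder at its ceiling; probing at full
amplitude keeps the wrong-sign rate under ~1 % against the per-trial disk
noise.

## Preprocessing

Offline chain (decoder construction): flag the initial 10 s (5 volumes) as
excluded → shift volumes 4 s toward stimulus time (an index shift of 2
volumes; the lag is an exact TR multiple, so no interpolation) → per-voxel
linear detrend fit on included volumes → per-voxel z-score over all
included volumes.  Online chain (induction): identical except the z-score
uses only the 20 s baseline starting 10 s after run onset (scan volumes
5–14) and is applied causally to everything later.  The detrend is fit
once per run on the included volumes available at computation time (for
the online path, the causal prefix); whether the original computation
refit the trend incrementally per volume is not recoverable, and the
choice is configurable by truncating the series.  Excluded volumes never
enter means, variances or trend fits but stay addressable so event
indexing matches scan time.  Stage tags on the run object enforce the
pipeline order; an out-of-order stage raises.

Trial samples are 3-volume averages (6 s at TR 2 s) per period;
train/test normalization inside cross-validation uses training statistics
only.

## Decoder

Weights are fit by scikit-learn's `ARDRegression` — per-voxel relevance
precisions with a shared noise variance, iterated to convergence (cap 500
iterations), voxels with weight precision above 1e4 pruned.  The 1e4
threshold is the estimator's default and the value at which selection is
meaningful: precisions of pure-noise voxels pass it within the iteration
budget while informative voxels stay orders of magnitude below.  (A far
larger threshold would never prune at these problem sizes.)  The fit has
no free intercept.

**Centering.** Ratings enter as `artanh((r − 5.5)/5)`, chosen so 1..10
maps symmetrically into ±artanh(0.9).  The fit is centered at the *mean of
the linearized ratings*, and the decoder bias is that center's
delinearized value.  This differs from the arithmetic mean rating by a
Jensen gap (≲ 0.2 rating points) but is the only center consistent with a
no-intercept fit against mean-centered voxel columns: centering at
`linearize(mean r)` leaves a constant residual no weight vector can
absorb (~0.15 rating points mid-scale).  With this choice a zero pattern
decodes exactly to the bias and the noiseless round trip is exact to
numerical precision.

**Degenerate cases.** Constant training ratings prune every weight and
the decoder predicts the bias everywhere.  Exactly noiseless multi-voxel
data makes the informative columns collinear (the fit is then only
identified on the signal direction); an infinitesimal symmetry-breaking
noise is used wherever support recovery is asserted.

**Prediction.** `R = delinearize(WᵀA + linearize(b))`, clipped to [1, 10]
only at the feedback/reporting boundary, never inside cross-validation
correlations.  Fold performance is `artanh(r)` per fold, averaged — never
the correlation of pooled predictions.  Fold correlations are clipped
infinitesimally inside (−1, 1) before the transform.

## Closed loop

Per induction trial, the policy emits a pattern, the pattern is embedded
into the synthetic volumes (optionally also in the fixation/inter-trial
windows, which builds the tonic-modulation counterexample), and the
online estimate is computed causally from exactly the volumes required to
cover the lag-shifted induction window — all acquired before the end of
the trial's fixation period, as the feedback timing requires.  The disk
rule (`r/10` higher, `(11 − r)/10` lower, uniform (0, 1] for the control
group) operates on the clipped estimate so it cannot leave [0.1, 1.0];
the daily bonus is `3000 JPY × mean disk`, rounded to the nearest yen.
Induced shift = estimated rating − decoder bias.

The period-shift analysis recomputes estimates for the induction, fixation
and inter-trial windows with the identical causal routine, so its
induction-period values equal the logged closed-loop estimates exactly.
The amplitude contrast is the offline per-voxel mean difference between
induction-period and inter-trial-period samples, averaged across ROI
voxels; because induced patterns have near-zero voxel mean, pattern
induction leaves this contrast near zero while a uniform activation
change would not.

## Leak analyses

**ROI-based.** The same ARD estimator reconstructs the target's estimated
ratings from each region's induction-period samples, leave-one-run-out.
The constant term is the average of the estimated ratings over the whole
stage — a single global constant.  A fold-local training mean would be the
leave-one-run-out mean of the targets, which anti-correlates with the
held-out run and distorts the pooled correlation; a global constant
cancels in the Pearson correlation entirely.

**Searchlight.** Spheres of radius 15 mm (configurable; the desk-scale
studies use 7.5 mm on smaller grids) collect gray-matter voxels by
center-to-center distance, clipped at mask borders.  Decoder-stage maps
use the nested procedure: an inner leave-one-run-out loop over the target
ROI produces the reconstruction targets; an outer leave-one-out loop
within each held-out run reconstructs them from the sphere pattern by
L1-regularized least squares (LASSO; elastic-net mixing fixed at 1); the
map value is the Fisher z of the pooled reconstruction-vs-target
correlation over all trials (a within-fold correlation is undefined at
fold size one, so pooling is the only coherent choice).  Induction-stage
maps train one L1 model per sphere on decoder-stage data and apply it,
frozen, to the induction samples.  The penalty weight is selected per
subject by exhaustive grid search (default: 20 values log-spaced over
[1e-3, 10]) maximizing the mean across-sphere Fisher z for decoding the
behavioral ratings; the desk-scale studies fix it at 0.3, a mid-grid
value at which sphere fits neither collapse to zero weights nor overfit
the 19-sample outer folds.  Maps are smoothed by a NaN-aware Gaussian
kernel, σ = FWHM / (2√(2 ln 2)) per axis in voxel units, renormalized over
valid neighbors.

Note an intrinsic feature of the nested design: because the outer loop
trains within the held-out run, even signal-free spheres acquire a small
positive baseline from between-run target variability; dissociations are
therefore always read against matched silent-region spheres, never against
zero.

## Permutation inference

Correlation significance follows the top-rank criterion: the pairing is
permuted 1000 times (fewer in the replicated calibration studies) and the
observed r must rank in the top 5 % of the null distribution; the add-one
rule keeps p strictly positive; the same distribution standardizes r into
a permutation z for between-subject t-tests.  Two refinements, both the
package's own methodological choices:

* **Run-aware permutation.**  Trials of the same run share run-wise
  normalization and are not exchangeable with other runs' trials; when run
  labels are supplied, runs are exchanged as blocks and trials shuffled
  within runs, preserving run-level dependence under the null.

* **Pipeline permutation for cross-validated reconstructions.**
  Correlating CV predictions with their own targets is not exchangeable
  under any pairing permutation of the finished vectors: under the null,
  CV predictions carry a systematic anti-correlation of order p/n and an
  over-dispersed correlation (≈1.6× the i.i.d. variance in the regimes
  measured here), so a vector-level permutation is anticonservative.  The
  false-positive/detection study therefore permutes the *targets* before
  refitting the reconstruction, with sequential early stopping (a null
  region exits after a couple of exceedances, so the cost stays near one
  extra refit per permutation actually needed).  The vector-level
  permutation z is retained as the descriptive statistic that
  between-subject t-tests operate on.

All multiple-comparison corrections are Bonferroni.  "Not significantly
different from zero" checks in the acceptance suite use α = 0.01
two-sided, and replicated rate assertions use one-sided 3σ binomial
bounds around the nominal rate — both fixed before any measurement.

## Desk-scale study sizes

The end-to-end studies in `decnef.study` (used by the acceptance suite
and `scripts/acceptance.py`) run at sizes chosen to keep a complete
reproduction on one CPU in minutes while retaining power: 24-voxel target
regions on compact grids; 12 simulated subjects per feedback group with 4
induction runs per day over 3 days; 200 replicates for the leak
false-positive study (6 null regions, 4-run sessions, 239 permutations
with early stopping) and 20 for the coupled-region detection; searchlight
studies over 6 sphere centers per region.  Fold structure (12 runs ×
20 trials, 220/20 splits) always matches the full design.

## Limitations

The generator omits hemodynamic convolution, physiological and motion
artifacts, spatial autocorrelation of noise, and anatomical atlases (the
38-region parcellation is replaced by configurable synthetic regions);
subject policies are stand-ins, and the oracle's learning curve is a
design choice, not a model of human learning.  Statistical power and
effect sizes in the synthetic studies reflect the generator's
signal-to-noise choice and do not predict real-data performance.  The
three-way mixed-model ANOVA and outlier screening of the behavioral
analysis are out of scope; the report layer exports the per-cell change
scores those omnibus routines consume.
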