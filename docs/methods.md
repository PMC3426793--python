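# Methods

This note documents the models and procedures crossmvpa implements, the
parameters that matter and their defaults, what the synthetic generator does
and does not emulate, the numerical choices, and known limitations.

## Experimental design model

A session is a slow event-related design: `n_stimuli_per_category = 20`
concepts per category (mammals, tools), each presented exactly once per run
in an order randomized per run by the design seed; `n_runs = 6` (240 trials);
3 s stimulus + 7 s rest per trial (10 s trial spacing); a 40 s fixation
block immediately after each run's final rest period; TR = 1 s. One run
therefore spans 40 × 10 + 40 = 440 s and a session 2640 volumes. Stimulus
onsets are snapped to the volume grid, which is exact at the default TR.
The fixation blocks double as guard intervals: every analysis window used by
the pipeline (boxcar up to delay 9 + width 9, single volumes up to latency
20 s, 11 s event-related windows) fits inside the session for every trial of
the default design.

Two sessions per participant carry modality tags `audio` and `ortho`. Both
use the same stimulus set with independently randomized orders and
independent noise.

## Synthetic BOLD model

Per voxel v and volume t:

    signal_v(t) = baseline
                + drift: slope_{v,r} · (t − t_r)   within run r
                + Σ_trials a_v(category) · h(t − onset)
                + ε_{v,t},   ε ~ N(0, σ²) i.i.d.

* `baseline` default 100 (arbitrary units); removed by preprocessing.
* Drift slopes are drawn per voxel and per run, N(0, drift_slope_sd²) with
  `drift_slope_sd = 0.01` a.u./volume, and re-zeroed at run boundaries —
  scanner drift is run-local, and the pipeline detrends per run.
* `h` is the haemodynamic response kernel (below), truncated at 24 s.
* Category amplitudes are ±`effect_size` with the sign randomized per voxel,
  and `a_v(tool) = −a_v(mammal)`: the category code is a distributed
  pattern of small signed changes, not a uniform activation contrast.
  Non-informative voxels carry no stimulus response.

Informative voxels are drawn without replacement from the mask in three
pairwise disjoint sets: `n_shared` voxels active identically in both
sessions and `n_specific_per_session` voxels active in only one. The overlap
fraction ρ = n_shared / (n_shared + n_specific_per_session) controls how
much of the category code generalizes across sessions; it is the generator's
ground-truth analogue of the cross-session transfer the pipeline measures.

Defaults: grid 20×20×10 (4000 voxels, full mask), `n_shared = 80`,
`n_specific_per_session = 80` (ρ = 0.5), `effect_size = 0.12` in units of
the noise s.d. (σ = 1). These were chosen once so that the default cohort
decodes in the regime reported for this kind of slow event-related category
experiment — within-session accuracy in the 80–90% range and cross-session
accuracy in the 65–75% range at the default boxcar — and are not tuned per
experiment.

What the generator deliberately does **not** emulate: temporally
autocorrelated or physiological noise, motion, spatial smoothness of noise
or of the informative map, anatomy (the grey-matter mask is a plain box by
default), nonlinear BOLD summation, and any modality-dependent
sensory-cortex structure — session specificity is purely the identity of the
informative voxel sets. Passing tests therefore demonstrate the correctness
and statistical calibration of the *analysis* under a known ground truth;
they do not certify performance numbers on real scanner data, where noise
correlations typically reduce effective sample size and accuracy.

## HRF parameterization

The kernel is a single gamma density t^(k−1) e^(−t/θ) rescaled to unit
maximum, parameterized by the two quantities usually reported: the mode
(`peak`, default 7 s) and the full width at half maximum (`fwhm`, default
6 s). Given (peak, fwhm), (k, θ) are solved numerically: θ = peak/(k−1)
enforces the mode, and k is found by bracketing root-finding (Brent) on the
numerically measured FWHM, which is strictly decreasing in k at fixed mode.
FWHM is measured by linear interpolation of the half-maximum crossings on a
0.01 s grid. A requested width narrower than any gamma with that mode
supports raises a parameterization error. The kernel is zero at t = 0,
non-negative and unimodal.

## Preprocessing and feature extraction

Fixed order: mask → per-run linear detrend → per-session z-score → trial
extraction. Masked columns are ordered by ascending linearized voxel
coordinate with x fastest; this ordering is the contract connecting feature
indices back to voxel coordinates. Detrending subtracts each voxel's
least-squares line within each run segment (segments run from each run's
first onset to the next run's, absorbing the trailing fixation block).
Z-scoring uses the population s.d. over the whole session including rests;
zero-variance voxels become all-zero columns with a logged warning.

Windows are half-open `[start, start + width)` in seconds, so a width in
seconds equals a number of volumes at TR = 1. Window timing is measured from
stimulus **onset** by default; a `delay_origin="offset"` switch measures the
delay from stimulus offset instead (the source convention is ambiguous
between the two; onset-relative is the default because the grid and profile
analyses are defined onset-relative). A window extending past the
inter-trial interval triggers a warning, not an error; a window running past
the end of the series either raises (default) or drops the trial with a log
entry (`on_overrun="drop"`, used by the temporal-profile analysis).

## Classifier numerics

The PLR objective Σ log(1+e^z) − y z + λ‖w‖² (intercept unpenalized, λ not
rescaled by the trial count) is minimized by damped Newton iteration from
w = 0: exact Hessian with 2λ added to the weight block's diagonal, Cholesky
solve, Armijo backtracking line search. Convergence is declared at gradient
2-norm ≤ 1e−6, with a cap of 1000 iterations (a warning reports the final
gradient norm if hit; typical fits converge in 5–10 iterations). The zero
start plus convexity make every fit exactly reproducible. A predicted
probability of exactly 0.5 is labeled as the positive class (the
lexicographically first label, i.e. "mammal"), a fixed documented tie-break.
ANOVA ranking breaks score ties by ascending voxel index via a stable sort.

## Evaluation

Fold construction is by repetition index; an unbalanced design (any stimulus
without exactly one trial per repetition) is rejected with the offending
stimulus named. Feature selection and training always see only the training
partition. The cross-session scheme is a single split, so its feature
selection uses all training-session trials. The significance threshold is
the smallest k with exact one-sided binomial tail P(X ≥ k | n, chance) <
alpha; at n = 240, chance 0.5, alpha 0.05 this is k = 134 (55.8%). The
one-sided exact test is used because a two-sided or normal-approximation
test yields different thresholds (56.7% and 55.4% respectively).

The gamma fit of a temporal profile runs bounded least squares in (baseline,
amplitude, shape, scale) space — always-feasible coordinates — with
multistarts at peaks {3, 5, 7, 9} s (FWHM 6 s) and keeps the best residual
sum of squares. The reported peak is the fitted mode; the reported FWHM is
measured numerically from the fitted curve. Profiles with fewer than 5
points above the chance floor, or fitted amplitudes below 0.02 (two
accuracy points), return an explicit no-fit result rather than parameters.

The spatio-temporal fit statistic selects the top-k ANOVA voxels on the
training session's boxcar features (so it is direction-specific), computes
each session's per-voxel mammal-minus-tool difference of 11 s event-related
averages, flattens voxel-major, and takes the cosine. The SE is the s.d. of
the statistic over seeded trial-level bootstrap resamples (default
B = 1000), resampling both sessions independently and stratified by
category; the voxel selection is held fixed across resamples. The voxel
count defaults to the classification k = 500; region counting uses the top
50 by default. These two counts differ because the region report
deliberately focuses on the strongest features while the similarity
statistic mirrors the classifier's feature set.

## Problem sizes of the validation experiments

The package's statistical validation runs on reduced-scale simulated
cohorts, chosen as the smallest sizes at which the phenomena of interest are
clearly resolved:

* gamma-profile recovery: 20 sessions on a 12×12×6 grid, 60 informative
  voxels, effect 0.4, k = 100. Per-voxel effects of this size make
  single-volume decoding informative across the HRF support, which is the
  regime in which the accuracy profile tracks the kernel shape: at lower
  SNR, training-partition feature selection fails at off-peak latencies and
  the profile narrows relative to the kernel; at much higher SNR the profile
  saturates near 1.0 at the peak and broadens. Recovered parameters (mean
  fitted peak ≈ 7 s, mean FWHM ≈ 6 s) quantify this fidelity.
* overlap sweep and similarity-vs-accuracy cohorts: 8×8×4 grid, 32
  informative voxels, effect 0.25, k = 64, ρ ∈ [0, 1].
* grid-search audit: five participants on a 20×20×5 grid (2000 voxels),
  k = 100, effect 0.17, enumerating all 4 × 9 × 9 decodings per participant
  (1620 in total) through the run manifest.

## Known limitations

* The i.i.d. Gaussian noise model understates real fMRI noise complexity;
  accuracies on synthetic data at a given effect size are optimistic
  relative to real data.
* Event-related averages are computed on the fully preprocessed (z-scored)
  series; amplitudes are therefore in normalized units, not percent signal
  change.
* Single-volume features at latencies beyond the 10 s trial spacing overlap
  the next trial's response, which adds label-independent variance to the
  late profile tail; trials whose windows overrun the session end are
  dropped, not imputed.
* The permutation null of cross-validated accuracy is wider than the
  binomial null (train/test fold class balances are anti-correlated under a
  label permutation), so chance-level checks on permuted labels should be
  made on means over permutations, as the test suite does.
* Spatial normalization, motion correction and smoothing are out of scope;
  inputs are assumed pre-normalized and analyses run on unsmoothed data.
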