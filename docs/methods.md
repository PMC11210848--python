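# Methods

This note documents the models, defaults and design choices behind
`nbacklight`, in the spirit of a statistical methods appendix.

## Task model

A session is a fixed sequence of blocks, one n-back level per block, in
the order 0-, 1-, 2-back repeated three times (nine blocks).  Each block
is 2 s instruction + 5 s rest + 16 stimuli at a 2.0 s stimulus-onset
asynchrony (500 ms stimulus, 1500 ms inter-stimulus interval), giving a
39 s block and a 351 s session.  Four of the 16 stimuli per block are
targets; in a level-n block a target can only occupy a within-block
index ≥ n (its reference must exist), and target placement is drawn
uniformly at random from those indices under a user seed.  Stimulus
identities are abstract integer codes (code 0 is the 0-back cue);
nontargets are drawn so they never accidentally match their n-back
reference.

Scoring counts *all* nontarget stimuli of a level's blocks as
nontargets, including the first n stimuli of each block whose reference
falls outside the block.  With the default design this yields 12 targets
and 36 nontargets per level, and 42 valid 2-back trials (3 blocks ×
(16 − 2)).  Balanced accuracy is the mean of sensitivity and
specificity, appropriate for this 12/36 imbalance; an always-respond or
never-respond strategy scores exactly 0.5.  A response is any button
press within the 2.0 s window from stimulus onset to the next onset (the
response-window definition is a package choice; reaction times are
summarised over hits only).

## BOLD signal model (synthetic cohorts)

The generator produces sessions on a common, already-normalised grid
(default 24×28×24 voxels at 3 mm — a desk-scale whole-brain stand-in;
the native-resolution 64×64×32 at 3.5 mm grid is available via the
`grid` field).  Spatial preprocessing (slice timing, realignment,
normalisation) is out of scope by construction: data are born aligned.

Per voxel v inside an ellipsoidal brain mask and volume t:

    signal(v,t) = baseline
                + Σ_levels amplitude[level] · x_level(t)
                + p(v) · x_2back(t)
                + ε(v,t)

where `x_level` is the level's stimulus boxcar convolved with a
double-gamma HRF (peak delay 6 s, undershoot delay 16 s, unit
dispersions, peak:undershoot ratio 6), normalised so an isolated
stimulus evokes a unit-peak response; amplitudes default to 1.0 / 1.5 /
2.0 signal units for 0/1/2-back (a monotone load response); `ε` is
i.i.d. Gaussian with SD 1.0 (an AR(1) temporal-correlation option
exists, off by default — the classifier consumes per-trial window
means, where autocorrelation largely washes out); and `p(v)` is a
participant-specific multivoxel pattern riding on the highest-load
regressor, drawn once per participant with SD 0.5.

**Injected time-point effects.**  A study's effect of interest — a
change in the multivoxel 2-back pattern between baseline and follow-up —
is injected through spherical clusters (centre voxel, world-space
radius, group, shift SD).  Inside a cluster, every participant of the
matching group has follow-up pattern `p(v) + s(v)`, where the shift
field `s` is Gaussian with the cluster's SD.  `s` is drawn once per
cluster and *shared by the group's participants*, while the baseline
pattern `p` is participant-specific.  This split is deliberate:
leave-one-participant-out cross-validation can only detect a time-point
effect that generalises across participants, so a recoverable effect
must have a shared component; participant idiosyncrasy is what makes
the cross-validation honest.

**Behavior.**  Responses follow a per-group, per-time-point lapse/guess
model: targets answered with probability 1 − p_omission, nontargets
falsely answered with p_commission, Gaussian reaction times (mean
0.55 s, SD 0.12 s, clipped to the response window).  Defaults encode the
asymmetry the pipeline is meant to detect — control-group omissions rise
from 0.15 to 0.35 at follow-up while the treated group stays at 0.15;
commissions are 0.05 throughout.

**Cohort sizes** default to 13 treated and 8 control participants with
both time points.  Every random draw is keyed on (seed, participant
index, time point), so any session can be regenerated bit-identically in
isolation and cohorts can be streamed session-by-session without holding
all volumes in memory.

What the generator does *not* emulate: motion and physiological
artifacts, anatomical structure, spatial autocorrelation of noise,
nonstationary hemodynamics, and realistic atlas geometry (tests use a
synthetic parcellation; a real atlas label volume can be supplied).
Passing tests therefore demonstrate correctness of the *analysis
machinery* under the stated signal model, not robustness to every
real-data nuisance.

## Trial-pattern extraction

A trial's evoked response is the mean of the volumes 2–3 TRs (4–6 s)
after stimulus onset — the canonical HRF peak; the lag window is
configurable.  Per session, the mean response over all 48 0-back trials
(same window) is subtracted from every 2-back trial response, yielding
42 baseline-referenced patterns per session (84 rows per participant
across the two time points).  How the original measurement should be
computed from TR = 2 s volumes is underdetermined (window means,
beta-series, percent signal change are all defensible); window means
were chosen as the simplest estimator with no fitting step.  The brain
mask defaults to voxels with nonzero temporal variance; an explicit mask
can be supplied.  Searchlight input is unsmoothed (standard multivariate
practice); Gaussian smoothing (FWHM 8 mm default) applies to the
univariate contrast path, and both choices are switchable.

## First-level model and contrasts

Per voxel, ordinary least squares of the signal on the HRF-convolved
level regressors, an intercept and a linear drift.  Contrasts are
weighted sums of level coefficients: "1>0", "2>1", "2>0" (weights sum to
zero) and "2>rest" (the 2-back effect alone).  A rank-deficient design
matrix raises an error naming the collinear columns.

## Searchlight

Spheres have a 4 mm world-space radius (on a 3 mm grid: the centre plus
its six face neighbours), truncated at the mask boundary.  At each
centre, trials are classified baseline vs follow-up with k-NN (Euclidean
distance on raw pattern values, k = 5) under leave-one-participant-out
cross-validation; the centre's value is the pooled accuracy over all
held-out trials (micro average — robust to unequal per-participant trial
counts).  k is a package choice: odd to avoid binary vote ties, small
because training folds are modest; an optional per-feature z-scoring fit
on training folds exists, off by default.  No participant-level
normalisation is applied, so above-chance accuracy reflects time-point
structure that generalises across participants.

Tie policy (the `knn_predict` contract): distance ties break by lower
training-row index, vote ties by the nearest neighbour's label, then by
the lower class code.  The production path exploits that for odd k and
binary labels the vote reduces to comparing the ⌈k/2⌉-th smallest
within-class distances, computed with batched Gram matrices in float32;
per-centre results are independent and identical regardless of batch
size or visit order.  Analyses run separately per group, so each group's
map reflects its own longitudinal pattern change.

## Cluster extraction, selection, and summaries

Accuracy maps are thresholded strictly above 0.65; connected components
use 26-connectivity by default (6-connectivity available) and components
under 20 voxels are dropped.  A second stage keeps clusters with peak
accuracy ≥ 0.7 *and* volume ≥ 520 mm³ (the extraction cut-off is strict,
the selection floors inclusive, following the respective threshold
conventions).  Volume is exactly voxel count × voxel volume, unrounded
until report formatting.  Atlas coverage is the percentage of member
voxels per label, descending; label 0 reports as "unlabeled".

Cluster-median BOLD: per cluster, participant, time point and level,
the member voxels' 0-back-referenced trial values are pooled
(voxels × trials) and reduced to one median.  Pooling within participant
first is deliberate: the group tests then operate on exactly one value
per participant, as paired nonparametric tests require.

## Statistical layer

- Wilcoxon signed-rank (within group, across time points): zeros
  dropped, midranks on |d|, W = min(W⁺, W⁻).  Exact two-sided p by
  full enumeration of sign assignments (dynamic programming over doubled
  ranks) for n ≤ 25; otherwise normal approximation with tie and
  continuity corrections.
- Wilcoxon rank-sum (between groups at one time point): midranked rank
  sum; exact by enumeration when the smaller sample has ≤ 10
  observations and there are no ties; corrected normal approximation
  otherwise.  The exact/approximate switchover points are implementation
  choices.
- Student's and paired t-tests for continuous neurocognitive-style
  measures; constant paired differences raise (zero standard error).
- Group×time interaction map: each participant's follow-up − baseline
  contrast difference, then a pooled-variance two-sample t per voxel
  (treated − control), df = n_participants − 2.  For two time points
  this two-stage computation tests exactly the factorial interaction
  contrast without committing to a within-participant covariance
  structure.  Voxels with identically zero differences get T = 0.
- Brain–behavior regression: OLS of the per-cluster 2-back BOLD change
  on the 2-back omission-error change, group (control = 0, treated = 1)
  and their interaction.  Slopes of interest are β₁ (control) and
  β₁+β₃ (treated), the latter with a delta-method SE from the
  coefficient covariance.  Change scores default to follow-up −
  baseline; the opposite convention merely flips slope signs and is
  configurable.

All p values are two-sided and raw: no multiple-comparison adjustment is
applied anywhere, matching the exploratory framing of small-cohort
longitudinal studies; the test suite asserts the reported p equals the
single-test p.

## Numerical and testing choices

Problem sizes in the test suite are chosen for desk-scale runtimes: the
default 24×28×24 grid (≈ 5400 in-mask voxels), cohorts of 4–8
participants for calibration and recovery checks, 20 seeded replicates
for the cluster-recovery rate, and 2000 replicates for type-I error
calibration.  Exact nonparametric p values are verified against full
enumeration oracles; the searchlight against both a pure-Python
exhaustive k-NN and an independent reference implementation
(nilearn SearchLight with a scikit-learn k-NN); cluster labeling against
a flood-fill oracle; smoothing against the closed-form discrete kernel.
The type-I calibration compares empirical rejection rates to each
discrete test's *enumerated* achievable size rather than to nominal
0.05.

## Known limitations

- The Gaussian-noise, shared-shift signal model is favourable to
  cross-participant decoding; real longitudinal effects are noisier and
  partly idiosyncratic, so real-data accuracies will be lower.
- Cluster counts and anatomical locations from any particular clinical
  dataset are not reproducible from synthetic data; the package
  reproduces the *procedure* and its calibration, not cohort-specific
  results.
- No random-field or permutation-based cluster-level inference is
  provided (deliberately out of scope); cluster thresholds are fixed
  operating points, not corrected significance levels.
- The behavioral model is per group × time point, not per load level;
  load-specific behavioral effects beyond the defaults must be injected
  by the user.
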