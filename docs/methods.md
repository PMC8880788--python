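# Methods

This note documents the models and procedures implemented in `leverkin`, the
parameter choices that matter, and what the synthetic-data generator does and
does not emulate.

## Task model and closed-loop shaping

The task rewards pairs of lever-presses whose interpress interval (IPI) falls
between performance-dependent boundaries around a 700-ms target.  The
`ShapingState` carries the boundaries (initially 200 and 1100 ms), the target,
and the reward landscape: each side of the target is divided into
`n_levels = 5` evenly spaced bins, with reward level 5 in the bin containing
the target and level 1 in the boundary bins.  IPIs outside the boundaries earn
level 0.  Tolerance intervals throughout the package (reward boundaries, the
±20% near-target label, the ±10% criterion band) are closed.

Boundaries update between sessions: when the session reward rate exceeds the
band's upper edge (40%), both boundaries move toward the target by a fixed
fraction (`step`, default 0.1) of their distance to it; below the lower edge
(30%) they move away by the same fraction, with the upper boundary clamped at
its initial 1100 ms and the lower at a 50-ms floor.  Only the update
*direction* is dictated by the protocol; the proportional step is this
package's choice — it is scale-free, preserves the boundary ordering
`lower < target < upper` for any `step < 1`, and converges geometrically.  For
any stationary press policy with probability mass on both sides of the
boundaries, the controller dithers around the reward-rate band: a uniform
(200, 1100)-ms presser is held at ≈ 35% long-run reward rate with 100-trial
sessions (binomial session noise makes single sessions leave the band;
the controller corrects on the next update).

## Trial segmentation

Trials are consecutive press pairs.  After an unsuccessful trial a press
starts the next trial only if at least 1.2 s has elapsed since the most recent
press; earlier presses are violations that reset the withholding clock and do
not themselves form trials (the task defines pressing after the withholding
period as what *initiates* a trial).  The intertrial interval (ITI) attached
to a trial is the time from the preceding failed trial's last press to the
very next press, whether or not that press was a violation; it is undefined
after rewarded trials.  Rewards are matched to the trial whose second press
most recently preceded the reward event; a reward with no such press is a
validation error.  The segmenter is verified against an independent
index-walk reimplementation on a thousand randomized simulated logs.

## Performance metrics and learning criterion

Sliding metrics (fraction of IPIs within ±20% of target; CV = sample SD /
mean, with the n−1 denominator) use trailing windows — the window ends at the
reported trial index — followed by a centered boxcar with edge truncation.
Window/boxcar sizes are 100/300 trials for learning-phase analyses and 25/50
for expert-manipulation analyses.  Window alignment is a package choice; the
trailing convention means a metric at trial *t* uses only information
available at *t*.

The learning criterion scans trailing 3000-trial windows at stride 1 and is
met at the earliest trial whose window has CV < 0.25 and mean IPI within ±10%
of 700 ms.  The additional expert gate — median ITI > 1.2 s — is reported
separately, computed over the criterion-achieving window (or all trials when
the criterion is not reached).  The CV of a uniform(200, 1100)-ms IPI
distribution is (900/√12)/650 ≈ 0.40, so a stationary species-typical presser
can never satisfy the criterion; a Gaussian IPI law with SD 100 ms at the
target has CV ≈ 0.14 and satisfies it immediately.

## Interval distributions and Jensen–Shannon divergence

IPI and ITI histograms share a uniform grid of 10-ms bins on [0, 2000] ms;
durations outside the range are clamped into the edge bins.  The binning is a
package choice (the analyses it supports are insensitive to it at this
resolution).  The divergence is

JSD(P, Q) = ½ KLD(P‖M) + ½ KLD(Q‖M),  M = (P + Q)/2,

computed in natural log (nats) with 0·log 0 = 0.  No pseudocounts are needed:
M is strictly positive wherever either input is, so every term is finite.  JSD
is symmetric, zero iff the distributions coincide on all bins, and bounded by
ln 2 (attained on disjoint supports).  The implementation is checked against a
brute-force per-bin summation and against an independent library evaluation.

## Pose-track cleaning

Markerless tracking yields per-frame positions and confidence scores for both
forelimbs.  Three regimes are distinguished by two thresholds:

* `score ≥ score_threshold` (default 0.5): the network prediction is passed
  through bit-exact.
* `occlusion_threshold ≤ score < score_threshold`: the frame is replaced by
  the estimate of a constant-acceleration Kalman smoother.
* `score < occlusion_threshold` (default 0.1): the limb is occluded; runs of
  up to 5 such frames are linearly interpolated between flanking valid frames,
  and longer runs (or runs touching the trial edges) discard the trial.

The smoother models each axis of each limb independently with state
(position, velocity, acceleration), constant acceleration between frames plus
white jerk noise (process noise `q = 1 px²/frame³`), and Gaussian position
measurements (`r = 2 px²`); frames below the score threshold contribute no
measurement.  A forward filter is followed by a Rauch–Tung–Striebel backward
pass, so every estimate conditions on the whole trial — this is what makes it
a smoother rather than a causal filter, and it is run per trial offline.  The
noise defaults are package choices exposed in configuration; on noise-free
constant-acceleration motion the smoother recovers corrupted frames to
sub-pixel RMSE essentially independent of them, because the model is exact
there.  Limb-identity swaps are handled implicitly: a swap manifests as a
low-score excursion and is replaced by the smoothed estimate; no explicit
swap detector is built.

## Time warping and stereotypy

Vertical position is analyzed up-positive (image y is negated).  To compare
trials with different IPIs, each trial is warped onto a canonical grid:
200 ms of context before press 1 and after press 2 and all samples within
±100 ms of each press are copied unwarped (press execution is stereotyped and
its shape must not be stretched); only the interior segment is mapped linearly
onto the 700-ms target.  The time map is linear; the *resampling* of the
interior uses a cubic spline rather than linear interpolation — with 30-Hz
samples, first-order interpolation leaves discretization error around 1e−4 in
trial-to-trial correlations, while cubic resampling keeps the warp identity
(noise-free trials from one underlying template correlate at 1 regardless of
their IPIs) accurate to better than 1e−6.  A trial whose IPI is at most twice
the guard width has no interior and cannot be warped.

Stereotypy is the Pearson correlation between warped vertical trajectories,
computed per forelimb and averaged across the two limbs; pairs involving a
zero-variance trace are flagged undefined and excluded from averages.  Trials
enter the stereotypy comparison only if they were rewarded and followed an
unrewarded trial (equalizing start and end postures around the reward port),
optionally restricted to the dominant sequence mode and to IPI bands around
the selection mean (±30 ms for trial-average figures, ±200 ms for single-trial
projections).  Condition summaries average within-animal trial pairs per
animal and then across animals; across-animal comparisons pair trials from
different animals, average per animal pair, then across pairs.  Amplitude
normalization (rebase to the first sample, divide by the maximum absolute
displacement) is applied for cross-animal trace comparisons; note Pearson
correlations are affine-invariant, so normalization affects displayed traces
and not correlation values.  Press-aligned comparisons use the frames within
±150 ms of each press (9 samples at 30 Hz), normalized the same way, with
correlations averaged first per press identity (animal × press number) and
then per condition pair.

## Sequence-mode identification

Every trial with two presses within 1.2 s (rewarded or not) and an intact
track contributes a feature row: {position, velocity, acceleration} ×
{horizontal, vertical} × {dominant, nondominant} = 12 channels on the
canonical warped timebase (200 ms before press 1 to 200 ms after press 2,
interpress segment at 700 ms).  Derivatives are computed at the native frame
rate *before* warping (central differences, one-sided at the ends), so warping
never manufactures velocity.  Each feature (position, velocity, acceleration)
is standardized by one SD pooled across trials, time points, components, and
limbs, preserving relative amplitudes between channels of the same feature.

Rows are embedded in 2-D by t-SNE (perplexity 30, PCA initialization, fixed
seed; deterministic under a fixed seed).  Density-peak clustering on the
embedding computes, per point, the local density ρ (number of points within
`d_c`, default the 2nd percentile of pairwise distances — common practice for
this algorithm) and δ, the distance to the nearest higher-density point (the
densest point takes its largest distance).  Cluster centers are the points
with the largest γ = ρ·δ (both factors max-normalized); the automatic center
rule takes the largest gap in the sorted γ sequence, which selects one center
for a single blob and one per blob for well-separated groups.  Remaining
points inherit, in decreasing density order, the label of their nearest
higher-density neighbor.  The assignment is verified against a brute-force
reimplementation.

Density-peak clustering tends to overcluster; the correction merges cluster
pairs iteratively while their similarity exceeds a threshold (default 0.8),
recomputing cluster means after each merge.  Similarity is the Pearson
correlation between cluster-mean traces computed *per channel* (each channel
centered) and averaged over the 12 channels.  Computing one correlation over
the raw concatenated rows would be dominated by per-channel coordinate
offsets shared by every trial and by the press-locked components shared by
all modes, and would merge genuinely distinct modes; the per-channel form
scores an artificial split of one mode at ≳ 0.9 and distinct planted modes at
≲ 0.5, so the threshold separates the two cases with a wide margin.  The
merge automates a judgment that is otherwise made by visual inspection of
task-aligned traces and is the package's reproducible surrogate for it.
Final modes are relabeled by decreasing trial count; the dominant mode is the
most frequent (ties to the lower id).

## Synthetic data: what it emulates and what it does not

The generator reproduces the *structure* of the study's data — event logs
from the closed-loop protocol and per-trial forelimb tracks with confidence
scores — under four agent stages:

* **naive**: IPIs uniform(200, 1100) ms (CV ≈ 0.40), ITI compliance 0.3;
* **learner**: Gaussian IPI law drifting from (500, 280) ms toward
  (700, 100) ms at rate 5e−4 per trial, ITI compliance drifting from 0.4
  toward 0.95 at the same rate;
* **expert**: stationary (700, 80) ms, compliance 0.95, trials drawn from 1–3
  stereotyped trajectory modes (default weights 0.7/0.3);
* **regressed**: broad (550, 240) ms, compliance 0.4, all animals sharing one
  simple press-dip template — the species-typical pattern expressed early in
  training and after loss of the learned skill.

ITI-compliant waits are 1.25 s plus an exponential tail (median ≈ 1.7 s);
violations press after uniform(0.15, 1.15) s and reset the clock.  Rewards
are emitted 10 ms after the triggering press so event times stay strictly
increasing.

Trajectory templates live on a canonical timebase (press 1 at 0 s, press 2 at
0.7 s) as sums of Gaussian bumps per limb and component plus a stereotyped
press dip at each press (fixed shape in absolute time, attenuated on the
nondominant limb).  Each trial samples its template through the same
piecewise time map the analysis warp inverts — absolute time within the press
guards and context, linear stretch in the interior — so the warp identity
holds by construction.  Template features are deliberately smooth (bump SD
0.18–0.28 s, dip SD 0.07 s): all features must be well-resolved at the 30-Hz
frame rate for the sampled tracks to represent their continuous model
faithfully; sharper features would alias into spurious trial-to-trial
differences.  Gaussian position noise (default 2 px against 40-px movement
amplitudes) and occlusion runs (corrupted positions, near-zero scores) are
added on top.

The generator does **not** emulate biomechanics, reward-volume effects,
session-level motivation drifts, camera distortion, or tracking-error
statistics of a real network (scores are drawn from simple ranges rather than
a learned confidence model).  Passing tests therefore demonstrate that the
*computations* are correct and that the pipeline recovers planted structure
under realistic noise; they do not certify performance on any particular real
recording setup.

## Numerical and scale choices

* Problem sizes in tests and the acceptance script (e.g. 50 × 100-trial
  sessions with 20 replicates for the controller band; 300-trial cohorts for
  mode recovery; 1000 randomized logs for the segmentation oracle) are chosen
  so each property is measured well inside its Monte-Carlo error at desk
  scale.
* All randomness flows from explicit seeds (numpy `SeedSequence` children for
  replicates); simulation outputs are byte-identical under a fixed seed.
* Degenerate inputs: empty duration lists, all-identical clustering points,
  zero-variance traces, tracks shorter than 3 frames, and windows larger than
  the trial count are either handled with a defined result or rejected with a
  specific error, as documented per function.
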