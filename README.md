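# leverkin

Analysis toolkit for a timed lever-press task used to study motor skill
learning in rodents, covering the behavioral and kinematic computations of
that paradigm: simulation of the closed-loop reward-shaping protocol, trial
segmentation and learning-criterion metrics, interval-distribution statistics,
pose-track cleaning, time-warped trajectory stereotypy, and sequence-mode
clustering.

## The task and the quantities computed

Animals are rewarded for pressing a lever twice with an interpress interval
(IPI) near a 700-ms target.  Reward boundaries start at 200 and 1100 ms and a
between-session controller tightens them when the session reward rate exceeds
40% and relaxes them below 30%, holding reward rates in the 30–40% band while
shaping behavior toward the target; between the target (largest reward) and
each boundary the reward magnitude falls off over five evenly spaced levels.
After an unsuccessful trial the animal must withhold pressing for 1.2 s (the
intertrial interval, ITI) before a new trial can start.

From press/reward event logs the package computes:

* **Trial metrics** — trial segmentation with the ITI-violation rule, the
  fraction of trials with IPI within ±20% of target and the IPI coefficient of
  variation (CV) in sliding windows (100-trial window / 300-trial boxcar for
  learning; 25/50 for expert manipulations), and the learning criterion:
  CV < 0.25 and mean IPI within ±10% of 700 ms over a trailing 3000-trial
  window, with the expert gate median ITI > 1.2 s reported alongside.
* **Interval-distribution statistics** — IPI/ITI probability histograms,
  training heatmaps, and the Jensen–Shannon divergence

  `JSD(IPI, ITI) = ½ KLD(IPI‖M) + ½ KLD(ITI‖M)`, `M = (IPI + ITI)/2`,

  in nats (bounded by ln 2 ≈ 0.693); an animal that has learned the task
  structure separates the two distributions and the JSD approaches its bound.

From tracked forelimb trajectories (30 Hz, per-frame confidence scores):

* **Pose cleaning** — weakly-scored frames are replaced by a
  constant-acceleration (zero-jerk) Kalman smoother estimate; occlusion gaps
  of up to 5 frames are linearly interpolated and longer gaps discard the
  trial.
* **Stereotypy** — press-preserving linear time warping (samples within
  ±100 ms of each press are kept unwarped; the interior is resampled to the
  700-ms target) followed by trial-to-trial Pearson correlations averaged
  across forelimbs, summarized per condition (pre/post manipulation, within
  and across animals) and for ±150-ms press-aligned snippets.
* **Sequence modes** — 12-channel kinematic features ({position, velocity,
  acceleration} × {horizontal, vertical} × both forelimbs, 200 ms before
  press 1 to 200 ms after press 2, interpress segment warped to 700 ms),
  t-SNE embedding, density-peak clustering, and a merge step that corrects
  overclustering.

A synthetic-data module simulates the whole study — naive, learning, expert,
and regressed agents under the closed-loop controller, plus forelimb
trajectories generated from planted movement-mode templates with noise and
occlusions — so every analysis stage can be exercised and validated without
animal data.

## Worked example

```python
from leverkin import (
    make_agent, simulate_sessions, segment_trials,
    detect_learning_criterion, ipi_iti_jsd,
)

agent = make_agent("learner")
log, rates, state = simulate_sessions(agent, n_sessions=80,
                                      trials_per_session=120, seed=3)
trials = segment_trials(log)
crit = detect_learning_criterion(trials)
print(f"trials: {len(trials)}")
print(f"reached criterion: {crit.reached} after {crit.trials_to_criterion} trials")
print(f"median ITI: {crit.iti_median:.2f} s (gate: {crit.iti_gate})")
print(f"JSD early: {ipi_iti_jsd(trials[:2000]):.3f}  "
      f"late: {ipi_iti_jsd(trials[-2000:]):.3f} nats")
print(f"final boundaries: {state.lower:.0f}-{state.upper:.0f} ms")
```

prints

```
trials: 9600
reached criterion: True after 4057 trials
median ITI: 1.52 s (gate: True)
JSD early: 0.368  late: 0.635 nats
final boundaries: 648-741 ms
```

The simulated learner drifts its IPI law toward the 700-ms target and reaches
the 3000-trial criterion after ~4000 trials; the shaping controller has
tightened the reward boundaries around the target; and the IPI/ITI divergence
grows from 0.37 to 0.64 nats as the two interval distributions separate — the
signature of an animal that has learned both the timing and the task
structure.  A naive agent pressing with uniform(200, 1100)-ms intervals never
reaches the criterion (its IPI CV is ≈ 0.40, above the 0.25 bound).

The same pipeline is available from a shell:

```sh
leverkin simulate --agent expert --trials 300 --seed 11 --out run/
leverkin metrics  --events run/events.csv --out run/metrics/
leverkin jsd      --events run/events.csv
leverkin smooth   --traj run/trajectories.csv --out run/clean.csv
leverkin modes    --traj run/trajectories.csv --events run/events.csv --seed 11 --out run/modes/
```

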