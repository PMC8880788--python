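"""Trial segmentation and performance metrics for the timed lever-press task.

A trial is a pair of consecutive lever-presses; the interpress interval (IPI)
is the time between them and the task rewards IPIs near a 700-ms target.
After an unsuccessful trial the animal must withhold pressing for 1.2 s (the
intertrial interval, ITI) before a press can initiate a new trial; presses
inside that window are violations that reset the withholding clock.  Learning
is declared when, over a trailing 3000-trial window, the IPI coefficient of
variation drops below 0.25 and the mean IPI falls within +/-10% of target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_core import EventLog, ValidationError

ITI_THRESHOLD_S = 1.2
TARGET_IPI_MS = 700.0


@dataclass
class Trial:
    index: int
    t_press1: float
    t_press2: float
    ipi: float  # seconds
    rewarded: bool
    reward_level: int
    preceding_iti: float | None  # defined only after an unsuccessful trial


@dataclass
class MetricSeries:
    trial_index: np.ndarray  # index of the trial at which each window ends
    value: np.ndarray
    window: int
    boxcar: int
    statistic: str

    def __len__(self) -> int:
        return len(self.value)


@dataclass
class CriterionResult:
    reached: bool
    trials_to_criterion: int | None
    iti_median: float | None
    iti_gate: bool  # median preceding ITI > threshold (expert gate)


def segment_trials(log: EventLog, iti_threshold: float = ITI_THRESHOLD_S) -> list[Trial]:
    """Segment an event log into two-press trials.

    Consecutive presses pair into trials.  After an unsuccessful trial a press
    starts the next trial only if at least ``iti_threshold`` elapsed since the
    most recent press; earlier presses are violations that reset the clock but
    are still recorded in the next trial's ``preceding_iti`` (the time from
    the failed trial's last press to the very next press, valid or not).
    After a rewarded trial the next press starts a trial immediately.
    """
    trials: list[Trial] = []
    pending_first: float | None = None
    last_press: float | None = None
    awaiting_iti = False
    fail_t2: float | None = None
    iti_pending: float | None = None
    open_trial: Trial | None = None

    for ev in log.events:
        if ev.kind == "press":
            if open_trial is not None and not open_trial.rewarded:
                awaiting_iti = True
                fail_t2 = open_trial.t_press2
            open_trial = None
            if pending_first is None:
                if awaiting_iti:
                    if iti_pending is None:
                        iti_pending = ev.time - fail_t2
                    if ev.time - last_press >= iti_threshold:
                        pending_first = ev.time
                        awaiting_iti = False
                    # else: violation press, clock resets via last_press below
                else:
                    pending_first = ev.time
            else:
                trial = Trial(
                    index=len(trials),
                    t_press1=pending_first,
                    t_press2=ev.time,
                    ipi=ev.time - pending_first,
                    rewarded=False,
                    reward_level=0,
                    preceding_iti=iti_pending,
                )
                trials.append(trial)
                open_trial = trial
                pending_first = None
                iti_pending = None
            last_press = ev.time
        else:  # reward
            if open_trial is None:
                raise ValidationError(
                    f"reward event at t={ev.time} has no matching trial-closing press"
                )
            open_trial.rewarded = True
            open_trial.reward_level = ev.magnitude
            open_trial = None
    if open_trial is not None and not open_trial.rewarded:
        pass  # final trial stays unrewarded; nothing follows it
    return trials


def _trailing_mean_std(values: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Trailing-window mean and sample SD (ddof=1) via cumulative sums."""
    c1 = np.concatenate(([0.0], np.cumsum(values, dtype=float)))
    c2 = np.concatenate(([0.0], np.cumsum(values.astype(float) ** 2)))
    s1 = c1[window:] - c1[:-window]
    s2 = c2[window:] - c2[:-window]
    mean = s1 / window
    var = np.maximum(s2 - s1 * s1 / window, 0.0) / (window - 1)
    return mean, np.sqrt(var)


def _boxcar(values: np.ndarray, width: int) -> np.ndarray:
    """Centered boxcar smoothing with edge truncation."""
    if width <= 1:
        return values
    return (
        pd.Series(values).rolling(width, center=True, min_periods=1).mean().to_numpy()
    )


def sliding_metric(
    trials: Sequence[Trial],
    statistic: str,
    window: int = 100,
    boxcar: int = 300,
    target_ms: float = TARGET_IPI_MS,
    tol: float = 0.20,
) -> MetricSeries:
    """Trailing-window performance metric, boxcar-smoothed.

    ``statistic`` is ``frac_near_target`` (fraction of trial IPIs within the
    closed interval target*(1 +/- tol)) or ``cv`` (sample SD / mean of the
    windowed IPIs).  Windows end at the reported trial index.  Defaults
    (100-trial window, 300-trial boxcar) are the learning-phase settings; the
    expert-manipulation analyses use 25/50.
    """
    if statistic not in ("frac_near_target", "cv"):
        raise ValueError(f"unknown statistic {statistic!r}")
    if window < 2 or boxcar < 1:
        raise ValueError("window must be >= 2 and boxcar >= 1")
    if not trials:
        raise ValueError("trials must be nonempty")
    ipis_ms = np.array([t.ipi for t in trials]) * 1000.0
    n = len(ipis_ms)
    if n < window:
        warnings.warn(
            f"only {n} trials for a {window}-trial window; empty metric series"
        )
        return MetricSeries(np.array([], int), np.array([]), window, boxcar, statistic)
    if statistic == "frac_near_target":
        near = (
            (ipis_ms >= target_ms * (1 - tol)) & (ipis_ms <= target_ms * (1 + tol))
        ).astype(float)
        vals = np.convolve(near, np.ones(window) / window, mode="valid")
    else:
        mean, sd = _trailing_mean_std(ipis_ms, window)
        vals = sd / mean
    return MetricSeries(
        trial_index=np.arange(window - 1, n),
        value=_boxcar(vals, boxcar),
        window=window,
        boxcar=boxcar,
        statistic=statistic,
    )


def detect_learning_criterion(
    trials: Sequence[Trial],
    window: int = 3000,
    cv_max: float = 0.25,
    mean_tol: float = 0.10,
    target_ms: float = TARGET_IPI_MS,
    iti_threshold: float = ITI_THRESHOLD_S,
) -> CriterionResult:
    """Earliest trial whose trailing window satisfies the learning criterion.

    The criterion is CV < ``cv_max`` and window-mean IPI within
    ``target_ms * (1 +/- mean_tol)`` (closed interval) over a trailing
    ``window``-trial span, scanned at stride 1.  The additional expert gate,
    median preceding ITI > ``iti_threshold``, is reported separately: over the
    criterion-achieving window when reached, otherwise over all trials.
    """
    if not trials:
        raise ValueError("trials must be nonempty")
    n = len(trials)
    ipis_ms = np.array([t.ipi for t in trials]) * 1000.0
    reached = False
    end_idx: int | None = None
    if n >= window:
        mean, sd = _trailing_mean_std(ipis_ms, window)
        ok = (sd / mean < cv_max) & (np.abs(mean - target_ms) <= target_ms * mean_tol)
        hits = np.flatnonzero(ok)
        if hits.size:
            reached = True
            end_idx = int(hits[0]) + window - 1
    if reached:
        span = trials[end_idx - window + 1 : end_idx + 1]
    else:
        span = trials
    itis = np.array([t.preceding_iti for t in span if t.preceding_iti is not None])
    iti_median = float(np.median(itis)) if itis.size else None
    return CriterionResult(
        reached=reached,
        trials_to_criterion=(end_idx + 1) if reached else None,
        iti_median=iti_median,
        iti_gate=bool(iti_median is not None and iti_median > iti_threshold),
    )


def trials_from_ipis(
    ipis_s: Sequence[float],
    rewarded: Sequence[bool] | None = None,
    gap_s: float = 2.0,
) -> list[Trial]:
    """Build a synthetic trial list directly from IPIs (testing/analysis aid)."""
    trials = []
    t = 0.0
    prev_rewarded = True
    for i, ipi in enumerate(ipis_s):
        rew = True if rewarded is None else bool(rewarded[i])
        trials.append(
            Trial(
                index=i,
                t_press1=t,
                t_press2=t + ipi,
                ipi=float(ipi),
                rewarded=rew,
                reward_level=5 if rew else 0,
                preceding_iti=None if prev_rewarded else gap_s,
            )
        )
        t += ipi + gap_s
        prev_rewarded = rew
    return trials
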