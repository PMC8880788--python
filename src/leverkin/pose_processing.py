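"""Cleaning of markerless forelimb tracks: Kalman smoothing and gap repair.

Tracker output assigns every frame a confidence score.  Three regimes are
distinguished:

* ``score >= score_threshold``: the network prediction is trusted and passed
  through verbatim (bit-exact).
* ``occlusion_threshold <= score < score_threshold``: the prediction is weak
  (e.g. limb-identity confusion); the frame is replaced by the estimate of a
  constant-acceleration Kalman smoother run over the whole trial.
* ``score < occlusion_threshold``: the limb is occluded; these frames are
  invalid.  Runs of up to ``max_gap`` invalid frames are linearly interpolated
  between flanking valid frames; longer runs make the trial unusable and the
  track is discarded.

The smoother models each axis of each limb independently with state
(position, velocity, acceleration), constant acceleration between frames
(zero jerk) plus white process noise on the jerk, and Gaussian measurement
noise on the observed position.  A forward Kalman filter (frames below the
score threshold contribute no measurement) is followed by a
Rauch-Tung-Striebel backward pass, so every estimate uses the whole trial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_core import RawTrack, ValidationError

SOURCE_NETWORK = "network"
SOURCE_KALMAN = "kalman"
SOURCE_INTERPOLATED = "interpolated"


@dataclass
class LimbClean:
    x: np.ndarray
    y: np.ndarray
    score: np.ndarray
    valid: np.ndarray  # False where occluded
    source: np.ndarray  # per-frame provenance string


@dataclass
class CleanTrack:
    trial_id: int
    limbs: dict[str, LimbClean]
    press_frames: np.ndarray
    frame_rate: float = 30.0
    discarded: bool = False

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.limbs.values())).x)


# ---------------------------------------------------------------------------
# constant-acceleration RTS smoother (per axis)

_F = np.array([[1.0, 1.0, 0.5], [0.0, 1.0, 1.0], [0.0, 0.0, 1.0]])
# discrete white-jerk process noise for unit frame interval
_Q_UNIT = np.array(
    [
        [1.0 / 20, 1.0 / 8, 1.0 / 6],
        [1.0 / 8, 1.0 / 3, 1.0 / 2],
        [1.0 / 6, 1.0 / 2, 1.0],
    ]
)
_H = np.array([[1.0, 0.0, 0.0]])


def _rts_smooth(z: np.ndarray, observed: np.ndarray, q: float, r: float) -> np.ndarray:
    """Smoothed positions for a scalar series with missing measurements."""
    n = len(z)
    Q = q * _Q_UNIT
    R = np.array([[r]])
    obs_idx = np.flatnonzero(observed)
    if obs_idx.size == 0:
        return z.astype(float).copy()
    x = np.zeros(3)
    x[0] = z[obs_idx[0]]
    P = np.diag([1e4, 1e4, 1e4])
    xp = np.empty((n, 3))
    Pp = np.empty((n, 3, 3))
    xf = np.empty((n, 3))
    Pf = np.empty((n, 3, 3))
    for k in range(n):
        if k == 0:
            x_pred, P_pred = x, P
        else:
            x_pred = _F @ xf[k - 1]
            P_pred = _F @ Pf[k - 1] @ _F.T + Q
        xp[k], Pp[k] = x_pred, P_pred
        if observed[k]:
            S = _H @ P_pred @ _H.T + R
            K = P_pred @ _H.T / S[0, 0]
            innov = z[k] - x_pred[0]
            x_new = x_pred + (K * innov).ravel()
            P_new = (np.eye(3) - K @ _H) @ P_pred
        else:
            x_new, P_new = x_pred, P_pred
        xf[k], Pf[k] = x_new, P_new
    xs = xf.copy()
    Ps = Pf.copy()
    for k in range(n - 2, -1, -1):
        C = np.linalg.solve(Pp[k + 1].T, (_F @ Pf[k].T)).T
        xs[k] = xf[k] + C @ (xs[k + 1] - xp[k + 1])
        Ps[k] = Pf[k] + C @ (Ps[k + 1] - Pp[k + 1]) @ C.T
    return xs[:, 0]


def kalman_smooth(
    track: RawTrack,
    score_threshold: float = 0.5,
    process_noise: float = 1.0,
    measurement_noise: float = 2.0,
    occlusion_threshold: float = 0.1,
) -> CleanTrack:
    """Replace weakly-scored frames with constant-acceleration smoother estimates.

    Frames scoring at or above ``score_threshold`` keep the network prediction
    verbatim.  Frames below it take the smoothed estimate; frames below
    ``occlusion_threshold`` are additionally flagged invalid for
    :func:`fill_gaps`.  ``process_noise`` is the white-jerk spectral density
    (px^2/frame^3) and ``measurement_noise`` the position noise variance
    (px^2).
    """
    if score_threshold <= 0 or process_noise <= 0 or measurement_noise <= 0:
        raise ValueError("thresholds and noise parameters must be positive")
    track.validate()
    if track.n_frames < 3:
        raise ValidationError("track shorter than 3 frames: acceleration unobservable")
    limbs: dict[str, LimbClean] = {}
    for name, d in track.limbs.items():
        observed = d.score >= score_threshold
        valid = d.score >= occlusion_threshold
        source = np.where(observed, SOURCE_NETWORK, SOURCE_KALMAN).astype(object)
        x = d.x.astype(float).copy()
        y = d.y.astype(float).copy()
        if not observed.all():
            for arr, raw in ((x, d.x), (y, d.y)):
                sm = _rts_smooth(raw.astype(float), observed, process_noise, measurement_noise)
                arr[~observed] = sm[~observed]
        limbs[name] = LimbClean(
            x=x, y=y, score=d.score.copy(), valid=valid, source=source
        )
    return CleanTrack(
        trial_id=track.trial_id,
        limbs=limbs,
        press_frames=np.asarray(track.press_frames, dtype=int).copy(),
        frame_rate=track.frame_rate,
        discarded=False,
    )


def _invalid_runs(valid: np.ndarray) -> list[tuple[int, int]]:
    """Inclusive (start, stop) spans of consecutive invalid frames."""
    runs = []
    n = len(valid)
    i = 0
    while i < n:
        if not valid[i]:
            j = i
            while j + 1 < n and not valid[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    return runs


def fill_gaps(track: CleanTrack, max_gap: int = 5) -> CleanTrack:
    """Linearly interpolate short occlusion gaps; discard the track otherwise.

    Runs of at most ``max_gap`` consecutive invalid frames with valid frames
    on both sides are filled by linear interpolation of x and y between the
    flanking valid frames.  Any longer run, or a run touching the start or end
    of the trial (no flank to interpolate from), marks the track discarded.
    Idempotent: a second application is a no-op.
    """
    limbs: dict[str, LimbClean] = {}
    discarded = track.discarded
    for name, d in track.limbs.items():
        x = d.x.copy()
        y = d.y.copy()
        valid = d.valid.copy()
        source = d.source.copy()
        for start, stop in _invalid_runs(d.valid):
            length = stop - start + 1
            if length > max_gap or start == 0 or stop == len(valid) - 1:
                discarded = True
                continue
            lo, hi = start - 1, stop + 1
            frac = np.arange(1, length + 1) / (length + 1)
            x[start : stop + 1] = x[lo] + frac * (x[hi] - x[lo])
            y[start : stop + 1] = y[lo] + frac * (y[hi] - y[lo])
            valid[start : stop + 1] = True
            source[start : stop + 1] = SOURCE_INTERPOLATED
        limbs[name] = LimbClean(x=x, y=y, score=d.score.copy(), valid=valid, source=source)
    return CleanTrack(
        trial_id=track.trial_id,
        limbs=limbs,
        press_frames=track.press_frames.copy(),
        frame_rate=track.frame_rate,
        discarded=discarded,
    )


def clean_track(raw: RawTrack, max_gap: int = 5, **kalman_kwargs) -> CleanTrack:
    """Full cleaning pipeline: Kalman smoothing then gap repair."""
    return fill_gaps(kalman_smooth(raw, **kalman_kwargs), max_gap=max_gap)


def as_clean(raw: RawTrack) -> CleanTrack:
    """Wrap a raw track as a CleanTrack with every frame trusted verbatim."""
    raw.validate()
    limbs = {
        name: LimbClean(
            x=d.x.astype(float).copy(),
            y=d.y.astype(float).copy(),
            score=d.score.copy(),
            valid=np.ones(len(d.x), dtype=bool),
            source=np.full(len(d.x), SOURCE_NETWORK, dtype=object),
        )
        for name, d in raw.limbs.items()
    }
    return CleanTrack(
        trial_id=raw.trial_id,
        limbs=limbs,
        press_frames=np.asarray(raw.press_frames, dtype=int).copy(),
        frame_rate=raw.frame_rate,
    )
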