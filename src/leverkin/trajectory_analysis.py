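"""Movement-stereotypy analysis of forelimb trajectories.

Trials are made comparable by a press-preserving linear time warp: samples
within a guard window (+/-100 ms) of each lever-press, plus 200 ms of context
on either side of the trial, are copied unwarped, and only the interior
segment between the guards is resampled so the press-to-press time equals the
700-ms target.  Stereotypy is then the trial-to-trial Pearson correlation of
the warped vertical trajectories, computed per forelimb and averaged across
the two limbs.

The time-warp *map* is linear; resampling uses a cubic spline so that
noise-free trials generated from one underlying movement template correlate
at 1 to within numerical precision regardless of their IPIs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from .pose_processing import CleanTrack

CONTEXT_S = 0.2
GUARD_S = 0.1
TARGET_IPI_S = 0.7
PRESS_WINDOW_S = 0.150


class WarpError(ValueError):
    """Trial geometry incompatible with the requested warp."""


@dataclass
class WarpedTrial:
    """Per-limb vertical position on the canonical warped timebase."""

    vertical: dict[str, np.ndarray]
    press_indices: tuple[int, int]
    trial_index: int
    animal_id: str = ""
    condition: str = ""
    normalization: str = "none"

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.vertical.values())))


@dataclass
class CorrelationMatrix:
    matrix: np.ndarray  # trial x trial, limb-averaged Pearson r (NaN = undefined)
    conditions: list[str]
    animals: list[str]


def canonical_grid(fs: float = 30.0) -> tuple[int, int, int, int]:
    """(context, guard, target-IPI intervals, total length) in frames."""
    c = round(CONTEXT_S * fs)
    g = round(GUARD_S * fs)
    T = round(TARGET_IPI_S * fs)
    return c, g, T, c + T + 1 + c


def warp_series(
    values: np.ndarray,
    p1: int,
    p2: int,
    fs: float = 30.0,
    target_ipi_s: float = TARGET_IPI_S,
    guard_s: float = GUARD_S,
    context_s: float = CONTEXT_S,
) -> np.ndarray:
    """Press-preserving linear time warp of one per-frame series.

    ``p1``/``p2`` are the press frame indices.  The output grid has
    ``context`` frames before press1 and after press2, presses at fixed
    indices, guard samples copied verbatim, and the interior linearly mapped
    onto ``target_ipi_s`` and resampled with a cubic spline.
    """
    values = np.asarray(values, dtype=float)
    c = round(context_s * fs)
    g = round(guard_s * fs)
    T = round(target_ipi_s * fs)
    if p2 - p1 <= 2 * g:
        raise WarpError(f"IPI of {p2 - p1} frames leaves no interior beyond the guards")
    if p1 - c < 0 or p2 + c >= len(values):
        raise WarpError("not enough context frames around the presses")
    out = np.empty(c + T + 1 + c)
    out[: c + g + 1] = values[p1 - c : p1 + g + 1]
    out[c + T - g :] = values[p2 - g : p2 + c + 1]
    ks = np.arange(c + g + 1, c + T - g)  # interior canonical indices
    src = p1 + g + (ks - (c + g)) * (p2 - p1 - 2 * g) / (T - 2 * g)
    knots = np.arange(p1 + g, p2 - g + 1)
    spline = CubicSpline(knots, values[p1 + g : p2 - g + 1])
    out[c + g + 1 : c + T - g] = spline(src)
    return out


def vertical_position(track: CleanTrack, limb: str) -> np.ndarray:
    """Up-positive vertical position (image y grows downward)."""
    return -track.limbs[limb].y


def time_warp_trial(
    track: CleanTrack,
    trial_index: int = -1,
    target_ipi_ms: float = TARGET_IPI_S * 1000,
    guard_ms: float = GUARD_S * 1000,
    normalize: str = "none",
    animal_id: str = "",
    condition: str = "",
) -> WarpedTrial:
    """Warp one trial's vertical trajectories onto the canonical timebase.

    ``normalize='max_amplitude'`` rebases each limb's trace to its first
    sample and divides by the maximum absolute displacement from it.
    """
    if track.discarded:
        raise WarpError(f"trial {track.trial_id} is discarded")
    if len(track.press_frames) < 2:
        raise WarpError(f"trial {track.trial_id} has fewer than two press frames")
    p1, p2 = int(track.press_frames[0]), int(track.press_frames[-1])
    fs = track.frame_rate
    c = round(CONTEXT_S * fs)
    g = round(guard_ms / 1000 * fs)
    T = round(target_ipi_ms / 1000 * fs)
    vertical = {}
    for limb in track.limbs:
        v = warp_series(
            vertical_position(track, limb),
            p1,
            p2,
            fs=fs,
            target_ipi_s=target_ipi_ms / 1000,
            guard_s=guard_ms / 1000,
        )
        if normalize == "max_amplitude":
            v = v - v[0]
            peak = np.max(np.abs(v))
            if peak > 0:
                v = v / peak
        vertical[limb] = v
    return WarpedTrial(
        vertical=vertical,
        press_indices=(c, c + T),
        trial_index=trial_index if trial_index >= 0 else int(track.trial_id),
        animal_id=animal_id,
        condition=condition,
        normalization=normalize,
    )


def select_stereotypy_trials(
    trials: Sequence,
    modes=None,
    ipi_band_ms: float | None = None,
) -> np.ndarray:
    """Trial indices suitable for stereotypy comparison.

    Keeps rewarded trials whose predecessor was unrewarded (same start and end
    posture: the animal comes up from the reward port only after a success).
    With ``modes`` (a ModeAssignment) only dominant-mode trials are kept; with
    ``ipi_band_ms`` the selection is further restricted to trials whose IPI is
    within that band of the selection's mean IPI (30 ms for trial-average
    panels, 200 ms for single-trial projections).
    """
    sel = [
        t.index
        for i, t in enumerate(trials)
        if i > 0 and t.rewarded and not trials[i - 1].rewarded
    ]
    if modes is not None:
        by_trial = dict(zip(modes.trial_indices, modes.labels))
        sel = [i for i in sel if by_trial.get(i) == modes.dominant_mode]
    if ipi_band_ms is not None and sel:
        ipis = np.array([trials[i].ipi for i in sel]) * 1000.0
        keep = np.abs(ipis - ipis.mean()) <= ipi_band_ms
        sel = [i for i, k in zip(sel, keep) if k]
    if not sel:
        warnings.warn("no trials qualify for stereotypy analysis")
    return np.asarray(sel, dtype=int)


def pairwise_correlations(warped: Sequence[WarpedTrial]) -> CorrelationMatrix:
    """Trial-to-trial Pearson correlations, per limb then limb-averaged.

    A pair involving a zero-variance trace gets NaN for that limb; NaN entries
    are excluded from all downstream averages.
    """
    if len(warped) < 2:
        raise ValueError("need at least two warped trials")
    limbs = list(warped[0].vertical)
    n = len(warped)
    per_limb = np.empty((len(limbs), n, n))
    for li, limb in enumerate(limbs):
        stack = np.vstack([w.vertical[limb] for w in warped])
        sd = stack.std(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            m = np.corrcoef(stack)
        m[sd == 0, :] = np.nan
        m[:, sd == 0] = np.nan
        per_limb[li] = m
    matrix = per_limb.mean(axis=0)
    np.fill_diagonal(matrix, 1.0)
    return CorrelationMatrix(
        matrix=matrix,
        conditions=[w.condition for w in warped],
        animals=[w.animal_id for w in warped],
    )


def _condition_key(a: str, b: str) -> tuple[str, str]:
    return tuple(sorted((a, b)))


def condition_summary(
    cm: CorrelationMatrix, scheme: str = "within_animal"
) -> dict[tuple[str, str], float]:
    """Mean correlation per condition pair (e.g. pre-pre, post-post, pre-post).

    ``within_animal``: only same-animal trial pairs; averaged per animal and
    condition pair, then across animals.  ``across_animal``: only pairs from
    different animals; averaged per animal pair and condition pair, then
    across animal pairs.  The diagonal is excluded; undefined (NaN) pairs are
    skipped; a condition pair with no valid trial pair is absent from the
    result.
    """
    if scheme not in ("within_animal", "across_animal"):
        raise ValueError(f"unknown scheme {scheme!r}")
    n = cm.matrix.shape[0]
    groups: dict[tuple, dict[tuple[str, str], list[float]]] = {}
    for i, j in combinations(range(n), 2):
        r = cm.matrix[i, j]
        if not np.isfinite(r):
            continue
        same = cm.animals[i] == cm.animals[j]
        if scheme == "within_animal":
            if not same:
                continue
            unit = (cm.animals[i],)
        else:
            if same:
                continue
            unit = tuple(sorted((cm.animals[i], cm.animals[j])))
        key = _condition_key(cm.conditions[i], cm.conditions[j])
        groups.setdefault(unit, {}).setdefault(key, []).append(float(r))
    result: dict[tuple[str, str], list[float]] = {}
    for unit_means in groups.values():
        for key, vals in unit_means.items():
            result.setdefault(key, []).append(float(np.mean(vals)))
    return {key: float(np.mean(vals)) for key, vals in result.items()}


def press_snippets(
    track: CleanTrack,
    animal_id: str = "",
    window_s: float = PRESS_WINDOW_S,
    limb: str = "dominant",
) -> list[tuple[tuple[str, int], np.ndarray]]:
    """Amplitude-normalized press trajectories (+/-window around each press).

    Returns ``[((animal_id, press_number), snippet), ...]``; presses too close
    to the trial edges are dropped.  Snippets cover the frames inside the
    closed +/-window range (9 samples at 30 Hz for +/-150 ms).
    """
    fs = track.frame_rate
    r = int(np.floor(window_s * fs))
    v = vertical_position(track, limb)
    out = []
    for press_no, p in enumerate(track.press_frames, start=1):
        p = int(p)
        if p - r < 0 or p + r >= len(v):
            continue
        snip = v[p - r : p + r + 1].copy()
        snip = snip - snip[0]
        peak = np.max(np.abs(snip))
        if peak > 0:
            snip = snip / peak
        out.append(((animal_id, press_no), snip))
    return out


def press_aligned_correlations(
    tracks_by_condition: Mapping[str, Sequence[tuple[CleanTrack, str]]],
    window_s: float = PRESS_WINDOW_S,
    limb: str = "dominant",
) -> dict[tuple[str, str], float]:
    """Mean pairwise correlations of press trajectories within/across conditions.

    ``tracks_by_condition`` maps a condition label (e.g. ``early``, ``pre``,
    ``post``) to ``(CleanTrack, animal_id)`` pairs.  Correlations are averaged
    first per press identity pair (animal x press number) and then per
    condition pair, mirroring how per-press averages are pooled.
    """
    snippets: list[tuple[str, tuple[str, int], np.ndarray]] = []
    for cond, items in tracks_by_condition.items():
        for track, animal in items:
            for key, snip in press_snippets(track, animal, window_s, limb):
                snippets.append((cond, key, snip))
    per_press: dict[tuple[tuple[str, str], tuple, tuple], list[float]] = {}
    for (ca, ka, sa), (cb, kb, sb) in combinations(snippets, 2):
        sda, sdb = sa.std(), sb.std()
        if sda == 0 or sdb == 0:
            continue
        r = float(np.corrcoef(sa, sb)[0, 1])
        ckey = _condition_key(ca, cb)
        pkey = tuple(sorted((ka, kb)))
        per_press.setdefault((ckey, pkey[0], pkey[1]), []).append(r)
    by_condition: dict[tuple[str, str], list[float]] = {}
    for (ckey, _, _), vals in per_press.items():
        by_condition.setdefault(ckey, []).append(float(np.mean(vals)))
    return {k: float(np.mean(v)) for k, v in by_condition.items()}
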