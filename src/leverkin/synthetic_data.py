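"""Simulation of the timed lever-press task and synthetic forelimb tracks.

The task rewards two lever-presses separated by an interpress interval (IPI)
near 700 ms.  Reward boundaries start at 200 and 1100 ms and are adapted
between sessions by a closed-loop controller that tightens them when the
session reward rate exceeds 40% and relaxes them when it falls below 30%,
holding the rate inside the 30-40% band for any stationary press policy with
mass on both sides of the target.  Between the target (largest reward) and
each boundary (smallest), rewards fall off over five evenly spaced levels.
After an unsuccessful trial the animal must withhold pressing for 1.2 s.

Agents emulate the behavioral cohorts: ``naive`` animals press with a broad
species-typical IPI distribution and largely ignore the withholding rule;
``learner`` agents drift their IPI law toward the target (narrowing CV) and
comply with the ITI; ``expert`` agents are converged and use one or more
stereotyped trajectory modes; ``regressed`` agents have lost the learned
pattern and share a single simple press template.

Synthetic trajectories are generated from mode templates laid out on a
canonical timebase (press1 at 0 s, press2 at 0.7 s).  Each trial samples its
template through the same piecewise-linear time map that the analysis-side
warp inverts (absolute time within the press guards and context, linear
stretch in the interior), so warped noise-free trials from one template are
identical up to resampling precision.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .io_core import Event, EventLog, LIMBS, RawTrack, LimbData
from .trajectory_analysis import CONTEXT_S, GUARD_S, TARGET_IPI_S
from .trial_metrics import segment_trials

FS = 30.0  # Hz, video frame rate
PRE_ROLL_S = 0.4  # track context before press1 / after press2
POST_ROLL_S = 0.4


class DomainError(ValueError):
    """Parameter outside its valid domain."""


class GenerationError(ValueError):
    """A trajectory cannot be generated for the requested trial."""


# ---------------------------------------------------------------------------
# closed-loop shaping controller


@dataclass(frozen=True)
class ShapingState:
    """Reward boundaries, target, and landscape of the shaping controller."""

    lower: float = 200.0  # ms
    upper: float = 1100.0  # ms
    target: float = 700.0  # ms
    n_levels: int = 5
    band: tuple[float, float] = (0.30, 0.40)
    step: float = 0.10  # fractional boundary move per update
    upper_max: float = 1100.0  # relax clamp (initial upper boundary)
    lower_min: float = 50.0  # relax floor, keeps lower > 0

    def validate(self) -> "ShapingState":
        if not (self.lower < self.target < self.upper):
            raise DomainError("boundaries must straddle the target")
        if not (0 < self.band[0] < self.band[1] < 1):
            raise DomainError("band fractions must satisfy 0 < low < high < 1")
        if self.n_levels < 1:
            raise DomainError("n_levels must be >= 1")
        return self


def update_boundaries(state: ShapingState, session_reward_rate: float) -> ShapingState:
    """Between-session boundary update: tighten above the band, relax below.

    Above the band both boundaries move toward the target by ``step`` of their
    distance to it; below the band they move away by the same fraction (upper
    clamped at its initial value, lower at a positive floor); inside the band
    the state is unchanged.
    """
    state.validate()
    if not 0 <= session_reward_rate <= 1:
        raise DomainError(f"reward rate {session_reward_rate} outside [0, 1]")
    low, high = state.band
    if session_reward_rate > high:
        lower = state.lower + state.step * (state.target - state.lower)
        upper = state.upper - state.step * (state.upper - state.target)
    elif session_reward_rate < low:
        lower = state.lower - state.step * (state.target - state.lower)
        upper = state.upper + state.step * (state.upper - state.target)
        lower = max(lower, state.lower_min)
        upper = min(upper, state.upper_max)
    else:
        return state
    return dataclasses.replace(state, lower=lower, upper=upper).validate()


def reward_for_ipi(ipi_ms: float, state: ShapingState) -> int:
    """Reward level 0-n_levels for an IPI under the current landscape.

    0 outside the boundaries; the level is largest (n_levels) in the bin
    containing the target and decreases over evenly spaced bins toward each
    boundary, reaching 1 in the boundary bins.
    """
    if ipi_ms <= 0:
        raise DomainError("IPI must be positive")
    state.validate()
    if ipi_ms < state.lower or ipi_ms > state.upper:
        return 0
    if ipi_ms <= state.target:
        width = (state.target - state.lower) / state.n_levels
        k = int((state.target - ipi_ms) // width)
    else:
        width = (state.upper - state.target) / state.n_levels
        k = int((ipi_ms - state.target) // width)
    return max(1, state.n_levels - k)


# ---------------------------------------------------------------------------
# agents


@dataclass
class AgentSpec:
    """A press policy: IPI law, ITI compliance, and (for learners) drift."""

    kind: str  # naive | learner | expert | regressed
    ipi_law: tuple[str, dict]  # ("uniform"|"normal"|"constant", params in ms)
    iti_compliance: float  # P(withhold >= 1.2 s after a failure)
    learning_rate: float = 0.0  # per-trial drift of the law toward ipi_goal
    ipi_goal: tuple[float, float] = (700.0, 100.0)  # (mean, sd) ms, learners
    iti_compliance_goal: float | None = None  # compliance drift target, learners
    mode_weights: tuple[float, ...] = (1.0,)

    def validate(self) -> "AgentSpec":
        if not 0 <= self.iti_compliance <= 1:
            raise DomainError("iti_compliance must be in [0, 1]")
        w = np.asarray(self.mode_weights, dtype=float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise DomainError("mode_weights must be probabilities summing to 1")
        name, params = self.ipi_law
        if name not in ("uniform", "normal", "constant"):
            raise DomainError(f"unknown IPI law {name!r}")
        if name == "uniform" and not 0 < params["low"] < params["high"]:
            raise DomainError("uniform law requires 0 < low < high")
        if name == "normal" and (params["mean"] <= 0 or params["sd"] < 0):
            raise DomainError("normal law requires positive mean and sd >= 0")
        if name == "constant" and params["value"] <= 0:
            raise DomainError("constant law requires a positive value")
        return self


def make_agent(kind: str) -> AgentSpec:
    """Default agent parameterizations for the four behavioral stages."""
    if kind == "naive":
        return AgentSpec(
            kind, ("uniform", {"low": 200.0, "high": 1100.0}), iti_compliance=0.3
        ).validate()
    if kind == "learner":
        return AgentSpec(
            kind,
            ("normal", {"mean": 500.0, "sd": 280.0}),
            iti_compliance=0.4,
            learning_rate=5e-4,
            iti_compliance_goal=0.95,
        ).validate()
    if kind == "expert":
        return AgentSpec(
            kind,
            ("normal", {"mean": 700.0, "sd": 80.0}),
            iti_compliance=0.95,
            mode_weights=(0.7, 0.3),
        ).validate()
    if kind == "regressed":
        return AgentSpec(
            kind, ("normal", {"mean": 550.0, "sd": 240.0}), iti_compliance=0.4
        ).validate()
    raise DomainError(f"unknown agent kind {kind!r}")


_MIN_IPI_MS = 60.0


def _draw_ipi(law: tuple[str, dict], rng: np.random.Generator) -> float:
    name, p = law
    if name == "constant":
        return p["value"]
    if name == "uniform":
        return float(rng.uniform(p["low"], p["high"]))
    for _ in range(100):
        v = float(rng.normal(p["mean"], p["sd"]))
        if v >= _MIN_IPI_MS:
            return v
    return _MIN_IPI_MS


def simulate_sessions(
    agent: AgentSpec,
    state: ShapingState | None = None,
    n_sessions: int = 50,
    trials_per_session: int = 100,
    seed=0,
    animal_id: str = "sim",
) -> tuple[EventLog, np.ndarray, ShapingState]:
    """Simulate training sessions under the closed-loop boundary controller.

    Each trial draws an IPI from the agent's law and a reward level from the
    current landscape.  After failures the agent either withholds for more
    than 1.2 s or emits violation presses (which reset the withholding clock
    and do not form trials).  Boundaries update between sessions; learner
    agents drift their IPI law toward ``ipi_goal`` every trial.  Returns the
    event log, per-session reward rates, and the final shaping state.
    """
    agent.validate()
    state = (state or ShapingState()).validate()
    if n_sessions < 1 or trials_per_session < 1:
        raise DomainError("n_sessions and trials_per_session must be >= 1")
    rng = np.random.default_rng(seed)
    law_name, law_params = agent.ipi_law
    params = dict(law_params)
    compliance = agent.iti_compliance
    events: list[Event] = []
    rates = np.empty(n_sessions)
    t = 0.0
    for s in range(n_sessions):
        rewarded = 0
        for _ in range(trials_per_session):
            ipi_ms = _draw_ipi((law_name, params), rng)
            t1, t2 = t, t + ipi_ms / 1000.0
            events.append(Event(t1, "press"))
            events.append(Event(t2, "press"))
            level = reward_for_ipi(ipi_ms, state)
            if level > 0:
                rewarded += 1
                events.append(Event(t2 + 0.01, "reward", level))
                t = t2 + 0.5 + rng.exponential(0.8)
            else:
                clock = t2
                while rng.random() > compliance:
                    clock += rng.uniform(0.15, 1.15)  # violation press, < 1.2 s
                    events.append(Event(clock, "press"))
                t = clock + 1.25 + rng.exponential(0.6)
            if agent.learning_rate > 0:
                if law_name == "normal":
                    params["mean"] += agent.learning_rate * (agent.ipi_goal[0] - params["mean"])
                    params["sd"] += agent.learning_rate * (agent.ipi_goal[1] - params["sd"])
                if agent.iti_compliance_goal is not None:
                    compliance += agent.learning_rate * (agent.iti_compliance_goal - compliance)
        rates[s] = rewarded / trials_per_session
        state = update_boundaries(state, rates[s])
    return EventLog(animal_id, events).validate(), rates, state


# ---------------------------------------------------------------------------
# trajectory templates and synthesis


@dataclass
class ModeTemplate:
    """A stereotyped movement pattern on the canonical trial timebase.

    The canonical timebase places press1 at 0 s and press2 at 0.7 s, with
    ``PRE_ROLL_S`` of context before and ``POST_ROLL_S`` after.  ``bumps``
    maps ``(limb, component)`` to Gaussian bump parameters
    ``(center_s, width_s, amplitude_px)``; a stereotyped press dip (depth,
    width in seconds) is added to the vertical component at each press time
    (full depth on the dominant limb, attenuated on the nondominant).
    """

    bumps: dict[tuple[str, str], list[tuple[float, float, float]]]
    press_dip: tuple[float, float] = (25.0, 0.07)
    nondominant_dip_scale: float = 0.3
    amplitude: float = 1.0

    @property
    def press_phases(self) -> tuple[float, float]:
        duration = PRE_ROLL_S + TARGET_IPI_S + POST_ROLL_S
        return (PRE_ROLL_S / duration, (PRE_ROLL_S + TARGET_IPI_S) / duration)

    def validate(self) -> "ModeTemplate":
        ph1, ph2 = self.press_phases
        if not (0 < ph1 < ph2 < 1):
            raise DomainError("press phases must be strictly increasing in (0, 1)")
        for params in self.bumps.values():
            for _, width, amp in params:
                if width <= 0 or not np.isfinite(amp):
                    raise DomainError("bump widths must be positive, amplitudes finite")
        return self

    def evaluate(self, tau_s: np.ndarray, limb: str, component: str) -> np.ndarray:
        out = np.zeros_like(tau_s, dtype=float)
        for center, width, amp in self.bumps.get((limb, component), []):
            out += self.amplitude * amp * np.exp(-0.5 * ((tau_s - center) / width) ** 2)
        if component == "vertical":
            depth, width = self.press_dip
            scale = 1.0 if limb == "dominant" else self.nondominant_dip_scale
            for press_t in (0.0, TARGET_IPI_S):
                out -= scale * depth * np.exp(-0.5 * ((tau_s - press_t) / width) ** 2)
        return out


def default_templates(
    n_modes: int = 2,
    seed: int = 0,
    amplitude_px: float = 40.0,
    simple: bool = False,
) -> list[ModeTemplate]:
    """Smooth bump-sum templates with stereotyped press dips.

    ``simple=True`` returns a single press-dip-only template, the shared
    species-typical pattern expressed early in training and after regression.
    """
    if simple:
        return [ModeTemplate(bumps={}, press_dip=(20.0, 0.07)).validate()]
    rng = np.random.default_rng(seed)
    templates = []
    for _ in range(n_modes):
        bumps: dict[tuple[str, str], list[tuple[float, float, float]]] = {}
        for limb in LIMBS:
            for comp, scale in (("vertical", 1.0), ("horizontal", 0.5)):
                n_bumps = int(rng.integers(2, 4))
                bumps[(limb, comp)] = [
                    (
                        float(rng.uniform(0.05, 0.65)),
                        float(rng.uniform(0.18, 0.28)),
                        float(rng.uniform(0.4, 1.0) * rng.choice([-1, 1]))
                        * amplitude_px
                        * scale,
                    )
                    for _ in range(n_bumps)
                ]
        templates.append(ModeTemplate(bumps=bumps).validate())
    return templates


def _canonical_tau(n: int, p1: int, p2: int, fs: float) -> np.ndarray:
    """Canonical time (s) of each frame under the press-preserving warp map."""
    g = round(GUARD_S * fs)
    T = round(TARGET_IPI_S * fs)
    k = np.arange(n, dtype=float)
    tau = np.empty(n)
    pre = k <= p1 + g
    post = k >= p2 - g
    mid = ~(pre | post)
    tau[pre] = k[pre] - p1
    tau[post] = k[post] - p2 + T
    tau[mid] = g + (k[mid] - p1 - g) * (T - 2 * g) / (p2 - p1 - 2 * g)
    return tau / fs


def synthesize_trajectories(
    log: EventLog,
    templates: Sequence[ModeTemplate],
    mode_weights: Sequence[float] | None = None,
    noise_sd: float = 2.0,
    occlusion: tuple[float, int] = (0.0, 0),
    score_model: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    seed=0,
    origin: tuple[float, float] = (150.0, 200.0),
    on_incompatible: str = "raise",
) -> tuple[list[RawTrack], np.ndarray]:
    """Generate per-trial forelimb tracks for every two-press trial in a log.

    Each trial draws a template by ``mode_weights`` and samples it through the
    canonical time map (press phases land on the trial's actual press frames),
    adds Gaussian position noise, and optionally corrupts occlusion runs
    (``occlusion=(per-frame start rate, max run length)``) with large position
    errors and near-zero confidence scores.  Returns the tracks and the
    planted mode label per trial (-1 for trials skipped as incompatible when
    ``on_incompatible='skip'``; the default is to raise).
    """
    if on_incompatible not in ("raise", "skip"):
        raise DomainError("on_incompatible must be 'raise' or 'skip'")
    if mode_weights is None:
        mode_weights = np.full(len(templates), 1.0 / len(templates))
    mode_weights = np.asarray(mode_weights, dtype=float)
    if len(mode_weights) != len(templates) or abs(mode_weights.sum() - 1) > 1e-9:
        raise DomainError("mode_weights must match templates and sum to 1")
    rng = np.random.default_rng(seed)
    trials = segment_trials(log)
    occl_rate, occl_max = occlusion
    g = round(GUARD_S * FS)
    x0, y0 = origin
    tracks: list[RawTrack] = []
    labels = np.full(len(trials), -1, dtype=int)
    for trial in trials:
        n_ipi = round(trial.ipi * FS)
        if n_ipi <= 2 * g:
            if on_incompatible == "skip":
                continue
            raise GenerationError(
                f"trial {trial.index}: IPI {trial.ipi * 1000:.0f} ms incompatible "
                f"with the {GUARD_S * 1000:.0f}-ms press guards"
            )
        label = int(rng.choice(len(templates), p=mode_weights))
        labels[trial.index] = label
        template = templates[label]
        pre = round(PRE_ROLL_S * FS)
        post = round(POST_ROLL_S * FS)
        n = pre + n_ipi + post + 1
        p1, p2 = pre, pre + n_ipi
        tau = _canonical_tau(n, p1, p2, FS)
        limbs: dict[str, LimbData] = {}
        for limb in LIMBS:
            vert = template.evaluate(tau, limb, "vertical")
            horiz = template.evaluate(tau, limb, "horizontal")
            x = x0 + horiz
            y = y0 - vert  # image coordinates: y grows downward
            if noise_sd > 0:
                x = x + rng.normal(0, noise_sd, n)
                y = y + rng.normal(0, noise_sd, n)
            if score_model is not None:
                score = np.clip(score_model(rng, n), 0.0, 1.0)
            else:
                score = rng.uniform(0.85, 1.0, n)
            if occl_rate > 0 and occl_max > 0:
                k = 0
                while k < n:
                    if rng.random() < occl_rate:
                        run = int(rng.integers(1, occl_max + 1))
                        stop = min(k + run, n)
                        x[k:stop] += rng.uniform(-60, 60, stop - k)
                        y[k:stop] += rng.uniform(-60, 60, stop - k)
                        score[k:stop] = rng.uniform(0.0, 0.04, stop - k)
                        k = stop
                    else:
                        k += 1
            limbs[limb] = LimbData(x=x, y=y, score=score)
        tracks.append(
            RawTrack(
                trial_id=trial.index,
                limbs=limbs,
                press_frames=np.array([p1, p2]),
                frame_rate=FS,
            ).validate()
        )
    return tracks, labels
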