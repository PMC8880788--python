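"""Interval probability distributions and the Jensen-Shannon divergence.

An animal that has learned the task structure produces two clearly different
interval distributions: IPIs concentrated near the 700-ms target and ITIs
pushed beyond the 1.2-s withholding threshold.  Their dissimilarity is
quantified by the Jensen-Shannon divergence

    JSD(P, Q) = 1/2 KLD(P || M) + 1/2 KLD(Q || M),   M = (P + Q) / 2,

computed in natural log (nats) with the convention 0*log 0 = 0, so JSD is
symmetric and bounded by ln 2.  Distributions are normalized histograms on a
shared uniform grid (default 10-ms bins on [0, 2000] ms; out-of-range
durations are clamped into the edge bins).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .trial_metrics import Trial

LN2 = float(np.log(2.0))


@dataclass
class DurationDistribution:
    bin_edges: np.ndarray  # ms, uniform width, strictly increasing
    p: np.ndarray

    def validate(self) -> "DurationDistribution":
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(self.p < 0) or abs(self.p.sum() - 1.0) > 1e-12:
            raise ValueError("p must be nonnegative and sum to 1")
        return self


@dataclass
class DistributionPair:
    ipi: DurationDistribution
    iti: DurationDistribution

    def validate(self) -> "DistributionPair":
        if not np.array_equal(self.ipi.bin_edges, self.iti.bin_edges):
            raise ValueError("IPI and ITI distributions must share bin edges")
        self.ipi.validate()
        self.iti.validate()
        return self


def bin_durations(
    durations_s: Sequence[float],
    bin_width_ms: float = 10.0,
    range_ms: tuple[float, float] = (0.0, 2000.0),
) -> DurationDistribution:
    """Normalized histogram of durations (seconds in, millisecond bins out)."""
    d = np.asarray(durations_s, dtype=float) * 1000.0
    if d.size == 0:
        raise ValueError("durations must be nonempty")
    lo, hi = range_ms
    edges = np.arange(lo, hi + bin_width_ms / 2, bin_width_ms)
    counts, _ = np.histogram(np.clip(d, lo, hi), bins=edges)
    return DurationDistribution(bin_edges=edges, p=counts / counts.sum()).validate()


def _kld_terms(p: np.ndarray, m: np.ndarray) -> float:
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / m[mask])))


def jsd(pair: DistributionPair) -> float:
    """Jensen-Shannon divergence of an IPI/ITI distribution pair, in nats."""
    pair.validate()
    p, q = pair.ipi.p, pair.iti.p
    m = 0.5 * (p + q)
    return 0.5 * _kld_terms(p, m) + 0.5 * _kld_terms(q, m)


def ipi_iti_jsd(
    trials: Sequence[Trial],
    bin_width_ms: float = 10.0,
    range_ms: tuple[float, float] = (0.0, 2000.0),
) -> float:
    """JSD between an animal's IPI and ITI distributions over given trials."""
    ipis = [t.ipi for t in trials]
    itis = [t.preceding_iti for t in trials if t.preceding_iti is not None]
    if not itis:
        raise ValueError("no defined ITIs (no trial follows an unsuccessful one)")
    pair = DistributionPair(
        ipi=bin_durations(ipis, bin_width_ms, range_ms),
        iti=bin_durations(itis, bin_width_ms, range_ms),
    )
    return jsd(pair)


def interval_heatmap(
    trials: Sequence[Trial],
    which: str = "ipi",
    trial_window: int = 100,
    bin_width_ms: float = 10.0,
    range_ms: tuple[float, float] = (0.0, 2000.0),
    stride: int = 1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Training heatmap: per-trial-window duration distributions over time.

    Returns ``(matrix, column_trial_index, bin_edges)`` where each column of
    ``matrix`` (bins x windows) is the normalized distribution of the chosen
    interval over the trailing ``trial_window`` trials.  Columns whose window
    contains no defined interval (possible for ITIs) are left at zero.
    """
    if which not in ("ipi", "iti"):
        raise ValueError("which must be 'ipi' or 'iti'")
    if not trials:
        raise ValueError("trials must be nonempty")
    if which == "ipi":
        durs = np.array([t.ipi for t in trials]) * 1000.0
    else:
        durs = np.array(
            [np.nan if t.preceding_iti is None else t.preceding_iti for t in trials]
        ) * 1000.0
    lo, hi = range_ms
    edges = np.arange(lo, hi + bin_width_ms / 2, bin_width_ms)
    n = len(durs)
    ends = np.arange(trial_window - 1, n, stride)
    matrix = np.zeros((len(edges) - 1, len(ends)))
    clamped = np.clip(durs, lo, hi)
    for j, end in enumerate(ends):
        win = clamped[end - trial_window + 1 : end + 1]
        win = win[np.isfinite(win)]
        if win.size:
            counts, _ = np.histogram(win, bins=edges)
            matrix[:, j] = counts / counts.sum()
    return matrix, ends, edges
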