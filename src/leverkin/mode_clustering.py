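"""Unsupervised identification of sequence modes from task-aligned kinematics.

Rats often solve the timed-press task with more than one stereotyped movement
pattern ("sequence mode").  Modes are recovered by (1) building a 12-channel
feature row per trial -- {position, velocity, acceleration} x {horizontal,
vertical} x {dominant, nondominant} forelimb, from 200 ms before the first
press to 200 ms after the second, with the interpress segment warped to
700 ms and each kinematic feature standardized by its pooled SD; (2) a 2-D
t-SNE embedding of the rows; (3) density-peak clustering on the embedding
(cluster centers are points of anomalously high local density rho times
distance delta to the nearest denser point); and (4) an overclustering
correction that merges clusters whose mean kinematic traces are highly
correlated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import TSNE

from .io_core import LIMBS
from .pose_processing import CleanTrack
from .trajectory_analysis import warp_series

FEATURES = ("position", "velocity", "acceleration")
COMPONENTS = ("horizontal", "vertical")


@dataclass
class FeatureMatrix:
    X: np.ndarray  # trials x (12 * n_time)
    trial_indices: np.ndarray
    channels: list[tuple[str, str, str]]  # (limb, component, feature)
    n_time: int
    feature_sds: dict[str, float]


@dataclass
class Embedding:
    coords: np.ndarray  # trials x 2
    trial_indices: np.ndarray


@dataclass
class DensityPeakResult:
    labels: np.ndarray
    centers: np.ndarray  # point indices of cluster centers
    rho: np.ndarray
    delta: np.ndarray
    gamma: np.ndarray
    d_c: float


@dataclass
class ModeAssignment:
    trial_indices: np.ndarray
    labels: np.ndarray  # final mode label per trial
    embedding: np.ndarray | None
    centers: np.ndarray
    merge_map: dict[int, int]  # raw cluster -> final mode
    dominant_mode: int


def build_feature_matrix(
    tracks: Sequence[CleanTrack],
    trials: Sequence,
    max_ipi_s: float = 1.2,
) -> FeatureMatrix:
    """Warped, standardized kinematic feature rows for clusterable trials.

    Includes every trial with two presses within ``max_ipi_s`` (rewarded or
    not) whose track was not discarded.  Velocity and acceleration are
    computed by finite differences at the native frame rate *before* warping
    (central differences, one-sided at the ends); each feature is then divided
    by its SD pooled across trials, time, components, and limbs.
    """
    trial_by_index = {t.index: t for t in trials}
    channels = [
        (limb, comp, feat) for limb in LIMBS for comp in COMPONENTS for feat in FEATURES
    ]
    rows = []
    kept = []
    n_time = None
    for track in tracks:
        trial = trial_by_index.get(int(track.trial_id))
        if trial is None or track.discarded or trial.ipi > max_ipi_s:
            continue
        if len(track.press_frames) < 2:
            continue
        p1, p2 = int(track.press_frames[0]), int(track.press_frames[-1])
        dt = 1.0 / track.frame_rate
        chunk = []
        for limb in LIMBS:
            for comp in COMPONENTS:
                series = (
                    track.limbs[limb].x if comp == "horizontal" else -track.limbs[limb].y
                )
                vel = np.gradient(series, dt)
                acc = np.gradient(vel, dt)
                for values in (series, vel, acc):
                    chunk.append(warp_series(values, p1, p2, fs=track.frame_rate))
        row = np.concatenate(chunk)
        if n_time is None:
            n_time = len(chunk[0])
        rows.append(row)
        kept.append(int(track.trial_id))
    if not rows:
        raise ValueError("no trials eligible for the feature matrix")
    X = np.vstack(rows)
    feature_sds = {}
    for fi, feat in enumerate(FEATURES):
        cols = np.concatenate(
            [
                np.arange(ci * n_time, (ci + 1) * n_time)
                for ci, ch in enumerate(channels)
                if ch[2] == feat
            ]
        )
        sd = float(X[:, cols].std())
        feature_sds[feat] = sd
        if sd > 0:
            X[:, cols] /= sd
    return FeatureMatrix(
        X=X,
        trial_indices=np.asarray(kept),
        channels=channels,
        n_time=n_time,
        feature_sds=feature_sds,
    )


def embed_2d(features: FeatureMatrix, perplexity: float = 30.0, seed: int = 0) -> Embedding:
    """Deterministic 2-D t-SNE embedding of the feature rows."""
    n = features.X.shape[0]
    if n < 3 * perplexity:
        raise ValueError(
            f"{n} trials is too few for perplexity {perplexity}; "
            "use a smaller perplexity"
        )
    coords = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        init="pca",
    ).fit_transform(features.X)
    return Embedding(coords=np.asarray(coords, dtype=float), trial_indices=features.trial_indices)


def density_peak_cluster(
    points: np.ndarray,
    d_c: float | None = None,
    center_rule: int | str = "auto",
) -> DensityPeakResult:
    """Decision-graph density-peak clustering.

    Per point: rho = number of other points within ``d_c`` (default: the 2nd
    percentile of pairwise distances) and delta = distance to the nearest
    point of higher density (the globally densest point takes its largest
    distance).  Centers are the points with the top gamma = rho * delta (both
    normalized); ``center_rule='auto'`` takes the largest gap in the sorted
    gamma sequence, an integer fixes the number of centers.  Remaining points
    inherit, in decreasing density order, the label of their nearest
    higher-density neighbor.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n < 2:
        raise ValueError("need at least 2 points")
    dists = pdist(points)
    D = squareform(dists)
    if not np.any(dists > 0):  # degenerate: all points identical
        return DensityPeakResult(
            labels=np.zeros(n, dtype=int),
            centers=np.array([0]),
            rho=np.full(n, n - 1.0),
            delta=np.zeros(n),
            gamma=np.zeros(n),
            d_c=0.0,
        )
    if d_c is None:
        d_c = float(np.percentile(dists, 2))
        if d_c <= 0:
            d_c = float(dists[dists > 0].min())
    rho = (D < d_c).sum(axis=1) - 1.0
    order = np.lexsort((np.arange(n), -rho))  # decreasing rho, ties by index
    delta = np.empty(n)
    nearest_higher = np.full(n, -1, dtype=int)
    for rank in range(n):
        i = order[rank]
        if rank == 0:
            delta[i] = D[i].max()
        else:
            prev = order[:rank]
            j = prev[np.argmin(D[i, prev])]
            delta[i] = D[i, j]
            nearest_higher[i] = j
    gamma = (rho / max(rho.max(), 1.0)) * (delta / delta.max())
    by_gamma = np.lexsort((np.arange(n), -gamma))
    if center_rule == "auto":
        gs = gamma[by_gamma]
        m = min(n - 1, 32)
        gaps = gs[:m] - gs[1 : m + 1]
        k = int(np.argmax(gaps)) + 1
    else:
        k = int(center_rule)
        if not 1 <= k <= n:
            raise ValueError("center_rule must select between 1 and n centers")
    centers = by_gamma[:k]
    labels = np.full(n, -1, dtype=int)
    for ci, c in enumerate(centers):
        labels[c] = ci
    for rank in range(n):
        i = order[rank]
        if labels[i] < 0:
            labels[i] = labels[nearest_higher[i]]
    return DensityPeakResult(
        labels=labels, centers=centers, rho=rho, delta=delta, gamma=gamma, d_c=float(d_c)
    )


def _mean_trace_corr(a: np.ndarray, b: np.ndarray, n_time: int) -> float:
    """Similarity of two mean feature traces: per-channel Pearson correlation
    (each channel centered, so coordinate offsets common to all trials do not
    inflate it), averaged over channels."""
    rs = []
    for start in range(0, len(a), n_time):
        ca = a[start : start + n_time]
        cb = b[start : start + n_time]
        ca = ca - ca.mean()
        cb = cb - cb.mean()
        if ca.std() == 0 or cb.std() == 0:
            continue
        rs.append(float(np.corrcoef(ca, cb)[0, 1]))
    return float(np.mean(rs)) if rs else 0.0


def merge_clusters(
    raw_labels: np.ndarray,
    features: FeatureMatrix,
    merge_r: float = 0.8,
    embedding: np.ndarray | None = None,
    centers: np.ndarray | None = None,
) -> ModeAssignment:
    """Correct density-peak overclustering by merging similar clusters.

    Iteratively merges the cluster pair with the highest Pearson correlation
    between their mean feature traces while that correlation exceeds
    ``merge_r``, recomputing means after each merge.  Final modes are
    relabeled 0..K-1 by decreasing trial count (ties to the lower raw id);
    ``dominant_mode`` is mode 0's label, the most common mode.
    """
    raw_labels = np.asarray(raw_labels, dtype=int)
    groups: dict[int, list[int]] = {}
    for idx, lab in enumerate(raw_labels):
        groups.setdefault(int(lab), []).append(idx)
    parents = {lab: lab for lab in groups}
    while len(groups) > 1:
        labs = sorted(groups)
        means = {lab: features.X[groups[lab]].mean(axis=0) for lab in labs}
        best, best_r = None, -np.inf
        for ai in range(len(labs)):
            for bi in range(ai + 1, len(labs)):
                r = _mean_trace_corr(means[labs[ai]], means[labs[bi]], features.n_time)
                if r > best_r:
                    best_r, best = r, (labs[ai], labs[bi])
        if best_r <= merge_r:
            break
        keep, drop = best
        groups[keep].extend(groups.pop(drop))
        for lab, parent in parents.items():
            if parent == drop:
                parents[lab] = keep
    final_order = sorted(groups, key=lambda lab: (-len(groups[lab]), lab))
    final_id = {lab: i for i, lab in enumerate(final_order)}
    merge_map = {lab: final_id[parent] for lab, parent in parents.items()}
    labels = np.array([merge_map[int(lab)] for lab in raw_labels])
    return ModeAssignment(
        trial_indices=features.trial_indices,
        labels=labels,
        embedding=embedding,
        centers=centers if centers is not None else np.array([], dtype=int),
        merge_map=merge_map,
        dominant_mode=0,
    )


def identify_modes(
    features: FeatureMatrix,
    perplexity: float = 30.0,
    seed: int = 0,
    d_c: float | None = None,
    center_rule: int | str = "auto",
    merge_r: float = 0.8,
) -> ModeAssignment:
    """Full mode-identification pipeline: embed, cluster, merge."""
    emb = embed_2d(features, perplexity=perplexity, seed=seed)
    dp = density_peak_cluster(emb.coords, d_c=d_c, center_rule=center_rule)
    return merge_clusters(
        dp.labels, features, merge_r=merge_r, embedding=emb.coords, centers=dp.centers
    )
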