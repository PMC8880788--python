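"""Trial subselection, press-preserving time warping, and stereotypy measures."""

import numpy as np
import pytest
from scipy.stats import pearsonr

from leverkin.io_core import Event, EventLog
from leverkin.mode_clustering import ModeAssignment
from leverkin.pose_processing import as_clean
from leverkin.synthetic_data import ModeTemplate, default_templates, synthesize_trajectories
from leverkin.trajectory_analysis import (
    CorrelationMatrix,
    WarpError,
    condition_summary,
    pairwise_correlations,
    press_aligned_correlations,
    press_snippets,
    select_stereotypy_trials,
    time_warp_trial,
)
from leverkin.trial_metrics import segment_trials, trials_from_ipis


def log_from_ipis(ipis, rewarded=None, animal_id="a"):
    events, t = [], 0.0
    for i, ipi in enumerate(ipis):
        rew = True if rewarded is None else rewarded[i]
        events += [Event(t, "press"), Event(t + ipi, "press")]
        if rew:
            events.append(Event(t + ipi + 0.01, "reward", 5))
        t += ipi + 3.0
    return EventLog(animal_id, events).validate()


def warped_set(ipis, template, seed=0, noise_sd=0.0, **warp_kw):
    log = log_from_ipis(ipis)
    tracks, _ = synthesize_trajectories(log, [template], noise_sd=noise_sd, seed=seed)
    return [time_warp_trial(as_clean(tr), **warp_kw) for tr in tracks]


class TestSelection:
    def test_alternating_log_selects_every_rewarded_trial(self):
        trials = trials_from_ipis([0.7] * 20, rewarded=[False, True] * 10)
        sel = select_stereotypy_trials(trials)
        assert list(sel) == list(range(1, 20, 2))

    def test_all_rewarded_selects_nothing(self):
        trials = trials_from_ipis([0.7] * 10, rewarded=[True] * 10)
        with pytest.warns(UserWarning):
            sel = select_stereotypy_trials(trials)
        assert len(sel) == 0

    def test_dominant_mode_filter(self):
        n = 100
        trials = trials_from_ipis([0.7] * n, rewarded=[False, True] * (n // 2))
        rng = np.random.default_rng(0)
        labels = (rng.random(n) < 0.3).astype(int)  # ~70/30 split, mode 0 dominant
        modes = ModeAssignment(
            trial_indices=np.arange(n),
            labels=labels,
            embedding=None,
            centers=np.array([]),
            merge_map={0: 0, 1: 1},
            dominant_mode=0,
        )
        sel = select_stereotypy_trials(trials, modes=modes)
        assert len(sel) > 0
        assert np.all(labels[sel] == 0)
        assert np.all(sel % 2 == 1)  # still only rewarded-after-unrewarded

    def test_ipi_band_filter(self):
        ipis = [0.60, 0.70, 0.71, 0.69, 0.95] * 4
        trials = trials_from_ipis(ipis, rewarded=[False, True] * 10)
        wide = select_stereotypy_trials(trials, ipi_band_ms=200.0)
        narrow = select_stereotypy_trials(trials, ipi_band_ms=30.0)
        assert set(narrow) <= set(wide)
        assert len(narrow) < len(wide)


class TestTimeWarp:
    def test_identity_for_target_ipi(self):
        tmpl = default_templates(1, seed=4)[0]
        log = log_from_ipis([0.7])
        (track,), _ = synthesize_trajectories(log, [tmpl], noise_sd=0.0)
        warped = time_warp_trial(as_clean(track))
        p1, p2 = track.press_frames
        for limb in track.limbs:
            np.testing.assert_array_equal(
                warped.vertical[limb], -track.limbs[limb].y[p1 - 6 : p2 + 7]
            )

    def test_guard_samples_bit_identical(self):
        tmpl = default_templates(1, seed=4)[0]
        log = log_from_ipis([0.9])
        (track,), _ = synthesize_trajectories(log, [tmpl], noise_sd=1.0, seed=1)
        warped = time_warp_trial(as_clean(track))
        p1, p2 = track.press_frames
        c, g, T = 6, 3, 21
        v = -track.limbs["dominant"].y
        out = warped.vertical["dominant"]
        np.testing.assert_array_equal(out[: c + g + 1], v[p1 - c : p1 + g + 1])
        np.testing.assert_array_equal(out[c + T - g :], v[p2 - g : p2 + c + 1])
        assert warped.press_indices == (c, c + T)

    def test_same_template_different_ipis_correlate_at_one(self):
        """Warping removes IPI differences: noise-free trials from one template
        with IPIs 600 and 800 ms correlate at 1 to within 1e-6."""
        tmpl = default_templates(1, seed=3)[0]
        warped = warped_set([0.6, 0.8], tmpl)
        cm = pairwise_correlations(warped)
        assert cm.matrix[0, 1] == pytest.approx(1.0, abs=1e-6)

    def test_ipi_below_guard_width_rejected(self):
        tmpl = default_templates(1, seed=0)[0]
        log = log_from_ipis([0.7])
        tracks, _ = synthesize_trajectories(log, [tmpl], noise_sd=0.0)
        track = as_clean(tracks[0])
        track.press_frames = np.array([12, 17])  # 5 frames < 2 * 3-frame guard
        with pytest.raises(WarpError):
            time_warp_trial(track)

    def test_max_amplitude_normalization(self):
        tmpl = default_templates(1, seed=5)[0]
        (w,) = warped_set([0.75], tmpl, normalize="max_amplitude")
        for v in w.vertical.values():
            assert v[0] == 0.0
            assert np.max(np.abs(v)) == pytest.approx(1.0)


class TestCorrelations:
    def test_matrix_matches_double_loop_oracle(self):
        tmpl = default_templates(1, seed=6)[0]
        warped = warped_set([0.6, 0.65, 0.7, 0.75, 0.8, 0.85, 0.9, 0.62, 0.72, 0.82], tmpl, noise_sd=3.0, seed=2)
        cm = pairwise_correlations(warped)
        n = len(warped)
        for i in range(n):
            for j in range(n):
                rs = [
                    pearsonr(warped[i].vertical[limb], warped[j].vertical[limb])[0]
                    for limb in ("dominant", "nondominant")
                ]
                assert cm.matrix[i, j] == pytest.approx(np.mean(rs), abs=1e-12)

    def test_self_and_negation(self):
        tmpl = default_templates(1, seed=1)[0]
        (w,) = warped_set([0.7], tmpl, noise_sd=1.0, seed=0)
        neg = type(w)(
            vertical={k: -v for k, v in w.vertical.items()},
            press_indices=w.press_indices,
            trial_index=1,
        )
        cm = pairwise_correlations([w, neg])
        assert cm.matrix[0, 0] == 1.0
        assert cm.matrix[0, 1] == pytest.approx(-1.0)

    def test_zero_variance_pair_flagged_nan(self):
        tmpl = default_templates(1, seed=1)[0]
        (w,) = warped_set([0.7], tmpl, noise_sd=0.0)
        flat = type(w)(
            vertical={k: np.zeros_like(v) for k, v in w.vertical.items()},
            press_indices=w.press_indices,
            trial_index=1,
        )
        cm = pairwise_correlations([w, flat])
        assert np.isnan(cm.matrix[0, 1])


class TestConditionSummary:
    def _warped(self, ipis, template, cond, animal, seed=0, noise_sd=1.0):
        log = log_from_ipis(ipis)
        tracks, _ = synthesize_trajectories(log, [template], noise_sd=noise_sd, seed=seed)
        return [
            time_warp_trial(as_clean(t), condition=cond, animal_id=animal)
            for t in tracks
        ]

    def test_identical_trials_all_ones(self):
        tmpl = default_templates(1, seed=2)[0]
        warped = self._warped([0.7] * 4, tmpl, "pre", "r1", noise_sd=0.0)
        cm = pairwise_correlations(warped)
        summary = condition_summary(cm, "within_animal")
        assert summary[("pre", "pre")] == pytest.approx(1.0)

    def test_planted_pre_post_contrast(self):
        """Pre trials from template A, post from template B: within-condition
        stereotypy exceeds the cross-condition correlation."""
        ta, tb = default_templates(2, seed=9)
        warped = self._warped([0.65, 0.7, 0.75, 0.7] * 2, ta, "pre", "r1", seed=1) + \
            self._warped([0.68, 0.72, 0.7, 0.74] * 2, tb, "post", "r1", seed=2)
        summary = condition_summary(pairwise_correlations(warped), "within_animal")
        assert summary[("pre", "pre")] > summary[("post", "pre")]
        assert summary[("post", "post")] > summary[("post", "pre")]

    def test_trial_order_permutation_invariant(self):
        ta, tb = default_templates(2, seed=10)
        warped = self._warped([0.7, 0.8, 0.75], ta, "pre", "r1", seed=3) + \
            self._warped([0.7, 0.66], tb, "post", "r1", seed=4)
        base = condition_summary(pairwise_correlations(warped), "within_animal")
        rng = np.random.default_rng(0)
        perm = list(rng.permutation(len(warped)))
        shuffled = condition_summary(
            pairwise_correlations([warped[i] for i in perm]), "within_animal"
        )
        for key, val in base.items():
            assert shuffled[key] == pytest.approx(val, abs=1e-12)

    def test_across_animal_scheme(self):
        tmpl = default_templates(1, seed=11)[0]
        warped = self._warped([0.7, 0.75], tmpl, "pre", "r1", seed=5) + \
            self._warped([0.7, 0.72], tmpl, "pre", "r2", seed=6)
        within = condition_summary(pairwise_correlations(warped), "within_animal")
        across = condition_summary(pairwise_correlations(warped), "across_animal")
        # same template everywhere: both schemes see high correlations
        assert within[("pre", "pre")] > 0.9
        assert across[("pre", "pre")] > 0.9


class TestPressAligned:
    def test_identical_snippets_correlate_at_one(self):
        # dip-only template: every press snippet has the same shape
        tmpl = default_templates(simple=True)[0]
        log = log_from_ipis([0.7, 0.7])
        tracks, _ = synthesize_trajectories(log, [tmpl], noise_sd=0.0)
        clean = [(as_clean(t), "r1") for t in tracks]
        out = press_aligned_correlations({"pre": clean})
        assert out[("pre", "pre")] == pytest.approx(1.0, abs=1e-9)

    def test_snippet_length_and_edge_drop(self):
        tmpl = default_templates(1, seed=0)[0]
        log = log_from_ipis([0.7])
        (track,), _ = synthesize_trajectories(log, [tmpl], noise_sd=0.0)
        snips = press_snippets(as_clean(track), "r1")
        assert len(snips) == 2  # both presses have full context
        assert all(len(s) == 9 for _, s in snips)  # frames within +/-150 ms at 30 Hz

    def test_regressed_cohort_shares_press_template(self):
        """Animals that regressed to the shared simple press pattern: post-post
        across-animal press correlations match early-early and both exceed
        the pre-post correlation with the idiosyncratic learned presses."""
        simple = default_templates(simple=True)[0]
        idio = [
            ModeTemplate(
                bumps=default_templates(1, seed=s)[0].bumps, press_dip=(35.0, 0.045)
            )
            for s in (21, 22)
        ]
        conditions = {"early": [], "pre": [], "post": []}
        for ai, animal in enumerate(["r1", "r2"]):
            for ci, (cond, tmpl) in enumerate(
                (("early", simple), ("pre", idio[ai]), ("post", simple))
            ):
                log = log_from_ipis([0.68, 0.7, 0.73])
                tracks, _ = synthesize_trajectories(
                    log, [tmpl], noise_sd=0.5, seed=ai * 10 + ci
                )
                conditions[cond] += [(as_clean(t), animal) for t in tracks]
        out = press_aligned_correlations(conditions)
        assert out[("post", "post")] == pytest.approx(out[("early", "early")], abs=0.1)
        assert out[("post", "post")] > out[("post", "pre")]
        assert out[("early", "early")] > out[("post", "pre")]
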