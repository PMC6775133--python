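"""Template matching: smoothing, z-scoring, epoching, templates,
winner-takes-all, stratified cross-validation and accuracy significance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from artidec import (GridLayout, HfbEnvelope, TrialTensor,
                     accuracy_significance, build_templates, classify_trial,
                     crossvalidate, loocv, moving_average, smooth_zscore_epoch,
                     stratified_folds)
from artidec.classify import loocv_accuracy
from artidec.sim import EventTable, permute_movement_labels

from conftest import make_tensor


def white_envelope(rng, trials_per_class=8, rest=8, n_classes=4, n_ch=6,
                   fs=50.0, cue_s=1.5, trial_s=3.0, signal=0.0):
    """Small white-noise envelope with a cued trial design; optional
    class-dependent mean shift on the first electrodes."""
    labels = np.array(
        [f"class_{i + 1}" for i in range(n_classes)
         for _ in range(trials_per_class)] + ["rest"] * rest, dtype=object)
    labels = labels[rng.permutation(len(labels))]
    step = int(trial_s * fs)
    onsets = int(fs) + np.arange(len(labels)) * step
    n = int(onsets[-1] + step + 2 * fs)
    power = rng.standard_normal((n_ch, n))
    cue = int(cue_s * fs)
    if signal:
        for i, lab in enumerate(labels):
            if lab == "rest":
                continue
            ch = int(lab.split("_")[1]) - 1
            power[ch % n_ch, onsets[i]:onsets[i] + cue] += signal
    events = EventTable(onsets, np.full(len(labels), cue), labels)
    return HfbEnvelope(power, fs, GridLayout(1, n_ch, 4.0), events)


class TestMovingAverage:
    def test_impulse_gives_plateau(self):
        x = np.zeros(64)
        x[32] = 1.0
        w = 9
        out = moving_average(x[None, :], w)[0]
        assert np.all(out[28:37] == pytest.approx(1.0 / w))
        assert out[27] == 0.0 and out[37] == 0.0

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        x=hnp.arrays(np.float64, st.integers(5, 60),
                     elements=st.floats(-100, 100)),
        w=st.integers(1, 12),
    )
    def test_matches_direct_convolution_oracle(self, x, w):
        """Cumulative-sum smoother equals a direct truncated-window mean."""
        out = moving_average(x[None, :], w)[0]
        n = len(x)
        expected = np.empty(n)
        for i in range(n):
            lo = max(i - (w - 1) // 2, 0)
            hi = min(i + w // 2, n - 1) + 1
            expected[i] = x[lo:hi].mean()
        np.testing.assert_allclose(out, expected, atol=1e-9 * max(1, np.abs(x).max()))


class TestSmoothZscoreEpoch:
    def test_zscore_moments(self, hi_snr_pipeline):
        _, _, mask, env = hi_snr_pipeline
        tensor = smooth_zscore_epoch(env, mask.included_indices)
        # recompute the smoothed z-scored series: full-run moments
        w = int(round(0.5 * env.sampling_rate_hz))
        sm = moving_average(env.power[mask.included_indices], w)
        z = (sm - sm.mean(axis=1, keepdims=True)) / sm.std(axis=1, keepdims=True)
        assert np.abs(z.mean(axis=1)).max() < 1e-6
        assert np.abs(z.std(axis=1) - 1).max() < 1e-6
        # tensor rows are slices of that series
        ev = env.events
        first_mov = np.flatnonzero(ev.movement_mask)[0]
        start = int(ev.onset_sample[first_mov])
        np.testing.assert_allclose(
            tensor.data[0], z[:, start:start + tensor.data.shape[2]])

    def test_rest_trials_excluded_and_epoch_length(self, hi_snr_pipeline):
        _, _, mask, env = hi_snr_pipeline
        tensor = smooth_zscore_epoch(env, mask.included_indices)
        assert tensor.data.shape == (80, 16, int(2.0 * env.sampling_rate_hz))
        assert "rest" not in set(tensor.labels)

    def test_constant_envelope_zscores_to_zero(self):
        env = HfbEnvelope(np.full((2, 300), 5.0), 50.0, GridLayout(1, 2, 4.0),
                          EventTable([10, 110], [50, 50],
                                     np.array(["class_1", "class_2"],
                                              dtype=object)))
        tensor = smooth_zscore_epoch(env, epoch_s=1.0)
        np.testing.assert_array_equal(tensor.data, 0.0)

    def test_epoch_past_run_end_raises(self):
        env = HfbEnvelope(np.zeros((2, 200)), 50.0, GridLayout(1, 2, 4.0),
                          EventTable([10, 150], [50, 50],
                                     np.array(["class_1", "class_2"],
                                              dtype=object)))
        with pytest.raises(ValueError, match="past the end"):
            smooth_zscore_epoch(env, epoch_s=2.0)


class TestTemplates:
    def test_hand_computed_spatial_templates(self):
        rng = np.random.default_rng(0)
        tensor = make_tensor(rng, n_per_class=2, n_classes=2, n_electrodes=3,
                             n_times=4)
        templates = build_templates(tensor, np.arange(4), "spatial")
        feats = tensor.data.mean(axis=2)
        for k, cls in enumerate(templates.classes):
            np.testing.assert_allclose(
                templates.templates[k], feats[tensor.labels == cls].mean(axis=0))

    def test_single_training_trial_equals_trial(self):
        rng = np.random.default_rng(1)
        tensor = make_tensor(rng, n_per_class=2, n_classes=2, n_electrodes=3)
        first_of = [np.flatnonzero(tensor.labels == c)[0]
                    for c in tensor.classes]
        templates = build_templates(tensor, np.array(first_of),
                                    "spatiotemporal")
        for k, idx in enumerate(first_of):
            np.testing.assert_allclose(templates.templates[k],
                                       tensor.data[idx])

    def test_missing_class_raises(self):
        rng = np.random.default_rng(2)
        tensor = make_tensor(rng, n_per_class=2, n_classes=2)
        only_one = np.flatnonzero(tensor.labels == "class_1")
        with pytest.raises(ValueError, match="class_2"):
            build_templates(tensor, only_one, "spatial")


class TestWinnerTakesAll:
    def _templates(self):
        rng = np.random.default_rng(3)
        tensor = make_tensor(rng, n_per_class=2, n_classes=4, n_electrodes=3,
                             n_times=2)
        return build_templates(tensor, np.arange(8), "spatial")

    def test_exact_template_match(self):
        templates = self._templates()
        for k, cls in enumerate(templates.classes):
            assert classify_trial(templates.templates[k], templates) == cls

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(scale=st.floats(0.1, 50), offset=st.floats(-20, 20))
    def test_affine_invariance(self, scale, offset):
        templates = self._templates()
        trial = scale * templates.templates[2] + offset
        assert classify_trial(trial, templates) == templates.classes[2]

    def test_hand_computed_correlations(self):
        templates = self._templates()
        rng = np.random.default_rng(4)
        trial = rng.standard_normal(3)
        corrs = [np.corrcoef(trial, t)[0, 1] for t in templates.templates]
        expected = templates.classes[int(np.argmax(corrs))]
        assert classify_trial(trial, templates) == expected

    def test_zero_variance_trial_takes_lowest_class(self):
        templates = self._templates()
        assert classify_trial(np.zeros(3), templates) == "class_1"


class TestFoldsAndCv:
    def test_fold_structure_80_trials(self):
        labels = np.repeat([f"class_{i}" for i in range(1, 5)], 20)
        folds = stratified_folds(labels, 10, seed=0)
        assert len(folds) == 10
        all_idx = np.concatenate(folds)
        assert len(all_idx) == 80 and len(set(all_idx)) == 80
        for fold in folds:
            assert len(fold) == 8
            _, counts = np.unique(labels[fold], return_counts=True)
            assert list(counts) == [2, 2, 2, 2]

    def test_non_divisible_counts_rejected(self):
        labels = np.repeat(["a", "b"], 9)
        with pytest.raises(ValueError, match="not divisible"):
            stratified_folds(labels, 6)

    def test_ceiling_on_high_snr_run(self, hi_snr_pipeline):
        _, _, mask, env = hi_snr_pipeline
        res = crossvalidate(env, mode="spatial", k=10, seed=0,
                            electrodes=mask.included_indices,
                            n_perm_select=200)
        assert res.mean_accuracy == 1.0
        assert res.confusion.trace() == 80
        assert np.allclose(res.confusion.sum(axis=1), 20)

    def test_cv_result_internal_consistency(self, hi_snr_pipeline):
        _, _, mask, env = hi_snr_pipeline
        res = crossvalidate(env, seed=1, electrodes=mask.included_indices,
                            n_perm_select=200)
        assert res.mean_accuracy == pytest.approx(res.fold_accuracies.mean())
        assert res.confusion.sum() == 80
        assert len(res.fold_accuracies) == res.n_folds == 10

    def test_affine_rescaled_envelope_gives_identical_results(
            self, hi_snr_pipeline):
        """Per-electrode affine rescaling of the envelope (gain > 0) cannot
        change selection or accuracy: r² and z-scores absorb it."""
        _, _, mask, env = hi_snr_pipeline
        rng = np.random.default_rng(5)
        gains = rng.uniform(0.5, 3.0, env.n_channels)[:, None]
        offsets = rng.uniform(-10, 10, env.n_channels)[:, None]
        scaled = HfbEnvelope(gains * env.power + offsets,
                             env.sampling_rate_hz, env.layout, env.events)
        a = crossvalidate(env, seed=2, electrodes=mask.included_indices,
                          n_perm_select=200)
        b = crossvalidate(scaled, seed=2, electrodes=mask.included_indices,
                          n_perm_select=200)
        np.testing.assert_array_equal(a.fold_accuracies, b.fold_accuracies)
        assert a.fold_electrodes == b.fold_electrodes

    def test_spatial_equals_spatiotemporal_on_time_constant_data(self):
        """With no within-trial temporal structure the two feature sets are
        the same vector up to repetition, so predictions coincide exactly."""
        rng = np.random.default_rng(6)
        means = 2.0 * np.eye(4, 8)
        tensor = make_tensor(rng, n_per_class=5, class_means=means,
                             n_electrodes=8, n_times=6)
        flat = TrialTensor(np.repeat(tensor.data.mean(axis=2)[:, :, None], 6,
                                     axis=2),
                           tensor.labels, tensor.electrodes,
                           tensor.sampling_rate_hz, 0.5, tensor.epoch_s)
        a = loocv(flat, "spatial")
        b = loocv(flat, "spatiotemporal")
        np.testing.assert_array_equal(a.fold_accuracies, b.fold_accuracies)

    def test_accuracy_monotone_in_snr(self):
        """Mean leave-one-out accuracy is non-decreasing along a 4-point
        effect-size ladder (paired noise; 1 inversion allowed over 5 ladders)."""
        inversions = 0
        for ladder in range(5):
            accs = []
            for effect in (0.0, 0.4, 0.8, 1.6):
                rng = np.random.default_rng(100 + ladder)  # paired noise
                means = effect * np.eye(4, 8)
                tensor = make_tensor(rng, n_per_class=10, class_means=means,
                                     n_electrodes=8, n_times=4)
                accs.append(loocv(tensor, "spatial").mean_accuracy)
            inversions += int(np.any(np.diff(accs) < -1e-12))
        assert inversions <= 1

    def test_loocv_fold_count_and_separable_toy(self):
        rng = np.random.default_rng(7)
        means = 10.0 * np.eye(4, 6)
        tensor = make_tensor(rng, n_per_class=5, class_means=means,
                             n_electrodes=6, n_times=3)
        res = loocv(tensor, "spatial")
        assert res.n_folds == 20
        assert res.mean_accuracy == 1.0

    def test_loocv_consistent_with_kfold(self):
        """Leave-one-out and 10-fold accuracies agree within 5 percentage
        points on a mid-accuracy synthetic envelope."""
        rng = np.random.default_rng(8)
        env = white_envelope(rng, trials_per_class=20, rest=20, signal=0.6)
        cv = crossvalidate(env, k=10, seed=0, select_electrodes=False)
        tensor = smooth_zscore_epoch(env)
        lo = loocv(tensor, "spatial")
        assert 0.3 < cv.mean_accuracy < 1.0  # genuinely mid-range
        assert abs(cv.mean_accuracy - lo.mean_accuracy) <= 0.05


class TestAccuracySignificance:
    def test_strong_signal_floor_p(self):
        """Observed accuracy beats every permutation: p = 1/(n_perm+1)."""
        rng = np.random.default_rng(9)
        env = white_envelope(rng, signal=4.0)
        p, obs, null = accuracy_significance(env, k=4, n_perm=99, seed=0,
                                             select_electrodes=False)
        assert obs.mean_accuracy == 1.0
        assert p == pytest.approx(0.01)

    def test_null_p_uniformish(self):
        """Under the null, permutation p-values spread over (0, 1]."""
        from scipy.stats import kstest
        rng = np.random.default_rng(10)
        ps = []
        for i in range(15):
            env = white_envelope(rng, signal=0.0)
            p, _, _ = accuracy_significance(env, k=4, n_perm=99, seed=i,
                                            select_electrodes=False)
            ps.append(p)
        assert kstest(ps, "uniform").pvalue > 0.05

    def test_n_perm_too_small_rejected(self):
        rng = np.random.default_rng(11)
        env = white_envelope(rng)
        with pytest.raises(ValueError):
            accuracy_significance(env, n_perm=50)


class TestLabelPermutation:
    def test_permutation_preserves_counts(self, hi_snr_pipeline):
        run, _, _, _ = hi_snr_pipeline
        pe = permute_movement_labels(run.events, 3)
        assert sorted(pe.label) == sorted(run.events.label)
        np.testing.assert_array_equal(pe.label == "rest",
                                      run.events.label == "rest")
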