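"""Decoding orchestration: reproducibility, chance calibration, temporal
generalization and split-half/cross-decoding contracts."""

import numpy as np
import pytest

import wmdecode as w
from wmdecode.decode import (
    CvScheme,
    cross_decode,
    decode_features,
    decode_timeavg_all,
    decode_window,
    split_half_decode,
    temporal_generalization,
)
from wmdecode.exceptions import ConfigurationError, PipelineError
from wmdecode.preprocess import PreprocConfig, preprocess_subject

from conftest import gaussian_epochs, make_epochset

CV_FAST = CvScheme(n_iterations=15, seed=3)


def _strong_static_epochs(seed=0, n_per=30, fs_target=100.0, rotate=False):
    """Full-pipeline epochs from a time-invariant strong-signal subject.

    Uses the sustained temporal profile with effectively no delay decay and
    a permissive low filter edge so the plateau survives preprocessing.
    """
    cfg = w.SessionConfig(n_trials_per_category=n_per, fs_raw_hz=2 * fs_target)
    model = w.SignalModel(
        amp_sensory=30.0,
        noise_sd=10.0,
        subject_snr_sd=0.0,
        artifact_rate=0.0,
        temporal_profile="sustained",
        delay_decay_tau_ms=1e9,
        delay_gain=1.0,
        rotate_at_offset=rotate,
    )
    pp = PreprocConfig(fs_target_hz=fs_target, band_hz=(0.02, 40.0), min_trials=0)
    sub = w.synthesize_subject(cfg, model, w.SubjectSpec("s"), seed=seed)
    ep, _, _ = preprocess_subject(sub, pp)
    return ep


class TestDecodeFeatures:
    def test_bit_identical_for_same_seed(self):
        ep = gaussian_epochs(np.random.default_rng(0))
        X = ep.data[:, :, 0]
        a = decode_features(X, ep.labels, CV_FAST)
        b = decode_features(X, ep.labels, CV_FAST)
        assert np.array_equal(a.per_iteration_accuracy, b.per_iteration_accuracy)
        assert a.confusion.equals(b.confusion)

    def test_shuffled_labels_decode_at_chance(self):
        rng = np.random.default_rng(1)
        ep = gaussian_epochs(rng, separation=3.0, n_per_class=60)
        X = ep.data[:, :, 0]
        y = rng.permutation(ep.labels)
        res = decode_features(X, y, CvScheme(n_iterations=30, seed=0))
        assert abs(res.mean_accuracy - 1 / 3) < 0.08

    def test_accuracy_monotone_in_separation(self):
        rng = np.random.default_rng(2)
        means = []
        for sep in (0.2, 0.8, 2.0):
            accs = [
                decode_features(
                    (e := gaussian_epochs(rng, separation=sep)).data[:, :, 0],
                    e.labels,
                    CvScheme(n_iterations=10, seed=r),
                ).mean_accuracy
                for r in range(3)
            ]
            means.append(np.mean(accs))
        assert means[0] < means[1] < means[2]

    def test_null_calibration_over_many_subjects(self):
        """Signal-free feature decoding is centred on 1/3 with no heavy
        upper tail."""
        rng = np.random.default_rng(3)
        means = []
        for _ in range(40):
            ep = gaussian_epochs(rng, separation=0.0, n_per_class=128, n_channels=64)
            means.append(
                decode_features(
                    ep.data[:, :, 0], ep.labels,
                    CvScheme(n_iterations=40, seed=int(rng.integers(2**31))),
                ).mean_accuracy
            )
        means = np.array(means)
        assert abs(means.mean() - 1 / 3) < 0.01
        # tails symmetric around chance (no heavy upper tail) and bounded;
        # with ~24 test pseudo-trials per iteration the per-subject null sd
        # is ~0.04, so individual subjects legitimately range a few sd wide
        upper = np.quantile(means, 0.9) - 1 / 3
        lower = 1 / 3 - np.quantile(means, 0.1)
        assert upper < 1.8 * lower + 0.01
        assert means.max() < 1 / 3 + 3.5 * means.std() + 0.01

    def test_insufficient_trials_error_names_class(self):
        X = np.random.default_rng(0).normal(size=(12, 4))
        y = np.array(["a"] * 6 + ["b"] * 6, dtype=object)
        with pytest.raises(PipelineError, match="'a'"):
            decode_features(X, y, CvScheme(n_iterations=1, group_size=5, seed=0))


class TestDecodeWindows:
    def test_window_names_and_confusion_rows(self):
        ep = gaussian_epochs(np.random.default_rng(4), separation=2.0)
        res = decode_timeavg_all(ep, CV_FAST)
        assert set(res) == {"Baseline", "Sensory", "Delay"}
        for r in res.values():
            assert np.allclose(r.confusion.sum(axis=1), 1.0, atol=1e-9)
            assert r.mean_accuracy == pytest.approx(r.per_iteration_accuracy.mean())

    def test_full_pipeline_zero_amplitude_all_windows_at_chance(self, fast_cfg, fast_pp):
        model = w.SignalModel(amp_sensory=0.0, artifact_rate=0.0)
        sub = w.synthesize_subject(fast_cfg, model, w.SubjectSpec("s"), seed=5)
        ep, _, _ = preprocess_subject(sub, fast_pp)
        res = decode_timeavg_all(ep, CvScheme(n_iterations=20, seed=0))
        for r in res.values():
            assert abs(r.mean_accuracy - 1 / 3) < 0.12

    def test_full_pipeline_strong_signal_ordering(self, fast_pp):
        cfg = w.SessionConfig(n_trials_per_category=45, fs_raw_hz=125.0)
        model = w.SignalModel(amp_sensory=30.0, subject_snr_sd=0.0, artifact_rate=0.0)
        sub = w.synthesize_subject(cfg, model, w.SubjectSpec("s"), seed=6)
        ep, _, _ = preprocess_subject(sub, fast_pp)
        res = decode_timeavg_all(ep, CvScheme(n_iterations=25, seed=0))
        assert res["Sensory"].mean_accuracy > 0.6
        assert res["Delay"].mean_accuracy > 0.45
        assert res["Sensory"].mean_accuracy > res["Delay"].mean_accuracy
        assert res["Baseline"].mean_accuracy < 0.45


class TestTemporalGeneralization:
    def test_static_pattern_generalizes_everywhere(self):
        ep = _strong_static_epochs(seed=7)
        gm = temporal_generalization(ep, 100.0, CvScheme(n_iterations=10, seed=0))
        post = gm.times_ms > 100.0  # fully post-onset bins
        block = gm.accuracy[np.ix_(post, post)]
        diag = np.diag(block)
        off = block[~np.eye(len(block), dtype=bool)]
        assert diag.mean() > 0.9
        assert abs(off.mean() - diag.mean()) < 0.05

    def test_rotating_pattern_blocks(self):
        ep = _strong_static_epochs(seed=8, rotate=True)
        gm = temporal_generalization(ep, 100.0, CvScheme(n_iterations=10, seed=0))
        sens = (gm.times_ms > 100) & (gm.times_ms < 950)
        delay = gm.times_ms > 1100
        within_sens = gm.accuracy[np.ix_(sens, sens)].mean()
        within_delay = gm.accuracy[np.ix_(delay, delay)].mean()
        cross = gm.accuracy[np.ix_(sens, delay)].mean()
        assert within_sens > 0.85 and within_delay > 0.85
        # no above-chance transfer across the rotation
        assert cross <= 1 / 3 + 0.08

    def test_diagonal_matches_independent_per_bin_decoding(self):
        ep = _strong_static_epochs(seed=9)
        cv = CvScheme(n_iterations=10, seed=1)
        gm = temporal_generalization(ep, 300.0, cv)
        curve = []
        for k, c in enumerate(gm.times_ms):
            lo = ep.times_ms[0] + k * 300.0
            curve.append(decode_window(ep, (lo, lo + 300.0), cv).mean_accuracy)
        r = np.corrcoef(np.diag(gm.accuracy), curve)[0, 1]
        assert r > 0.9

    def test_fine_and_coarse_bins_agree_after_block_averaging(self):
        ep = _strong_static_epochs(seed=10)
        cv = CvScheme(n_iterations=16, seed=2)
        gm20 = temporal_generalization(ep, 20.0, cv)
        gm50 = temporal_generalization(ep, 50.0, cv)

        def to_blocks(gm, width):
            f = int(round(100.0 / width))
            n = (gm.accuracy.shape[0] // f) * f
            a = gm.accuracy[:n, :n]
            return a.reshape(n // f, f, n // f, f).mean(axis=(1, 3))

        b20, b50 = to_blocks(gm20, 20.0), to_blocks(gm50, 50.0)
        n = min(b20.shape[0], b50.shape[0])
        assert np.abs(b20[:n, :n] - b50[:n, :n]).max() < 0.05 + 1e-9

    def test_bin_width_must_fit_sample_grid(self):
        ep = gaussian_epochs(np.random.default_rng(5), fs_hz=10.0)
        with pytest.raises(ConfigurationError):
            temporal_generalization(ep, 70.0, CV_FAST)  # 0.7 samples per bin


class TestSplitHalfAndCross:
    def test_halves_have_expected_sizes_and_match_stationary_accuracy(self):
        rng = np.random.default_rng(6)
        ep = gaussian_epochs(rng, n_per_class=60, separation=1.2)
        halves = split_half_decode(ep, CvScheme(n_iterations=15, seed=0))
        early, late = halves["early"], halves["late"]
        n_early = (ep.trial_meta.block <= 4).sum()
        assert n_early == len(ep.labels) // 2
        a_e = early["Sensory"].per_iteration_accuracy
        a_l = late["Sensory"].per_iteration_accuracy
        pooled_se = np.sqrt(a_e.var(ddof=1) / len(a_e) + a_l.var(ddof=1) / len(a_l))
        assert abs(a_e.mean() - a_l.mean()) < 3 * pooled_se + 0.05

    def test_planted_nonstationarity_detected(self):
        rng = np.random.default_rng(7)
        ep = gaussian_epochs(rng, n_per_class=60, separation=2.5)
        late = ep.trial_meta.block.to_numpy() > 4
        data = ep.data.copy()
        noise = rng.standard_normal(data[late].shape).astype(np.float32)
        data[late] = noise  # late half: signal replaced by noise
        ep2 = make_epochset(data, fs_hz=ep.fs_hz, labels=ep.labels,
                            blocks=ep.trial_meta.block.to_numpy())
        halves = split_half_decode(ep2, CvScheme(n_iterations=15, seed=1))
        assert halves["early"]["Sensory"].mean_accuracy > 0.6
        assert abs(halves["late"]["Sensory"].mean_accuracy - 1 / 3) < 0.12

    def test_missing_block_metadata_errors(self):
        ep = gaussian_epochs(np.random.default_rng(8))
        ep.trial_meta = ep.trial_meta.drop(columns=["block"])
        with pytest.raises(ConfigurationError, match="block"):
            split_half_decode(ep, CV_FAST)

    def test_cross_decoding_identical_data_matches_within(self):
        rng = np.random.default_rng(9)
        ep = gaussian_epochs(rng, n_per_class=45, separation=1.5)
        cross = cross_decode(ep, ep, CvScheme(n_iterations=15, seed=0))
        within = decode_timeavg_all(ep, CvScheme(n_iterations=15, seed=0))
        assert abs(cross["Sensory"].mean_accuracy - within["Sensory"].mean_accuracy) < 0.1

    def test_cross_decoding_independent_patterns_at_chance(self):
        """Training and test sets with independently drawn class topographies
        cross-decode at chance on average over pattern draws."""
        rng = np.random.default_rng(10)
        accs = []
        for _ in range(12):
            ep_a = gaussian_epochs(rng, n_per_class=30, separation=0.5)
            ep_b = gaussian_epochs(rng, n_per_class=30, separation=0.5)
            cross = cross_decode(ep_a, ep_b, CvScheme(n_iterations=5, seed=0))
            accs.append(cross["Sensory"].mean_accuracy)
        # single draws scatter widely with the pattern geometry; the mean
        # over independent pattern draws sits at chance
        assert abs(np.mean(accs) - 1 / 3) < 0.09

    def test_montage_mismatch_errors(self):
        rng = np.random.default_rng(11)
        ep_a = gaussian_epochs(rng, n_channels=8)
        ep_b = gaussian_epochs(rng, n_channels=16)
        with pytest.raises(ConfigurationError, match="montage"):
            cross_decode(ep_a, ep_b, CV_FAST)
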