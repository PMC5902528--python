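import numpy as np
import pytest

import eegpipe as e
from eegpipe import artifact_detection as ad
from eegpipe import preprocessing_ops as po
from eegpipe.recording_io import Channel, Recording


def _noise_rec(n_ch=32, n_samp=5120, seed=0, scale=None):
    rng = np.random.default_rng(seed)
    signals = rng.standard_normal((n_ch, n_samp))
    if scale is not None:
        signals *= np.asarray(scale)[:, None]
    chans = [Channel(f"c{i:02d}", None, "eeg") for i in range(n_ch)]
    return Recording(signals=signals, fs=256.0, channels=chans, measurement_id="noise")


class TestBlinkEvents:
    def test_recall_and_precision_on_injected_blinks(self):
        spec = e.GeneratorSpec(duration_s=150.0, n_trials=60, n_blinks=30)
        rec, truth = e.generate_recording(spec, seed=11)
        rec2, det = ad.detect_blink_events(rec, ["VEOG"])
        found = ad.blink_latencies(rec2)
        tol = int(0.05 * rec.fs)
        hit = [t for t in truth.blink_latencies if any(abs(f - t) <= tol for f in found)]
        matched = [f for f in found if any(abs(f - t) <= tol for t in truth.blink_latencies)]
        assert len(hit) / len(truth.blink_latencies) >= 0.9
        assert len(matched) / max(1, len(found)) >= 0.9

    def test_flat_veog_finds_nothing(self):
        rec = _noise_rec(n_ch=2)
        rec.channels[1] = Channel("VEOG", None, "eog")
        rec.signals[1] = 0.0
        rec2, det = ad.detect_blink_events(rec, ["VEOG"])
        assert det.n_flagged == 0

    def test_threshold_is_scale_invariant(self, clean_oddball):
        rec, _ = clean_oddball
        doubled = rec.copy()
        doubled.signals = doubled.signals * 2.0
        a = ad.detect_blink_events(rec, ["VEOG"])[1]
        b = ad.detect_blink_events(doubled, ["VEOG"])[1]
        assert a.flagged == b.flagged

    def test_missing_veog_channel(self, clean_oddball):
        rec, _ = clean_oddball
        with pytest.raises(KeyError):
            ad.detect_blink_events(rec, ["NOPE"])

    def test_input_events_not_mutated(self, clean_oddball):
        rec, _ = clean_oddball
        n_before = len(rec.events)
        rec2, _ = ad.detect_blink_events(rec, ["VEOG"])
        assert len(rec.events) == n_before
        assert len(rec2.events) > n_before


class TestBlinkTemplate:
    def test_average_of_identical_blinks_equals_one_blink(self):
        # noiseless VEOG with identical injected deflections
        fs = 256.0
        n = 256 * 30
        v = np.zeros(n)
        lats = [1000, 3000, 5000, 7000]
        w = np.arange(-40, 41)
        shape = 100.0 * np.exp(-0.5 * (w / 12.0) ** 2)
        for lat in lats:
            v[lat + w] += shape
        rec = Recording(
            signals=v[None, :],
            fs=fs,
            channels=[Channel("VEOG", None, "eog")],
            events=[e.Event(lat, "blink") for lat in lats],
        )
        tmpl = ad.build_blink_template(rec, ["VEOG"])
        lo = int(round(-0.3 * fs))
        one = v[lats[0] + lo : lats[0] + lo + len(tmpl.waveform)]
        assert np.allclose(tmpl.waveform, one, atol=1e-10)
        assert tmpl.waveform.max() > 0  # positive-polarity convention

    def test_too_few_blinks(self, clean_oddball):
        rec, _ = clean_oddball
        with pytest.raises(ValueError, match=">=3"):
            ad.build_blink_template(rec, ["VEOG"])  # no blink events yet


class TestBlinkIcs:
    def test_ground_truth_blink_ic_scores_highest(self, ica_rec, oddball):
        _, truth = oddball
        tmpl = ad.build_blink_template(ica_rec, ["VEOG"])
        det = ad.detect_blink_ics(ica_rec, tmpl)
        scores = det.scores["template_correlation"]
        acts = po.ic_activations(ica_rec)
        truth_ic = int(
            np.argmax([abs(np.corrcoef(a, truth.blink_source)[0, 1]) for a in acts])
        )
        assert int(np.argmax(scores)) == truth_ic
        assert scores[truth_ic] > 0.7
        assert truth_ic in det.flagged

    def test_unreachable_threshold_flags_nothing(self, ica_rec):
        tmpl = ad.build_blink_template(ica_rec, ["VEOG"])
        det = ad.detect_blink_ics(ica_rec, tmpl, r_threshold=1.0 + 1e-9)
        assert det.flagged == []

    def test_no_blink_events_warns_and_returns_empty(self, ica_rec):
        rec = ica_rec.copy()
        rec.events = [ev for ev in rec.events if ev.type != "blink"]
        tmpl = ad.build_blink_template(ica_rec, ["VEOG"])
        with pytest.warns(UserWarning, match="no blink"):
            det = ad.detect_blink_ics(rec, tmpl)
        assert det.flagged == []


class TestMultimetric:
    def _rec_with_identity_ica(self, acts, fs=256.0):
        n = acts.shape[0]
        rec = Recording(
            signals=acts.copy(),
            fs=fs,
            channels=[Channel(f"c{i}", None, "eeg") for i in range(n)],
        )
        rec.ica = e.recording_io.IcaDecomposition(
            unmixing=np.eye(n), mixing=np.eye(n), retained=list(range(n))
        )
        return rec

    def test_identical_components_nothing_flagged(self):
        row = np.random.default_rng(0).standard_normal(2048)
        rec = self._rec_with_identity_ica(np.tile(row, (5, 1)))
        det = ad.detect_bad_ics_multimetric(rec, metrics=["median_gradient", "spectral_slope"])
        assert det.flagged == []
        assert np.allclose(det.scores["z_median_gradient"], 0.0)

    def test_white_noise_ic_flagged_by_spectral_slope(self):
        rng = np.random.default_rng(1)
        import scipy.signal

        sos = scipy.signal.butter(4, 8.0, fs=256.0, output="sos")
        smooth = scipy.signal.sosfiltfilt(sos, rng.standard_normal((7, 8192)), axis=1)
        smooth /= smooth.std(axis=1, keepdims=True)
        white = rng.standard_normal((1, 8192))
        rec = self._rec_with_identity_ica(np.vstack([smooth, white]))
        det = ad.detect_bad_ics_multimetric(
            rec, metrics=["spectral_slope"], match_logic="any"
        )
        assert det.flagged == [7]

    def test_any_logic_is_superset_of_all_logic(self, ica_rec):
        any_det = ad.detect_bad_ics_multimetric(ica_rec, match_logic="any")
        all_det = ad.detect_bad_ics_multimetric(ica_rec, match_logic="all")
        assert set(any_det.flagged) >= set(all_det.flagged)

    def test_too_few_components(self):
        rec = self._rec_with_identity_ica(np.random.default_rng(0).standard_normal((3, 512)))
        with pytest.raises(ValueError, match=">=4"):
            ad.detect_bad_ics_multimetric(rec)


class TestVarianceDetector:
    def test_null_calibration_rarely_flags(self):
        # i.i.d. channels: score ~ z/0.674 in MAD units, so P(s > 2.5) ~ 4.6%
        # and the expected null flag count at [-5, 2.5] is ~1.5 of 32
        flags = []
        for seed in range(20):
            det = ad.detect_bad_channels_variance(_noise_rec(seed=seed), bounds=(-5.0, 2.5))
            flags.append(det.n_flagged)
        assert np.mean(flags) <= 2.5

    def test_scaled_channel_flagged_and_matches_bruteforce(self):
        scale = np.ones(32)
        scale[17] = 8.0
        rec = _noise_rec(scale=scale, seed=3)
        det = ad.detect_bad_channels_variance(rec, bounds=(-5.0, 2.5))
        assert "c17" in det.flagged
        assert int(np.argmax(det.scores["variance_mad"])) == 17
        # independent brute-force score computation
        v = np.var(rec.signals, axis=1)
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        oracle = (v - med) / mad
        assert np.allclose(det.scores["variance_mad"], oracle)

    def test_global_scaling_invariance(self):
        rec = _noise_rec(seed=4)
        rec.signals[5] *= 6.0
        a = ad.detect_bad_channels_variance(rec, bounds=3.0)
        big = rec.copy()
        big.signals = big.signals * 10.0
        b = ad.detect_bad_channels_variance(big, bounds=3.0)
        assert a.flagged == b.flagged
        assert np.allclose(a.scores["variance_mad"], b.scores["variance_mad"])

    def test_scalar_bounds_catch_flat_and_noisy(self):
        scale = np.ones(32)
        scale[2] = 8.0
        scale[9] = 0.01
        rec = _noise_rec(scale=scale, seed=5)
        det = ad.detect_bad_channels_variance(rec, bounds=3.0)
        assert set(det.flagged) == {"c02", "c09"}
        assert det.params["b_lo"] == -3.0 and det.params["b_hi"] == 3.0

    def test_zero_mad_warns_and_flags_nothing(self):
        rec = _noise_rec(n_ch=4, seed=6)
        rec.signals = np.tile(rec.signals[0], (4, 1))
        with pytest.warns(UserWarning, match="MAD=0"):
            det = ad.detect_bad_channels_variance(rec)
        assert det.flagged == []

    def test_too_few_channels(self):
        with pytest.raises(ValueError, match=">=4"):
            ad.detect_bad_channels_variance(_noise_rec(n_ch=3))

    def test_detector_is_pure(self):
        rec = _noise_rec(seed=7)
        before = rec.signals.copy()
        ad.detect_bad_channels_variance(rec)
        assert np.array_equal(rec.signals, before)


class TestSpectralDetector:
    def test_line_noise_channel_flagged_in_high_band(self):
        rec = _noise_rec(seed=8)
        t = np.arange(rec.n_samples) / rec.fs
        rec.signals[11] += 20.0 * np.sin(2 * np.pi * 30.0 * t)
        det = ad.detect_bad_channels_spectral(rec)
        assert "c11" in det.flagged
        assert det.scores["db_dev_20_40"][11] > 5.0

    def test_identical_channels_no_flags(self):
        rec = _noise_rec(n_ch=6, seed=9)
        rec.signals = np.tile(rec.signals[0], (6, 1))
        det = ad.detect_bad_channels_spectral(rec)
        assert det.flagged == []

    def test_tighter_bounds_flag_superset(self):
        rec = _noise_rec(seed=10)
        t = np.arange(rec.n_samples) / rec.fs
        rec.signals[4] += 5.0 * np.sin(2 * np.pi * 25.0 * t)
        wide = ad.detect_bad_channels_spectral(rec, db_bounds=(-6.0, 6.0))
        narrow = ad.detect_bad_channels_spectral(rec, db_bounds=(-2.0, 2.0))
        assert set(narrow.flagged) >= set(wide.flagged)

    def test_band_above_nyquist(self):
        with pytest.raises(ValueError, match="Nyquist"):
            ad.detect_bad_channels_spectral(_noise_rec(), bands=[(0, 200.0)])


class TestFractionCap:
    def test_keeps_top_scores_by_sort_oracle(self):
        rng = np.random.default_rng(0)
        scores = rng.permutation(10).astype(float) - 4.5
        det = ad.DetectionResult(
            "channels",
            [f"i{k}" for k in range(10)],
            {"variance_mad": scores},
            [f"i{k}" for k in range(10)],
            method="variance",
            primary_metric="variance_mad",
        )
        capped = ad.apply_fraction_cap(det, 0.5)
        oracle = [f"i{k}" for k in np.argsort(-np.abs(scores), kind="stable")[:5]]
        assert sorted(capped.flagged) == sorted(oracle)
        assert capped.params["cap"] == 5

    def test_f1_keeps_everything(self):
        det = ad.DetectionResult(
            "channels", ["a", "b"], {"s": np.array([1.0, 2.0])}, ["a"], primary_metric="s"
        )
        assert ad.apply_fraction_cap(det, 1.0).flagged == ["a"]

    def test_nonpositive_fraction(self):
        det = ad.DetectionResult("channels", ["a"], {}, [], primary_metric="s")
        with pytest.raises(ValueError):
            ad.apply_fraction_cap(det, 0.0)
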