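import numpy as np
import pytest

from conftest import toy_recording
from eegpipe import artifact_detection as ad
from eegpipe import preprocessing_ops as po
from eegpipe.recording_io import Channel, Recording


def _sine_rec(freqs, fs=256.0, dur=30.0, amps=None):
    t = np.arange(int(fs * dur)) / fs
    amps = amps or [1.0] * len(freqs)
    signals = np.vstack([a * np.sin(2 * np.pi * f * t) for f, a in zip(freqs, amps)])
    chans = [Channel(f"c{i}", (0.0, 0.0, 1.0), "eeg") for i in range(len(freqs))]
    return Recording(signals=signals, fs=fs, channels=chans, measurement_id="sine")


class TestRereference:
    def test_average_reference_zeroes_eeg_mean(self, oddball):
        rec, _ = oddball
        out = po.rereference(rec, "average")
        eeg = out.picks("eeg")
        assert np.abs(out.signals[eeg].mean(axis=0)).max() < 1e-10

    def test_eog_excluded_from_reference_computation(self, oddball):
        rec, _ = oddball
        out = po.rereference(rec, "average")
        # the subtracted reference equals the EEG-only mean of the input
        eeg = rec.picks("eeg")
        ref = rec.signals[eeg].mean(axis=0)
        veog = rec.channel_index("VEOG")
        assert np.allclose(out.signals[veog], rec.signals[veog] - ref)

    def test_channel_differences_preserved(self, oddball):
        rec, _ = oddball
        out = po.rereference(rec, "average")
        d_before = rec.signals[3] - rec.signals[10]
        d_after = out.signals[3] - out.signals[10]
        assert np.allclose(d_before, d_after)

    def test_average_is_idempotent(self, oddball):
        rec, _ = oddball
        once = po.rereference(rec, "average")
        twice = po.rereference(once, "average")
        assert np.allclose(once.signals, twice.signals)

    def test_single_channel_reference_becomes_zero(self):
        rec = toy_recording()
        out = po.rereference(rec, ["ch2"])
        assert np.abs(out.signals[2]).max() < 1e-12

    def test_missing_reference_channel(self):
        rec = toy_recording()
        with pytest.raises(KeyError):
            po.rereference(rec, ["nope"])

    def test_appends_one_history_entry_and_keeps_events(self, oddball):
        rec, _ = oddball
        out = po.rereference(rec, "average")
        assert len(out.history) == len(rec.history) + 1
        assert out.events == rec.events


class TestHighpass:
    def test_dc_offset_removed(self):
        rec = _sine_rec([10.0])
        rec.signals[0] += 50.0
        out = po.highpass_filter(rec, 1.0, 1.0)
        # forward-backward Hamming FIR: DC suppressed by >100 dB
        assert abs(out.signals[0].mean()) < 50.0 * 1e-4

    def test_stopband_attenuation_and_passband_ripple(self):
        rec = _sine_rec([0.1, 10.0])
        out = po.highpass_filter(rec, 1.0, 1.0)
        mid = slice(2000, -2000)
        gain_stop = out.signals[0, mid].std() / rec.signals[0, mid].std()
        gain_pass = out.signals[1, mid].std() / rec.signals[1, mid].std()
        assert 20 * np.log10(gain_stop) < -20.0
        assert abs(20 * np.log10(gain_pass)) < 1.0

    def test_cutoff_above_nyquist(self):
        rec = _sine_rec([10.0])
        with pytest.raises(ValueError, match="Nyquist"):
            po.highpass_filter(rec, 200.0)


class TestIca:
    def test_recovers_independent_sources(self):
        rng = np.random.default_rng(0)
        n = 20000
        t = np.arange(n) / 256.0
        sources = np.vstack([
            rng.laplace(size=n),
            np.sign(np.sin(2 * np.pi * 3 * t)),
            np.sin(2 * np.pi * 7 * t + 0.5),
        ])
        A = np.array([[1.0, 0.6, 0.3], [0.4, 1.0, 0.7], [0.2, 0.5, 1.0]])
        rec = Recording(
            signals=A @ sources,
            fs=256.0,
            channels=[Channel(f"c{i}", None, "eeg") for i in range(3)],
        )
        with pytest.warns(UserWarning):  # no highpass in history
            out = po.ica_decompose(rec, n_components=3, seed=1)
        acts = po.ic_activations(out)
        for s in sources:
            best = max(abs(np.corrcoef(s, a)[0, 1]) for a in acts)
            assert best >= 0.95

    def test_full_rank_reconstruction(self, ica_rec):
        picks = ica_rec.picks("eeg") + ica_rec.picks("eog")
        X = ica_rec.signals[picks]
        Xc = X - X.mean(axis=1, keepdims=True)
        recon = (ica_rec.ica.mixing @ (ica_rec.ica.unmixing @ ica_rec.signals))[
            np.arange(len(picks))
        ]
        recon = ica_rec.ica.mixing @ (ica_rec.ica.unmixing @ ica_rec.signals)
        recon = recon[picks] - recon[picks].mean(axis=1, keepdims=True)
        err = np.linalg.norm(Xc - recon) / np.linalg.norm(Xc)
        assert err <= 1e-6

    def test_zero_components_rejected(self):
        rec = toy_recording()
        with pytest.raises(ValueError):
            po.ica_decompose(rec, n_components=0)

    def test_seeded_determinism(self, oddball):
        rec, _ = oddball
        hp = po.highpass_filter(rec)
        a = po.ica_decompose(hp, seed=4)
        b = po.ica_decompose(hp, seed=4)
        assert np.array_equal(a.ica.unmixing, b.ica.unmixing)


class TestRejectChannels:
    def test_no_flags_is_identity(self, oddball):
        rec, _ = oddball
        det = ad.DetectionResult("channels", rec.labels(), {}, [], method="variance")
        out, record = po.reject_channels(rec, det)
        assert record is None
        assert np.array_equal(out.signals, rec.signals)

    def test_flat_channel_interpolation_matches_neighbours(self, oddball):
        # spatially coherent field (smooth source topographies + sensor noise),
        # as in real EEG where neighbouring channels are strongly correlated
        base, _ = oddball
        rng = np.random.default_rng(8)
        eeg = base.picks("eeg")
        pos = base.positions(eeg)
        n_src, n_samp = 10, 2560
        centers = rng.standard_normal((n_src, 3))
        centers /= np.linalg.norm(centers, axis=1, keepdims=True)
        topos = np.exp(-0.5 * (np.arccos(np.clip(pos @ centers.T, -1, 1)) / 0.6) ** 2)
        field = topos @ rng.standard_normal((n_src, n_samp))
        field += 0.2 * rng.standard_normal(field.shape)
        rec = Recording(
            signals=field,
            fs=base.fs,
            channels=[base.channels[i] for i in eeg],
            measurement_id="field",
        )
        i_bad = rec.channel_index("P7")
        rec.signals[i_bad] = 0.01 * rng.standard_normal(n_samp)  # flat/dead
        det = ad.DetectionResult("channels", rec.labels(), {}, ["P7"], method="variance")
        out, record = po.reject_channels(rec, det, interpolate=True)
        dists = {
            j: np.arccos(np.clip(pos[j] @ pos[i_bad], -1, 1))
            for j in range(len(eeg))
            if j != i_bad
        }
        nn = sorted(dists, key=dists.get)[:4]
        oracle = rec.signals[nn].mean(axis=0)
        r = np.corrcoef(out.signals[i_bad], oracle)[0, 1]
        assert r >= 0.8
        assert record.fraction_of_total == pytest.approx(1 / 32)

    def test_drop_mode_removes_channels(self, oddball):
        rec, _ = oddball
        det = ad.DetectionResult("channels", rec.labels(), {}, ["F3"], method="variance")
        out, _ = po.reject_channels(rec, det, interpolate=False)
        assert out.n_channels == rec.n_channels - 1
        assert "F3" not in out.labels()

    def test_majority_flagged_is_an_error(self, oddball):
        rec, _ = oddball
        flagged = [c.label for c in rec.channels if c.kind == "eeg"][:20]
        det = ad.DetectionResult("channels", rec.labels(), {}, flagged, method="variance")
        with pytest.raises(ValueError, match="insufficient support"):
            po.reject_channels(rec, det, interpolate=True)


class TestRejectComponents:
    def test_empty_flag_set_is_identity_within_tolerance(self, ica_rec):
        det = ad.DetectionResult(
            "components", list(range(ica_rec.ica.n_components)), {}, [], method="m"
        )
        out, record = po.reject_components(ica_rec, det)
        assert record is None
        assert np.allclose(out.signals, ica_rec.signals, atol=1e-8)

    def test_removing_blink_ic_reduces_frontal_variance(self, ica_rec):
        tmpl = ad.build_blink_template(ica_rec, ["VEOG"])
        blink = ad.detect_blink_ics(ica_rec, tmpl)
        assert blink.flagged
        out, record = po.reject_components(ica_rec, blink)
        fp = ica_rec.channel_index("Fp1")
        assert out.signals[fp].var() < ica_rec.signals[fp].var()
        assert len(out.ica.retained) == ica_rec.ica.n_components - len(blink.flagged)

    def test_all_flagged_is_an_error(self, ica_rec):
        n = ica_rec.ica.n_components
        det = ad.DetectionResult("components", list(range(n)), {}, list(range(n)), method="m")
        with pytest.raises(ValueError):
            po.reject_components(ica_rec, det)


class TestFilterBlinkIcs:
    def test_veog_blink_erp_reduced(self, ica_rec):
        tmpl = ad.build_blink_template(ica_rec, ["VEOG"])
        blink = ad.detect_blink_ics(ica_rec, tmpl)
        out, record = po.filter_blink_ics(ica_rec, blink.flagged)

        def peak(rc):
            lats = ad.blink_latencies(rc)
            v = rc.signals[rc.channel_index("VEOG")]
            lo, hi = int(-0.3 * rc.fs), int(0.5 * rc.fs)
            rows = [v[l + lo : l + hi] for l in lats if l + lo >= 0 and l + hi <= rc.n_samples]
            return np.abs(np.mean(rows, axis=0)).max()

        assert peak(out) <= 0.3 * peak(ica_rec)
        assert record.kind == "components"

    def test_non_blink_activations_untouched(self, ica_rec):
        tmpl = ad.build_blink_template(ica_rec, ["VEOG"])
        blink = ad.detect_blink_ics(ica_rec, tmpl)
        out, _ = po.filter_blink_ics(ica_rec, blink.flagged)
        acts_in = po.ic_activations(ica_rec)
        acts_out = po.ic_activations(out)
        others = [i for i in range(ica_rec.ica.n_components) if i not in blink.flagged]
        assert np.allclose(acts_in[others], acts_out[others], atol=1e-10)

    def test_silent_ic_leaves_signals_unchanged(self, ica_rec):
        rec = ica_rec.copy()
        # silence component 0 by projecting it out first
        acts = po.ic_activations(rec)
        rec.signals = rec.signals - rec.ica.mixing[:, [0]] @ acts[[0]]
        out, _ = po.filter_blink_ics(rec, [0])
        assert np.allclose(out.signals, rec.signals, atol=1e-8)

    def test_empty_set_warns_and_noops(self, ica_rec):
        with pytest.warns(UserWarning, match="no blink"):
            out, record = po.filter_blink_ics(ica_rec, [])
        assert record is None
        assert np.array_equal(out.signals, ica_rec.signals)


class TestSpatialClustering:
    def test_scattered_flags_no_warning(self, oddball):
        rec, _ = oddball
        eeg_labels = [c.label for c in rec.channels if c.kind == "eeg"]
        diag = po.check_spatial_clustering(eeg_labels[::2], rec)
        assert not diag["warning"]

    def test_contiguous_frontal_cluster_warns(self):
        from eegpipe.synthetic_oddball import GeneratorSpec, generate_recording

        rec, _ = generate_recording(GeneratorSpec(n_channels=64, duration_s=10.0, n_trials=4), seed=0)
        frontal = ["Fp1", "Fpz", "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8", "F7", "F5", "F3", "F1"]
        diag = po.check_spatial_clustering(frontal, rec)
        assert diag["warning"] and diag["dispersion"] > 1.5

    def test_empty_set(self, oddball):
        rec, _ = oddball
        diag = po.check_spatial_clustering([], rec)
        assert diag == {"dispersion": 0.0, "warning": False}
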