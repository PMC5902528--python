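import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import eegpipe as e
from eegpipe.erp_analysis import (
    ErpParams,
    average_erps,
    baseline_correct,
    extract_epochs,
    plot_erp_grid,
    smooth_moving_average,
)
from eegpipe.recording_io import Channel, Event, Recording


def _rec_with_events(latencies, types=None, n_samp=25600, fs=256.0, seed=0):
    rng = np.random.default_rng(seed)
    types = types or ["std_short"] * len(latencies)
    return Recording(
        signals=rng.standard_normal((1, n_samp)),
        fs=fs,
        channels=[Channel("T7", (1.0, 0.0, 0.0), "eeg")],
        events=[Event(int(l), t) for l, t in zip(latencies, types)],
        subject_id="s01",
        measurement_id="s01_m",
    )


class TestExtractEpochs:
    def test_pm1s_window_at_256hz_is_512_samples(self):
        rec = _rec_with_events([5000, 9000])
        ep = extract_epochs(rec, ["std_short"], (-1.0, 1.0), "T7")
        assert ep.shape == (2, 512)

    def test_boundary_event_dropped_with_warning(self):
        rec = _rec_with_events([10, 5000])
        with pytest.warns(UserWarning, match="dropped"):
            ep = extract_epochs(rec, ["std_short"], (-1.0, 1.0), "T7")
        assert ep.shape[0] == 1

    def test_all_inbounds_events_epoch(self):
        lats = np.linspace(300, 25000, 100).astype(int)
        rec = _rec_with_events(lats)
        ep = extract_epochs(rec, ["std_short"], (-1.0, 1.0), "T7")
        assert ep.shape[0] == 100

    def test_epoch_content_matches_half_open_convention(self):
        rec = _rec_with_events([1000])
        ep = extract_epochs(rec, ["std_short"], (-1.0, 1.0), "T7")
        assert np.array_equal(ep[0], rec.signals[0, 1000 - 256 : 1000 + 256])


class TestBaseline:
    def test_baseline_mean_is_zero_for_every_epoch(self):
        rng = np.random.default_rng(1)
        epochs = rng.standard_normal((50, 512)) + rng.uniform(-30, 30, (50, 1))
        out = baseline_correct(epochs, (-1.0, 1.0), (-1.0, 0.0), 256.0)
        assert np.abs(out[:, :256].mean(axis=1)).max() < 1e-10

    def test_constant_epoch_becomes_zero(self):
        out = baseline_correct(np.full((1, 512), 7.0), (-1.0, 1.0), (-1.0, 0.0), 256.0)
        assert np.allclose(out, 0.0)

    def test_linear_ramp_closed_form(self):
        # ramp over (-1, 1) s: baseline mean = value at -0.5 s, so the
        # corrected value at onset equals half the rise over the baseline window
        fs = 256.0
        t = np.arange(-256, 256) / fs
        slope = 4.0
        out = baseline_correct(slope * t[None, :], (-1.0, 1.0), (-1.0, 0.0), fs)
        rise = slope * 1.0
        onset_value = out[0, 256]
        assert onset_value == pytest.approx(rise / 2, abs=0.02)

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        epochs = rng.standard_normal((5, 512))
        once = baseline_correct(epochs, (-1.0, 1.0), (-1.0, 0.0), 256.0)
        twice = baseline_correct(once, (-1.0, 1.0), (-1.0, 0.0), 256.0)
        assert np.allclose(once, twice)

    def test_empty_baseline_window_rejected(self):
        with pytest.raises(ValueError):
            baseline_correct(np.zeros((1, 512)), (-1.0, 1.0), (0.0, 0.0), 256.0)


class TestSmoothing:
    def test_constant_input_unchanged(self):
        assert np.allclose(smooth_moving_average(np.full(100, 3.3), 64), 3.3)

    def test_impulse_response_plateau_is_one_over_w(self):
        x = np.zeros(512)
        x[256] = 1.0
        out = smooth_moving_average(x, 64)
        interior = out[256 - 20 : 256 + 20]
        assert np.allclose(interior, 1 / 64)

    def test_w1_is_identity_and_length_preserved(self):
        x = np.random.default_rng(0).standard_normal(77)
        assert np.array_equal(smooth_moving_average(x, 1), x)
        assert smooth_moving_average(x, 10).shape == x.shape

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(ValueError):
            smooth_moving_average(np.zeros(10), 11)

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(1, 30), st.floats(-5, 5), st.floats(-5, 5))
    def test_linearity(self, w, a, b):
        rng = np.random.default_rng(5)
        x, y = rng.standard_normal((2, 64))
        lhs = smooth_moving_average(a * x + b * y, w)
        rhs = a * smooth_moving_average(x, w) + b * smooth_moving_average(y, w)
        assert np.allclose(lhs, rhs, atol=1e-9)

    def test_edges_shrink_window(self):
        x = np.arange(100.0)
        out = smooth_moving_average(x, 64)
        # first output averages only the first (right-half) window samples
        assert out[0] == pytest.approx(x[:33].mean())


class TestAverageErps:
    def test_single_subject_single_epoch_grand_average(self):
        rec = _rec_with_events([5000])
        params = ErpParams(channel="T7", smooth_window=8,
                           conditions={"std_short": "std_short"})
        erps = average_erps({"s01": rec}, params)
        ep = extract_epochs(rec, ["std_short"], params.window, "T7")
        ep = baseline_correct(ep, params.window, params.baseline, rec.fs)
        expected = smooth_moving_average(ep, 8)[0]
        assert np.allclose(erps.grand_average["std_short"], expected)
        assert erps.n_epochs["std_short"]["s01"] == 1

    def test_opposite_waveforms_cancel(self):
        a = _rec_with_events([5000], seed=1)
        b = a.copy()
        b.signals = -a.signals
        params = ErpParams(conditions={"std_short": "std_short"})
        erps = average_erps({"s1": a, "s2": b}, params)
        assert np.allclose(erps.grand_average["std_short"], 0.0, atol=1e-12)

    def test_grand_average_is_mean_of_means_and_permutation_invariant(self):
        recs = {f"s{i}": _rec_with_events([4000, 9000, 15000], seed=i) for i in range(4)}
        params = ErpParams(conditions={"std_short": "std_short"})
        erps = average_erps(recs, params)
        oracle = np.mean(
            [erps.subject_erps["std_short"][s] for s in recs], axis=0
        )
        assert np.allclose(erps.grand_average["std_short"], oracle)
        shuffled = dict(reversed(list(recs.items())))
        erps2 = average_erps(shuffled, params)
        assert np.allclose(erps.grand_average["std_short"], erps2.grand_average["std_short"])

    def test_deviant_p300_surplus_sign_recovered(self):
        recs = {}
        for i in range(3):
            rec, _ = e.generate_recording(e.GeneratorSpec(duration_s=150.0, n_trials=100), seed=40 + i)
            recs[f"s{i}"] = rec
        erps = average_erps(recs, ErpParams())
        t = erps.time_s
        win = (t >= 0.25) & (t <= 0.40)
        for tone in ("short", "long"):
            diff = erps.grand_average[f"dev_{tone}"][win].mean() - erps.grand_average[f"std_{tone}"][win].mean()
            assert diff > 0

    def test_missing_condition_omitted_with_warning(self):
        rec = _rec_with_events([5000])
        with pytest.warns(UserWarning, match="omitted"):
            erps = average_erps({"s01": rec}, ErpParams())
        assert "dev_long" not in erps.grand_average


class TestPlot:
    def test_renders_with_expected_line_count(self, tmp_path, monkeypatch):
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        lats = [4000, 9000, 14000, 19000]
        types = ["std_short", "dev_short", "std_long", "dev_long"]
        recs = {f"s{i}": _rec_with_events(lats, types, seed=i) for i in range(2)}
        erps = average_erps(recs, ErpParams(smooth_window=4))

        kept = []
        monkeypatch.setattr(plt, "close", lambda fig: kept.append(fig))
        path = plot_erp_grid(erps, tmp_path)
        assert path.exists() and path.stat().st_size > 0
        fig = kept[0]
        try:
            n_subj = 2
            for ax in fig.axes:
                # 2 conditions x (subjects + grand average) + the onset marker
                assert len(ax.get_lines()) == 2 * (n_subj + 1) + 1
        finally:
            import matplotlib.pyplot  # noqa: F401

            matplotlib.pyplot.figure().clear()

    def test_empty_set_rejected(self, tmp_path):
        from eegpipe.erp_analysis import ErpSet

        empty = ErpSet(np.arange(4), {}, {}, {})
        with pytest.raises(ValueError):
            plot_erp_grid(empty, tmp_path)
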