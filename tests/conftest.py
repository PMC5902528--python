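import numpy as np
import pytest

import eegpipe as e
from eegpipe import artifact_detection as ad
from eegpipe import preprocessing_ops as po
from eegpipe.recording_io import Channel, Event, Recording

CODE_MAP = {1: "std_short", 2: "std_long", 3: "dev_short", 4: "dev_long"}


@pytest.fixture(scope="session")
def oddball():
    """60 s oddball recording with one noisy and one flat injected channel."""
    spec = e.GeneratorSpec(
        duration_s=60.0,
        n_trials=30,
        bad_channels=[("F3", "noisy", 8.0), ("P7", "flat", None)],
    )
    return e.generate_recording(spec, seed=2)


@pytest.fixture(scope="session")
def clean_oddball():
    """Artifact-free oddball recording (blinks only, no bad channels)."""
    spec = e.GeneratorSpec(duration_s=60.0, n_trials=30)
    return e.generate_recording(spec, seed=7)


@pytest.fixture(scope="session")
def ica_rec(oddball):
    """Blink-marked, highpassed, ICA-decomposed version of the oddball fixture."""
    rec, _ = oddball
    rec, _ = ad.detect_blink_events(rec, ["VEOG"])
    rec = po.highpass_filter(rec)
    return po.ica_decompose(rec, seed=0)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """On-disk BDF fixture set: 3 subjects, 16 channels, 40 s."""
    td = tmp_path_factory.mktemp("fixtures")
    spec = e.GeneratorSpec(duration_s=40.0, n_trials=20, n_channels=16)
    mc = e.write_fixture_set(3, spec, td, seed=5)
    return td, mc


def toy_recording(n_ch=6, n_samp=2560, fs=256.0, seed=0, positions=True):
    """Small deterministic Recording for unit tests of signal operations."""
    rng = np.random.default_rng(seed)
    signals = rng.standard_normal((n_ch, n_samp))
    chans = []
    for i in range(n_ch):
        theta = np.pi * (i + 1) / (n_ch + 2)
        pos = (np.sin(theta), 0.2 * (-1) ** i, np.cos(theta)) if positions else None
        chans.append(Channel(f"ch{i}", pos, "eeg"))
    events = [Event(100, "a"), Event(1200, "b")]
    return Recording(signals=signals, fs=fs, channels=chans, events=events,
                     subject_id="t", measurement_id="toy")
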