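"""Synthetic oddball EEG with injected, labelled artifacts.

Generates continuous recordings that emulate an auditory two-tone oddball
session: standard and deviant tones (deviants ~10%), short/long tone lengths,
256 Hz sampling. The signal is a linear mixture of latent sources —
spectrally shaped 1/f background per channel, an amplitude-modulated 10 Hz
alpha source over posterior sites, an event-locked ERP generator (negative
N1 near 100 ms, positive P300 near 325 ms, with a configurable deviant P300
surplus), a blink source projected to frontal channels and a vertical-EOG
channel, and optional isolated impulse artifacts. Channels can then be
corrupted (extra noise at xk scale, flat, or mains sinusoid). Every injected
feature is reported in a :class:`GroundTruth` sidecar, so detector
performance can be scored exactly.

Deterministic for a fixed seed. Fixture sets are written as BDF (or EDF)
with trigger codes on a Status channel, a cartesian electrode-location
sidecar, a ground-truth JSON sidecar, and a measurement sheet.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._edf import write_edf
from .recording_io import Channel, Event, MeasurementConfig, Recording, history_entry

__all__ = [
    "DEFAULT_EVENT_CODES",
    "GeneratorSpec",
    "GroundTruth",
    "generate_events",
    "generate_recording",
    "montage_positions",
    "write_fixture_set",
]

CONDITIONS = ("std_short", "std_long", "dev_short", "dev_long")
DEFAULT_EVENT_CODES = {"std_short": 1, "std_long": 2, "dev_short": 3, "dev_long": 4}

# BioSemi-style 32-channel 10-20 subset and a 64-channel 10-10 set; labels
# resolve against the standard montage shipped with mne.
_LABELS_32 = [
    "Fp1", "AF3", "F7", "F3", "FC1", "FC5", "T7", "C3", "CP1", "CP5", "P7",
    "P3", "Pz", "PO3", "O1", "Oz", "O2", "PO4", "P4", "P8", "CP6", "CP2",
    "C4", "T8", "FC6", "FC2", "F4", "F8", "AF4", "Fp2", "Fz", "Cz",
]
_LABELS_64 = [
    "Fp1", "Fpz", "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8", "F7", "F5", "F3",
    "F1", "Fz", "F2", "F4", "F6", "F8", "FT7", "FC5", "FC3", "FC1", "FCz",
    "FC2", "FC4", "FC6", "FT8", "T7", "C5", "C3", "C1", "Cz", "C2", "C4",
    "C6", "T8", "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6",
    "TP8", "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8", "PO7",
    "PO3", "POz", "PO4", "PO8", "O1", "Oz", "O2", "PO9", "PO10", "TP9",
]


def montage_positions(labels: Sequence[str]) -> dict[str, np.ndarray]:
    """Unit-sphere xyz for standard 10-10 labels (x right, y front, z up)."""
    import warnings

    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        montage = mne.channels.make_standard_montage("standard_1005")
    pos = montage.get_positions()["ch_pos"]
    out = {}
    for lab in labels:
        if lab not in pos:
            raise KeyError(f"label {lab!r} not in the standard montage")
        v = np.asarray(pos[lab], dtype=float)
        out[lab] = v / np.linalg.norm(v)
    return out


def _montage(n_channels: int) -> tuple[list[str], dict[str, np.ndarray]]:
    if n_channels <= 32:
        labels = _LABELS_32[:n_channels]
    elif n_channels <= 64:
        labels = _LABELS_64[:n_channels]
    else:
        raise ValueError("generator supports up to 64 EEG channels")
    return labels, montage_positions(labels)


@dataclass
class GeneratorSpec:
    """Study conditions for one synthetic oddball recording.

    Amplitudes are in microvolts. ``bad_channels`` is a list of
    ``(label, kind, param)`` tuples with kind in {"noisy", "flat", "line"}:
    ``noisy`` adds white noise at ``param`` times the background scale,
    ``flat`` collapses the channel to near-zero, ``line`` adds a mains
    sinusoid at ``param`` Hz.
    """

    n_channels: int = 32            # EEG channels; a VEOG channel is appended
    fs: float = 256.0
    duration_s: float = 300.0
    # event plan
    n_trials: int = 200
    deviant_rate: float = 0.10
    isi_s: float = 1.4
    isi_jitter_s: float = 0.15
    # ERP model
    erp_channel: str = "T7"
    n1_latency_s: float = 0.10
    n1_amp_uv: float = -5.0
    n1_width_s: float = 0.03
    p300_latency_s: float = 0.325
    p300_amp_uv: float = 6.0
    p300_width_s: float = 0.15
    deviant_p300_surplus_uv: float = 4.0
    # noise model
    noise_scale_uv: float = 10.0
    channel_scale_jitter: float = 0.18
    alpha_amp_uv: float = 2.5
    # artifacts
    blink_rate_per_min: float = 15.0
    n_blinks: int | None = None
    blink_amp_uv: float = 400.0       # on the VEOG channel
    blink_scalp_amp_uv: float = 140.0  # at the frontal topography peak
    blink_width_s: float = 0.08
    bad_channels: list = field(default_factory=list)
    n_impulses: int = 0
    impulse_amp_uv: float = 150.0

    def __post_init__(self):
        if not (0.0 <= self.deviant_rate < 1.0):
            raise ValueError("deviant_rate must be in [0, 1)")
        if len(self.bad_channels) > 0.5 * self.n_channels:
            raise ValueError("bad channels limited to half the montage")


@dataclass
class GroundTruth:
    """Labels for everything the generator injected."""

    events: pd.DataFrame                  # latency, type, tone, is_deviant
    blink_latencies: list[int]
    bad_channels: list[tuple]             # (label, kind, param)
    impulse_latencies: list[int]
    blink_source: np.ndarray              # latent blink time course (unit amplitude)
    erp: dict

    def bad_channel_labels(self) -> list[str]:
        return [b[0] for b in self.bad_channels]

    def to_json(self) -> str:
        return json.dumps(
            {
                "events": self.events.to_dict(orient="records"),
                "blink_latencies": self.blink_latencies,
                "bad_channels": [list(b) for b in self.bad_channels],
                "impulse_latencies": self.impulse_latencies,
                "erp": self.erp,
            }
        )


# ---------------------------------------------------------------------------
# event plan
# ---------------------------------------------------------------------------

def generate_events(spec: GeneratorSpec, seed: int = 0) -> pd.DataFrame:
    """Trial table: ISI-spaced jittered onsets, deviant/tone-length assignment."""
    if spec.n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
    start_s = 2.0
    onsets = start_s + np.arange(spec.n_trials) * spec.isi_s
    onsets = onsets + rng.uniform(-spec.isi_jitter_s, spec.isi_jitter_s, spec.n_trials)
    if onsets[-1] + 1.2 > spec.duration_s:
        raise ValueError(
            f"duration {spec.duration_s}s too short for {spec.n_trials} trials at ISI {spec.isi_s}s"
        )
    is_dev = rng.random(spec.n_trials) < spec.deviant_rate
    tone = np.where(rng.random(spec.n_trials) < 0.5, "short", "long")
    rows = []
    for t, d, tn in zip(onsets, is_dev, tone):
        cond = ("dev_" if d else "std_") + tn
        rows.append(
            {
                "latency": int(round(t * spec.fs)),
                "type": cond,
                "tone": tn,
                "is_deviant": bool(d),
            }
        )
    return pd.DataFrame(rows)


def _sparse_latencies(
    rng: np.random.Generator, n: int, fs: float, duration_s: float, min_gap_s: float
) -> list[int]:
    """n latencies uniform in the interior with a minimum mutual gap."""
    if n == 0:
        return []
    lo, hi = 2.0, duration_s - 2.0
    span = hi - lo - n * min_gap_s
    if span <= 0:
        raise ValueError("recording too short for the requested artifact count")
    gaps = np.sort(rng.uniform(0, span, n))
    times = lo + gaps + np.arange(n) * min_gap_s
    return [int(round(t * fs)) for t in times]


# ---------------------------------------------------------------------------
# signal synthesis
# ---------------------------------------------------------------------------

def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-RMS noise with a 1/f amplitude spectrum."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n)
    return x / x.std()


def _gauss_bump(t: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / width) ** 2)


def _topography(positions: np.ndarray, center: np.ndarray, width_rad: float) -> np.ndarray:
    cosang = np.clip(positions @ center, -1.0, 1.0)
    ang = np.arccos(cosang)
    return np.exp(-0.5 * (ang / width_rad) ** 2)


def generate_recording(spec: GeneratorSpec, seed: int = 0):
    """Synthesize one recording; returns ``(Recording, GroundTruth)``."""
    labels, posmap = _montage(spec.n_channels)
    positions = np.vstack([posmap[lab] for lab in labels])
    fs = spec.fs
    n = int(round(spec.duration_s * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 23]))

    events = generate_events(spec, seed)

    # per-channel 1/f background with slight scale heterogeneity
    scales = spec.noise_scale_uv * (
        1.0 + rng.uniform(-spec.channel_scale_jitter, spec.channel_scale_jitter, spec.n_channels)
    )
    signals = np.vstack([_pink_noise(rng, n) * s for s in scales])

    # posterior alpha: amplitude-modulated 10 Hz
    envelope = np.abs(_pink_noise(rng, n))
    envelope /= max(envelope.std(), 1e-12)
    alpha_src = np.sin(2 * np.pi * 10.0 * t + rng.uniform(0, 2 * np.pi)) * envelope
    alpha_src /= max(alpha_src.std(), 1e-12)
    occ_center = posmap.get("Oz")
    if occ_center is None:
        occ_center = np.array([0.0, -0.95, 0.31])
        occ_center /= np.linalg.norm(occ_center)
    topo_alpha = _topography(positions, occ_center, 0.7)
    signals += np.outer(topo_alpha, spec.alpha_amp_uv * alpha_src)

    # event-locked ERP source, unit topography at the ERP channel
    erp_src = np.zeros(n)
    win = np.arange(int(round(-0.1 * fs)), int(round(0.8 * fs)))
    tw = win / fs
    base_wave = (
        spec.n1_amp_uv * _gauss_bump(tw, spec.n1_latency_s, spec.n1_width_s)
        + spec.p300_amp_uv * _gauss_bump(tw, spec.p300_latency_s, spec.p300_width_s)
    )
    surplus_wave = _gauss_bump(tw, spec.p300_latency_s, spec.p300_width_s)
    for _, ev in events.iterrows():
        idx = ev["latency"] + win
        ok = (idx >= 0) & (idx < n)
        wave = base_wave + (spec.deviant_p300_surplus_uv if ev["is_deviant"] else 0.0) * surplus_wave
        erp_src[idx[ok]] += wave[ok]
    erp_center = posmap.get(spec.erp_channel, positions[0])
    topo_erp = _topography(positions, np.asarray(erp_center), 0.7)
    signals += np.outer(topo_erp, erp_src)

    # blinks: latent unit-amplitude source, frontal scalp projection
    n_blinks = (
        spec.n_blinks
        if spec.n_blinks is not None
        else int(round(spec.blink_rate_per_min * spec.duration_s / 60.0))
    )
    blink_lats = _sparse_latencies(rng, n_blinks, fs, spec.duration_s, min_gap_s=1.5)
    blink_src = np.zeros(n)
    half = int(round(4 * spec.blink_width_s * fs))
    bwin = np.arange(-half, half + 1)
    bshape = _gauss_bump(bwin / fs, 0.0, spec.blink_width_s)
    for lat in blink_lats:
        idx = lat + bwin
        ok = (idx >= 0) & (idx < n)
        blink_src[idx[ok]] += bshape[ok]
    front = posmap.get("Fp1", positions[0]) + posmap.get("Fp2", positions[-1])
    front = front / np.linalg.norm(front)
    topo_blink = _topography(positions, front, 0.5)
    signals += np.outer(spec.blink_scalp_amp_uv * topo_blink, blink_src)

    # impulse artifacts: isolated sharp spikes, frontally weighted
    impulse_lats = _sparse_latencies(rng, spec.n_impulses, fs, spec.duration_s, min_gap_s=0.5)
    if impulse_lats:
        imp_src = np.zeros(n)
        for lat in impulse_lats:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            imp_src[lat] += sign
            if lat + 1 < n:
                imp_src[lat + 1] += 0.5 * sign
            if lat - 1 >= 0:
                imp_src[lat - 1] += 0.5 * sign
        frontal_idx = int(np.argmax(positions @ front))
        topo_imp = _topography(positions, positions[frontal_idx], 0.35)
        signals += np.outer(spec.impulse_amp_uv * topo_imp, imp_src)

    # VEOG channel: blinks at high amplitude over its own noise floor
    veog = spec.blink_amp_uv * blink_src + 5.0 * _pink_noise(rng, n)
    veog_pos = front * np.array([1.0, 1.0, 0.0])
    veog_pos[2] = -0.15
    veog_pos /= np.linalg.norm(veog_pos)

    # corrupt bad channels after mixing
    bad_specs = [tuple(b) for b in spec.bad_channels]
    for lab, kind, param in bad_specs:
        ci = labels.index(lab)
        if kind == "noisy":
            signals[ci] += float(param) * spec.noise_scale_uv * rng.standard_normal(n)
        elif kind == "flat":
            signals[ci] = 0.01 * rng.standard_normal(n)
        elif kind == "line":
            signals[ci] += 80.0 * np.sin(2 * np.pi * float(param) * t)
        else:
            raise ValueError(f"unknown bad-channel kind {kind!r}")

    channels = [Channel(lab, tuple(posmap[lab]), "eeg") for lab in labels]
    channels.append(Channel("VEOG", tuple(veog_pos), "eog"))
    all_signals = np.vstack([signals, veog[None, :]])
    rec_events = [Event(int(r["latency"]), str(r["type"])) for _, r in events.iterrows()]
    rec = Recording(
        signals=all_signals,
        fs=fs,
        channels=channels,
        events=sorted(rec_events, key=lambda e: e.latency),
        subject_id="sim",
        measurement_id="sim",
    )
    rec.with_history(
        history_entry(
            "generate_recording",
            {"seed": int(seed), "n_channels": spec.n_channels, "duration_s": spec.duration_s},
            f"synthetic oddball: {len(rec_events)} trials, {len(blink_lats)} blinks",
        )
    )
    truth = GroundTruth(
        events=events,
        blink_latencies=blink_lats,
        bad_channels=bad_specs,
        impulse_latencies=impulse_lats,
        blink_source=blink_src,
        erp={
            "n1_amp_uv": spec.n1_amp_uv,
            "p300_amp_uv": spec.p300_amp_uv,
            "deviant_p300_surplus_uv": spec.deviant_p300_surplus_uv,
            "erp_channel": spec.erp_channel,
        },
    )
    return rec, truth


# ---------------------------------------------------------------------------
# fixture sets on disk
# ---------------------------------------------------------------------------

def write_fixture_set(
    n_subjects: int,
    spec: GeneratorSpec,
    out_dir: str | Path,
    seed: int = 0,
    fmt: str = "bdf",
) -> MeasurementConfig:
    """Write ``sNN_eeg_1.<ext>`` files with sidecars and a measurement sheet.

    Each subject gets its own child seed, so any subject subset regenerates
    identically. The trigger codes on the Status channel follow
    ``DEFAULT_EVENT_CODES``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(1, n_subjects + 1):
        child_seed = int(np.random.SeedSequence([int(seed), i]).generate_state(1)[0] % (2**31))
        rec, truth = generate_recording(spec, seed=child_seed)
        stem = f"s{i:02d}_eeg_1"
        eeg_path = out_dir / f"{stem}.{fmt}"
        status = np.zeros(rec.n_samples, dtype=np.int64)
        pulse = max(1, int(round(0.05 * rec.fs)))
        for ev in rec.events:
            code = DEFAULT_EVENT_CODES.get(ev.type)
            if code is not None:
                status[ev.latency : ev.latency + pulse] = code
        write_edf(
            eeg_path,
            rec.signals,
            rec.fs,
            rec.labels(),
            status=status,
            fmt=fmt,
            patient_id=stem.split("_")[0],
            recording_id=stem,
        )
        loc_path = out_dir / f"{stem}_locs.txt"
        with open(loc_path, "w") as fh:
            fh.write("# label x y z (unit sphere)\n")
            for ch in rec.channels:
                x, y, z = ch.position
                fh.write(f"{ch.label} {x:.6f} {y:.6f} {z:.6f}\n")
        (out_dir / f"{stem}_truth.json").write_text(truth.to_json())
        rows.append(
            {
                "subject": f"s{i:02d}",
                "session": "session",
                "measurement": stem,
                "path": str(eeg_path),
                "loc_path": str(loc_path),
            }
        )
    sheet = out_dir / "measurements.csv"
    pd.DataFrame(rows).to_csv(sheet, index=False)
    from .recording_io import MeasurementEntry

    entries = [
        MeasurementEntry(
            subject_id=r["subject"],
            session=r["session"],
            measurement_id=r["measurement"],
            eeg_path=Path(r["path"]),
            loc_path=Path(r["loc_path"]),
        )
        for r in rows
    ]
    return MeasurementConfig(entries)
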