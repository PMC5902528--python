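"""Oddball ERP post-processing: epoching, baseline, smoothing, grand averages.

The analysis mirrors a classic auditory oddball read-out: epochs of ±1 s
around tone onsets at a single temporal channel, baseline-corrected by the
mean of the pre-stimulus second, smoothed with a quarter-second moving
average, averaged within subject and condition, then grand-averaged across
subjects (unweighted). Deviant tones are expected to show an enlarged P300
relative to standards.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .recording_io import Recording

__all__ = [
    "ErpParams",
    "ErpSet",
    "average_erps",
    "baseline_correct",
    "extract_epochs",
    "plot_erp_grid",
    "smooth_moving_average",
]

ODDBALL_CONDITIONS = ("std_short", "dev_short", "std_long", "dev_long")


@dataclass(frozen=True)
class ErpParams:
    """ERP extraction settings; defaults match a T7-channel oddball read-out."""

    channel: str = "T7"
    window: tuple[float, float] = (-1.0, 1.0)
    baseline: tuple[float, float] = (-1.0, 0.0)
    smooth_window: int | None = None  # samples; None -> round(fs / 4)
    conditions: Mapping[str, str] = field(
        default_factory=lambda: {c: c for c in ODDBALL_CONDITIONS}
    )

    def __post_init__(self):
        if not (self.window[0] <= self.baseline[0] and self.baseline[1] <= self.window[1]):
            raise ValueError("baseline window must lie inside the epoch window")


@dataclass
class ErpSet:
    """Per-subject and grand-average waveforms for each condition."""

    time_s: np.ndarray
    subject_erps: dict[str, dict[str, np.ndarray]]   # condition -> subject -> waveform
    grand_average: dict[str, np.ndarray]             # condition -> waveform
    n_epochs: dict[str, dict[str, int]]              # condition -> subject -> count


def extract_epochs(
    rec: Recording,
    event_types: Sequence[str],
    window: tuple[float, float] = (-1.0, 1.0),
    channel: str = "T7",
) -> np.ndarray:
    """Epoch one channel around the named events; returns trials x samples.

    The sample window is half-open: ``[latency + round(t_pre*fs),
    latency + round(t_post*fs))``, so a ±1 s window at 256 Hz is exactly 512
    samples. Events whose window crosses the recording bounds are dropped.
    """
    ch = rec.channel_index(channel)
    lo = int(round(window[0] * rec.fs))
    hi = int(round(window[1] * rec.fs))
    if hi <= lo:
        raise ValueError("epoch window is empty")
    wanted = set(event_types)
    rows, dropped = [], 0
    for ev in rec.events:
        if ev.type not in wanted:
            continue
        a, b = ev.latency + lo, ev.latency + hi
        if a < 0 or b > rec.n_samples:
            dropped += 1
            continue
        rows.append(rec.signals[ch, a:b])
    if dropped:
        warnings.warn(f"{dropped} event(s) dropped: epoch window outside recording")
    if not rows:
        return np.empty((0, hi - lo))
    return np.vstack(rows)


def baseline_correct(
    epochs: np.ndarray,
    window: tuple[float, float],
    baseline: tuple[float, float],
    fs: float,
) -> np.ndarray:
    """Subtract each epoch's mean over the baseline interval (idempotent)."""
    lo = int(round(window[0] * fs))
    b0 = int(round(baseline[0] * fs)) - lo
    b1 = int(round(baseline[1] * fs)) - lo
    if b1 <= b0 or b0 < 0 or b1 > epochs.shape[-1]:
        raise ValueError("baseline window empty or outside the epoch window")
    base = epochs[..., b0:b1].mean(axis=-1, keepdims=True)
    return epochs - base


def smooth_moving_average(waveform: np.ndarray, w: int) -> np.ndarray:
    """Centered moving average of window ``w`` samples, edges shrink the window.

    Linear in its input and length-preserving; ``w=1`` is the identity. The
    interior response to a unit impulse is a plateau of height ``1/w``.
    """
    waveform = np.asarray(waveform, dtype=float)
    n = waveform.shape[-1]
    if w < 1:
        raise ValueError("window must be >= 1")
    if w > n:
        raise ValueError(f"window ({w}) longer than waveform ({n})")
    if w == 1:
        return waveform.copy()
    left = (w - 1) // 2
    right = w - 1 - left
    c = np.concatenate(
        [np.zeros((*waveform.shape[:-1], 1)), np.cumsum(waveform, axis=-1)], axis=-1
    )
    idx_hi = np.minimum(np.arange(n) + right + 1, n)
    idx_lo = np.maximum(np.arange(n) - left, 0)
    sums = c[..., idx_hi] - c[..., idx_lo]
    counts = idx_hi - idx_lo
    return sums / counts


def average_erps(
    recs: Mapping[str, Recording],
    params: ErpParams,
) -> ErpSet:
    """Per-subject condition averages and the unweighted grand average.

    Each subject's epochs are baseline-corrected and smoothed (moving
    average of ``round(fs/4)`` samples by default), averaged within subject,
    then averaged across subjects with equal weight per subject. Conditions
    with no epochs anywhere are omitted with a warning.
    """
    if not recs:
        raise ValueError("no recordings supplied")
    fs = next(iter(recs.values())).fs
    w = params.smooth_window if params.smooth_window is not None else int(round(fs / 4))
    lo = int(round(params.window[0] * fs))
    hi = int(round(params.window[1] * fs))
    time_s = np.arange(lo, hi) / fs
    subject_erps: dict[str, dict[str, np.ndarray]] = {}
    n_epochs: dict[str, dict[str, int]] = {}
    for cond, etype in params.conditions.items():
        per_subj: dict[str, np.ndarray] = {}
        counts: dict[str, int] = {}
        for subj, rec in recs.items():
            epochs = extract_epochs(rec, [etype], params.window, params.channel)
            if epochs.shape[0] == 0:
                continue
            epochs = baseline_correct(epochs, params.window, params.baseline, fs)
            epochs = smooth_moving_average(epochs, w)
            per_subj[subj] = epochs.mean(axis=0)
            counts[subj] = epochs.shape[0]
        if not per_subj:
            warnings.warn(f"condition {cond!r} has no epochs in any subject; omitted")
            continue
        subject_erps[cond] = per_subj
        n_epochs[cond] = counts
    grand = {
        cond: np.mean(list(per_subj.values()), axis=0)
        for cond, per_subj in subject_erps.items()
    }
    return ErpSet(time_s=time_s, subject_erps=subject_erps, grand_average=grand, n_epochs=n_epochs)


def plot_erp_grid(erps: ErpSet, out_dir: str | Path, stem: str = "oddball_erps") -> Path:
    """Short|long condition panels: thick grand averages, thin subject lines.

    Standards plot in blues, deviants in reds; x in seconds (0 = onset),
    y in microvolts.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if not erps.grand_average:
        raise ValueError("empty ERP set")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    panels = [
        ("short tones", ("std_short", "dev_short")),
        ("long tones", ("std_long", "dev_long")),
    ]
    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    palette = {"std": ("#3b6fb5", "#a8c4e4"), "dev": ("#c03030", "#e4a8a8")}
    for ax, (title, conds) in zip(axes, panels):
        for cond in conds:
            if cond not in erps.grand_average:
                continue
            fam = "std" if cond.startswith("std") else "dev"
            thick, thin = palette[fam]
            for wf in erps.subject_erps[cond].values():
                ax.plot(erps.time_s, wf, color=thin, lw=0.5)
            ax.plot(erps.time_s, erps.grand_average[cond], color=thick, lw=2.0, label=cond)
        ax.axvline(0.0, color="gray", lw=0.5)
        ax.set_title(title)
        ax.set_xlabel("time (s)")
        ax.legend(fontsize=8)
    axes[0].set_ylabel("$\\mu$V")
    path = out_dir / f"{stem}.png"
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path
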