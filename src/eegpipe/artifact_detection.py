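"""Detectors for bad channels, bad independent components, and blink events.

Every detector is pure — it scores the items of one kind (channels,
components, events), applies its thresholds, and returns a
:class:`DetectionResult` with all raw scores retained, so quality-control
reports and the parameter sweep can re-examine the decision. The only
exception is :func:`detect_blink_events`, which by contract appends the
blink events it finds to a copy of the recording.

Channel scoring follows the robust variance convention: a channel's variance
is expressed in units of the median absolute deviation (MAD) of all channel
variances from their median. Bounds like ``[-5, 2.5]`` are in those MAD
units — no Gaussian consistency constant is applied. The multi-metric IC
detector, by contrast, emulates z-score thresholding and therefore scales
its MAD by 1.4826.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.signal
import scipy.stats

from .preprocessing_ops import ic_activations
from .recording_io import Event, Recording

__all__ = [
    "BlinkTemplate",
    "DetectionResult",
    "apply_fraction_cap",
    "build_blink_template",
    "detect_bad_channels_spectral",
    "detect_bad_channels_variance",
    "detect_bad_ics_multimetric",
    "detect_blink_events",
    "detect_blink_ics",
    "mad",
]

BLINK_EVENT_TYPE = "blink"


def mad(x: np.ndarray, consistency: bool = False) -> float:
    """Median absolute deviation from the median; optionally x1.4826."""
    x = np.asarray(x, dtype=float)
    m = float(np.median(np.abs(x - np.median(x))))
    return m * 1.4826 if consistency else m


@dataclass
class DetectionResult:
    """Scores, thresholds, and the flagged subset for one detector run."""

    kind: str                                   # channels | components | events
    item_ids: list
    scores: Mapping[str, np.ndarray]
    flagged: list
    params: Mapping[str, object] = field(default_factory=dict)
    method: str = ""
    primary_metric: str = ""

    def __post_init__(self):
        ids = set(self.item_ids)
        if not set(self.flagged) <= ids:
            raise ValueError("flagged items must be a subset of item_ids")

    @property
    def n_flagged(self) -> int:
        return len(self.flagged)


@dataclass(frozen=True)
class BlinkTemplate:
    """Average peri-blink VEOG waveform used to score components."""

    waveform: np.ndarray          # microvolts over the window
    window: tuple[float, float]   # (pre_s, post_s), pre negative
    n_blinks: int

    def __post_init__(self):
        if self.n_blinks < 3:
            raise ValueError("blink template requires at least 3 blink events")


# ---------------------------------------------------------------------------
# blinks
# ---------------------------------------------------------------------------

def _veog_trace(rec: Recording, veog_labels: Sequence[str]) -> np.ndarray:
    idx = [rec.channel_index(lab) for lab in veog_labels]
    return rec.signals[idx].mean(axis=0)


def detect_blink_events(
    rec: Recording,
    veog_labels: Sequence[str],
    k: float = 5.0,
    band_hz: tuple[float, float] = (0.5, 5.0),
    refractory_s: float = 0.5,
):
    """Find blink latencies on the VEOG channel(s); returns ``(rec2, result)``.

    The VEOG trace is band-passed to the blink band and peaks exceeding
    ``k`` times the MAD of the filtered trace, separated by the refractory
    period, become blink events. MAD scaling makes the threshold invariant
    to overall amplitude.
    """
    if isinstance(veog_labels, str):
        veog_labels = [veog_labels]
    veog = _veog_trace(rec, veog_labels)
    sos = scipy.signal.butter(3, band_hz, btype="bandpass", fs=rec.fs, output="sos")
    filt = scipy.signal.sosfiltfilt(sos, veog)
    scale = mad(filt)
    if scale == 0:
        peaks = np.array([], dtype=int)
    else:
        peaks, _ = scipy.signal.find_peaks(
            filt, height=k * scale, distance=max(1, int(round(refractory_s * rec.fs)))
        )
    out = rec.copy()
    existing = {(e.latency, e.type) for e in out.events}
    new_events = [
        Event(int(p), BLINK_EVENT_TYPE)
        for p in peaks
        if (int(p), BLINK_EVENT_TYPE) not in existing
    ]
    out.events = sorted(out.events + new_events, key=lambda e: e.latency)
    det = DetectionResult(
        kind="events",
        item_ids=[int(p) for p in peaks],
        scores={"amplitude": filt[peaks] if len(peaks) else np.array([])},
        flagged=[int(p) for p in peaks],
        params={"k": k, "band_hz": list(band_hz), "refractory_s": refractory_s},
        method="veog_mad_peaks",
        primary_metric="amplitude",
    )
    return out, det


def blink_latencies(rec: Recording) -> list[int]:
    return [e.latency for e in rec.events if e.type == BLINK_EVENT_TYPE]


def _epoch_matrix(trace: np.ndarray, latencies: Sequence[int], lo: int, hi: int) -> np.ndarray:
    """Stack trace[lat+lo : lat+hi) for every latency fully inside bounds."""
    rows = [trace[lat + lo : lat + hi] for lat in latencies if lat + lo >= 0 and lat + hi <= len(trace)]
    if not rows:
        return np.empty((0, hi - lo))
    return np.vstack(rows)


def build_blink_template(
    rec: Recording,
    veog_labels: Sequence[str],
    window: tuple[float, float] = (-0.3, 0.5),
) -> BlinkTemplate:
    """Average the VEOG waveform around detected blink events."""
    if isinstance(veog_labels, str):
        veog_labels = [veog_labels]
    lats = blink_latencies(rec)
    if len(lats) < 3:
        raise ValueError(f"need >=3 blink events to build a template, have {len(lats)}")
    lo = int(round(window[0] * rec.fs))
    hi = int(round(window[1] * rec.fs))
    veog = _veog_trace(rec, veog_labels)
    epochs = _epoch_matrix(veog, lats, lo, hi)
    if epochs.shape[0] < 3:
        raise ValueError("fewer than 3 blink events fit inside the recording")
    return BlinkTemplate(waveform=epochs.mean(axis=0), window=window, n_blinks=epochs.shape[0])


def detect_blink_ics(
    rec: Recording,
    template: BlinkTemplate,
    r_threshold: float = 0.7,
) -> DetectionResult:
    """Flag components whose blink-locked average activation matches the template.

    Score is the absolute Pearson correlation between each component's
    average activation around blink events and the VEOG template; components
    scoring above ``r_threshold`` are flagged.
    """
    if rec.ica is None:
        raise ValueError("detect_blink_ics requires an ICA decomposition")
    lats = blink_latencies(rec)
    ids = list(range(rec.ica.n_components))
    if not lats:
        warnings.warn("no blink events present; blink-IC detection returns empty")
        return DetectionResult(
            kind="components",
            item_ids=ids,
            scores={"template_correlation": np.zeros(len(ids))},
            flagged=[],
            params={"r_threshold": r_threshold},
            method="blink_template",
            primary_metric="template_correlation",
        )
    lo = int(round(template.window[0] * rec.fs))
    hi = int(round(template.window[1] * rec.fs))
    acts = ic_activations(rec)
    scores = np.zeros(len(ids))
    t = template.waveform
    for i in ids:
        epochs = _epoch_matrix(acts[i], lats, lo, hi)
        if epochs.shape[0] == 0 or np.ptp(epochs.mean(axis=0)) == 0:
            continue
        avg = epochs.mean(axis=0)
        m = min(len(avg), len(t))
        r = np.corrcoef(avg[:m], t[:m])[0, 1]
        scores[i] = abs(r) if np.isfinite(r) else 0.0
    flagged = [i for i in ids if scores[i] > r_threshold]
    return DetectionResult(
        kind="components",
        item_ids=ids,
        scores={"template_correlation": scores},
        flagged=flagged,
        params={"r_threshold": r_threshold, "n_blinks": len(lats)},
        method="blink_template",
        primary_metric="template_correlation",
    )


# ---------------------------------------------------------------------------
# multi-metric IC detector (FASTER-style emulation)
# ---------------------------------------------------------------------------

def _metric_median_gradient(acts: np.ndarray, rec: Recording) -> np.ndarray:
    return np.median(np.abs(np.diff(acts, axis=1)), axis=1)


def _metric_spatial_kurtosis(acts: np.ndarray, rec: Recording) -> np.ndarray:
    eeg = rec.picks("eeg")
    maps = rec.ica.mixing[eeg]  # channels x components
    return scipy.stats.kurtosis(maps, axis=0, fisher=True, bias=True)


def _metric_spectral_slope(acts: np.ndarray, rec: Recording) -> np.ndarray:
    f_lo, f_hi = 8.0, rec.fs / 4.0
    nper = min(acts.shape[1], int(rec.fs * 2))
    freqs, psd = scipy.signal.welch(acts, fs=rec.fs, nperseg=nper, axis=1)
    band = (freqs >= f_lo) & (freqs <= f_hi)
    logf = np.log10(freqs[band])
    out = np.empty(acts.shape[0])
    for i in range(acts.shape[0]):
        logp = np.log10(np.maximum(psd[i, band], 1e-30))
        out[i] = np.polyfit(logf, logp, 1)[0]
    return out


def _metric_hurst(acts: np.ndarray, rec: Recording) -> np.ndarray:
    """Hurst exponent by rescaled-range analysis over dyadic window sizes."""
    n = acts.shape[1]
    sizes = [s for s in (64, 128, 256, 512, 1024, 2048) if s <= n // 4]
    if len(sizes) < 2:
        sizes = [max(8, n // 8), max(16, n // 4)]
    out = np.empty(acts.shape[0])
    for i, x in enumerate(acts):
        rs = []
        for s in sizes:
            nwin = n // s
            segs = x[: nwin * s].reshape(nwin, s)
            dev = segs - segs.mean(axis=1, keepdims=True)
            cum = np.cumsum(dev, axis=1)
            rng = cum.max(axis=1) - cum.min(axis=1)
            std = segs.std(axis=1)
            ok = std > 0
            rs.append(np.mean(rng[ok] / std[ok]) if ok.any() else 1.0)
        out[i] = np.polyfit(np.log(sizes), np.log(np.maximum(rs, 1e-12)), 1)[0]
    return out


def _metric_eog_correlation(acts: np.ndarray, rec: Recording) -> np.ndarray:
    eog = rec.picks("eog")
    if not eog:
        raise ValueError("eog_correlation metric requires EOG channels")
    eog_sig = rec.signals[eog]
    out = np.zeros(acts.shape[0])
    for i, a in enumerate(acts):
        sa = a.std()
        if sa == 0:
            continue
        cors = [
            abs(np.corrcoef(a, e)[0, 1]) for e in eog_sig if e.std() > 0
        ]
        out[i] = max(cors) if cors else 0.0
    return out


_IC_METRICS = {
    "median_gradient": _metric_median_gradient,
    "spatial_kurtosis": _metric_spatial_kurtosis,
    "spectral_slope": _metric_spectral_slope,
    "hurst_exponent": _metric_hurst,
    "eog_correlation": _metric_eog_correlation,
}


def detect_bad_ics_multimetric(
    rec: Recording,
    metrics: Sequence[str] = ("median_gradient", "spatial_kurtosis", "spectral_slope", "hurst_exponent"),
    z_threshold: float = 3.0,
    match_logic: str = "any",
) -> DetectionResult:
    """Flag components that are outliers on several statistical features.

    Each metric is computed per component and robust-z-scored across
    components (median/MAD x 1.4826); a component exceeds a metric at
    ``|z| > z_threshold``. ``match_logic='any'`` flags the union of
    per-metric flags (liberal), ``'all'`` the intersection (conservative).
    """
    if rec.ica is None:
        raise ValueError("multimetric IC detection requires an ICA decomposition")
    if match_logic not in ("any", "all"):
        raise ValueError(f"match_logic must be 'any' or 'all', got {match_logic!r}")
    unknown = [m for m in metrics if m not in _IC_METRICS]
    if unknown:
        raise ValueError(f"unknown IC metric(s): {unknown}")
    n = rec.ica.n_components
    if n < 4:
        raise ValueError(f"need >=4 components for cross-component z-scores, have {n}")
    acts = ic_activations(rec)
    ids = list(range(n))
    scores: dict[str, np.ndarray] = {}
    zsets = []
    for name in metrics:
        vals = np.asarray(_IC_METRICS[name](acts, rec), dtype=float)
        scores[name] = vals
        scale = mad(vals, consistency=True)
        z = np.zeros(n) if scale == 0 else (vals - np.median(vals)) / scale
        scores[f"z_{name}"] = z
        zsets.append({i for i in ids if abs(z[i]) > z_threshold})
    if match_logic == "any":
        flagged = set().union(*zsets)
    else:
        flagged = set(ids).intersection(*zsets)
    return DetectionResult(
        kind="components",
        item_ids=ids,
        scores=scores,
        flagged=sorted(flagged),
        params={"metrics": list(metrics), "z_threshold": z_threshold, "match_logic": match_logic},
        method="multimetric",
        primary_metric=f"z_{metrics[0]}",
    )


# ---------------------------------------------------------------------------
# bad channels
# ---------------------------------------------------------------------------

def _as_bounds(bounds) -> tuple[float, float]:
    """Scalar t expands to symmetric bounds [-t, +t]."""
    if np.isscalar(bounds):
        t = float(bounds)
        if t <= 0:
            raise ValueError("scalar bounds must be positive")
        return (-t, t)
    b_lo, b_hi = float(bounds[0]), float(bounds[1])
    if b_lo >= b_hi:
        raise ValueError(f"bounds [{b_lo}, {b_hi}] are not increasing")
    return (b_lo, b_hi)


def detect_bad_channels_variance(
    rec: Recording,
    bounds=(-5.0, 2.5),
    fraction_cap: float | None = None,
) -> DetectionResult:
    """Flag channels whose variance is an outlier in MAD units.

    Each EEG channel's full-signal variance ``v_c`` is scored as
    ``s_c = (v_c - median(v)) / MAD(v)`` and flagged outside
    ``[b_lo, b_hi]``. A scalar ``bounds`` t means symmetric ``[-t, +t]``,
    catching flat channels as well as noisy ones. The score is invariant
    to global amplitude scaling.
    """
    eeg = rec.picks("eeg")
    if len(eeg) < 4:
        raise ValueError(f"variance detection needs >=4 EEG channels, have {len(eeg)}")
    b_lo, b_hi = _as_bounds(bounds)
    labels = [rec.channels[i].label for i in eeg]
    v = rec.signals[eeg].var(axis=1)
    scale = mad(v)
    if scale == 0:
        warnings.warn("all channel variances identical (MAD=0); no channel flagged")
        s = np.zeros(len(eeg))
        flagged: list[str] = []
    else:
        s = (v - np.median(v)) / scale
        flagged = [lab for lab, sc in zip(labels, s) if sc < b_lo or sc > b_hi]
    det = DetectionResult(
        kind="channels",
        item_ids=labels,
        scores={"variance_mad": s, "variance": v},
        flagged=flagged,
        params={"b_lo": b_lo, "b_hi": b_hi},
        method="variance",
        primary_metric="variance_mad",
    )
    if fraction_cap is not None:
        det = apply_fraction_cap(det, fraction_cap)
    return det


def detect_bad_channels_spectral(
    rec: Recording,
    bands: Sequence[tuple[float, float]] = ((0.0, 2.0), (20.0, 40.0)),
    db_bounds: tuple[float, float] = (-5.0, 5.0),
) -> DetectionResult:
    """Flag channels whose band power deviates from the channel mean in dB.

    Per channel, band power is the Welch power averaged inside each band,
    in dB (log of the band mean, so narrowband lines are not diluted); a
    channel is flagged if its deviation from the across-channel mean falls
    outside ``db_bounds`` in any band. Defaults target drift/flat channels
    (0-2 Hz) and muscle/line noise (20-40 Hz).
    """
    eeg = rec.picks("eeg")
    labels = [rec.channels[i].label for i in eeg]
    nyq = rec.fs / 2
    for f_lo, f_hi in bands:
        if f_hi > nyq:
            raise ValueError(f"band ({f_lo}, {f_hi}) Hz exceeds Nyquist {nyq} Hz")
    d_lo, d_hi = float(db_bounds[0]), float(db_bounds[1])
    nper = min(rec.n_samples, int(rec.fs * 2))
    freqs, psd = scipy.signal.welch(rec.signals[eeg], fs=rec.fs, nperseg=nper, axis=1)
    scores: dict[str, np.ndarray] = {}
    flagged: set[str] = set()
    for f_lo, f_hi in bands:
        sel = (freqs >= f_lo) & (freqs <= f_hi)
        band_db = 10 * np.log10(np.maximum(psd[:, sel].mean(axis=1), 1e-30))
        dev = band_db - band_db.mean()
        scores[f"db_dev_{f_lo:g}_{f_hi:g}"] = dev
        flagged |= {lab for lab, d in zip(labels, dev) if d < d_lo or d > d_hi}
    first = next(iter(scores))
    return DetectionResult(
        kind="channels",
        item_ids=labels,
        scores=scores,
        flagged=[lab for lab in labels if lab in flagged],
        params={"bands": [list(b) for b in bands], "d_lo": d_lo, "d_hi": d_hi},
        method="spectral",
        primary_metric=first,
    )


def apply_fraction_cap(det: DetectionResult, f: float) -> DetectionResult:
    """Constrain a detection to the worst ``floor(f * n_items)`` items.

    Keeps the capped number of flagged items with the largest absolute
    primary score; ties break by item order. A 254-channel montage capped
    at 0.05 keeps at most 12 channels.
    """
    if not (0 < f <= 1):
        raise ValueError(f"fraction cap must be in (0, 1], got {f}")
    cap = int(np.floor(f * len(det.item_ids)))
    params = dict(det.params)
    params.update({"fraction_cap": f, "cap": cap})
    if len(det.flagged) <= cap:
        return DetectionResult(
            det.kind, det.item_ids, det.scores, list(det.flagged), params, det.method, det.primary_metric
        )
    score = np.asarray(det.scores[det.primary_metric], dtype=float)
    pos = {item: i for i, item in enumerate(det.item_ids)}
    order = sorted(det.flagged, key=lambda it: (-abs(score[pos[it]]), pos[it]))
    return DetectionResult(
        det.kind, det.item_ids, det.scores, order[:cap], params, det.method, det.primary_metric
    )
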