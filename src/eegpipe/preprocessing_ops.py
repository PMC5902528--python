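"""Signal-level pipeline steps: referencing, filtering, ICA, rejection.

All operations are functional — they return a new :class:`Recording`, append
exactly one history entry, and never touch the event list. Detection lives in
:mod:`eegpipe.artifact_detection`; the operations here consume its
:class:`DetectionResult` objects to reject or correct data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.signal

from .recording_io import IcaDecomposition, Recording, history_entry

__all__ = [
    "RejectionRecord",
    "check_spatial_clustering",
    "filter_blink_ics",
    "highpass_filter",
    "ica_decompose",
    "reject_channels",
    "reject_components",
    "rereference",
    "spline_interpolation_matrix",
]


@dataclass(frozen=True)
class RejectionRecord:
    """What was rejected/corrected, by which method, and how much of the total."""

    kind: str                      # channels | components | epochs | segments
    items: tuple                   # labels or indices
    method: str
    params: Mapping[str, object] = field(default_factory=dict)
    fraction_of_total: float = 0.0

    def __post_init__(self):
        if not self.items:
            raise ValueError("RejectionRecord requires a non-empty item set")
        if not (0.0 <= self.fraction_of_total <= 1.0):
            raise ValueError("fraction_of_total must lie in [0, 1]")


# ---------------------------------------------------------------------------
# referencing and filtering
# ---------------------------------------------------------------------------

def rereference(rec: Recording, scheme: str | Sequence[str] = "average") -> Recording:
    """Re-reference EEG channels to the average of EEG channels or to named ones.

    EOG channels are excluded from the reference computation but still have
    the reference subtracted, so ocular potentials stay comparable to scalp
    channels.
    """
    eeg = rec.picks("eeg")
    if len(eeg) < 2:
        raise ValueError("re-referencing requires at least 2 EEG channels")
    out = rec.copy()
    if isinstance(scheme, str) and scheme == "average":
        ref = out.signals[eeg].mean(axis=0)
        scheme_desc: object = "average"
    else:
        labels = [scheme] if isinstance(scheme, str) else list(scheme)
        idx = [rec.channel_index(lab) for lab in labels]
        ref = out.signals[idx].mean(axis=0)
        scheme_desc = labels
    apply_to = [i for i, c in enumerate(rec.channels) if c.kind in ("eeg", "eog")]
    out.signals[apply_to] -= ref[None, :]
    return out.with_history(
        history_entry("rereference", {"scheme": scheme_desc}, f"referenced {len(apply_to)} channels")
    )


def _fir_highpass(fs: float, cutoff_hz: float, transition_hz: float) -> np.ndarray:
    numtaps = int(np.ceil(3.3 * fs / transition_hz))
    numtaps += 1 - numtaps % 2  # odd length for a type-I (allpass-capable) FIR
    return scipy.signal.firwin(numtaps, cutoff_hz, window="hamming", pass_zero=False, fs=fs)


def highpass_filter(rec: Recording, cutoff_hz: float = 1.0, transition_hz: float = 1.0) -> Recording:
    """Zero-phase FIR high-pass; removes DC and drift before ICA.

    Hamming-window FIR applied forward-backward, so the effective attenuation
    is doubled and the phase response is exactly zero.
    """
    if cutoff_hz >= rec.fs / 2:
        raise ValueError(f"cutoff {cutoff_hz} Hz >= Nyquist ({rec.fs / 2} Hz)")
    if cutoff_hz <= 0 or transition_hz <= 0:
        raise ValueError("cutoff and transition width must be positive")
    taps = _fir_highpass(rec.fs, cutoff_hz, transition_hz)
    out = rec.copy()
    padlen = min(3 * len(taps), rec.n_samples - 1)
    out.signals = scipy.signal.filtfilt(taps, [1.0], out.signals, axis=1, padlen=padlen)
    return out.with_history(
        history_entry(
            "highpass_filter",
            {"cutoff_hz": cutoff_hz, "transition_hz": transition_hz, "n_taps": len(taps)},
            f"high-passed at {cutoff_hz} Hz",
        )
    )


# ---------------------------------------------------------------------------
# ICA
# ---------------------------------------------------------------------------

def ica_decompose(
    rec: Recording,
    n_components: int | str = "all",
    algorithm: str = "fastica",
    seed: int = 0,
) -> Recording:
    """Fit a seeded fixed-point ICA on the EEG+EOG channels, store the unmixing.

    EOG channels are included so ocular components load on them and ocular
    correction propagates to the EOG traces; other channel kinds pass through
    untouched when components are rejected. With ``n_components`` equal to
    the data rank the decomposition reconstructs the signals to numerical
    precision.
    """
    import warnings

    from sklearn.decomposition import FastICA

    if algorithm != "fastica":
        raise ValueError(f"unknown ICA algorithm {algorithm!r}")
    if not any(h.op_name == "highpass_filter" for h in rec.history):
        warnings.warn("ICA on data with no highpass step in history; drift may dominate")
    eeg = rec.picks("eeg") + rec.picks("eog")
    X = rec.signals[eeg]  # channels x samples
    rank = int(np.linalg.matrix_rank(X @ X.T / X.shape[1]))
    if n_components == "all":
        k = rank
    else:
        k = int(n_components)
        if k <= 0:
            raise ValueError("n_components must be positive")
        if k > rank:
            warnings.warn(f"requested {k} components but rank is {rank}; reducing")
            k = rank
    ica = FastICA(
        n_components=k,
        whiten="unit-variance",
        max_iter=1000,
        tol=1e-7,
        random_state=int(seed),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ica.fit(X.T)
    # components_ maps centred data to sources; mixing_ maps sources back.
    # After the highpass step channel means are ~0, so the centring offset
    # is negligible and the matrices act directly in channel space.
    unmix_eeg = ica.components_
    mix_eeg = ica.mixing_
    n_ch = rec.n_channels
    unmixing = np.zeros((k, n_ch))
    mixing = np.zeros((n_ch, k))
    for j, ch in enumerate(eeg):
        unmixing[:, ch] = unmix_eeg[:, j]
        mixing[ch, :] = mix_eeg[j, :]
    out = rec.copy()
    out.ica = IcaDecomposition(unmixing=unmixing, mixing=mixing, retained=list(range(k)))
    err = _reconstruction_error(out)
    return out.with_history(
        history_entry(
            "ica_decompose",
            {"n_components": k, "algorithm": algorithm, "seed": int(seed)},
            f"{k} components, relative reconstruction error {err:.2e}",
        )
    )


def ic_activations(rec: Recording) -> np.ndarray:
    """Component activations (components x samples) for the stored decomposition."""
    if rec.ica is None:
        raise ValueError("recording has no ICA decomposition")
    return rec.ica.unmixing @ rec.signals


def _reconstruction_error(rec: Recording) -> float:
    eeg = rec.picks("eeg") + rec.picks("eog")
    X = rec.signals[eeg]
    Xc = X - X.mean(axis=1, keepdims=True)
    recon = (rec.ica.mixing @ (rec.ica.unmixing @ rec.signals))[eeg]
    recon -= recon.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(Xc)
    return float(np.linalg.norm(Xc - recon) / denom) if denom > 0 else 0.0


# ---------------------------------------------------------------------------
# spherical-spline interpolation (Perrin 1989)
# ---------------------------------------------------------------------------

def _g_matrix(cosang: np.ndarray, stiffness: int = 4, n_terms: int = 50) -> np.ndarray:
    """Perrin g(cos) kernel via a truncated Legendre series."""
    n = np.arange(1, n_terms + 1, dtype=float)
    coeff = (2 * n + 1) / (n ** stiffness * (n + 1) ** stiffness) / (4 * np.pi)
    c = np.concatenate([[0.0], coeff])  # no constant term
    return np.polynomial.legendre.legval(np.clip(cosang, -1.0, 1.0), c)


def spline_interpolation_matrix(
    good_pos: np.ndarray,
    bad_pos: np.ndarray,
    stiffness: int = 4,
    reg: float = 1e-5,
) -> np.ndarray:
    """Matrix mapping good-channel data to spherical-spline estimates at bad sites."""
    good_pos = good_pos / np.linalg.norm(good_pos, axis=1, keepdims=True)
    bad_pos = bad_pos / np.linalg.norm(bad_pos, axis=1, keepdims=True)
    G = _g_matrix(good_pos @ good_pos.T, stiffness)
    Gb = _g_matrix(bad_pos @ good_pos.T, stiffness)
    ng = len(good_pos)
    G = G + reg * np.eye(ng)
    ones = np.ones((ng, 1))
    C = np.block([[G, ones], [ones.T, np.zeros((1, 1))]])
    C_inv = np.linalg.pinv(C)
    return np.hstack([Gb, np.ones((len(bad_pos), 1))]) @ C_inv[:, :ng]


# ---------------------------------------------------------------------------
# rejection / correction
# ---------------------------------------------------------------------------

def reject_channels(rec: Recording, det, interpolate: bool = True):
    """Interpolate (or drop) the channels a detector flagged.

    Returns ``(recording, rejection_record_or_None)``. Interpolation is the
    Perrin spherical spline over the remaining EEG channels and requires
    positions; more than 50% flagged leaves too little support and errors.
    """
    if det.kind != "channels":
        raise ValueError(f"detector result of kind {det.kind!r}, expected 'channels'")
    flagged = [lab for lab in det.flagged]
    if not flagged:
        out = rec.copy().with_history(
            history_entry("reject_channels", {"flagged": [], "interpolate": interpolate}, "0 flagged")
        )
        return out, None
    eeg = rec.picks("eeg")
    if len(flagged) > 0.5 * len(eeg):
        raise ValueError(
            f"{len(flagged)} of {len(eeg)} EEG channels flagged: insufficient support to interpolate"
        )
    flag_idx = [rec.channel_index(lab) for lab in flagged]
    out = rec.copy()
    if interpolate:
        good_idx = [i for i in eeg if i not in flag_idx]
        M = spline_interpolation_matrix(rec.positions(good_idx), rec.positions(flag_idx))
        out.signals[flag_idx] = M @ out.signals[good_idx]
        action = "interpolated"
    else:
        keep = [i for i in range(rec.n_channels) if i not in flag_idx]
        out.signals = out.signals[keep]
        out.channels = [rec.channels[i] for i in keep]
        if out.ica is not None:
            out.ica = None  # channel basis changed; decomposition invalid
        action = "dropped"
    record = RejectionRecord(
        kind="channels",
        items=tuple(flagged),
        method=det.method,
        params=dict(det.params),
        fraction_of_total=len(flagged) / len(eeg),
    )
    out.with_history(
        history_entry(
            "reject_channels",
            {"flagged": flagged, "interpolate": interpolate, "method": det.method},
            f"{action} {len(flagged)}/{len(eeg)} channels",
        )
    )
    return out, record


def reject_components(rec: Recording, det):
    """Reconstruct the signals without the flagged independent components."""
    if rec.ica is None:
        raise ValueError("reject_components requires an ICA decomposition")
    if det.kind != "components":
        raise ValueError(f"detector result of kind {det.kind!r}, expected 'components'")
    flagged = sorted(int(i) for i in det.flagged)
    n = rec.ica.n_components
    if len(flagged) >= n:
        raise ValueError("all components flagged; nothing would remain")
    out = rec.copy()
    if not flagged:
        return (
            out.with_history(
                history_entry("reject_components", {"flagged": []}, "0 flagged")
            ),
            None,
        )
    acts = ic_activations(rec)
    out.signals = out.signals - rec.ica.mixing[:, flagged] @ acts[flagged]
    out.ica.retained = [i for i in rec.ica.retained if i not in flagged]
    record = RejectionRecord(
        kind="components",
        items=tuple(flagged),
        method=det.method,
        params=dict(det.params),
        fraction_of_total=len(flagged) / n,
    )
    out.with_history(
        history_entry(
            "reject_components",
            {"flagged": flagged, "method": det.method},
            f"removed {len(flagged)}/{n} components",
        )
    )
    return out, record


def filter_blink_ics(
    rec: Recording,
    blink_ics: Sequence[int],
    cutoff_hz: float = 4.0,
):
    """Correct blink components by filtering instead of wholesale removal.

    The flagged components' activation time courses are zero-phase high-pass
    filtered at ``cutoff_hz`` (the blink potential lives below ~4 Hz) and
    back-projected, so any genuine high-frequency brain signal the component
    carries is kept. Non-flagged component activations are untouched.
    """
    import warnings

    if rec.ica is None:
        raise ValueError("filter_blink_ics requires an ICA decomposition")
    blink_ics = sorted(int(i) for i in blink_ics)
    out = rec.copy()
    if not blink_ics:
        warnings.warn("filter_blink_ics called with no blink components; no-op")
        return (
            out.with_history(history_entry("filter_blink_ics", {"blink_ics": []}, "no-op")),
            None,
        )
    acts = ic_activations(rec)[blink_ics]
    sos = scipy.signal.butter(4, cutoff_hz, btype="highpass", fs=rec.fs, output="sos")
    filtered = scipy.signal.sosfiltfilt(sos, acts, axis=1)
    out.signals = out.signals + rec.ica.mixing[:, blink_ics] @ (filtered - acts)
    record = RejectionRecord(
        kind="components",
        items=tuple(blink_ics),
        method="blink_ic_filter",
        params={"cutoff_hz": cutoff_hz},
        fraction_of_total=len(blink_ics) / rec.ica.n_components,
    )
    out.with_history(
        history_entry(
            "filter_blink_ics",
            {"blink_ics": blink_ics, "cutoff_hz": cutoff_hz},
            f"filtered {len(blink_ics)} blink component(s)",
        )
    )
    return out, record


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def check_spatial_clustering(flagged: Sequence[str], rec: Recording) -> dict:
    """Warn when flagged channels form a co-located cluster.

    Interpolation borrows from neighbours; a contiguous patch of bad channels
    has no nearby good support. Dispersion is the mean, over flagged channels,
    of the great-circle distance to the nearest non-flagged EEG channel,
    normalized by the montage's median nearest-neighbour distance. Values
    above 1.5 trigger the warning flag.
    """
    flagged = list(flagged)
    if not flagged:
        return {"dispersion": 0.0, "warning": False}
    eeg = rec.picks("eeg")
    labels = rec.labels()
    flag_idx = [rec.channel_index(lab) for lab in flagged]
    good_idx = [i for i in eeg if i not in flag_idx]
    if not good_idx:
        return {"dispersion": float("inf"), "warning": True}
    pos_all = rec.positions(eeg)
    pos_all /= np.linalg.norm(pos_all, axis=1, keepdims=True)
    ang = np.arccos(np.clip(pos_all @ pos_all.T, -1, 1))
    np.fill_diagonal(ang, np.inf)
    median_nn = float(np.median(ang.min(axis=1)))
    row = {ch: k for k, ch in enumerate(eeg)}
    dists = []
    for i in flag_idx:
        if i not in row:
            continue
        d = min(ang[row[i], row[j]] for j in good_idx)
        dists.append(d)
    dispersion = float(np.mean(dists) / median_nn) if dists else 0.0
    return {"dispersion": dispersion, "warning": dispersion > 1.5, "flagged": [labels[i] for i in flag_idx]}
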