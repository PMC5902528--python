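"""Raw EEG input, measurement configuration, and pipeline state persistence.

A measurement batch is described either by scanning a directory of EDF/BDF
files or by a subject/recording sheet. Continuous data lives in a
:class:`Recording` — a plain channels-by-samples matrix in microvolts with
channel metadata, events, an optional ICA decomposition, and an append-only
operation history that every pipeline step extends. State between step sets
is persisted to an HDF5 container whose round trip is bit-exact on signals
and value-exact on events/history.
"""

from __future__ import annotations

import datetime as _dt
import fnmatch
import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

STATE_FORMAT_VERSION = 1

__all__ = [
    "Channel",
    "Event",
    "HistoryEntry",
    "IcaDecomposition",
    "MeasurementConfig",
    "MeasurementEntry",
    "Recording",
    "load_measurement_sheet",
    "load_state",
    "read_channel_locations",
    "read_raw",
    "save_state",
    "scan_measurement_dir",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Channel:
    """One electrode: label, optional unit-sphere position, signal kind."""

    label: str
    position: tuple[float, float, float] | None = None
    kind: str = "eeg"  # "eeg" | "eog" | "other"


@dataclass(frozen=True)
class Event:
    """A trigger: 0-based sample latency, condition string, duration in samples."""

    latency: int
    type: str
    duration: int = 0


@dataclass(frozen=True)
class HistoryEntry:
    op_name: str
    args: Mapping[str, object]
    timestamp: str
    outcome_summary: str = ""

    def to_json(self) -> str:
        return json.dumps(
            {
                "op_name": self.op_name,
                "args": _jsonify(self.args),
                "timestamp": self.timestamp,
                "outcome_summary": self.outcome_summary,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "HistoryEntry":
        d = json.loads(s)
        return cls(d["op_name"], d["args"], d["timestamp"], d.get("outcome_summary", ""))


def _jsonify(obj):
    """Serialize step arguments losslessly; fail loudly on opaque objects."""
    if isinstance(obj, Mapping):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if obj is None or isinstance(obj, (bool, int, float, str)):
        return obj
    raise TypeError(f"history argument of type {type(obj).__name__} is not serializable")


def history_entry(op_name: str, args: Mapping[str, object], summary: str = "") -> HistoryEntry:
    args = _jsonify(args)  # raises before any computation if not serializable
    return HistoryEntry(
        op_name=op_name,
        args=args,
        timestamp=_dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds"),
        outcome_summary=summary,
    )


@dataclass
class IcaDecomposition:
    """Linear unmixing of channels into sources plus the retained source set."""

    unmixing: np.ndarray  # components x channels
    mixing: np.ndarray    # channels x components
    retained: list[int]

    @property
    def n_components(self) -> int:
        return self.unmixing.shape[0]

    def copy(self) -> "IcaDecomposition":
        return IcaDecomposition(self.unmixing.copy(), self.mixing.copy(), list(self.retained))


@dataclass
class Recording:
    """Continuous multichannel EEG in microvolts with full provenance."""

    signals: np.ndarray  # channels x samples, float64, microvolts
    fs: float
    channels: list[Channel]
    events: list[Event] = field(default_factory=list)
    ica: IcaDecomposition | None = None
    history: list[HistoryEntry] = field(default_factory=list)
    peek_latencies: list[int] | None = None
    subject_id: str = ""
    measurement_id: str = ""

    def __post_init__(self):
        self.signals = np.asarray(self.signals, dtype=np.float64)
        if self.signals.ndim != 2:
            raise ValueError("signals must be 2-D (channels x samples)")
        if self.signals.shape[0] != len(self.channels):
            raise ValueError(
                f"signal rows ({self.signals.shape[0]}) != channel count ({len(self.channels)})"
            )
        for ev in self.events:
            if not (0 <= ev.latency < self.n_samples):
                raise ValueError(f"event latency {ev.latency} outside [0, {self.n_samples})")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def labels(self) -> list[str]:
        return [c.label for c in self.channels]

    def channel_index(self, label: str) -> int:
        try:
            return self.labels().index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not present") from None

    def picks(self, kind: str) -> list[int]:
        return [i for i, c in enumerate(self.channels) if c.kind == kind]

    def positions(self, idx: Iterable[int] | None = None) -> np.ndarray:
        idx = range(self.n_channels) if idx is None else idx
        out = []
        for i in idx:
            pos = self.channels[i].position
            if pos is None:
                raise ValueError(f"channel {self.channels[i].label!r} has no position")
            out.append(pos)
        return np.asarray(out, dtype=float)

    def copy(self) -> "Recording":
        return Recording(
            signals=self.signals.copy(),
            fs=self.fs,
            channels=list(self.channels),
            events=list(self.events),
            ica=self.ica.copy() if self.ica is not None else None,
            history=list(self.history),
            peek_latencies=list(self.peek_latencies) if self.peek_latencies is not None else None,
            subject_id=self.subject_id,
            measurement_id=self.measurement_id,
        )

    def with_history(self, entry: HistoryEntry) -> "Recording":
        self.history = list(self.history) + [entry]
        return self


@dataclass(frozen=True)
class MeasurementEntry:
    subject_id: str
    session: str
    measurement_id: str
    eeg_path: Path
    loc_path: Path | None = None
    metadata: Mapping[str, object] = field(default_factory=dict)


@dataclass
class MeasurementConfig:
    entries: list[MeasurementEntry]

    def __post_init__(self):
        if not self.entries:
            raise ValueError("measurement config is empty: no recordings to process")
        ids = [e.measurement_id for e in self.entries]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise ValueError(f"duplicate measurement ids: {dupes}")

    def __iter__(self):
        return iter(self.entries)

    def __len__(self):
        return len(self.entries)

    def subset(self, subjects: Sequence[str]) -> "MeasurementConfig":
        keep = [e for e in self.entries if e.subject_id in subjects]
        return MeasurementConfig(keep)

    def to_sheet(self, path) -> Path:
        rows = [
            {
                "subject": e.subject_id,
                "session": e.session,
                "measurement": e.measurement_id,
                "path": str(e.eeg_path),
                "loc_path": "" if e.loc_path is None else str(e.loc_path),
            }
            for e in self.entries
        ]
        path = Path(path)
        pd.DataFrame(rows).to_csv(path, index=False)
        return path


# ---------------------------------------------------------------------------
# measurement discovery
# ---------------------------------------------------------------------------

def scan_measurement_dir(
    dir: str | Path,
    pattern: str = "*.bdf",
    subject_token: str | None = None,
) -> MeasurementConfig:
    """Build a measurement config from every file in ``dir`` matching ``pattern``.

    The subject id is parsed from the filename: by default the first
    underscore-delimited token (``s01_eeg_1.bdf`` -> ``s01``); pass a regex
    with one group in ``subject_token`` to override. A channel-location
    sidecar ``<stem>_locs.txt`` is attached when present.
    """
    dir = Path(dir)
    if not dir.is_dir():
        raise FileNotFoundError(f"measurement directory {dir} does not exist")
    files = sorted(p for p in dir.iterdir() if p.is_file() and fnmatch.fnmatch(p.name, pattern))
    if not files:
        raise ValueError(f"no files matching {pattern!r} in {dir}")
    entries = []
    for p in files:
        if subject_token is not None:
            m = re.match(subject_token, p.name)
            subject = m.group(1) if m else p.stem
        else:
            subject = p.name.split("_")[0] if "_" in p.name else p.stem
        loc = p.with_name(p.stem + "_locs.txt")
        entries.append(
            MeasurementEntry(
                subject_id=subject,
                session="session",
                measurement_id=p.stem,
                eeg_path=p,
                loc_path=loc if loc.exists() else None,
            )
        )
    return MeasurementConfig(entries)


def load_measurement_sheet(path: str | Path) -> MeasurementConfig:
    """Read a subject/recording sheet (CSV/TSV/XLSX) into a measurement config.

    Required columns: ``subject``, ``measurement``, ``path``; any extra
    columns are kept as per-entry metadata. Rows keep sheet order.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path, sep=None, engine="python")
    required = ["subject", "measurement", "path"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"measurement sheet is missing required column(s): {missing}")
    bad_rows = [
        int(i) for i, p in df["path"].items() if not Path(str(p)).exists()
    ]
    if bad_rows:
        raise ValueError(f"measurement sheet rows with nonexistent eeg_path: {bad_rows}")
    extra_cols = [c for c in df.columns if c not in required + ["session", "loc_path"]]
    entries = []
    for _, row in df.iterrows():
        loc = row.get("loc_path", "")
        loc = Path(str(loc)) if isinstance(loc, str) and loc.strip() else None
        entries.append(
            MeasurementEntry(
                subject_id=str(row["subject"]),
                session=str(row.get("session", "session")),
                measurement_id=str(row["measurement"]),
                eeg_path=Path(str(row["path"])),
                loc_path=loc,
                metadata={c: row[c] for c in extra_cols},
            )
        )
    return MeasurementConfig(entries)


# ---------------------------------------------------------------------------
# raw data input
# ---------------------------------------------------------------------------

def read_channel_locations(path: str | Path, dialect: str = "cartesian") -> dict[str, tuple]:
    """Parse a delimited electrode-location table into label -> unit-sphere xyz.

    ``cartesian`` rows are ``label x y z``; ``degrees`` rows are
    ``label theta phi`` (inclination from vertex, azimuth from the nose
    toward the right ear, both in degrees). Positions are normalized onto
    the unit sphere.
    """
    out: dict[str, tuple] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = re.split(r"[,\s]+", line)
        if dialect == "cartesian":
            if len(parts) < 4:
                raise ValueError(f"bad cartesian location row: {line!r}")
            label, x, y, z = parts[0], *map(float, parts[1:4])
        elif dialect == "degrees":
            if len(parts) < 3:
                raise ValueError(f"bad degrees location row: {line!r}")
            label = parts[0]
            theta, phi = np.deg2rad(float(parts[1])), np.deg2rad(float(parts[2]))
            x = np.sin(theta) * np.sin(phi)
            y = np.sin(theta) * np.cos(phi)
            z = np.cos(theta)
        else:
            raise ValueError(f"unknown location dialect {dialect!r}")
        v = np.array([x, y, z], dtype=float)
        n = np.linalg.norm(v)
        if n == 0:
            raise ValueError(f"zero-length position for channel {label!r}")
        out[label] = tuple(v / n)
    return out


def _channel_kind(label: str) -> str:
    lab = label.upper()
    if "EOG" in lab:
        return "eog"
    if lab in ("STATUS", "TRIGGER", "STI 014", "STI014"):
        return "other"
    return "eeg"


def read_raw(
    entry: MeasurementEntry,
    event_code_map: Mapping[int, str] | None = None,
    loc_dialect: str = "cartesian",
) -> Recording:
    """Load an EDF/BDF recording into a :class:`Recording` (microvolts).

    Trigger events come from rising edges of the ``Status`` channel (BDF) or
    from container annotations; numeric codes are mapped to condition strings
    through ``event_code_map`` (unmapped codes keep their decimal string).
    Channel positions are attached from the entry's location sidecar.
    """
    import mne

    path = Path(entry.eeg_path)
    if not path.exists():
        raise FileNotFoundError(f"EEG file {path} does not exist")
    suffix = path.suffix.lower()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if suffix == ".bdf":
            raw = mne.io.read_raw_bdf(path, preload=True, stim_channel="Status", verbose="error")
        elif suffix == ".edf":
            raw = mne.io.read_raw_edf(path, preload=True, stim_channel="auto", verbose="error")
        else:
            raise ValueError(f"unsupported container {suffix!r} (EDF/BDF only)")
    fs = float(raw.info["sfreq"])
    labels = list(raw.ch_names)
    if not labels:
        raise ValueError(f"{path} contains no channels")

    stim_labels = {labels[i] for i in mne.pick_types(raw.info, stim=True, eeg=False, eog=False)}
    data = raw.get_data()  # volts for eeg/eog; raw codes for stim

    events: list[Event] = []
    keep_idx: list[int] = []
    channels: list[Channel] = []
    locations = {}
    if entry.loc_path is not None:
        locations = read_channel_locations(entry.loc_path, dialect=loc_dialect)
    for i, lab in enumerate(labels):
        if lab in stim_labels or _channel_kind(lab) == "other":
            codes = np.rint(data[i]).astype(np.int64)
            events.extend(_events_from_codes(codes, event_code_map))
            continue
        keep_idx.append(i)
        channels.append(
            Channel(label=lab, position=locations.get(lab), kind=_channel_kind(lab))
        )
    if not channels:
        raise ValueError(f"{path} contains no signal channels")
    signals = data[keep_idx] * 1e6  # volts -> microvolts

    if not events and raw.annotations is not None and len(raw.annotations):
        for onset, dur, desc in zip(
            raw.annotations.onset, raw.annotations.duration, raw.annotations.description
        ):
            lat = int(round(onset * fs))
            if 0 <= lat < signals.shape[1]:
                events.append(Event(lat, str(desc), int(round(dur * fs))))

    rec = Recording(
        signals=signals,
        fs=fs,
        channels=channels,
        events=sorted(events, key=lambda e: e.latency),
        subject_id=entry.subject_id,
        measurement_id=entry.measurement_id,
    )
    rec.with_history(
        history_entry(
            "load",
            {"path": str(path), "n_channels": rec.n_channels, "fs": fs},
            f"loaded {rec.n_channels} ch x {rec.n_samples} samples",
        )
    )
    return rec


def _events_from_codes(codes: np.ndarray, code_map: Mapping[int, str] | None) -> list[Event]:
    """Rising-edge transitions of a trigger-code channel become events."""
    events = []
    prev = np.concatenate([[0], codes[:-1]])
    onsets = np.nonzero((codes != prev) & (codes != 0))[0]
    for lat in onsets:
        code = int(codes[lat])
        if code_map is not None:
            if code not in code_map:
                continue
            etype = str(code_map[code])
        else:
            etype = str(code)
        events.append(Event(int(lat), etype))
    return events


# ---------------------------------------------------------------------------
# state persistence between step sets
# ---------------------------------------------------------------------------

def save_state(rec: Recording, out_dir: str | Path, step_id: str, overwrite: bool = False) -> Path:
    """Persist a full Recording to ``<out_dir>/<measurement_id>.<step_id>.h5``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{rec.measurement_id}.{step_id}.h5"
    if path.exists() and not overwrite:
        raise FileExistsError(f"state file {path} exists and overwrite is disabled")
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = STATE_FORMAT_VERSION
        f.attrs["fs"] = rec.fs
        f.attrs["subject_id"] = rec.subject_id
        f.attrs["measurement_id"] = rec.measurement_id
        f.create_dataset("signals", data=rec.signals, dtype="f8")
        chans = [
            {"label": c.label, "position": None if c.position is None else list(c.position), "kind": c.kind}
            for c in rec.channels
        ]
        f.create_dataset("channels", data=json.dumps(chans))
        evs = [{"latency": e.latency, "type": e.type, "duration": e.duration} for e in rec.events]
        f.create_dataset("events", data=json.dumps(evs))
        f.create_dataset("history", data=json.dumps([h.to_json() for h in rec.history]))
        if rec.peek_latencies is not None:
            f.create_dataset("peek_latencies", data=np.asarray(rec.peek_latencies, dtype=np.int64))
        if rec.ica is not None:
            g = f.create_group("ica")
            g.create_dataset("unmixing", data=rec.ica.unmixing, dtype="f8")
            g.create_dataset("mixing", data=rec.ica.mixing, dtype="f8")
            g.create_dataset("retained", data=np.asarray(rec.ica.retained, dtype=np.int64))
    return path


def load_state(path: str | Path) -> Recording:
    """Restore a Recording saved by :func:`save_state` (exact round trip)."""
    path = Path(path)
    try:
        with h5py.File(path, "r") as f:
            version = int(f.attrs.get("format_version", -1))
            if version != STATE_FORMAT_VERSION:
                raise ValueError(
                    f"state file {path} has format version {version}; "
                    f"this build reads version {STATE_FORMAT_VERSION}"
                )
            chans = [
                Channel(
                    label=c["label"],
                    position=None if c["position"] is None else tuple(c["position"]),
                    kind=c["kind"],
                )
                for c in json.loads(f["channels"][()])
            ]
            events = [
                Event(int(e["latency"]), str(e["type"]), int(e["duration"]))
                for e in json.loads(f["events"][()])
            ]
            history = [HistoryEntry.from_json(s) for s in json.loads(f["history"][()])]
            peeks = None
            if "peek_latencies" in f:
                peeks = [int(v) for v in f["peek_latencies"][()]]
            ica = None
            if "ica" in f:
                g = f["ica"]
                ica = IcaDecomposition(
                    unmixing=np.asarray(g["unmixing"][()], dtype=np.float64),
                    mixing=np.asarray(g["mixing"][()], dtype=np.float64),
                    retained=[int(v) for v in g["retained"][()]],
                )
            return Recording(
                signals=np.asarray(f["signals"][()], dtype=np.float64),
                fs=float(f.attrs["fs"]),
                channels=chans,
                events=events,
                ica=ica,
                history=history,
                peek_latencies=peeks,
                subject_id=str(f.attrs["subject_id"]),
                measurement_id=str(f.attrs["measurement_id"]),
            )
    except OSError as err:
        raise ValueError(f"cannot read state file {path}: {err}") from err
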