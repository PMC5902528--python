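"""Quality control: synchronized peeks, rejection ledgers, branch comparison.

A "peek" is a set of data segments at latencies that are drawn once per
recording and then *reused* by every later peek in the pipe, so summary
statistics before and after a correction step describe the same stretches
of data. Rejection records from every step accumulate in an append-mode
ledger (`logs/all_rejections.txt` plus a CSV twin), and branch outputs are
compared with a parsimony rule: among branches of similar signal quality,
prefer the one that rejected the least data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .preprocessing_ops import RejectionRecord
from .recording_io import Recording, history_entry

__all__ = [
    "NodeSummary",
    "PeekStats",
    "compare_branches",
    "peek_data",
    "render_qc_figures",
    "summarize_rejections",
    "write_rejection_ledger",
]

LEDGER_COLUMNS = ["measurement", "step_tag", "kind", "method", "n_items", "items", "percentage"]


# ---------------------------------------------------------------------------
# peeks
# ---------------------------------------------------------------------------

@dataclass
class PeekStats:
    """Per-channel per-segment moments for one peek of one recording."""

    measurement_id: str
    tag: str
    latencies: list[int]
    stats: pd.DataFrame  # channel, segment, mean, sd, min, max, range, skewness, kurtosis, normality_p
    mean_range: float    # file-level aggregate over channels and segments
    mean_sd: float


def _draw_nonoverlapping(
    rng: np.random.Generator, n: int, seg_len: int, lo: int, hi: int
) -> list[int]:
    """n uniform non-overlapping segment starts in [lo, hi - seg_len]."""
    free = (hi - lo) - n * seg_len
    if free < 0:
        raise ValueError("segments do not fit")
    gaps = np.sort(rng.uniform(0, free, size=n))
    return [int(lo + gaps[i] + i * seg_len) for i in range(n)]


def _normality_p(x: np.ndarray, test: str) -> float:
    if np.std(x) == 0:
        return 0.0
    if test == "lilliefors":
        from statsmodels.stats.diagnostic import lilliefors

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, p = lilliefors(x, dist="norm", pvalmethod="table")
        return float(p)
    if test == "ks":
        _, p = scipy.stats.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
        return float(p)
    raise ValueError(f"unknown normality test {test!r}")


def peek_data(
    rec: Recording,
    n_segments: int = 10,
    seg_len_s: float = 10.0,
    seed: int = 0,
    tag: str = "peek",
    edge_margin_s: float = 1.0,
    normality_test: str = "lilliefors",
):
    """Snapshot segment statistics at latencies held fixed across the pipe.

    On the first peek of a recording the segment latencies are drawn
    uniformly (non-overlapping, at least ``edge_margin_s`` from the edges)
    and stored on the recording; later peeks reuse them exactly, which is
    what makes pre/post comparisons meaningful. Returns ``(rec2, PeekStats)``.

    The normality column is a Lilliefors-corrected Kolmogorov–Smirnov p-value
    by default (calibrated for estimated mean/SD); pass ``normality_test='ks'``
    for the plain one-sample KS against the fitted normal.
    """
    seg_len = int(round(seg_len_s * rec.fs))
    margin = int(round(edge_margin_s * rec.fs))
    out = rec.copy()
    if out.peek_latencies is None:
        avail = rec.n_samples - 2 * margin
        n_use = n_segments
        if avail < n_segments * seg_len:
            n_use = max(1, avail // seg_len)
            if n_use < 1 or avail <= 0:
                raise ValueError("recording too short for a single peek segment")
            warnings.warn(
                f"recording too short for {n_segments} x {seg_len_s}s segments; using {n_use}"
            )
        rng = np.random.default_rng(seed)
        out.peek_latencies = _draw_nonoverlapping(
            rng, n_use, seg_len, margin, rec.n_samples - margin
        )
    lats = list(out.peek_latencies)
    rows = []
    labels = rec.labels()
    for s_i, lat in enumerate(lats):
        seg = rec.signals[:, lat : lat + seg_len]
        mean = seg.mean(axis=1)
        sd = seg.std(axis=1, ddof=1)
        mn = seg.min(axis=1)
        mx = seg.max(axis=1)
        skw = scipy.stats.skew(seg, axis=1)
        krt = scipy.stats.kurtosis(seg, axis=1)
        for c_i, lab in enumerate(labels):
            rows.append(
                {
                    "channel": lab,
                    "segment": s_i,
                    "latency": lat,
                    "mean": mean[c_i],
                    "sd": sd[c_i],
                    "min": mn[c_i],
                    "max": mx[c_i],
                    "range": mx[c_i] - mn[c_i],
                    "skewness": skw[c_i],
                    "kurtosis": krt[c_i],
                    "normality_p": _normality_p(seg[c_i], normality_test),
                }
            )
    df = pd.DataFrame(rows)
    stats = PeekStats(
        measurement_id=rec.measurement_id,
        tag=tag,
        latencies=lats,
        stats=df,
        mean_range=float(df["range"].mean()),
        mean_sd=float(df["sd"].mean()),
    )
    out.with_history(
        history_entry(
            "peek_data",
            {"n_segments": len(lats), "seg_len_s": seg_len_s, "tag": tag, "seed": int(seed)},
            f"mean range {stats.mean_range:.1f} uV, mean SD {stats.mean_sd:.1f} uV",
        )
    )
    return out, stats


# ---------------------------------------------------------------------------
# rejection ledger
# ---------------------------------------------------------------------------

def write_rejection_ledger(
    records: Sequence[RejectionRecord],
    measurement_id: str,
    step_tag: str,
    logs_dir: str | Path,
) -> Path:
    """Append rejection records to ``logs/all_rejections.txt`` (+ CSV twin)."""
    logs_dir = Path(logs_dir)
    logs_dir.mkdir(parents=True, exist_ok=True)
    txt = logs_dir / "all_rejections.txt"
    csv = logs_dir / "all_rejections.csv"
    new_file = not txt.exists()
    rows = []
    for r in records:
        rows.append(
            {
                "measurement": measurement_id,
                "step_tag": step_tag,
                "kind": r.kind,
                "method": r.method,
                "n_items": len(r.items),
                "items": ";".join(str(i) for i in r.items),
                "percentage": round(100.0 * r.fraction_of_total, 4),
            }
        )
    with open(txt, "a") as fh:
        if new_file:
            fh.write("\t".join(LEDGER_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in LEDGER_COLUMNS) + "\n")
    df = pd.DataFrame(rows, columns=LEDGER_COLUMNS)
    df.to_csv(csv, mode="a", header=not csv.exists(), index=False)
    return txt


def read_rejection_ledger(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        return pd.DataFrame(columns=LEDGER_COLUMNS)
    return pd.read_csv(path, sep="\t")


def summarize_rejections(ledger: str | Path | pd.DataFrame) -> pd.DataFrame:
    """Percentage rejected per (measurement, kind) plus per-kind batch means.

    Batch rows carry measurement id ``__batch_mean__``. Percentages within a
    measurement and kind accumulate across steps.
    """
    df = ledger if isinstance(ledger, pd.DataFrame) else read_rejection_ledger(ledger)
    if df.empty:
        return pd.DataFrame(columns=["measurement", "kind", "percentage"])
    per = (
        df.groupby(["measurement", "kind"], as_index=False)["percentage"].sum()
    )
    batch = per.groupby("kind", as_index=False)["percentage"].mean()
    batch.insert(0, "measurement", "__batch_mean__")
    return pd.concat([per, batch], ignore_index=True)


# ---------------------------------------------------------------------------
# branch comparison
# ---------------------------------------------------------------------------

@dataclass
class NodeSummary:
    """Peek aggregates and rejection totals for one pipe x source node."""

    node_id: str
    mean_range: float
    mean_sd: float
    rejection_pct: Mapping[str, float] = field(default_factory=dict)
    measurements: frozenset = frozenset()

    @property
    def total_rejection_pct(self) -> float:
        return float(sum(self.rejection_pct.values()))


def node_summary(
    node_id: str,
    peeks: Sequence[PeekStats],
    ledger: pd.DataFrame | None = None,
) -> NodeSummary:
    """Aggregate a node's final peeks and its rejection ledger."""
    if not peeks:
        raise ValueError(f"node {node_id!r} has no peek statistics")
    rej: dict[str, float] = {}
    if ledger is not None and len(ledger):
        summary = summarize_rejections(ledger)
        batch = summary[summary["measurement"] == "__batch_mean__"]
        rej = dict(zip(batch["kind"], batch["percentage"]))
    return NodeSummary(
        node_id=node_id,
        mean_range=float(np.mean([p.mean_range for p in peeks])),
        mean_sd=float(np.mean([p.mean_sd for p in peeks])),
        rejection_pct=rej,
        measurements=frozenset(p.measurement_id for p in peeks),
    )


def compare_branches(
    nodes: Sequence[NodeSummary],
    similarity_tol: float = 0.10,
):
    """Tabulate branch quality and apply the parsimony rule.

    Among nodes whose mean range *and* mean SD are within ``similarity_tol``
    (relative) of the best (lowest) node, the recommendation is the one with
    the lowest total rejection percentage; ties break on node id so the
    result is independent of input order. Returns ``(table, recommendation)``;
    the recommendation is ``None`` for a single node.
    """
    if not nodes:
        raise ValueError("no nodes to compare")
    nodes = sorted(nodes, key=lambda n: n.node_id)
    if len(nodes) > 1:
        common = frozenset.intersection(*[n.measurements for n in nodes])
        if not common:
            raise ValueError("nodes share no common measurements; statistics not comparable")
    base_range = min(n.mean_range for n in nodes)
    base_sd = min(n.mean_sd for n in nodes)
    rows = []
    candidates = []
    for n in nodes:
        similar = (
            n.mean_range <= base_range * (1 + similarity_tol)
            and n.mean_sd <= base_sd * (1 + similarity_tol)
        )
        rows.append(
            {
                "node": n.node_id,
                "mean_range": n.mean_range,
                "mean_sd": n.mean_sd,
                "delta_range_vs_best": n.mean_range - base_range,
                "delta_sd_vs_best": n.mean_sd - base_sd,
                "total_rejection_pct": n.total_rejection_pct,
                **{f"rejected_{k}_pct": v for k, v in n.rejection_pct.items()},
                "similar_quality": similar,
            }
        )
        if similar:
            candidates.append(n)
    table = pd.DataFrame(rows)
    if len(nodes) == 1:
        return table, None
    best = min(candidates, key=lambda n: (n.total_rejection_pct, n.node_id))
    return table, best.node_id


# ---------------------------------------------------------------------------
# figures
# ---------------------------------------------------------------------------

def _mpl():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def _scalp_scatter(ax, rec: Recording, flagged: Sequence[str] = ()):
    eeg = rec.picks("eeg")
    pos = rec.positions(eeg)
    pos = pos / np.linalg.norm(pos, axis=1, keepdims=True)
    # azimuthal-equidistant projection to 2-D
    theta = np.arccos(np.clip(pos[:, 2], -1, 1))
    phi = np.arctan2(pos[:, 0], pos[:, 1])
    x, y = theta * np.sin(phi), theta * np.cos(phi)
    flag_set = set(flagged)
    colors = ["red" if rec.channels[i].label in flag_set else "black" for i in eeg]
    ax.scatter(x, y, c=colors, s=12)
    for k, i in enumerate(eeg):
        if rec.channels[i].label in flag_set:
            ax.annotate(rec.channels[i].label, (x[k], y[k]), fontsize=6, color="red")
    ax.set_aspect("equal")
    ax.axis("off")


def render_qc_figures(
    rec: Recording,
    what: str,
    out_dir: str | Path,
    *,
    det=None,
    peek: PeekStats | None = None,
    component: int | None = None,
    blink_erp: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> Path | None:
    """Render one QC figure kind to PNG; skip with a warning if prerequisites miss.

    Kinds: ``scalp_map_set`` (flagged channels on the montage),
    ``variance_histogram`` (scores with threshold lines), ``raw_snapshot``
    (peek segment traces), ``ic_diagnostics`` (scalp map, spectrum,
    ERP-image of one component), ``blink_erp`` (before/after blink-locked
    average, ``blink_erp=(time_s, before, after)``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    plt = _mpl()
    try:
        if what == "scalp_map_set":
            if any(rec.channels[i].position is None for i in rec.picks("eeg")):
                raise _Skip("channel positions missing")
            fig, ax = plt.subplots(figsize=(4, 4))
            _scalp_scatter(ax, rec, flagged=list(det.flagged) if det is not None else [])
            ax.set_title("flagged channels")
            path = out_dir / "scalp_map.png"
        elif what == "variance_histogram":
            if det is None or "variance_mad" not in det.scores:
                raise _Skip("no variance detection result")
            fig, ax = plt.subplots(figsize=(5, 3.5))
            ax.hist(det.scores["variance_mad"], bins=30, color="steelblue")
            for b in (det.params.get("b_lo"), det.params.get("b_hi")):
                if b is not None:
                    ax.axvline(b, color="red", linestyle="--")
            ax.set_xlabel("channel variance score (MAD units)")
            ax.set_ylabel("channels")
            path = out_dir / "variance_histogram.png"
        elif what == "raw_snapshot":
            if peek is None:
                raise _Skip("no peek statistics")
            lat = peek.latencies[0]
            seg_len = int(min(rec.fs * 10, rec.n_samples - lat))
            t = (lat + np.arange(seg_len)) / rec.fs
            fig, ax = plt.subplots(figsize=(8, 6))
            offset = 0.0
            for i in rec.picks("eeg")[:24]:
                trace = rec.signals[i, lat : lat + seg_len]
                ax.plot(t, trace - trace.mean() + offset, lw=0.4, color="black")
                offset += 4 * max(1.0, np.std(trace))
            ax.set_xlabel("time (s)")
            ax.set_yticks([])
            path = out_dir / f"raw_snapshot_{peek.tag}.png"
        elif what == "ic_diagnostics":
            if rec.ica is None or component is None:
                raise _Skip("no ICA decomposition / component index")
            from .preprocessing_ops import ic_activations

            act = ic_activations(rec)[component]
            fig, axes = plt.subplots(1, 3, figsize=(10, 3))
            eeg = rec.picks("eeg")
            try:
                pos = rec.positions(eeg)
                pos = pos / np.linalg.norm(pos, axis=1, keepdims=True)
                theta = np.arccos(np.clip(pos[:, 2], -1, 1))
                phi = np.arctan2(pos[:, 0], pos[:, 1])
                w = rec.ica.mixing[eeg, component]
                sc = axes[0].scatter(theta * np.sin(phi), theta * np.cos(phi), c=w, cmap="RdBu_r", s=14)
                fig.colorbar(sc, ax=axes[0])
            except ValueError:
                axes[0].text(0.5, 0.5, "no positions", ha="center")
            axes[0].set_title(f"IC{component} map")
            axes[0].axis("off")
            import scipy.signal as sps

            f, p = sps.welch(act, fs=rec.fs, nperseg=min(len(act), int(rec.fs * 2)))
            axes[1].semilogy(f, p)
            axes[1].set_xlabel("Hz")
            axes[1].set_title("spectrum")
            n_rows = min(100, max(1, len(act) // int(rec.fs)))
            seg = act[: n_rows * int(rec.fs)].reshape(n_rows, int(rec.fs))
            axes[2].imshow(seg, aspect="auto", cmap="RdBu_r")
            axes[2].set_title("continuous-data image")
            path = out_dir / f"ic{component:03d}_diagnostics.png"
        elif what == "blink_erp":
            if blink_erp is None:
                raise _Skip("no blink ERP data")
            t, before, after = blink_erp
            fig, ax = plt.subplots(figsize=(5, 3.5))
            ax.plot(t, before, label="before", color="firebrick")
            ax.plot(t, after, label="after", color="steelblue")
            ax.axvline(0.0, color="gray", lw=0.5)
            ax.set_xlabel("time from blink (s)")
            ax.set_ylabel("$\\mu$V")
            ax.legend()
            path = out_dir / "blink_erp.png"
        else:
            raise ValueError(f"unknown figure kind {what!r}")
    except _Skip as why:
        warnings.warn(f"QC figure {what!r} skipped: {why}")
        return None
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path


class _Skip(Exception):
    pass
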