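"""Batch execution of linear and branched step-set pipelines.

A *pipe* is an ordered list of *step sets*; each step set is an ordered list
of registered operations with arguments. The trunk pipe loads raw data;
branch pipes declare ``pipe_id#step_id`` source references and start from the
saved state of that step. The looper runs one pipe over the whole measurement
batch with per-recording fault isolation: a failing recording is logged and
skipped, the batch continues. The brancher runs a topologically ordered tree
of pipes, executing multi-source pipes once per source into separately
labelled output directories.

Every operation is looked up in a registry that declares its parameter
schema, so a configuration is validated in full — unknown operations,
unknown arguments, unresolvable sources — before any data is read.

Output layout per node (pipe x source)::

    <project_root>/<pipe_id>[__src_<pipe>#<step>]/
        state/            <measurement_id>.<step_set_id>.h5
        quality_control/  <op>/<step_tag>/<measurement_id>/*.png
        logs/             run.log, all_rejections.txt(+.csv), peek_stats_log.csv
"""

from __future__ import annotations

import time
import traceback
import warnings
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import yaml

from . import artifact_detection as ad
from . import preprocessing_ops as ops
from . import qc_reporting as qc
from .recording_io import (
    HistoryEntry,
    MeasurementConfig,
    Recording,
    history_entry,
    load_measurement_sheet,
    load_state,
    read_raw,
    save_state,
    scan_measurement_dir,
)

__all__ = [
    "BatchReport",
    "Pipe",
    "PipelineConfig",
    "SourceRef",
    "Step",
    "StepSet",
    "append_history",
    "get_operation",
    "load_config",
    "node_dir_name",
    "register_operation",
    "resolve_source",
    "run_brancher",
    "run_looper",
    "run_postproc",
    "validate_config",
]

REQUIRED = object()  # sentinel: argument has no default and must be supplied
_META_ARGS = {"_swept_param", "_sweep"}  # provenance keys, not op parameters


# ---------------------------------------------------------------------------
# workflow types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Step:
    op_name: str
    args: Mapping[str, object] = field(default_factory=dict)


@dataclass(frozen=True)
class StepSet:
    id: str
    steps: tuple
    save: bool = True

    def __post_init__(self):
        if not self.steps:
            raise ValueError(f"step set {self.id!r} has no steps")


@dataclass(frozen=True)
class SourceRef:
    pipe_id: str
    step_id: str

    def __str__(self) -> str:
        return f"{self.pipe_id}#{self.step_id}"

    @classmethod
    def parse(cls, text: str) -> "SourceRef":
        if "#" not in text:
            raise ValueError(f"source reference {text!r} is not of the form pipe_id#step_id")
        p, s = text.split("#", 1)
        return cls(p, s)


@dataclass(frozen=True)
class Pipe:
    id: str
    step_sets: tuple
    sources: tuple = ()


@dataclass
class PipelineConfig:
    project_root: Path
    measurement_config: MeasurementConfig
    pipes: list[Pipe]
    global_args: dict = field(default_factory=dict)
    overwrite: bool = False
    run_subset: Sequence[str] | None = None   # subject ids
    seed: int = 0
    debug: bool = False
    validated: bool = False


@dataclass
class MeasurementStatus:
    measurement_id: str
    status: str                  # completed | failed | skipped
    step_id: str | None = None
    error: str | None = None


@dataclass
class BatchReport:
    pipe_id: str
    source: SourceRef | None
    statuses: list[MeasurementStatus]
    wall_s: float
    output_dir: Path

    @property
    def n_completed(self) -> int:
        return sum(s.status == "completed" for s in self.statuses)

    @property
    def n_failed(self) -> int:
        return sum(s.status == "failed" for s in self.statuses)

    @property
    def n_skipped(self) -> int:
        return sum(s.status == "skipped" for s in self.statuses)


# ---------------------------------------------------------------------------
# operation registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OpSpec:
    name: str
    func: Callable          # (rec, ctx, **args) -> Recording
    params: Mapping[str, object]
    detect: Callable | None = None  # (rec, **args) -> DetectionResult (sweep target)


_REGISTRY: dict[str, OpSpec] = {}


def register_operation(name, func, params, detect=None):
    _REGISTRY[name] = OpSpec(name=name, func=func, params=dict(params), detect=detect)


def get_operation(name: str) -> OpSpec:
    if name not in _REGISTRY:
        raise KeyError(f"unknown operation {name!r}; registered: {sorted(_REGISTRY)}")
    return _REGISTRY[name]


class RunContext:
    """Mutable per-measurement scratch shared by the steps of one pipe run."""

    def __init__(self, cfg=None, measurement_id="", seed=0, node_dir=None, step_tag=""):
        self.cfg = cfg
        self.measurement_id = measurement_id
        self.seed = int(seed)
        self.node_dir = Path(node_dir) if node_dir is not None else None
        self.step_tag = step_tag
        self.detections: dict[str, object] = {}
        self.rejections: list = []
        self.peeks: list = []
        self.sweeps: dict[str, dict] = {}

    @property
    def figures_enabled(self) -> bool:
        return self.node_dir is not None

    def qc_dir(self, op_name: str) -> Path | None:
        if self.node_dir is None:
            return None
        d = self.node_dir / "quality_control" / op_name / self.step_tag / self.measurement_id
        d.mkdir(parents=True, exist_ok=True)
        return d

    def global_arg(self, key, default=None):
        if self.cfg is None:
            return default
        return self.cfg.global_args.get(key, default)


# ---------------------------------------------------------------------------
# registered step implementations
# ---------------------------------------------------------------------------

def _step_rereference(rec, ctx, scheme="average"):
    return ops.rereference(rec, scheme=scheme)


def _step_highpass(rec, ctx, cutoff_hz=1.0, transition_hz=1.0):
    return ops.highpass_filter(rec, cutoff_hz=cutoff_hz, transition_hz=transition_hz)


def _step_ica(rec, ctx, n_components="all", algorithm="fastica"):
    return ops.ica_decompose(rec, n_components=n_components, algorithm=algorithm, seed=ctx.seed)


def _step_detect_blink_events(rec, ctx, veog_labels=None, k=5.0):
    veog = veog_labels or ctx.global_arg("veog_labels", ["VEOG"])
    rec2, det = ad.detect_blink_events(rec, veog, k=k)
    ctx.detections["blink_events"] = det
    return rec2.with_history(
        history_entry("detect_blink_events", {"veog_labels": list(veog), "k": k},
                      f"{det.n_flagged} blink(s)")
    )


def _step_detect_blink_ics(rec, ctx, veog_labels=None, r_threshold=0.7):
    veog = veog_labels or ctx.global_arg("veog_labels", ["VEOG"])
    if ad.blink_latencies(rec):
        template = ad.build_blink_template(rec, veog)
        det = ad.detect_blink_ics(rec, template, r_threshold=r_threshold)
    else:
        warnings.warn("no blink events detected upstream; blink-IC step flags nothing")
        det = ad.DetectionResult(
            kind="components",
            item_ids=list(range(rec.ica.n_components)) if rec.ica else [],
            scores={"template_correlation": np.zeros(rec.ica.n_components if rec.ica else 0)},
            flagged=[],
            method="blink_template",
            primary_metric="template_correlation",
        )
    ctx.detections["blink_components"] = det
    d = ctx.qc_dir("detect_blink_ics")
    if d is not None:
        for comp in det.flagged:
            qc.render_qc_figures(rec, "ic_diagnostics", d, component=comp)
    return rec.copy().with_history(
        history_entry("detect_blink_ics", {"r_threshold": r_threshold},
                      f"{det.n_flagged} blink IC(s)")
    )


def _blink_locked_erp(rec, labels):
    lats = ad.blink_latencies(rec)
    lo, hi = int(-0.3 * rec.fs), int(0.5 * rec.fs)
    idx = [rec.channel_index(lab) for lab in labels if lab in rec.labels()]
    trace = rec.signals[idx].mean(axis=0)
    rows = [trace[l + lo : l + hi] for l in lats if l + lo >= 0 and l + hi <= rec.n_samples]
    t = np.arange(lo, hi) / rec.fs
    return t, (np.mean(rows, axis=0) if rows else np.zeros(hi - lo))


def _step_filter_blink_ics(rec, ctx, cutoff_hz=4.0):
    det = ctx.detections.get("blink_components")
    flagged = list(det.flagged) if det is not None else []
    veog = ctx.global_arg("veog_labels", ["VEOG"])
    vertex = ctx.global_arg("vertex_labels", ["Cz"])
    t, before = _blink_locked_erp(rec, list(veog) + list(vertex))
    rec2, record = ops.filter_blink_ics(rec, flagged, cutoff_hz=cutoff_hz)
    if record is not None:
        ctx.rejections.append(("filter_blink_ics", ctx.step_tag, record))
    d = ctx.qc_dir("filter_blink_ics")
    if d is not None:
        _, after = _blink_locked_erp(rec2, list(veog) + list(vertex))
        qc.render_qc_figures(rec2, "blink_erp", d, blink_erp=(t, before, after))
    return rec2


def _step_detect_bad_ics(rec, ctx, metrics=("median_gradient", "spatial_kurtosis", "spectral_slope", "hurst_exponent"), z_threshold=3.0, match_logic="any"):
    det = ad.detect_bad_ics_multimetric(
        rec, metrics=metrics, z_threshold=z_threshold, match_logic=match_logic
    )
    ctx.detections["components"] = det
    return rec.copy().with_history(
        history_entry(
            "detect_bad_ics",
            {"metrics": list(metrics), "z_threshold": z_threshold, "match_logic": match_logic},
            f"{det.n_flagged} bad IC(s)",
        )
    )


def _step_reject_components(rec, ctx):
    det = ctx.detections.get("components")
    if det is None:
        raise RuntimeError("reject_components requires a preceding component detection step")
    rec2, record = ops.reject_components(rec, det)
    if record is not None:
        ctx.rejections.append(("reject_components", ctx.step_tag, record))
        d = ctx.qc_dir("reject_components")
        if d is not None:
            for comp in det.flagged:
                qc.render_qc_figures(rec, "ic_diagnostics", d, component=comp)
    return rec2


def _step_detect_bad_channels_variance(rec, ctx, bounds=(-5.0, 2.5), fraction_cap=None, **meta):
    det = ad.detect_bad_channels_variance(rec, bounds=bounds, fraction_cap=fraction_cap)
    ctx.detections["channels"] = det
    d = ctx.qc_dir("detect_bad_channels_variance")
    if d is not None:
        qc.render_qc_figures(rec, "variance_histogram", d, det=det)
    args = {"bounds": bounds if np.isscalar(bounds) else list(bounds), "fraction_cap": fraction_cap}
    if meta.get("_swept_param"):
        args["swept_param"] = meta["_swept_param"]
        args["sweep"] = meta.get("_sweep")
    return rec.copy().with_history(
        history_entry("detect_bad_channels_variance", args, f"{det.n_flagged} bad channel(s)")
    )


def _step_detect_bad_channels_spectral(rec, ctx, bands=((0.0, 2.0), (20.0, 40.0)), db_bounds=(-5.0, 5.0), **meta):
    det = ad.detect_bad_channels_spectral(rec, bands=bands, db_bounds=db_bounds)
    ctx.detections["channels"] = det
    args = {"bands": [list(b) for b in bands], "db_bounds": list(db_bounds)}
    if meta.get("_swept_param"):
        args["swept_param"] = meta["_swept_param"]
        args["sweep"] = meta.get("_sweep")
    return rec.copy().with_history(
        history_entry("detect_bad_channels_spectral", args, f"{det.n_flagged} bad channel(s)")
    )


def _step_reject_channels(rec, ctx, interpolate=True):
    det = ctx.detections.get("channels")
    if det is None:
        raise RuntimeError("reject_channels requires a preceding channel detection step")
    d = ctx.qc_dir("reject_channels")
    if d is not None and det.flagged:
        qc.render_qc_figures(rec, "scalp_map_set", d, det=det)
    if det.flagged:
        diag = ops.check_spatial_clustering(det.flagged, rec)
        if diag["warning"]:
            warnings.warn(
                f"{rec.measurement_id}: flagged channels form a spatial cluster "
                f"(dispersion {diag['dispersion']:.2f}); interpolation support is weak"
            )
    rec2, record = ops.reject_channels(rec, det, interpolate=interpolate)
    if record is not None:
        ctx.rejections.append(("reject_channels", ctx.step_tag, record))
    return rec2


def _step_peek(rec, ctx, n_segments=10, seg_len_s=10.0, tag=None):
    tag = tag or ctx.step_tag or "peek"
    rec2, stats = qc.peek_data(
        rec,
        n_segments=n_segments,
        seg_len_s=seg_len_s,
        seed=ctx.seed,
        tag=tag,
        normality_test=ctx.global_arg("normality_test", "lilliefors"),
    )
    ctx.peeks.append(stats)
    d = ctx.qc_dir("peek_data")
    if d is not None:
        qc.render_qc_figures(rec2, "raw_snapshot", d, peek=stats)
    return rec2


def _step_sweep(rec, ctx, target_op, sweep_param, values, method_params=None, mini_pipe=None):
    from .param_sweep import SweepSpec, run_sweep

    steps = tuple(
        s if isinstance(s, Step) else Step(s["op"], s.get("args", {}))
        for s in (mini_pipe or [])
    )
    spec = SweepSpec(
        target_op=target_op,
        sweep_param=sweep_param,
        values=values,
        method_params=method_params or {},
        mini_pipe=steps,
    )
    result = run_sweep(rec, spec, seed=ctx.seed)
    ctx.sweeps[target_op] = {"param": sweep_param, "value": result.selected_value, "result": result}
    d = ctx.qc_dir("sweep")
    if d is not None:
        import pandas as pd

        pd.DataFrame({"value": result.values, "outcome": result.outcomes}).to_csv(
            d / f"sweep_{target_op}.csv", index=False
        )
        _sweep_figure(result, d / f"sweep_{target_op}.png")
    return rec.copy().with_history(
        history_entry(
            "sweep",
            {"target_op": target_op, "sweep_param": sweep_param,
             "values": [float(v) for v in values],
             "selected_value": result.selected_value},
            f"selected {sweep_param}={result.selected_value:g} for {target_op}",
        )
    )


def _sweep_figure(result, path):
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(result.values, result.outcomes, marker="o", ms=3)
    ax.axvline(result.selected_value, color="red")
    ax.annotate(
        f"selected {result.selected_value:g}",
        (result.selected_value, max(result.outcomes)),
        color="red",
        fontsize=8,
    )
    ax.set_xlabel("swept parameter value")
    ax.set_ylabel(f"n flagged {result.outcome_kind}")
    fig.savefig(path, dpi=100)
    plt.close(fig)


register_operation("rereference", _step_rereference, {"scheme": "average"})
register_operation("highpass_filter", _step_highpass, {"cutoff_hz": 1.0, "transition_hz": 1.0})
register_operation("ica_decompose", _step_ica, {"n_components": "all", "algorithm": "fastica"})
register_operation("detect_blink_events", _step_detect_blink_events, {"veog_labels": None, "k": 5.0})
register_operation("detect_blink_ics", _step_detect_blink_ics, {"veog_labels": None, "r_threshold": 0.7})
register_operation("filter_blink_ics", _step_filter_blink_ics, {"cutoff_hz": 4.0})
register_operation(
    "detect_bad_ics",
    _step_detect_bad_ics,
    {"metrics": ("median_gradient", "spatial_kurtosis", "spectral_slope", "hurst_exponent"),
     "z_threshold": 3.0, "match_logic": "any"},
)
register_operation("reject_components", _step_reject_components, {})
register_operation(
    "detect_bad_channels_variance",
    _step_detect_bad_channels_variance,
    {"bounds": (-5.0, 2.5), "fraction_cap": None},
    detect=ad.detect_bad_channels_variance,
)
register_operation(
    "detect_bad_channels_spectral",
    _step_detect_bad_channels_spectral,
    {"bands": ((0.0, 2.0), (20.0, 40.0)), "db_bounds": (-5.0, 5.0)},
    detect=ad.detect_bad_channels_spectral,
)
register_operation("reject_channels", _step_reject_channels, {"interpolate": True})
register_operation("peek_data", _step_peek, {"n_segments": 10, "seg_len_s": 10.0, "tag": None})
register_operation(
    "sweep",
    _step_sweep,
    {"target_op": REQUIRED, "sweep_param": REQUIRED, "values": REQUIRED,
     "method_params": None, "mini_pipe": None},
)


# ---------------------------------------------------------------------------
# history & plain step running
# ---------------------------------------------------------------------------

def append_history(rec: Recording, entry: HistoryEntry) -> Recording:
    """Append a fully serialized entry; fails before any computation if args aren't."""
    entry.to_json()  # raises on non-serializable args
    return rec.with_history(entry)


def run_steps_plain(rec: Recording, steps: Sequence[Step], seed: int = 0) -> Recording:
    """Run steps with a lightweight context (no QC output); used by the sweep."""
    ctx = RunContext(seed=seed, measurement_id=rec.measurement_id)
    for step in steps:
        op = get_operation(step.op_name)
        rec = op.func(rec, ctx, **dict(step.args))
    return rec


# ---------------------------------------------------------------------------
# config validation
# ---------------------------------------------------------------------------

def validate_config(cfg: PipelineConfig) -> PipelineConfig:
    """Check the whole workflow before touching data; returns a normalized copy.

    Collects *all* problems — unknown operations, unknown argument keys,
    duplicate ids, unresolvable or cyclic source references — and raises one
    error listing them. Defaults from each operation's declared schema are
    merged into the step arguments.
    """
    errors: list[str] = []
    pipe_ids = [p.id for p in cfg.pipes]
    for dup in sorted({i for i in pipe_ids if pipe_ids.count(i) > 1}):
        errors.append(f"duplicate pipe id {dup!r}")
    declared: dict[str, set[str]] = {}
    new_pipes = []
    for pipe in cfg.pipes:
        set_ids = [s.id for s in pipe.step_sets]
        for dup in sorted({i for i in set_ids if set_ids.count(i) > 1}):
            errors.append(f"pipe {pipe.id!r}: duplicate step set id {dup!r}")
        declared[pipe.id] = set(set_ids)
        new_sets = []
        for sset in pipe.step_sets:
            new_steps = []
            for step in sset.steps:
                if step.op_name not in _REGISTRY:
                    errors.append(f"pipe {pipe.id!r} step set {sset.id!r}: unknown op {step.op_name!r}")
                    new_steps.append(step)
                    continue
                spec = _REGISTRY[step.op_name]
                args = dict(step.args)
                for key in args:
                    if key not in spec.params and key not in _META_ARGS:
                        errors.append(
                            f"pipe {pipe.id!r} step {step.op_name!r}: unknown argument {key!r}"
                        )
                for key, default in spec.params.items():
                    if key not in args:
                        if default is REQUIRED:
                            errors.append(
                                f"pipe {pipe.id!r} step {step.op_name!r}: missing required argument {key!r}"
                            )
                        else:
                            args[key] = default
                new_steps.append(Step(step.op_name, args))
            new_sets.append(StepSet(sset.id, tuple(new_steps), sset.save))
        new_pipes.append(Pipe(pipe.id, tuple(new_sets), tuple(pipe.sources)))

    # source resolution and cycle check
    for pipe in new_pipes:
        for src in pipe.sources:
            if src.pipe_id not in declared:
                errors.append(f"pipe {pipe.id!r}: source {src} references unknown pipe")
            elif src.step_id not in declared[src.pipe_id]:
                errors.append(f"pipe {pipe.id!r}: source {src} references unknown step set")
            else:
                src_pipe = next(p for p in new_pipes if p.id == src.pipe_id)
                sset = next(s for s in src_pipe.step_sets if s.id == src.step_id)
                if not sset.save:
                    errors.append(
                        f"pipe {pipe.id!r}: source {src} references a step set with save=false"
                    )
    try:
        _topological_order(new_pipes)
    except ValueError as err:
        errors.append(str(err))

    if errors:
        raise ValueError("invalid pipeline configuration:\n  - " + "\n  - ".join(errors))
    out = replace(cfg, pipes=new_pipes, validated=True)
    out.project_root = Path(cfg.project_root)
    return out


def _topological_order(pipes: Sequence[Pipe]) -> list[Pipe]:
    order, done, seen = [], set(), set()

    by_id = {p.id: p for p in pipes}

    def visit(p: Pipe):
        if p.id in done:
            return
        if p.id in seen:
            raise ValueError(f"cyclic source graph involving pipe {p.id!r}")
        seen.add(p.id)
        for src in p.sources:
            if src.pipe_id in by_id:
                visit(by_id[src.pipe_id])
        done.add(p.id)
        order.append(p)

    for p in pipes:
        visit(p)
    return order


# ---------------------------------------------------------------------------
# execution
# ---------------------------------------------------------------------------

def node_dir_name(pipe: Pipe, source: SourceRef | None) -> str:
    return pipe.id if source is None else f"{pipe.id}__src_{source}"


def measurement_seed(master_seed: int, measurement_id: str) -> int:
    """Stable per-measurement child seed: subset runs reproduce full-run values."""
    return (int(master_seed) * 2654435761 + zlib.crc32(measurement_id.encode())) % (2**31)


def resolve_source(ref: SourceRef, cfg: PipelineConfig) -> Path:
    """State directory holding the saved step ``ref`` points at.

    The referenced pipe must have a single node instance (no sources or one
    source) — a multi-source pipe would be ambiguous as a source itself.
    """
    matches = [p for p in cfg.pipes if p.id == ref.pipe_id]
    if not matches:
        raise ValueError(f"source {ref}: no pipe {ref.pipe_id!r} in config")
    pipe = matches[0]
    sset = next((s for s in pipe.step_sets if s.id == ref.step_id), None)
    if sset is None:
        raise ValueError(f"source {ref}: pipe {pipe.id!r} has no step set {ref.step_id!r}")
    if not sset.save:
        raise ValueError(f"source {ref}: step set {ref.step_id!r} has save=false; no state exists")
    if len(pipe.sources) > 1:
        raise ValueError(f"source {ref}: pipe {pipe.id!r} has multiple sources; ambiguous")
    src = pipe.sources[0] if pipe.sources else None
    state_dir = Path(cfg.project_root) / node_dir_name(pipe, src) / "state"
    if not state_dir.is_dir():
        raise FileNotFoundError(f"source {ref}: expected state directory {state_dir} is missing")
    return state_dir


def _log(node_dir: Path, message: str):
    logs = node_dir / "logs"
    logs.mkdir(parents=True, exist_ok=True)
    with open(logs / "run.log", "a") as fh:
        fh.write(f"[{time.strftime('%Y-%m-%dT%H:%M:%S')}] {message}\n")


def run_looper(
    pipe: Pipe,
    cfg: PipelineConfig,
    source: SourceRef | None = None,
) -> BatchReport:
    """Run one pipe (one node instance) over the measurement batch.

    Loads each recording from raw (trunk) or from the resolved source state,
    applies the step sets in order, persists state after every step set with
    ``save=true``, and isolates failures: an error in one recording is
    recorded and logged, and the loop continues. With ``cfg.debug`` the first
    error re-raises with a full traceback instead.
    """
    if not cfg.validated:
        cfg = validate_config(cfg)
        pipe = next(p for p in cfg.pipes if p.id == pipe.id)
    t0 = time.time()
    node_dir = Path(cfg.project_root) / node_dir_name(pipe, source)
    node_dir.mkdir(parents=True, exist_ok=True)
    state_dir = node_dir / "state"
    logs_dir = node_dir / "logs"
    source_state = resolve_source(source, cfg) if source is not None else None

    entries = list(cfg.measurement_config)
    if cfg.run_subset:
        entries = [e for e in entries if e.subject_id in cfg.run_subset]
    statuses: list[MeasurementStatus] = []
    for entry in entries:
        mid = entry.measurement_id
        seed_m = measurement_seed(cfg.seed, mid)
        saved_sets = [s.id for s in pipe.step_sets if s.save]
        if not cfg.overwrite and saved_sets and all(
            (state_dir / f"{mid}.{sid}.h5").exists() for sid in saved_sets
        ):
            statuses.append(MeasurementStatus(mid, "skipped"))
            _log(node_dir, f"{mid}: skipped (state exists, overwrite=false)")
            continue
        ctx = RunContext(cfg=cfg, measurement_id=mid, seed=seed_m, node_dir=node_dir)
        current_step = None
        try:
            if source_state is None:
                rec = read_raw(entry, event_code_map=cfg.global_args.get("event_code_map"))
            else:
                path = source_state / f"{mid}.{source.step_id}.h5"
                if not path.exists():
                    raise FileNotFoundError(f"source state {path} missing (upstream failure?)")
                rec = load_state(path)
            for sset in pipe.step_sets:
                ctx.step_tag = sset.id
                for step in sset.steps:
                    current_step = f"{sset.id}/{step.op_name}"
                    args = dict(step.args)
                    pending = ctx.sweeps.pop(step.op_name, None)
                    if pending is not None:
                        args[pending["param"]] = pending["value"]
                        args["_swept_param"] = pending["param"]
                        args["_sweep"] = pending["result"].to_dict()
                    op = get_operation(step.op_name)
                    rec = op.func(rec, ctx, **args)
                if sset.save:
                    save_state(rec, state_dir, sset.id, overwrite=cfg.overwrite)
                    _log(node_dir, f"{mid}: saved state after step set {sset.id!r}")
            for op_name, step_tag, record in ctx.rejections:
                qc.write_rejection_ledger([record], mid, f"{op_name}@{step_tag}", logs_dir)
            _write_peek_log(ctx.peeks, logs_dir)
            statuses.append(MeasurementStatus(mid, "completed"))
            _log(node_dir, f"{mid}: completed ({len(rec.history)} history entries)")
        except Exception as err:  # noqa: BLE001 — fault isolation is the contract
            if cfg.debug:
                raise
            tb = traceback.format_exc(limit=5)
            statuses.append(MeasurementStatus(mid, "failed", step_id=current_step, error=str(err)))
            _log(node_dir, f"{mid}: FAILED at {current_step}: {err}\n{tb}")
    return BatchReport(
        pipe_id=pipe.id,
        source=source,
        statuses=statuses,
        wall_s=time.time() - t0,
        output_dir=node_dir,
    )


def _write_peek_log(peeks, logs_dir: Path):
    if not peeks:
        return
    import pandas as pd

    logs_dir.mkdir(parents=True, exist_ok=True)
    path = logs_dir / "peek_stats_log.csv"
    frames = []
    for p in peeks:
        df = p.stats.copy()
        df.insert(0, "measurement", p.measurement_id)
        df.insert(1, "tag", p.tag)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(path, mode="a", header=not path.exists(), index=False)


def run_brancher(cfg: PipelineConfig) -> list[BatchReport]:
    """Run the whole pipe tree: topological order, one run per pipe per source."""
    cfg = validate_config(cfg) if not cfg.validated else cfg
    reports: list[BatchReport] = []
    for pipe in _topological_order(cfg.pipes):
        if not pipe.sources:
            reports.append(run_looper(pipe, cfg, None))
        else:
            for src in pipe.sources:
                reports.append(run_looper(pipe, cfg, src))
    return reports


def run_postproc(
    fn: Callable,
    cfg: PipelineConfig,
    pipe: Pipe,
    source: SourceRef | None = None,
    step_id: str | None = None,
):
    """Apply a post-processing function to a node's saved states.

    Loads every measurement's state at ``step_id`` (default: the pipe's last
    saved step set) with per-measurement fault isolation, then calls
    ``fn(recordings_by_measurement_id, out_dir)`` once. Returns the
    function's result (with an empty node, a warning and ``fn`` on an empty
    dict).
    """
    cfg = validate_config(cfg) if not cfg.validated else cfg
    pipe = next(p for p in cfg.pipes if p.id == pipe.id)
    if step_id is None:
        saved = [s.id for s in pipe.step_sets if s.save]
        if not saved:
            raise ValueError(f"pipe {pipe.id!r} saves no state; nothing to post-process")
        step_id = saved[-1]
    node_dir = Path(cfg.project_root) / node_dir_name(pipe, source)
    state_dir = node_dir / "state"
    recs: dict[str, Recording] = {}
    for entry in cfg.measurement_config:
        path = state_dir / f"{entry.measurement_id}.{step_id}.h5"
        if not path.exists():
            _log(node_dir, f"postproc: no state for {entry.measurement_id} at {step_id}")
            continue
        try:
            recs[entry.measurement_id] = load_state(path)
        except Exception as err:  # noqa: BLE001
            _log(node_dir, f"postproc: failed loading {path}: {err}")
    out_dir = node_dir / "export"
    out_dir.mkdir(parents=True, exist_ok=True)
    if not recs:
        warnings.warn(f"post-processing node {node_dir.name}: no loadable state; empty output")
    return fn(recs, out_dir)


# ---------------------------------------------------------------------------
# YAML configuration
# ---------------------------------------------------------------------------

def load_config(path: str | Path, **overrides) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file (see the example in the README).

    ``measurements`` is either ``{dir: ..., pattern: ...}`` (directory scan)
    or ``{sheet: ...}``. Relative paths resolve against the config file's
    directory. Keyword overrides (e.g. ``overwrite=True``) take precedence.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    base = path.parent

    def _resolve(p):
        p = Path(p)
        return p if p.is_absolute() else base / p

    meas = raw.get("measurements", {})
    if "sheet" in meas:
        mc = load_measurement_sheet(_resolve(meas["sheet"]))
    elif "dir" in meas:
        mc = scan_measurement_dir(
            _resolve(meas["dir"]),
            pattern=meas.get("pattern", "*.bdf"),
            subject_token=meas.get("subject_token"),
        )
    else:
        raise ValueError("config must give measurements.dir or measurements.sheet")
    pipes = []
    for p in raw.get("pipes", []):
        sources = tuple(SourceRef.parse(s) for s in p.get("sources", []))
        sets = []
        for s in p.get("step_sets", []):
            steps = tuple(Step(st["op"], st.get("args", {})) for st in s.get("steps", []))
            sets.append(StepSet(str(s["id"]), steps, bool(s.get("save", True))))
        pipes.append(Pipe(str(p["id"]), tuple(sets), sources))
    global_args = dict(raw.get("global_args", {}))
    if "event_code_map" in global_args:
        global_args["event_code_map"] = {
            int(k): str(v) for k, v in global_args["event_code_map"].items()
        }
    cfg = PipelineConfig(
        project_root=_resolve(raw.get("project_root", "output")),
        measurement_config=mc,
        pipes=pipes,
        global_args=global_args,
        overwrite=bool(raw.get("overwrite", False)),
        run_subset=raw.get("run_subset"),
        seed=int(raw.get("seed", 0)),
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return validate_config(cfg)
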