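"""Data-driven detector parameterization by range sweep.

A detector threshold (e.g. the variance bounds scalar) is swept over a
numeric grid; each candidate is evaluated on a copy of the recording (after
an optional "mini-pipe" of preparatory steps) and the number of flagged
items forms an outcome curve. The selected value sits at the curve's
inflection point: the grid step whose outcome change is closest to one
standard deviation of the whole outcome set — a change big enough to clear
the plateau's fluctuations, but past the steepest fall. The value passed
onward is the midpoint of that step's two grid points, so each recording
ends up with its own threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .recording_io import Recording

__all__ = ["SweepSpec", "SweepResult", "inject_selected", "run_sweep", "select_inflection"]


@dataclass
class SweepSpec:
    """What to sweep: target detector, fixed args, grid, and preparatory steps."""

    target_op: str
    sweep_param: str
    values: Sequence[float]
    method_params: Mapping[str, object] = field(default_factory=dict)
    mini_pipe: Sequence = ()  # Steps applied to a copy before each evaluation
    sd_mode: str = "sample"   # "sample" (n-1) or "population"

    def __post_init__(self):
        vals = [float(v) for v in self.values]
        if len(vals) < 2:
            raise ValueError("sweep grid needs at least 2 values")
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError("sweep values must be strictly increasing")
        self.values = vals


@dataclass
class SweepResult:
    values: list[float]
    outcomes: list[int]
    diffs: list[float]
    sd_outcomes: float
    selected_index: int          # 0-based index of the chosen grid step
    selected_value: float        # midpoint of the chosen step's grid points
    outcome_kind: str = "channels"

    def to_dict(self) -> dict:
        return {
            "values": self.values,
            "outcomes": self.outcomes,
            "selected_index": self.selected_index,
            "selected_value": self.selected_value,
            "sd_outcomes": self.sd_outcomes,
            "outcome_kind": self.outcome_kind,
        }


def select_inflection(
    values: Sequence[float],
    outcomes: Sequence[float],
    sd_mode: str = "sample",
) -> tuple[int, float]:
    """Pick the grid step whose outcome change is closest to 1 SD of all outcomes.

    With diffs ``d_i = |y_{i+1} - y_i|`` and ``sd_y`` the standard deviation
    of the full outcome vector, the chosen step is
    ``argmin_i |d_i - sd_y|`` (ties to the smallest i) and the returned value
    is the midpoint ``(p_i + p_{i+1}) / 2``, strictly inside the grid.
    """
    values = [float(v) for v in values]
    y = np.asarray(outcomes, dtype=float)
    if len(values) != len(y):
        raise ValueError("values and outcomes differ in length")
    if len(y) < 2:
        raise ValueError("need at least 2 grid points")
    ddof = 1 if sd_mode == "sample" else 0
    sd_y = float(np.std(y, ddof=ddof))
    d = np.abs(np.diff(y))
    i_star = int(np.argmin(np.abs(d - sd_y)))  # argmin takes the first minimum
    p_star = (values[i_star] + values[i_star + 1]) / 2.0
    return i_star, p_star


def run_sweep(rec: Recording, spec: SweepSpec, seed: int = 0) -> SweepResult:
    """Evaluate the target detector across the grid; the input is untouched.

    For every grid value, the mini-pipe steps run on a fresh copy of the
    recording, the target detector runs with the sweep parameter bound to
    that value, and the outcome is the flagged-item count.
    """
    from .pipeline_engine import get_operation, run_steps_plain

    op = get_operation(spec.target_op)
    outcomes: list[int] = []
    kind = "channels"
    for k, p in enumerate(spec.values):
        work = rec.copy()
        try:
            if spec.mini_pipe:
                work = run_steps_plain(work, spec.mini_pipe, seed=seed)
            args = dict(spec.method_params)
            args[spec.sweep_param] = p
            det = op.detect(work, **args)
        except Exception as err:
            raise RuntimeError(
                f"sweep evaluation failed at grid index {k} (value {p}): {err}"
            ) from err
        kind = det.kind
        outcomes.append(int(det.n_flagged))
    i_star, p_star = select_inflection(spec.values, outcomes, sd_mode=spec.sd_mode)
    ddof = 1 if spec.sd_mode == "sample" else 0
    return SweepResult(
        values=list(spec.values),
        outcomes=outcomes,
        diffs=[float(v) for v in np.abs(np.diff(outcomes))],
        sd_outcomes=float(np.std(outcomes, ddof=ddof)),
        selected_index=i_star,
        selected_value=p_star,
        outcome_kind=kind,
    )


def inject_selected(step, sweep_param: str, p_star: float, sweep_result: SweepResult | None = None):
    """Bind the swept value into a pipeline step, with sweep provenance.

    Returns a new Step whose args carry ``sweep_param = p_star`` plus a
    provenance marker, so the detector's eventual history entry records that
    the threshold was data-driven rather than hand-set.
    """
    from .pipeline_engine import Step, get_operation

    op = get_operation(step.op_name)
    if sweep_param not in op.params:
        raise ValueError(
            f"operation {step.op_name!r} does not accept parameter {sweep_param!r}"
        )
    args = dict(step.args)
    if args.get("_swept_param") == sweep_param:
        import warnings

        warnings.warn(f"re-binding swept parameter {sweep_param!r}; overwriting previous value")
    args[sweep_param] = p_star
    args["_swept_param"] = sweep_param
    if sweep_result is not None:
        args["_sweep"] = sweep_result.to_dict()
    return Step(op_name=step.op_name, args=args)
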