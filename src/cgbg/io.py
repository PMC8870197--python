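"""Configuration documents, trace tables and state snapshots.

Runs are configured by a small YAML (or JSON) document with three sections
— ``task``, ``model``, ``execution`` — all optional; an empty document
reproduces the single-pair 0.9/0.2 demonstration task with default model
parameters.  Traces are written as tidy CSV tables (per-trial scalars and
long-format weight trajectories, including a trial-0 row for the initial
weights) plus a JSON provenance document, and can be read back exactly.
Per-phase state snapshots are JSON documents listing every unit's activity
by layer together with the weights in force on that trial.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import List, Literal, Optional, Tuple, Union

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .params import ModelParams
from .simulation import BehaviorMetrics, SessionTrace, TrialRecord, metrics_from_series
from .tasks import StimulusPair, TaskSpec, make_instructed, make_pst, make_reversal

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "write_trace",
    "read_trace",
    "metrics_from_trace_dir",
    "write_state_snapshot",
]

_FLOAT_FMT = "%.9g"  # 9 significant digits: stable round-trips at this model's range


def _round9(x: float) -> float:
    return float(f"{float(x):.9g}")


class PstTaskConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kind: Literal["pst"] = "pst"
    pairs: List[Tuple[float, float]] = Field(default=[(0.9, 0.2)])
    n_trials: int = Field(default=10, ge=1)
    pair_sampling: Literal["uniform", "shuffled_blocks"] = "uniform"

    def to_spec(self) -> TaskSpec:
        return make_pst(self.pairs, n_trials=self.n_trials, pair_sampling=self.pair_sampling)


class ReversalTaskConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kind: Literal["reversal"] = "reversal"
    p_first: float = Field(default=0.9, ge=0.0, le=1.0)
    p_second: float = Field(default=0.2, ge=0.0, le=1.0)
    block: int = Field(default=20, ge=1)
    n_trials: int = Field(default=100, ge=1)

    def to_spec(self) -> TaskSpec:
        return make_reversal(self.p_first, self.p_second, self.block, self.n_trials)


class InstructedTaskConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kind: Literal["instructed"] = "instructed"
    p_first: float = Field(default=0.9, ge=0.0, le=1.0)
    p_second: float = Field(default=0.2, ge=0.0, le=1.0)
    instructed: int = Field(default=1, ge=0, le=1)
    n_trials: int = Field(default=30, ge=1)

    def to_spec(self) -> TaskSpec:
        return make_instructed(self.p_first, self.p_second, self.instructed, self.n_trials)


TaskConfig = Union[PstTaskConfig, ReversalTaskConfig, InstructedTaskConfig]


class ModelConfig(BaseModel):
    """Overrides for :class:`~cgbg.params.ModelParams`; ranges checked there."""

    model_config = ConfigDict(extra="forbid")
    a: float = ModelParams.a
    lr_striatum: float = ModelParams.lr_striatum
    lr_pmc: float = ModelParams.lr_pmc
    beta: float = ModelParams.beta
    w_pfc_stria: float = ModelParams.w_pfc_stria
    w_pfc_pmc: float = ModelParams.w_pfc_pmc
    snc_dip: float = ModelParams.snc_dip
    snc_tonic: float = ModelParams.snc_tonic
    snc_burst: float = ModelParams.snc_burst
    init_mean: float = ModelParams.init_mean
    init_var: float = ModelParams.init_var
    presynaptic_gating: bool = ModelParams.presynaptic_gating

    @model_validator(mode="after")
    def _check_ranges(self) -> "ModelConfig":
        self.to_params()  # ModelParams.__post_init__ does the range checks
        return self

    def to_params(self) -> ModelParams:
        return ModelParams(**self.model_dump())


class ExecutionConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seeds: List[int] = Field(default=[1])
    out_dir: str = "runs"
    snapshot_trials: List[int] = Field(default=[])

    @field_validator("seeds")
    @classmethod
    def _nonempty(cls, v: List[int]) -> List[int]:
        if not v:
            raise ValueError("execution.seeds must not be empty")
        return v


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    task: TaskConfig = Field(default_factory=PstTaskConfig, discriminator="kind")
    model: ModelConfig = Field(default_factory=ModelConfig)
    execution: ExecutionConfig = Field(default_factory=ExecutionConfig)

    def to_task_spec(self) -> TaskSpec:
        return self.task.to_spec()

    def to_params(self) -> ModelParams:
        return self.model.to_params()


def load_config(path) -> RunConfig:
    """Parse and validate a YAML/JSON run configuration.

    An empty document yields the full default configuration (the 0.9/0.2
    ten-trial demonstration task).  Unknown keys and out-of-range values
    raise a validation error naming the offending key.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping, got {type(data).__name__}")
    return RunConfig(**data)


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=False))


# ---------------------------------------------------------------------------
# trace tables
# ---------------------------------------------------------------------------


def _unit_label(n_stimuli: int, k: int) -> str:
    return f"go_{k}" if k < n_stimuli else f"nogo_{k - n_stimuli}"


def _weight_rows(trial: int, weights) -> list:
    n = weights.n_stimuli
    rows = []
    for i in range(n):
        for k in range(2 * n):
            rows.append((trial, "striatum", i, _unit_label(n, k), weights.w_in_stria[i, k]))
        for k in range(n):
            rows.append((trial, "pmc", i, f"pmc_{k}", weights.w_in_pmc[i, k]))
    return rows


def _spec_to_dict(spec: TaskSpec) -> dict:
    return {
        "n_stimuli": spec.n_stimuli,
        "pairs": [
            {"first": p.first, "second": p.second, "p_first": p.p_first, "p_second": p.p_second}
            for p in spec.pairs
        ],
        "n_trials": spec.n_trials,
        "reversal_trials": list(spec.reversal_trials),
        "instruction": spec.instruction,
        "pair_sampling": spec.pair_sampling,
    }


def _spec_from_dict(d: dict) -> TaskSpec:
    return TaskSpec(
        n_stimuli=d["n_stimuli"],
        pairs=tuple(
            StimulusPair(p["first"], p["second"], p["p_first"], p["p_second"])
            for p in d["pairs"]
        ),
        n_trials=d["n_trials"],
        reversal_trials=tuple(d["reversal_trials"]),
        instruction=d["instruction"],
        pair_sampling=d["pair_sampling"],
    )


def write_trace(trace: SessionTrace, directory) -> dict:
    """Write one session as CSV tables plus a JSON provenance document.

    Produces ``trials.csv`` (per-trial scalars), ``weights.csv``
    (long-format weight trajectories; the trial-0 rows hold the initial
    values) and ``provenance.json`` (task spec, model parameters, seed).
    Returns the mapping of table names to paths.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    trials = pd.DataFrame(
        {
            "trial": [r.trial_index for r in trace.records],
            "pair_first": [r.pair.first for r in trace.records],
            "pair_second": [r.pair.second for r in trace.records],
            "p_first": [r.pair.p_first for r in trace.records],
            "p_second": [r.pair.p_second for r in trace.records],
            "side": [r.side for r in trace.records],
            "chosen": [r.chosen for r in trace.records],
            "rewarded": [int(r.rewarded) for r in trace.records],
        }
    )
    rows = _weight_rows(0, trace.initial_weights)
    for r in trace.records:
        rows.extend(_weight_rows(r.trial_index, r.weights_after))
    weights = pd.DataFrame(rows, columns=["trial", "layer", "source", "target", "value"])

    paths = {
        "trials": directory / "trials.csv",
        "weights": directory / "weights.csv",
        "provenance": directory / "provenance.json",
    }
    try:
        trials.to_csv(paths["trials"], index=False, float_format=_FLOAT_FMT)
        weights.to_csv(paths["weights"], index=False, float_format=_FLOAT_FMT)
        provenance = {
            "spec": _spec_to_dict(trace.spec),
            "params": dataclasses.asdict(trace.params),
            "seed": trace.seed,
        }
        paths["provenance"].write_text(json.dumps(provenance, indent=2))
    except OSError as exc:
        raise OSError(f"failed writing trace under {directory}: {exc}") from exc
    return {k: str(v) for k, v in paths.items()}


def read_trace(directory) -> tuple:
    """Read back the tables written by :func:`write_trace`.

    Returns ``(trials_df, weights_df, provenance_dict)``.
    """
    directory = Path(directory)
    try:
        trials = pd.read_csv(directory / "trials.csv")
        weights = pd.read_csv(directory / "weights.csv")
        provenance = json.loads((directory / "provenance.json").read_text())
    except OSError as exc:
        raise OSError(f"failed reading trace under {directory}: {exc}") from exc
    return trials, weights, provenance


def metrics_from_trace_dir(directory) -> BehaviorMetrics:
    """Recompute behavioral metrics from a stored trace directory."""
    trials, _, provenance = read_trace(directory)
    spec = _spec_from_dict(provenance["spec"])
    better = np.where(
        trials["p_first"].to_numpy() >= trials["p_second"].to_numpy(),
        trials["pair_first"].to_numpy(),
        trials["pair_second"].to_numpy(),
    )
    return metrics_from_series(
        trials["chosen"].to_numpy(),
        trials["rewarded"].to_numpy().astype(bool),
        better,
        reversal_trials=spec.reversal_trials,
        instruction=spec.instruction,
    )


# ---------------------------------------------------------------------------
# state snapshots
# ---------------------------------------------------------------------------


def write_state_snapshot(record: TrialRecord, phase: str, path) -> dict:
    """Write one phase of one trial as a JSON state document.

    A machine-readable counterpart of a network-state diagram: every unit's
    activity by layer (at fixed 9-significant-digit precision) and the
    weights in force during the trial.
    """
    if phase not in ("minus", "plus"):
        raise ValueError(f"phase must be 'minus' or 'plus', got {phase!r}")
    state = record.minus_state if phase == "minus" else record.plus_state
    n = len(state.y_in)
    doc = {
        "trial": record.trial_index,
        "phase": phase,
        "chosen": record.chosen,
        "rewarded": record.rewarded,
        "layers": {
            "input": [int(v) for v in state.y_in],
            "pfc": {"active": bool(state.y_pfc), "instructed": state.instructed_index},
            "snc": [_round9(v) for v in state.y_snc_per_unit],
            "striatum_go": [_round9(v) for v in state.y_stria[:n]],
            "striatum_nogo": [_round9(v) for v in state.y_stria[n:]],
            "gpe": [_round9(v) for v in state.y_gpe],
            "gpi": [_round9(v) for v in state.y_gpi],
            "thalamus": [_round9(v) for v in state.y_thal],
            "pmc_preactivation": [_round9(v) for v in state.x_pmc],
            "pmc": [_round9(v) for v in state.y_pmc],
            "output": [int(v) for v in state.y_out],
        },
        "active_inputs": list(state.presented),
        "weights": {
            "input_to_striatum": [
                [_round9(v) for v in row] for row in record.weights_before.w_in_stria
            ],
            "input_to_pmc": [
                [_round9(v) for v in row] for row in record.weights_before.w_in_pmc
            ],
        },
    }
    path = Path(path)
    try:
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(doc, indent=2))
    except OSError as exc:
        raise OSError(f"failed writing snapshot to {path}: {exc}") from exc
    return doc
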