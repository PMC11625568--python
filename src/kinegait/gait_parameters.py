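"""Spatio-temporal gait parameters from segmented strides and steps.

Eight parameters are computed per gait cycle:

=================  ======  ==================================================
step_length        m       depth difference between a stance onset of one
                           foot and the next stance onset of the other
step_time          s       time between those two stance onsets
stride_length      m       depth difference between two successive stance
                           onsets of the same foot
stride_time        s       time between those stance onsets (the gait cycle)
double_support     s       time inside the cycle with both ankles stationary
foot_off_pct       %       stance time of the cycle's foot as % of the cycle
walking_speed      m/s     stride_length / stride_time
cadence            1/min   120 / stride_time (steps per minute)
=================  ======  ==================================================

Parameters are computed separately for left and right cycles and then
pooled.  Summary tables use the sample standard deviation (n-1).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .segmentation import PhaseLabelSeries, Step, Stride

__all__ = [
    "PARAMETER_NAMES",
    "stride_metrics",
    "step_metrics",
    "cycle_timing",
    "trial_records",
    "aggregate_parameters",
]

PARAMETER_NAMES = (
    "step_length",
    "step_time",
    "stride_length",
    "stride_time",
    "double_support",
    "foot_off_pct",
    "walking_speed",
    "cadence",
)


def stride_metrics(stride: Stride) -> dict[str, float]:
    """Length, duration, walking speed and cadence of one stride."""
    if stride.duration <= 0:
        raise ValueError("stride has non-positive duration")
    return {
        "stride_length": stride.length,
        "stride_time": stride.duration,
        "walking_speed": stride.length / stride.duration,
        "cadence": 120.0 / stride.duration,
    }


def step_metrics(step: Step) -> dict[str, float]:
    """Length and duration of one step."""
    return {"step_length": step.length, "step_time": step.duration}


def cycle_timing(
    left: PhaseLabelSeries,
    right: PhaseLabelSeries,
    stride: Stride,
) -> tuple[float, float]:
    """Double support and foot-off percentage over one gait cycle.

    Double support is the total time within [start, end) where both ankle
    labels read stance; foot-off is the stance time of the stride's own side
    as a percentage of the cycle duration.  Both are sample counts times the
    grid step, so they are quantized to the 50 Hz cell.
    """
    if not np.array_equal(left.times, right.times):
        raise ValueError("left/right label series must share one time grid")
    t = left.times
    if stride.start.time < t[0] - 1e-9 or stride.end.time > t[-1] + 1e-9:
        raise ValueError("labels do not cover the stride span")
    dt = float(np.median(np.diff(t)))
    mask = (t >= stride.start.time - 1e-12) & (t < stride.end.time - 1e-12)
    both_stance = (left.labels == 0) & (right.labels == 0) & mask
    double_support = float(both_stance.sum() * dt)
    own = left if stride.side == "left" else right
    stance_time = float(((own.labels == 0) & mask).sum() * dt)
    foot_off_pct = 100.0 * stance_time / stride.duration
    return double_support, foot_off_pct


def _match_step(stride: Stride, steps: list[Step]) -> Step | None:
    """The step terminating at this stride's closing stance onset."""
    for s in steps:
        if s.side == stride.side and s.end == stride.end:
            return s
    return None


def trial_records(
    left: PhaseLabelSeries,
    right: PhaseLabelSeries,
    strides: list[Stride],
    steps: list[Step],
    trial_id: str = "trial",
) -> pd.DataFrame:
    """One row per stride with all eight parameters.

    Step length/time attach to the stride whose closing stance onset ends
    the step; strides without a matching step carry NaN there.
    """
    rows = []
    for k, stride in enumerate(strides):
        row: dict[str, object] = {"trial_id": trial_id, "side": stride.side,
                                  "cycle_id": k}
        row.update(stride_metrics(stride))
        ds, fo = cycle_timing(left, right, stride)
        row["double_support"] = ds
        row["foot_off_pct"] = fo
        step = _match_step(stride, steps)
        if step is not None:
            row.update(step_metrics(step))
        else:
            row["step_length"] = np.nan
            row["step_time"] = np.nan
        rows.append(row)
    columns = ["trial_id", "side", "cycle_id", *PARAMETER_NAMES]
    return pd.DataFrame(rows, columns=columns)


def aggregate_parameters(
    records: pd.DataFrame,
    pooling: str = "trial_mean",
    sd: str = "sample",
) -> pd.DataFrame:
    """Pooled mean/SD per parameter.

    pooling="trial_mean" (default) first averages the strides of each trial
    (both sides together), then summarizes across trials; pooling="stride"
    treats every stride as one observation.  ``sd`` selects the sample
    (n-1, default) or population (n) denominator; a single observation
    yields NaN under the sample convention.
    """
    if records.empty:
        raise ValueError("no records to aggregate")
    if pooling not in ("trial_mean", "stride"):
        raise ValueError(f"unknown pooling {pooling!r}")
    ddof = 1 if sd == "sample" else 0
    present = [p for p in PARAMETER_NAMES if p in records.columns]
    if pooling == "trial_mean":
        obs = records.groupby("trial_id")[present].mean()
    else:
        obs = records[present]
    out = pd.DataFrame(
        {
            "parameter": present,
            "mean": [obs[p].mean() for p in present],
            "sd": [obs[p].std(ddof=ddof) for p in present],
            "n": [int(obs[p].count()) for p in present],
        }
    )
    return out
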