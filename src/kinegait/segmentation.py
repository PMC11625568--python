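"""Stance/swing segmentation of ankle depth trajectories.

The detector is a per-sample depth-delta threshold: an ankle is *in motion*
(swing, label 1) at sample i when the absolute difference between its depth
at samples i and i-1 exceeds a fixed threshold (2 cm by default on the 50 Hz
grid, i.e. a 1 m/s velocity gate); otherwise it is *stationary* (stance,
label 0).  Ties at exactly the threshold count as stance — motion requires a
strictly greater delta.  Label transitions are the gait events: 0→1 is a
swing onset (foot off), 1→0 is a stance onset (initial contact).

Strides pair consecutive stance onsets of the same foot; steps run from a
contralateral stance onset to the next ipsilateral one.  Both are gated to
the virtual gait-analysis path (VGAP): the depth window 1.5–4.5 m from the
camera where whole-body tracking is reliable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SegmentationConfig",
    "PhaseLabelSeries",
    "GaitEvent",
    "Stride",
    "Step",
    "label_phases",
    "extract_events",
    "build_strides_and_steps",
]


@dataclass(frozen=True)
class SegmentationConfig:
    """Detector parameters.

    threshold : depth-delta gate in meters (0.02). At 50 Hz this equals a
        1 m/s ankle-velocity gate.
    min_phase_samples : runs shorter than this are merged into the
        surrounding phase (debounce); 3 samples = 60 ms at 50 Hz.
    vgap_near / vgap_far : accepted depth window in meters (1.5 / 4.5).
    """

    threshold: float = 0.02
    min_phase_samples: int = 3
    vgap_near: float = 1.5
    vgap_far: float = 4.5

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if not self.vgap_near < self.vgap_far:
            raise ValueError("vgap_near must be below vgap_far")


@dataclass
class PhaseLabelSeries:
    """Per-sample stance(0)/swing(1) labels for one ankle."""

    side: str
    times: np.ndarray
    depth: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.depth = np.asarray(self.depth, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if not (self.times.size == self.depth.size == self.labels.size):
            raise ValueError("times, depth and labels must have equal length")
        if self.labels.size and not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0 (stance) or 1 (swing)")


@dataclass(frozen=True)
class GaitEvent:
    side: str
    kind: str  # "stance_onset" | "swing_onset"
    index: int
    time: float
    depth: float


@dataclass(frozen=True)
class Stride:
    """One full gait cycle: consecutive stance onsets of the same foot."""

    side: str
    start: GaitEvent
    end: GaitEvent

    @property
    def length(self) -> float:
        return abs(self.end.depth - self.start.depth)

    @property
    def duration(self) -> float:
        return self.end.time - self.start.time


@dataclass(frozen=True)
class Step:
    """Contralateral stance onset to the next ipsilateral stance onset.

    ``side`` names the leading (ipsilateral, later-striking) foot.
    """

    side: str
    start: GaitEvent
    end: GaitEvent

    @property
    def length(self) -> float:
        return abs(self.end.depth - self.start.depth)

    @property
    def duration(self) -> float:
        return self.end.time - self.start.time


def _runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """(start, stop, value) for each constant run; stop is exclusive."""
    out = []
    start = 0
    for i in range(1, labels.size + 1):
        if i == labels.size or labels[i] != labels[start]:
            out.append((start, i, int(labels[start])))
            start = i
    return out


def _debounce(labels: np.ndarray, min_len: int) -> np.ndarray:
    """Merge runs shorter than ``min_len`` into the surrounding phase.

    The shortest run is flipped first (first-of-equals on ties) and the scan
    repeats until every remaining run is long enough — deterministic and
    order-independent of the input chatter pattern.
    """
    labels = labels.copy()
    while True:
        runs = _runs(labels)
        if len(runs) <= 1:
            return labels
        short = [(stop - start, k) for k, (start, stop, _) in enumerate(runs)
                 if stop - start < min_len]
        if not short:
            return labels
        _, k = min(short)
        start, stop, value = runs[k]
        labels[start:stop] = 1 - value


def label_phases(
    times: np.ndarray,
    depth: np.ndarray,
    side: str,
    config: SegmentationConfig = SegmentationConfig(),
    debounce: bool = True,
) -> PhaseLabelSeries:
    """Label each sample of an ankle depth series stance (0) or swing (1).

    The rule: label[i] = 1 iff |depth[i] - depth[i-1]| > threshold, with the
    tie (delta exactly equal) resolved to stance.  label[0] copies label[1]
    since sample 0 has no predecessor.  With ``debounce=True`` (default),
    runs shorter than ``config.min_phase_samples`` are merged into the
    surrounding phase; pass ``debounce=False`` for the raw per-sample rule.
    """
    times = np.asarray(times, dtype=float)
    depth = np.asarray(depth, dtype=float)
    if depth.size < 2:
        raise ValueError("need at least 2 samples to label phases")
    labels = np.zeros(depth.size, dtype=int)
    labels[1:] = (np.abs(np.diff(depth)) > config.threshold).astype(int)
    labels[0] = labels[1]
    if debounce and config.min_phase_samples > 1:
        labels = _debounce(labels, config.min_phase_samples)
    return PhaseLabelSeries(side=side, times=times, depth=depth, labels=labels)


def _side_events(series: PhaseLabelSeries) -> list[GaitEvent]:
    events = []
    labels = series.labels
    for i in np.flatnonzero(np.diff(labels)) + 1:
        kind = "stance_onset" if labels[i] == 0 else "swing_onset"
        events.append(
            GaitEvent(
                side=series.side,
                kind=kind,
                index=int(i),
                time=float(series.times[i]),
                depth=float(series.depth[i]),
            )
        )
    return events


def extract_events(
    left: PhaseLabelSeries, right: PhaseLabelSeries
) -> list[GaitEvent]:
    """Gait events from both ankles' label series, sorted by time.

    Each 0↔1 transition emits one event at the transition sample; per-side
    events alternate in kind by construction.  A side with no transitions
    contributes nothing (and triggers a warning).
    """
    events: list[GaitEvent] = []
    for series in (left, right):
        side_ev = _side_events(series)
        if not side_ev:
            warnings.warn(
                f"no phase transitions on side {series.side!r}", stacklevel=2
            )
        events.extend(side_ev)
    return sorted(events, key=lambda e: (e.time, e.side))


def _in_vgap(event: GaitEvent, config: SegmentationConfig) -> bool:
    return config.vgap_near <= event.depth <= config.vgap_far


def build_strides_and_steps(
    events: list[GaitEvent],
    config: SegmentationConfig = SegmentationConfig(),
    gate_vgap: bool = True,
    step_definition: str = "alternating",
) -> tuple[list[Stride], list[Step]]:
    """Assemble strides and steps from stance-onset events.

    Strides pair consecutive stance onsets of one side.  Steps, under the
    conventional ``"alternating"`` definition, run from a stance onset of one
    side to the next stance onset of the other side; the literal
    ``"single_ankle"`` reading instead takes one ankle's displacement from
    its swing onset to its next stance onset.  With ``gate_vgap`` (default),
    strides/steps whose bounding events fall outside the accepted depth
    window are discarded.
    """
    if step_definition not in ("alternating", "single_ankle"):
        raise ValueError(f"unknown step_definition {step_definition!r}")
    onsets = [e for e in events if e.kind == "stance_onset"]

    strides: list[Stride] = []
    for side in ("left", "right"):
        side_onsets = [e for e in onsets if e.side == side]
        if len(side_onsets) < 2:
            warnings.warn(f"fewer than 2 stance onsets on side {side!r}: "
                          "no strides", stacklevel=2)
        for a, b in zip(side_onsets, side_onsets[1:]):
            strides.append(Stride(side=side, start=a, end=b))

    steps: list[Step] = []
    if step_definition == "alternating":
        for a, b in zip(onsets, onsets[1:]):
            if a.side != b.side:
                steps.append(Step(side=b.side, start=a, end=b))
    else:
        for side in ("left", "right"):
            side_ev = [e for e in events if e.side == side]
            for a, b in zip(side_ev, side_ev[1:]):
                if a.kind == "swing_onset" and b.kind == "stance_onset":
                    steps.append(Step(side=side, start=a, end=b))

    if gate_vgap:
        strides = [s for s in strides
                   if _in_vgap(s.start, config) and _in_vgap(s.end, config)]
        steps = [s for s in steps
                 if _in_vgap(s.start, config) and _in_vgap(s.end, config)]
    return strides, steps
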