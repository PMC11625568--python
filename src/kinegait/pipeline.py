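"""End-to-end orchestration: ingest → preprocess → segment → parameters/CoM.

The stage order is fixed — resample, filter, segment, then parameter and
CoM computation — matching the processing chain the detector's threshold
was designed for.  All randomness lives in the synthetic generator; given a
stream and a configuration, the analysis path is deterministic.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import com_metrics, gait_parameters
from .agreement_stats import agreement_table, bland_altman, plot_bland_altman
from .preprocessing import PreprocessConfig, preprocess
from .segmentation import (
    PhaseLabelSeries,
    SegmentationConfig,
    Stride,
    build_strides_and_steps,
    extract_events,
    label_phases,
)
from .skeleton_io import SkeletonTrajectorySet, read_mak_json

__all__ = ["RunConfig", "TrialResult", "run_trial", "run_comparison"]

logger = logging.getLogger("kinegait")

#: Exit-code conventions for the CLI: success / no strides detected / error.
EXIT_OK, EXIT_ERROR, EXIT_NO_STRIDES = 0, 1, 2


@dataclass
class RunConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    pooling: str = "trial_mean"
    step_definition: str = "alternating"
    gate_vgap: bool = True


@dataclass
class TrialResult:
    trial_id: str
    records: pd.DataFrame
    com_excursions: pd.DataFrame
    strides: list[Stride]
    labels_left: PhaseLabelSeries
    labels_right: PhaseLabelSeries
    report: dict

    @property
    def n_strides(self) -> int:
        return len(self.strides)


def run_trial(
    stream: SkeletonTrajectorySet | str | Path,
    config: RunConfig = RunConfig(),
) -> TrialResult:
    """Run the full single-trial pipeline on a skeletal stream.

    Accepts an in-memory trajectory set or a path to a JSON stream.  The
    report collects dropped-frame counts, per-stage tallies and any
    warnings (e.g. strides excluded by the VGAP depth gate).
    """
    if not isinstance(stream, SkeletonTrajectorySet):
        stream = read_mak_json(stream)
    report: dict = {"trial_id": stream.trial_id, "warnings": []}
    if stream.load_report is not None:
        report["frames_total"] = stream.load_report.n_frames_total
        report["frames_dropped"] = stream.load_report.n_frames_dropped

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        clean = preprocess(stream, config.preprocess)
        left = label_phases(
            clean.times, clean.depth_of("ANKLE_LEFT"), "left", config.segmentation
        )
        right = label_phases(
            clean.times, clean.depth_of("ANKLE_RIGHT"), "right", config.segmentation
        )
        events = extract_events(left, right)
        all_strides, _ = build_strides_and_steps(
            events, config.segmentation, gate_vgap=False,
            step_definition=config.step_definition,
        )
        strides, steps = build_strides_and_steps(
            events, config.segmentation, gate_vgap=config.gate_vgap,
            step_definition=config.step_definition,
        )
        records = gait_parameters.trial_records(
            left, right, strides, steps, trial_id=stream.trial_id
        )
        com = com_metrics.com_from_hips(clean)
        excursions = com_metrics.excursions_per_cycle(com, strides)
    report["warnings"] = [str(w.message) for w in caught]
    report["n_events"] = len(events)
    report["n_strides_detected"] = len(all_strides)
    report["n_strides_kept"] = len(strides)
    report["n_strides_excluded_vgap"] = len(all_strides) - len(strides)
    logger.info(json.dumps({"stage": "run_trial", **report}))
    return TrialResult(
        trial_id=stream.trial_id,
        records=records,
        com_excursions=excursions,
        strides=strides,
        labels_left=left,
        labels_right=right,
        report=report,
    )


def run_comparison(
    pairs: pd.DataFrame,
    plot_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Agreement battery over a tidy measured/actual pair table.

    Emits one summary row per (parameter × group) cell — pooled plus per
    group — and, when ``plot_dir`` is given, a Bland–Altman plot per
    parameter on the pooled pairs.
    """
    orphans = pairs[pairs[["measured", "actual"]].isna().any(axis=1)]
    if len(orphans):
        raise ValueError(
            f"unmatched pairs at rows {orphans.index.tolist()}"
        )
    if "group" not in pairs.columns or pairs["group"].isna().all():
        warnings.warn("no group labels: pooled-only output", stacklevel=2)
        pairs = pairs.drop(columns=["group"], errors="ignore")
    table = agreement_table(pairs)
    if plot_dir is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        plot_dir = Path(plot_dir)
        plot_dir.mkdir(parents=True, exist_ok=True)
        for parameter, sub in pairs.groupby("parameter"):
            if len(sub) < 2:
                continue
            ba = bland_altman(sub["measured"], sub["actual"])
            ax = plot_bland_altman(ba, title=str(parameter))
            ax.figure.savefig(plot_dir / f"bland_altman_{parameter}.svg")
            plt.close(ax.figure)
    return table
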