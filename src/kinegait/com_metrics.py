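"""Pelvis-level center-of-mass trajectories and per-cycle excursions.

The CoM proxy differs by system: for the depth camera it is the midpoint of
the two hip joints of the skeletal model; for the marker-based reference it
is the midpoint of the segment joining the ASIS midpoint and the PSIS
midpoint of the four pelvis markers.  For each gait cycle the maximum
excursion (peak-to-peak range) of the CoM along the medio-lateral (ML),
vertical (V) and antero-posterior (AP) body directions is reported in
millimeters.  AP is the progression of the body along the walking direction
— roughly the stride length — rather than a sway measure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segmentation import Stride
from .skeleton_io import (
    MarkerTrajectorySet,
    SkeletonTrajectorySet,
)

__all__ = [
    "CoMTrajectory",
    "com_from_hips",
    "com_from_pelvis_markers",
    "excursions_per_cycle",
    "summarize_excursions",
]


@dataclass
class CoMTrajectory:
    times: np.ndarray
    position: np.ndarray  # (N, 3) meters
    axis_roles: "object"
    source: str  # "hips_midpoint" | "pelvis_markers"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (self.times.size, 3):
            raise ValueError("position must be (n_samples, 3)")


def com_from_hips(traj: SkeletonTrajectorySet) -> CoMTrajectory:
    """CoM as the midpoint of the two hip joints."""
    traj.require(("HIP_LEFT", "HIP_RIGHT"))
    pos = 0.5 * (traj.joint("HIP_LEFT") + traj.joint("HIP_RIGHT"))
    return CoMTrajectory(
        times=traj.times,
        position=pos,
        axis_roles=traj.axis_roles,
        source="hips_midpoint",
    )


def com_from_pelvis_markers(markers: MarkerTrajectorySet) -> CoMTrajectory:
    """CoM as the midpoint between the ASIS midpoint and the PSIS midpoint."""
    m = markers.markers
    asis_mid = 0.5 * (m["LASI"] + m["RASI"])
    psis_mid = 0.5 * (m["LPSI"] + m["RPSI"])
    return CoMTrajectory(
        times=markers.times,
        position=0.5 * (asis_mid + psis_mid),
        axis_roles=markers.axis_roles,
        source="pelvis_markers",
    )


def _detrend(x: np.ndarray, t: np.ndarray) -> np.ndarray:
    coeff = np.polyfit(t, x, 1)
    return x - np.polyval(coeff, t)


def excursions_per_cycle(
    com: CoMTrajectory,
    strides: list[Stride],
    mode: str = "peak_to_peak",
    detrend_ml_v: bool = False,
) -> pd.DataFrame:
    """Maximum CoM excursion per gait cycle along ML/V/AP, in millimeters.

    Each stride defines one cycle [start, end); the excursion along a role
    axis is the max-minus-min of that coordinate within the cycle
    (``mode="peak_to_peak"``, the default) or twice the maximum deviation
    from the cycle mean (``mode="max_deviation"``, reported on the same
    peak-to-peak scale for comparability).  ``detrend_ml_v`` removes a
    linear trend from the ML and V coordinates within each cycle, for walks
    not aligned with the measurement axes; the laboratory setup emulated
    here is axis-aligned, so it defaults off.  Cycles extending beyond the
    trajectory are skipped with a warning.
    """
    if mode not in ("peak_to_peak", "max_deviation"):
        raise ValueError(f"unknown mode {mode!r}")
    roles = com.axis_roles
    rows = []
    for k, stride in enumerate(strides):
        mask = (com.times >= stride.start.time - 1e-12) & (
            com.times < stride.end.time - 1e-12
        )
        if (
            stride.start.time < com.times[0] - 1e-9
            or stride.end.time > com.times[-1] + 1e-9
            or mask.sum() < 2
        ):
            warnings.warn(
                f"cycle {k} outside CoM trajectory span; skipped", stacklevel=2
            )
            continue
        t = com.times[mask]
        row: dict[str, object] = {"cycle_id": k, "side": stride.side}
        for role in ("ap", "ml", "v"):
            x = com.position[mask, roles.index(role)]
            if detrend_ml_v and role in ("ml", "v"):
                x = _detrend(x, t)
            if mode == "peak_to_peak":
                exc = float(x.max() - x.min())
            else:
                exc = float(2.0 * np.abs(x - x.mean()).max())
            row[f"{role}_mm"] = exc * 1000.0
        rows.append(row)
    return pd.DataFrame(rows, columns=["cycle_id", "side", "ap_mm", "ml_mm", "v_mm"])


def summarize_excursions(excursions: pd.DataFrame, sd: str = "sample") -> pd.DataFrame:
    """Pooled mean/SD of the per-cycle excursions (all cycles, both sides)."""
    if excursions.empty:
        raise ValueError("no excursion records")
    ddof = 1 if sd == "sample" else 0
    rows = []
    for col, name in (("ap_mm", "AP"), ("ml_mm", "ML"), ("v_mm", "V")):
        rows.append(
            {
                "parameter": name,
                "mean_mm": excursions[col].mean(),
                "sd_mm": excursions[col].std(ddof=ddof),
                "n": int(excursions[col].count()),
            }
        )
    return pd.DataFrame(rows)
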