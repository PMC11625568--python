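"""I/O and coordinate conventions for skeletal joint streams and pelvis markers.

Two kinds of input are handled:

* depth-camera body-tracking streams (32-joint skeletal model, nominally
  30 fps, serialized as JSON) — the markerless system under test;
* four-marker pelvis trajectories (LASI/RASI/LPSI/RPSI) as CSV — the
  marker-based reference used for the CoM comparison.

Everything is converted to SI (meters, seconds) on read; the time origin is
re-based to zero at the first retained frame.  Downstream code never touches
raw x/y/z axes directly: each trajectory set carries an :class:`AxisRoles`
mapping naming which axis plays the antero-posterior (AP), medio-lateral
(ML) and vertical (V) role for its source system.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "AXIS_INDEX",
    "REQUIRED_JOINTS",
    "PELVIS_MARKERS",
    "AxisRoles",
    "LoadReport",
    "SkeletonTrajectorySet",
    "MarkerTrajectorySet",
    "axis_roles_for",
    "read_mak_json",
    "write_mak_json",
    "read_marker_csv",
    "write_marker_csv",
]

AXIS_INDEX = {"x": 0, "y": 1, "z": 2}

#: Joints the analysis pipeline cannot run without: both ankles drive the
#: stance/swing segmentation, both hips define the pelvis-level CoM proxy.
REQUIRED_JOINTS = ("ANKLE_LEFT", "ANKLE_RIGHT", "HIP_LEFT", "HIP_RIGHT")

PELVIS_MARKERS = ("LASI", "RASI", "LPSI", "RPSI")


@dataclass(frozen=True)
class AxisRoles:
    """Which coordinate axis plays each anatomical role.

    ``ap``/``ml``/``v`` must be a permutation of ``{x, y, z}``.  ``depth``
    names the axis encoding distance from the camera; for the depth-camera
    system it coincides with the walking (AP) direction.
    """

    ap: str
    ml: str
    v: str
    depth: str | None = None

    def __post_init__(self) -> None:
        if sorted((self.ap, self.ml, self.v)) != ["x", "y", "z"]:
            raise ValueError(
                f"axis roles must be a permutation of x/y/z, got "
                f"ap={self.ap!r} ml={self.ml!r} v={self.v!r}"
            )
        if self.depth is not None and self.depth not in AXIS_INDEX:
            raise ValueError(f"unknown depth axis {self.depth!r}")

    def index(self, role: str) -> int:
        """Column index (0/1/2) of a role: 'ap', 'ml', 'v' or 'depth'."""
        axis = getattr(self, role)
        if axis is None:
            raise ValueError(f"role {role!r} is not defined for this system")
        return AXIS_INDEX[axis]


def axis_roles_for(system: str) -> AxisRoles:
    """Standard axis-role conventions for the two measurement systems.

    Depth camera ("MAK"): ML = x, V = y, AP = depth = z (the subject walks
    toward the camera, so depth decreases along the trial).  Marker-based
    reference ("MoCap"): ML = z, V = y, AP = x in the laboratory frame.
    """
    key = system.strip().lower()
    if key == "mak":
        return AxisRoles(ap="z", ml="x", v="y", depth="z")
    if key == "mocap":
        return AxisRoles(ap="x", ml="z", v="y", depth=None)
    raise ValueError(f"unknown system {system!r}; expected 'MAK' or 'MoCap'")


@dataclass
class LoadReport:
    """Bookkeeping from a stream read: frames seen, frames dropped, joints skipped."""

    n_frames_total: int = 0
    n_frames_dropped: int = 0
    skipped_joints: list[str] = field(default_factory=list)


@dataclass
class SkeletonTrajectorySet:
    """Time-stamped 3D joint trajectories from one walking trial.

    All joints share the single ``times`` vector (strictly increasing,
    seconds, origin at zero); each joint maps to an ``(N, 3)`` float array in
    meters.
    """

    trial_id: str
    system: str
    fps_nominal: float
    times: np.ndarray
    joints: dict[str, np.ndarray]
    axis_roles: AxisRoles
    load_report: LoadReport | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("times must be one-dimensional")
        if self.times.size and self.times[0] < 0:
            raise ValueError("timestamps must be non-negative")
        bad = np.flatnonzero(np.diff(self.times) <= 0)
        if bad.size:
            raise ValueError(
                f"timestamps not strictly increasing at indices {bad.tolist()}"
            )
        n = self.times.size
        for name, arr in list(self.joints.items()):
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (n, 3):
                raise ValueError(
                    f"joint {name!r} has shape {arr.shape}, expected ({n}, 3)"
                )
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"joint {name!r} contains non-finite positions")
            self.joints[name] = arr

    @property
    def n_frames(self) -> int:
        return int(self.times.size)

    def joint(self, name: str) -> np.ndarray:
        try:
            return self.joints[name]
        except KeyError:
            raise KeyError(
                f"joint {name!r} not present in trial {self.trial_id!r}"
            ) from None

    def depth_of(self, name: str) -> np.ndarray:
        """Depth (distance-from-camera) component of one joint, meters."""
        return self.joint(name)[:, self.axis_roles.index("depth")]

    def require(self, names: Iterable[str]) -> None:
        missing = [n for n in names if n not in self.joints]
        if missing:
            raise KeyError(
                f"trial {self.trial_id!r} is missing required joints: {missing}"
            )


@dataclass
class MarkerTrajectorySet:
    """Four-marker pelvis trajectories (LASI/RASI/LPSI/RPSI) in meters."""

    times: np.ndarray
    markers: dict[str, np.ndarray]
    rate_nominal: float
    axis_roles: AxisRoles

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        missing = [m for m in PELVIS_MARKERS if m not in self.markers]
        if missing:
            raise ValueError(f"missing marker {missing[0]}")
        n = self.times.size
        for name, arr in list(self.markers.items()):
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (n, 3):
                raise ValueError(f"marker {name!r} has shape {arr.shape}")
            self.markers[name] = arr


# ---------------------------------------------------------------------------
# JSON skeletal stream
#
# Schema: {"trial_id": str, "fps_nominal": number, "units": "mm"|"m",
#          "frames": [{"t": seconds, "joints": {"ANKLE_LEFT": [x,y,z], ...}}]}
# ---------------------------------------------------------------------------


def read_mak_json(
    path: str | Path,
    units: str | None = None,
    required: tuple[str, ...] = REQUIRED_JOINTS,
) -> SkeletonTrajectorySet:
    """Read a body-tracking JSON stream into a validated trajectory set.

    Parameters
    ----------
    path
        JSON file following the documented stream schema.
    units
        Override the ``units`` field of the file ("mm" or "m").  Positions
        are always returned in meters.
    required
        Joints a frame must carry (with finite coordinates) to be retained.
        Frames missing any of them are dropped and counted in the load
        report; if more than half of the frames lack a required joint the
        read fails.

    Notes
    -----
    Timestamps are re-based so the first retained frame is at t = 0 —
    device clocks are arbitrary.  Joints absent from some retained frames
    are skipped entirely (and listed in the report) so that every stored
    trajectory shares the common timestamp vector.
    """
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(
            f"malformed JSON in {path}: {exc.msg} at byte offset {exc.pos}"
        ) from exc

    unit = units or raw.get("units", "m")
    if unit not in ("mm", "m"):
        raise ValueError(f"unknown units {unit!r}; expected 'mm' or 'm'")
    scale = 0.001 if unit == "mm" else 1.0

    frames = raw.get("frames", [])
    report = LoadReport(n_frames_total=len(frames))
    kept: list[dict] = []
    for fr in frames:
        joints = fr.get("joints", {})
        ok = all(
            j in joints and np.all(np.isfinite(joints[j])) for j in required
        )
        if ok:
            kept.append(fr)
    report.n_frames_dropped = len(frames) - len(kept)
    if len(frames) and len(kept) < 0.5 * len(frames):
        raise ValueError(
            f"required joints absent in {report.n_frames_dropped} of "
            f"{len(frames)} frames (> 50%); stream unusable"
        )
    if not kept:
        raise ValueError(f"no usable frames in {path}")

    t = np.asarray([fr["t"] for fr in kept], dtype=float)
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        raise ValueError(
            f"non-monotone timestamps at frame indices {bad.tolist()}"
        )
    t = t - t[0]

    common = set(kept[0]["joints"])
    for fr in kept[1:]:
        common &= set(fr["joints"])
    report.skipped_joints = sorted(
        {j for fr in kept for j in fr["joints"]} - common
    )
    joints = {
        name: np.asarray([fr["joints"][name] for fr in kept], dtype=float) * scale
        for name in sorted(common)
    }
    return SkeletonTrajectorySet(
        trial_id=str(raw.get("trial_id", path.stem)),
        system="MAK",
        fps_nominal=float(raw.get("fps_nominal", 30.0)),
        times=t,
        joints=joints,
        axis_roles=axis_roles_for("MAK"),
        load_report=report,
    )


def write_mak_json(
    traj: SkeletonTrajectorySet, path: str | Path, units: str = "m"
) -> None:
    """Serialize a trajectory set back to the documented JSON schema."""
    if units not in ("mm", "m"):
        raise ValueError(f"unknown units {units!r}")
    scale = 1000.0 if units == "mm" else 1.0
    frames = []
    for i, t in enumerate(traj.times):
        frames.append(
            {
                "t": float(t),
                "joints": {
                    name: [float(v * scale) for v in arr[i]]
                    for name, arr in traj.joints.items()
                },
            }
        )
    doc = {
        "trial_id": traj.trial_id,
        "fps_nominal": traj.fps_nominal,
        "units": units,
        "frames": frames,
    }
    Path(path).write_text(json.dumps(doc))


# ---------------------------------------------------------------------------
# Pelvis marker CSV: header time,LASI_x,LASI_y,LASI_z,..., one row per frame
# ---------------------------------------------------------------------------


def read_marker_csv(path: str | Path, rate_nominal: float = 100.0) -> MarkerTrajectorySet:
    """Read a four-marker pelvis CSV (positions in meters)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"ragged CSV {path}: {exc}") from exc
    if "time" not in df.columns:
        raise ValueError(f"{path}: missing 'time' column")
    markers: dict[str, np.ndarray] = {}
    for m in PELVIS_MARKERS:
        cols = [f"{m}_{ax}" for ax in "xyz"]
        for c in cols:
            if c not in df.columns:
                raise ValueError(f"missing marker {m} (no column {c!r})")
        markers[m] = df[cols].to_numpy(dtype=float)
    if df.isna().any().any():
        rows = (df.isna().any(axis=1)).to_numpy().nonzero()[0] + 2  # header = line 1
        raise ValueError(f"ragged/incomplete rows at lines {rows.tolist()}")
    return MarkerTrajectorySet(
        times=df["time"].to_numpy(dtype=float),
        markers=markers,
        rate_nominal=rate_nominal,
        axis_roles=axis_roles_for("MoCap"),
    )


def write_marker_csv(markers: MarkerTrajectorySet, path: str | Path) -> None:
    data: dict[str, np.ndarray] = {"time": markers.times}
    for m in PELVIS_MARKERS:
        for k, ax in enumerate("xyz"):
            data[f"{m}_{ax}"] = markers.markers[m][:, k]
    # shortest exact round-trip form of each float
    pd.DataFrame(data).to_csv(
        path, index=False, float_format=lambda v: repr(float(v))
    )
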