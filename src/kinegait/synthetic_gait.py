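"""Synthetic skeletal walking trials with exact ground truth.

The generator emulates what a depth camera's body tracker sees when a
subject walks straight toward the device: ~30 fps frames with timestamp
jitter, ankle depth traces that alternate stance plateaus with smooth swing
transitions, pelvis translation at constant mean speed with vertical and
lateral sinusoidal oscillation, and additive Gaussian joint noise.  Every
trial comes with its generating truth — event instants, the eight
spatio-temporal parameters, per-cycle CoM excursions — so the full analysis
pipeline can be validated by parameter recovery rather than against human
recordings.

Model
-----
Each ankle advances one stride length per cycle.  During stance (a fraction
``duty_factor`` of the cycle) its depth is constant; during swing it follows
a minimum-jerk profile 10s^3 − 15s^4 + 6s^5, which has zero velocity and
acceleration at both phase borders — deliberately the hardest case for a
velocity-threshold event detector, since the ankle creeps sub-threshold at
early and late swing.  The two sides are offset so that contralateral
stance onsets split the cycle according to the configured step-length
ratio; with a duty factor above 0.5 the double-support phases emerge from
the overlap of the two stance patterns.  The pelvis (hip midpoint)
translates toward the camera at the constant mean speed
stride_length / stride_time, so the true per-cycle antero-posterior CoM
excursion equals the stride length exactly.

Presets
-------
``healthy``: 1.40 m stride, 1.02 s cycle, duty 0.60, symmetric.
``hemiplegic``: 0.76 m stride, 1.62 s cycle, duty 0.67, lateral sway
roughly doubled, affected-side step length 0.8× the unaffected side.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .skeleton_io import SkeletonTrajectorySet, axis_roles_for

__all__ = [
    "Asymmetry",
    "SyntheticGaitConfig",
    "TrueEvent",
    "GroundTruth",
    "preset",
    "simulate_walk",
    "emit_paired_trials",
]

_HIP_HALF_WIDTH = 0.10  # m, lateral hip offset from the midline
_HIP_HEIGHT = 0.90  # m
_ANKLE_HEIGHT = 0.08  # m
_FOOT_LEAD = 0.05  # m, foot joint slightly nearer the camera than the ankle


@dataclass(frozen=True)
class Asymmetry:
    """Affected-side (left) vs unaffected-side ratios; 1.0 = symmetric.

    step_ratio : affected / unaffected step length (and step time).
    stance_ratio : affected / unaffected stance-phase duration.
    """

    step_ratio: float = 1.0
    stance_ratio: float = 1.0


@dataclass(frozen=True)
class SyntheticGaitConfig:
    """Generating parameters of one walking trial.

    Defaults are the healthy preset: 1.40 m strides at 1.02 s per cycle
    with a 0.60 duty factor; lateral and vertical CoM amplitudes are half
    the intended peak-to-peak excursion.  ``noise_sd`` (3 mm) reflects
    typical body-tracking joint jitter.
    """

    stride_length: float = 1.40  # m
    stride_time: float = 1.02  # s
    duty_factor: float = 0.60  # stance fraction of the cycle
    start_depth: float = 5.5  # m, where tracking begins
    stop_depth: float = 1.0  # m, closest approach
    v_amplitude: float = 0.022  # m, half peak-to-peak vertical CoM
    ml_amplitude: float = 0.021  # m, half peak-to-peak lateral CoM
    asymmetry: Asymmetry = field(default_factory=Asymmetry)
    fps: float = 30.0
    timestamp_jitter_sd: float = 0.002  # s
    noise_sd: float = 0.003  # m per joint coordinate
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.start_depth > self.stop_depth > 0:
            raise ValueError("need start_depth > stop_depth > 0")
        if not 0.5 < self.duty_factor < 0.8:
            raise ValueError("duty_factor must lie in (0.5, 0.8)")
        if self.stride_length <= 0 or self.stride_time <= 0:
            raise ValueError("stride_length and stride_time must be positive")

    @property
    def phase_split(self) -> float:
        """Fraction of the cycle at which the affected (left) side strikes."""
        rho = self.asymmetry.step_ratio
        return rho / (1.0 + rho)

    def duty(self, side: str) -> float:
        d = self.duty_factor
        if side == "left":
            d = d * self.asymmetry.stance_ratio
        return float(min(d, 0.95))


def preset(name: str) -> SyntheticGaitConfig:
    """Named walking conditions with literature-scale central values."""
    if name == "healthy":
        return SyntheticGaitConfig(
            stride_length=1.40,
            stride_time=1.02,
            duty_factor=0.60,
            ml_amplitude=0.021,
            v_amplitude=0.022,
        )
    if name == "hemiplegic":
        return SyntheticGaitConfig(
            stride_length=0.76,
            stride_time=1.62,
            duty_factor=0.67,
            ml_amplitude=0.046,
            v_amplitude=0.014,
            asymmetry=Asymmetry(step_ratio=0.8, stance_ratio=1.0),
        )
    raise ValueError(f"unknown preset {name!r}; expected 'healthy' or 'hemiplegic'")


@dataclass(frozen=True)
class TrueEvent:
    side: str
    kind: str  # "stance_onset" | "swing_onset"
    time: float
    depth: float


@dataclass
class GroundTruth:
    """Generating truth of one simulated trial."""

    config: SyntheticGaitConfig
    n_strides: int
    events: list[TrueEvent]
    cycles: pd.DataFrame  # one row per (side, cycle): the eight parameters
    com_excursions_mm: dict[str, float]  # ap / ml / v, peak-to-peak

    def events_of(self, side: str, kind: str) -> list[TrueEvent]:
        return [e for e in self.events if e.side == side and e.kind == kind]


def _minimum_jerk(s: np.ndarray) -> np.ndarray:
    return 10.0 * s**3 - 15.0 * s**4 + 6.0 * s**5


def _ankle_depth(
    t: np.ndarray, t0: float, z0: float, L: float, T: float, d: float, n: int
) -> np.ndarray:
    """Piecewise plateau/min-jerk depth of one ankle.

    Stance onsets at t0 + k*T (k = 0..n) with depth z0 − k*L; cycle −1
    provides a lead-in swing so the first onset is a genuine transition;
    after onset n the ankle stays in stance.
    """
    k = np.floor((t - t0) / T).astype(int)
    k = np.clip(k, -1, n)
    tau = t - t0 - k * T
    z = z0 - k * L
    swing = (tau > d * T) & (k < n)
    s = np.zeros_like(t)
    s[swing] = _minimum_jerk((tau[swing] - d * T) / ((1.0 - d) * T))
    return z - L * s


def _interval_overlap(
    window: tuple[float, float], intervals: list[tuple[float, float]]
) -> float:
    lo, hi = window
    total = 0.0
    for a, b in intervals:
        total += max(0.0, min(b, hi) - max(a, lo))
    return total


def _stance_intervals(
    t0: float, d: float, T: float, n: int, t_end: float
) -> list[tuple[float, float]]:
    iv = [(0.0, t0 - T)] if t0 - T > 0 else []  # pre-trial plateau
    iv += [(t0 + k * T, t0 + k * T + d * T) for k in range(-1, n)]
    iv.append((t0 + n * T, t_end))  # final stance holds to the end
    return iv


def simulate_walk(
    config: SyntheticGaitConfig, n_strides: int = 4
) -> tuple[SkeletonTrajectorySet, GroundTruth]:
    """Generate one walking trial and its ground truth.

    A trial of ``n_strides`` full cycles per leg needs a depth budget of
    (n_strides + 1) × stride_length between ``start_depth`` and
    ``stop_depth``; if the requested count does not fit, the walk is
    truncated with a warning.  Identical configs (including ``seed``)
    produce bitwise-identical output.
    """
    if n_strides < 2:
        raise ValueError("n_strides must be at least 2")
    L, T = config.stride_length, config.stride_time
    n_fit = int(np.floor((config.start_depth - L - config.stop_depth) / L))
    if n_fit < 1:
        raise ValueError(
            "depth window too short for even one stride; "
            "increase start_depth or shorten the stride"
        )
    if n_strides > n_fit:
        warnings.warn(
            f"requested {n_strides} strides exceed the depth window; "
            f"truncated to {n_fit}",
            stacklevel=2,
        )
        n_strides = n_fit
    n = n_strides

    phi = config.phase_split
    d_left, d_right = config.duty("left"), config.duty("right")
    t0_right = T
    t0_left = T * (1.0 + phi)
    z0_right = config.start_depth - L
    z0_left = z0_right - phi * L
    t_end = t0_left + n * T + d_left * T + 0.3

    rng = np.random.default_rng(config.seed)
    t = np.arange(0.0, t_end, 1.0 / config.fps)
    if config.timestamp_jitter_sd > 0:
        t = t + rng.normal(0.0, config.timestamp_jitter_sd, t.size)
        t = np.sort(np.abs(t))
        # enforce strict monotonicity after jitter
        t = np.maximum.accumulate(t + 1e-9 * np.arange(t.size))

    ankle_l = _ankle_depth(t, t0_left, z0_left, L, T, d_left, n)
    ankle_r = _ankle_depth(t, t0_right, z0_right, L, T, d_right, n)
    com_depth = config.start_depth - (L / T) * t
    com_x = config.ml_amplitude * np.sin(2.0 * np.pi * t / T)
    com_y = _HIP_HEIGHT + config.v_amplitude * np.sin(4.0 * np.pi * t / T)

    def col(x, y, z):
        return np.column_stack([x, y, z])

    ones = np.ones_like(t)
    joints = {
        "ANKLE_LEFT": col(-_HIP_HALF_WIDTH * ones, _ANKLE_HEIGHT * ones, ankle_l),
        "ANKLE_RIGHT": col(_HIP_HALF_WIDTH * ones, _ANKLE_HEIGHT * ones, ankle_r),
        "FOOT_LEFT": col(
            -_HIP_HALF_WIDTH * ones, 0.03 * ones, ankle_l - _FOOT_LEAD
        ),
        "FOOT_RIGHT": col(
            _HIP_HALF_WIDTH * ones, 0.03 * ones, ankle_r - _FOOT_LEAD
        ),
        "HIP_LEFT": col(com_x - _HIP_HALF_WIDTH, com_y, com_depth),
        "HIP_RIGHT": col(com_x + _HIP_HALF_WIDTH, com_y, com_depth),
    }
    if config.noise_sd > 0:
        for name in joints:
            joints[name] = joints[name] + rng.normal(
                0.0, config.noise_sd, joints[name].shape
            )

    traj = SkeletonTrajectorySet(
        trial_id=f"synthetic-{config.seed}",
        system="MAK",
        fps_nominal=config.fps,
        times=t - t[0],
        joints=joints,
        axis_roles=axis_roles_for("MAK"),
    )
    return traj, _ground_truth(config, n, t0_left, t0_right, z0_left, z0_right, t_end)


def _ground_truth(
    config: SyntheticGaitConfig,
    n: int,
    t0_left: float,
    t0_right: float,
    z0_left: float,
    z0_right: float,
    t_end: float,
) -> GroundTruth:
    L, T = config.stride_length, config.stride_time
    phi = config.phase_split
    events: list[TrueEvent] = []
    side_params = {
        "left": (t0_left, z0_left, config.duty("left")),
        "right": (t0_right, z0_right, config.duty("right")),
    }
    for side, (t0, z0, d) in side_params.items():
        for k in range(0, n + 1):
            events.append(
                TrueEvent(side, "stance_onset", t0 + k * T, z0 - k * L)
            )
        for k in range(-1, n):
            events.append(
                TrueEvent(side, "swing_onset", t0 + k * T + d * T, z0 - k * L)
            )
    events.sort(key=lambda e: (e.time, e.side))

    stance = {
        side: _stance_intervals(t0, d, T, n, t_end)
        for side, (t0, _, d) in side_params.items()
    }
    rows = []
    for side, (t0, _, d) in side_params.items():
        other = "right" if side == "left" else "left"
        step_frac = phi if side == "left" else 1.0 - phi
        for k in range(n):
            window = (t0 + k * T, t0 + (k + 1) * T)
            own_overlap = _interval_overlap(window, stance[side])
            both = 0.0
            for a, b in stance[side]:
                seg = (max(a, window[0]), min(b, window[1]))
                if seg[1] > seg[0]:
                    both += _interval_overlap(seg, stance[other])
            rows.append(
                {
                    "side": side,
                    "cycle": k,
                    "stride_length": L,
                    "stride_time": T,
                    "step_length": step_frac * L,
                    "step_time": step_frac * T,
                    "double_support": both,
                    "foot_off_pct": 100.0 * own_overlap / T,
                    "walking_speed": L / T,
                    "cadence": 120.0 / T,
                }
            )
    return GroundTruth(
        config=config,
        n_strides=n,
        events=events,
        cycles=pd.DataFrame(rows),
        com_excursions_mm={
            "ap": 1000.0 * L,
            "ml": 2000.0 * config.ml_amplitude,
            "v": 2000.0 * config.v_amplitude,
        },
    )


def emit_paired_trials(
    config: SyntheticGaitConfig,
    bias: float | dict[str, float] = 1.0,
    noise_sd: float | dict[str, float] = 0.0,
    target_r: float | None = None,
    n_trials: int = 30,
    between_trial_cv: float = 0.08,
    group: str = "healthy",
    seed: int | None = None,
) -> tuple[SkeletonTrajectorySet, SkeletonTrajectorySet, pd.DataFrame]:
    """Paired measured/actual parameter tables with known bias and noise.

    For each of the eight parameters, trial-level reference values are the
    config's truth scattered with a ``between_trial_cv`` coefficient of
    variation; test-system values are ``bias × actual + noise``.  With
    ``target_r`` given, the noise SD per parameter is set to
    bias·sd(actual)·sqrt(1/r² − 1), which makes the expected Pearson
    correlation equal ``target_r``.  Returns a noisy test trial, a
    noise-free reference trial (same walking truth), and the tidy pair
    table (parameter, group, trial, measured, actual).
    """
    rng = np.random.default_rng(seed)
    test_cfg = replace(config, seed=0 if seed is None else seed)
    ref_cfg = replace(test_cfg, noise_sd=0.0, timestamp_jitter_sd=0.0)
    test_traj, truth = simulate_walk(test_cfg)
    ref_traj, _ = simulate_walk(ref_cfg)

    truths = truth.cycles.drop(columns=["side", "cycle"]).mean()
    rows = []
    for parameter, center in truths.items():
        b = bias[parameter] if isinstance(bias, dict) else bias
        actual = center * (1.0 + between_trial_cv * rng.standard_normal(n_trials))
        if target_r is not None:
            sigma = (
                abs(b) * float(np.std(actual, ddof=1))
                * np.sqrt(max(1.0 / target_r**2 - 1.0, 0.0))
            )
        else:
            sigma = noise_sd[parameter] if isinstance(noise_sd, dict) else noise_sd
        measured = b * actual + sigma * rng.standard_normal(n_trials)
        for i in range(n_trials):
            rows.append(
                {
                    "parameter": parameter,
                    "group": group,
                    "trial": i,
                    "measured": measured[i],
                    "actual": actual[i],
                }
            )
    return test_traj, ref_traj, pd.DataFrame(rows)
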