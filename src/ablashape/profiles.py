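"""Ablation profiles and their kinematic discretization.

An ablation profile is a treatment program: an ordered series of
(power, duration, retraction distance) intervals executed while the
ablation probe is withdrawn along its axis.  The axial coordinate runs
from the deepest planned position of the heat source (``position 0``,
the profile starting point) toward the entry; retraction increases it.

Because the robot cannot track linear speeds below ~1 mm/s, slow moving
intervals are discretized into short 2 mm / 2 s retraction steps followed
by a waiting period, chosen so that the mean speed of every segment
equals the commanded speed.  :func:`discretize` reproduces that stepping.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "AblationInterval",
    "AblationProfile",
    "ProbeSchedule",
    "ValidationError",
    "total_energy",
    "interval_speed",
    "discretize",
    "probe_position",
    "profile_power",
    "speed_at",
    "load_profile",
    "save_profile",
    "study_profiles",
    "SHAPE_LABELS",
]

SHAPE_LABELS = ("OVAL", "LONG", "HOUR", "TEAR", "PEAR")


class ValidationError(ValueError):
    """Raised when a profile, interval or schedule violates its invariants."""


@dataclass(frozen=True)
class AblationInterval:
    """One program interval: constant power while retracting ``distance`` mm.

    Parameters
    ----------
    power : float
        Generator power setting in watts; must be positive.
    duration : float
        Interval duration in seconds; must be positive.
    distance : float
        Axial retraction during the interval in millimeters; ``0`` for a
        static (fixed-probe) interval.
    """

    power: float
    duration: float
    distance: float = 0.0

    def __post_init__(self) -> None:
        if not self.power > 0:
            raise ValidationError(f"power must be > 0, got {self.power}")
        if not self.duration > 0:
            raise ValidationError(f"duration must be > 0, got {self.duration}")
        if self.distance < 0:
            raise ValidationError(f"distance must be >= 0, got {self.distance}")


@dataclass(frozen=True)
class AblationProfile:
    """A named treatment program made of ordered intervals."""

    name: str
    intervals: tuple[AblationInterval, ...]
    shape_label: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "intervals", tuple(self.intervals))
        if len(self.intervals) == 0:
            raise ValidationError("profile needs at least one interval")
        if self.shape_label not in SHAPE_LABELS:
            raise ValidationError(
                f"shape_label must be one of {SHAPE_LABELS}, got {self.shape_label!r}"
            )

    @property
    def total_duration(self) -> float:
        """Total program duration in seconds."""
        return float(sum(iv.duration for iv in self.intervals))

    @property
    def total_distance(self) -> float:
        """Total probe retraction (trajectory length) in millimeters."""
        return float(sum(iv.distance for iv in self.intervals))

    @property
    def is_standard(self) -> bool:
        """Standard (fixed-probe, ellipsoidal) programs have zero travel."""
        return self.total_distance == 0.0


@dataclass(frozen=True)
class ProbeSchedule:
    """Timestamped axial waypoints of the heat-source center.

    Positions are millimeters from the profile starting point (deepest
    source position); between waypoints motion is linear.  Dwells are
    represented by consecutive waypoints with equal position.
    """

    waypoints: tuple[tuple[float, float], ...]
    speed_threshold: float = 1.0
    step: float = 2.0
    move_time: float = 2.0

    def __post_init__(self) -> None:
        wp = tuple((float(t), float(p)) for t, p in self.waypoints)
        object.__setattr__(self, "waypoints", wp)
        times = np.array([t for t, _ in wp])
        pos = np.array([p for _, p in wp])
        if len(wp) < 2:
            raise ValidationError("schedule needs at least two waypoints")
        if not np.all(np.diff(times) > 0):
            raise ValidationError("waypoint times must be strictly increasing")
        if np.any(np.diff(pos) < -1e-12):
            raise ValidationError("waypoint positions must be non-decreasing")
        if times[0] != 0 or pos[0] != 0:
            raise ValidationError("schedule must start at (t=0, position=0)")

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.waypoints])

    @property
    def positions(self) -> np.ndarray:
        return np.array([p for _, p in self.waypoints])

    @property
    def total_duration(self) -> float:
        return self.waypoints[-1][0]

    @property
    def total_distance(self) -> float:
        return self.waypoints[-1][1]


def total_energy(profile: AblationProfile) -> float:
    """Delivered energy of the program, Σ power×duration, in kilojoules."""
    return sum(iv.power * iv.duration for iv in profile.intervals) / 1000.0


def interval_speed(interval: AblationInterval) -> float:
    """Commanded retraction speed of an interval in mm/s (0 when static)."""
    if not interval.duration > 0:
        raise ValidationError("interval duration must be > 0")
    return interval.distance / interval.duration


def discretize(
    profile: AblationProfile,
    step: float = 2.0,
    move_time: float = 2.0,
    speed_threshold: float = 1.0,
) -> ProbeSchedule:
    """Turn a profile into an executable probe schedule.

    Moving intervals slower than ``speed_threshold`` become alternating
    (``move_time`` s, ``step`` mm) retraction steps and waiting periods so
    that every segment's mean speed equals the commanded interval speed;
    a final partial step gets proportionally scaled move/dwell times.
    Static intervals become a single dwell and intervals at or above the
    threshold a single constant-speed move.  Total time and distance are
    conserved exactly.
    """
    if step <= 0 or move_time <= 0:
        raise ValidationError("step and move_time must be positive")
    if step / move_time < speed_threshold:
        raise ValidationError(
            "step/move_time must be at least speed_threshold, otherwise the "
            "discretized move segments cannot reach the commanded mean speed"
        )
    t, p = 0.0, 0.0
    t_target, p_target = 0.0, 0.0
    waypoints: list[tuple[float, float]] = [(0.0, 0.0)]

    def _append(t_new: float, p_new: float) -> None:
        waypoints.append((t_new, p_new))

    for iv in profile.intervals:
        v = interval_speed(iv)
        t_target += iv.duration
        p_target += iv.distance
        if iv.distance == 0:
            t += iv.duration
            _append(t, p)
        elif v >= speed_threshold:
            t += iv.duration
            p += iv.distance
            _append(t, p)
        else:
            n_before = len(waypoints)
            remaining = iv.distance
            while remaining > 1e-12:
                s = min(step, remaining)
                seg_time = s / v
                mt = move_time * (s / step)
                t += mt
                p += s
                _append(t, p)
                dwell = seg_time - mt
                if dwell > 1e-12:
                    t += dwell
                    _append(t, p)
                remaining -= s
            if len(waypoints) == n_before:  # sub-epsilon distance: plain move
                _append(t_target, p_target)
        # kill accumulated float drift so conservation holds exactly
        waypoints[-1] = (t_target, p_target)
        t, p = t_target, p_target
    waypoints[-1] = (profile.total_duration, profile.total_distance)
    return ProbeSchedule(
        waypoints=tuple(waypoints),
        speed_threshold=speed_threshold,
        step=step,
        move_time=move_time,
    )


def probe_position(schedule: ProbeSchedule, t: float | np.ndarray) -> float | np.ndarray:
    """Axial source position (mm from the profile start) at time ``t``.

    Piecewise-linear interpolation between waypoints; ``t`` must lie in
    ``[0, total duration]``.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < -1e-9) or np.any(t_arr > schedule.total_duration + 1e-9):
        raise ValidationError(
            f"t must lie within [0, {schedule.total_duration}] s"
        )
    out = np.interp(t_arr, schedule.times, schedule.positions)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def profile_power(profile: AblationProfile) -> Callable[[float], float]:
    """Planned generator power as a function of time (piecewise constant).

    Power is held constant within each interval and switches instantly at
    interval boundaries; the last interval's power applies at the final
    instant.  Power delivery continues during discretized dwell periods.
    """
    edges = np.cumsum([iv.duration for iv in profile.intervals])
    powers = [iv.power for iv in profile.intervals]

    def power_of_t(t: float) -> float:
        if t < 0 or t > edges[-1] + 1e-9:
            raise ValidationError(f"t={t} outside program duration")
        k = int(np.searchsorted(edges, t, side="right"))
        return powers[min(k, len(powers) - 1)]

    return power_of_t


def speed_at(profile: AblationProfile, z: float) -> float:
    """Commanded probe speed (mm/s) at axial position ``z`` of the program.

    If any static interval takes place at ``z`` the speed is 0 (the probe
    dwells there); otherwise the speed of the moving interval covering
    ``z``.  ``z`` outside [0, total distance] is an error.
    """
    if z < -1e-9 or z > profile.total_distance + 1e-9:
        raise ValidationError(f"z={z} outside trajectory [0, {profile.total_distance}]")
    start = 0.0
    best: float | None = None
    for iv in profile.intervals:
        end = start + iv.distance
        if start - 1e-9 <= z <= end + 1e-9:
            v = interval_speed(iv)
            if iv.distance == 0:
                return 0.0
            best = v if best is None else min(best, v)
        start = end
    if best is None:  # numerically at a boundary
        raise ValidationError(f"no interval covers z={z}")
    return best


# ---------------------------------------------------------------------------
# serialization and the shipped study-program fixtures


def _profile_to_dict(profile: AblationProfile) -> dict:
    return {
        "name": profile.name,
        "shape_label": profile.shape_label,
        "intervals": [
            {"power_w": iv.power, "duration_s": iv.duration, "distance_mm": iv.distance}
            for iv in profile.intervals
        ],
    }


def _profile_from_dict(d: dict) -> AblationProfile:
    return AblationProfile(
        name=d["name"],
        shape_label=d["shape_label"],
        intervals=tuple(
            AblationInterval(
                power=float(iv["power_w"]),
                duration=float(iv["duration_s"]),
                distance=float(iv.get("distance_mm", 0.0)),
            )
            for iv in d["intervals"]
        ),
    )


def save_profile(profile: AblationProfile, path: str | Path) -> None:
    """Write a profile definition to YAML."""
    Path(path).write_text(yaml.safe_dump(_profile_to_dict(profile), sort_keys=False))


def load_profile(path: str | Path) -> AblationProfile:
    """Read a profile definition from YAML (or JSON — a YAML subset)."""
    return _profile_from_dict(yaml.safe_load(Path(path).read_text()))


def study_profiles() -> dict[str, AblationProfile]:
    """The ten shipped study profiles, keyed by name.

    Six standard fixed-probe programs (OVAL, 60/100 W × 120/240/360 s)
    and four configurable programs (LONG, HOUR, TEAR, PEAR; all 60 W,
    600 s total).
    """
    root = importlib.resources.files("ablashape").joinpath("data/profiles")
    out: dict[str, AblationProfile] = {}
    for res in sorted(root.iterdir(), key=lambda r: r.name):
        if res.name.endswith(".yaml"):
            prof = _profile_from_dict(yaml.safe_load(res.read_text()))
            out[prof.name] = prof
    return out
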