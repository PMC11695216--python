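"""Contour morphometry of segmented ablation cross-sections.

Widths are measured perpendicular to the probe axis at 5 mm steps along
the planned trajectory (a single point at z = 0 for fixed-probe
shapes); head and tail are the axial extents of the ablation zone beyond
the proximal (entry-side) and distal ends of the trajectory.  Volume and
sphericity of the revolved contour support comparison against catalogue
ellipsoids.

Coordinates: z is measured in mm from the trajectory start (the deepest
planned source position) and increases toward the entry.  Images carry
``axis_column``/``start_row``/``scale`` metadata, so masks need no
registration: row = start_row − z / scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .profiles import ValidationError

__all__ = [
    "WidthProfile",
    "MeasurementError",
    "measurement_points",
    "width_at",
    "head_tail",
    "measure_profile",
    "width_function",
    "revolve_volume",
    "revolve_surface",
    "sphericity",
    "summarize",
    "widths_table",
]


class MeasurementError(ValueError):
    """Raised when a measurement cannot be made (e.g. empty mask)."""


@dataclass
class WidthProfile:
    """Per-sample morphometry: widths along the axis plus head/tail.

    ``points`` is an ordered list of (z_mm, width_mm) at the 5 mm
    measurement grid; ``head``/``tail`` are the extents beyond the
    trajectory; ``length_total`` = head + trajectory + tail.
    """

    points: list[tuple[float, float]]
    head: float
    tail: float
    length_total: float
    shape_label: str | None = None
    sample_id: str | None = None

    @property
    def z(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def widths(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])


def measurement_points(trajectory_length: float, step: float = 5.0) -> list[float]:
    """Measurement z positions: multiples of ``step`` within the trajectory.

    ``{0, step, 2·step, …}`` not exceeding the trajectory length (the
    endpoint is included only when the length is divisible); a zero
    length trajectory (fixed-probe shape) has the single point ``[0]``.
    """
    if trajectory_length < 0:
        raise ValidationError("trajectory_length must be >= 0")
    if step <= 0:
        raise ValidationError("step must be > 0")
    n = int(np.floor(trajectory_length / step + 1e-9))
    return [i * step for i in range(n + 1)]


def _z_to_row(meta, z: float) -> int:
    return int(round(meta.start_row - z / meta.scale))


def width_at(mask: np.ndarray, meta, z: float) -> float:
    """Width (mm) of the foreground run crossing the probe axis at depth z.

    ``meta`` is any object with ``scale``, ``axis_column`` and
    ``start_row`` attributes (typically a :class:`CrossSectionImage`).
    Returns 0 when the axis pixel at that depth is background.
    """
    row = _z_to_row(meta, z)
    if not 0 <= row < mask.shape[0]:
        raise MeasurementError(f"z={z} mm maps to row {row} outside the raster")
    line = mask[row]
    c = meta.axis_column
    if not line[c]:
        return 0.0
    lo = c
    while lo - 1 >= 0 and line[lo - 1]:
        lo -= 1
    hi = c
    while hi + 1 < line.size and line[hi + 1]:
        hi += 1
    return (hi - lo + 1) * meta.scale


def head_tail(mask: np.ndarray, meta, trajectory_length: float) -> tuple[float, float]:
    """Axial extents (mm) of the ablation beyond the planned trajectory.

    ``tail`` is the extent distal of the trajectory start (below
    ``start_row``); ``head`` the extent proximal of the trajectory end.
    Both are clipped at 0.
    """
    mask = np.asarray(mask, bool)
    rows = np.nonzero(mask.any(axis=1))[0]
    if rows.size == 0:
        raise MeasurementError("empty mask")
    end_row = _z_to_row(meta, trajectory_length)
    tail = max(0.0, (rows[-1] - meta.start_row) * meta.scale)
    head = max(0.0, (end_row - rows[0]) * meta.scale)
    return head, tail


def measure_profile(
    mask: np.ndarray,
    meta,
    trajectory_length: float | None = None,
    step: float = 5.0,
    shape_label: str | None = None,
    sample_id: str | None = None,
) -> WidthProfile:
    """Measure widths at the 5 mm grid plus head/tail for one sample."""
    if trajectory_length is None:
        trajectory_length = getattr(meta, "trajectory_length", None)
    if trajectory_length is None:
        raise MeasurementError("trajectory_length not provided and absent from metadata")
    zs = measurement_points(trajectory_length, step)
    pts = [(z, width_at(mask, meta, z)) for z in zs]
    head, tail = head_tail(mask, meta, trajectory_length)
    return WidthProfile(
        points=pts,
        head=head,
        tail=tail,
        length_total=head + trajectory_length + tail,
        shape_label=shape_label,
        sample_id=sample_id if sample_id is not None else getattr(meta, "sample_id", None),
    )


def width_function(mask: np.ndarray, meta) -> tuple[np.ndarray, np.ndarray]:
    """Per-row axial width samples ``(z, w)`` over the full mask extent.

    z runs over every raster row containing foreground (finest available
    sampling); widths are the axis-crossing run extents, 0 where the
    axis pixel is background.
    """
    mask = np.asarray(mask, bool)
    rows = np.nonzero(mask.any(axis=1))[0]
    if rows.size == 0:
        raise MeasurementError("empty mask")
    zs, ws = [], []
    for row in range(rows[0], rows[-1] + 1):
        z = (meta.start_row - row) * meta.scale
        zs.append(z)
        line = mask[row]
        c = meta.axis_column
        if line[c]:
            lo = c
            while lo - 1 >= 0 and line[lo - 1]:
                lo -= 1
            hi = c
            while hi + 1 < line.size and line[hi + 1]:
                hi += 1
            ws.append((hi - lo + 1) * meta.scale)
        else:
            ws.append(0.0)
    order = np.argsort(zs)
    return np.asarray(zs)[order], np.asarray(ws)[order]


def revolve_volume(
    width_fn: Callable[[np.ndarray], np.ndarray] | tuple[np.ndarray, np.ndarray],
    z_range: tuple[float, float] | None = None,
    ds: float = 0.5,
) -> float:
    """Volume (mm³) of the solid of revolution, V = ∫ π (w/2)² dz.

    Accepts either a callable width function with an explicit
    ``z_range``, or a ``(z, w)`` sample pair; integration is by the
    trapezoid rule at a spacing of at most ``ds`` mm.
    """
    z, w = _width_samples(width_fn, z_range, ds)
    if np.any(w < 0):
        raise ValidationError("widths must be >= 0")
    return float(np.trapezoid(np.pi * (w / 2.0) ** 2, z))


def revolve_surface(
    width_fn: Callable[[np.ndarray], np.ndarray] | tuple[np.ndarray, np.ndarray],
    z_range: tuple[float, float] | None = None,
    ds: float = 0.5,
) -> float:
    """Lateral surface (mm²) of the revolved contour, A = ∫ 2π r √(1+r'²) dz."""
    z, w = _width_samples(width_fn, z_range, ds)
    r = w / 2.0
    dr = np.gradient(r, z)
    return float(np.trapezoid(2.0 * np.pi * r * np.sqrt(1.0 + dr**2), z))


def _width_samples(width_fn, z_range, ds) -> tuple[np.ndarray, np.ndarray]:
    if callable(width_fn):
        if z_range is None:
            raise ValidationError("z_range required with a callable width function")
        z0, z1 = z_range
        n = max(int(np.ceil((z1 - z0) / ds)), 1) + 1
        z = np.linspace(z0, z1, n)
        w = np.asarray(width_fn(z), dtype=float)
    else:
        z, w = (np.asarray(a, dtype=float) for a in width_fn)
        if z.size > 1:
            span = z[-1] - z[0]
            if span > 0 and (np.diff(z).max() > ds + 1e-9):
                zf = np.linspace(z[0], z[-1], max(int(np.ceil(span / ds)) + 1, 2))
                w = np.interp(zf, z, w)
                z = zf
    return z, w


def sphericity(volume: float, surface: float) -> float:
    """Wadell sphericity ψ = π^{1/3} (6V)^{2/3} / A ∈ (0, 1]."""
    if volume <= 0 or surface <= 0:
        raise ValidationError("volume and surface must be positive")
    return float(np.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / surface)


def widths_table(profiles: Iterable[WidthProfile]) -> pd.DataFrame:
    """Long-format width table (sample_id, shape_label, z_mm, width_mm)."""
    rows = []
    for wp in profiles:
        for z, w in wp.points:
            rows.append(
                {
                    "sample_id": wp.sample_id,
                    "shape_label": wp.shape_label,
                    "z_mm": z,
                    "width_mm": w,
                }
            )
    return pd.DataFrame(rows, columns=["sample_id", "shape_label", "z_mm", "width_mm"])


def summarize(profiles: Sequence[WidthProfile]) -> pd.DataFrame:
    """Per-measurement-point median and IQR of widths across a cohort.

    All samples must share the same z grid; returns a DataFrame with
    columns z_mm, median_mm, iqr_mm, n.
    """
    if len(profiles) < 2:
        raise ValidationError("summarize needs at least 2 samples")
    z0 = [p[0] for p in profiles[0].points]
    for wp in profiles[1:]:
        if [p[0] for p in wp.points] != z0:
            raise ValidationError("mismatched measurement grids across samples")
    W = np.array([[p[1] for p in wp.points] for wp in profiles])
    q1, med, q3 = np.percentile(W, [25, 50, 75], axis=0)
    return pd.DataFrame(
        {
            "z_mm": z0,
            "median_mm": med,
            "iqr_mm": q3 - q1,
            "n": len(profiles),
        }
    )
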