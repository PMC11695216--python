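"""Synthetic cross-section image generator.

Renders simulated ablation masks into photograph-like images of cut
phantom samples: ablated gel is magenta, intact gel off-white, and the
transition at the contour is a 1–2 mm color gradient (the phantom has no
sharp cut-off color, which is why the study's measurement uncertainty is
of that order).  Per-sample variability emulates the generator output
(85–90 % of planned power) and gel inhomogeneity (relative diffusivity
jitter); optional contour artifacts reproduce the lateral extrusions and
proximal indents seen on real samples.

All randomness is seeded; a cohort regenerated from the same spec is
bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.color import hsv2rgb

from . import heatsim
from .profiles import AblationProfile, ValidationError, discretize, profile_power

__all__ = [
    "RenderParams",
    "ContourArtifact",
    "CohortSpec",
    "CrossSectionImage",
    "SceneMask",
    "scene_from_field",
    "render",
    "perturb_contour",
    "generate_cohort",
    "save_image",
    "load_image",
]

#: default phantom colors, HSV with hue in degrees and s, v in [0, 1]
MAGENTA_HSV = (300.0, 0.65, 0.75)
OFFWHITE_HSV = (40.0, 0.06, 0.94)


@dataclass(frozen=True)
class ContourArtifact:
    """A localized contour perturbation.

    ``kind='extrusion'``: outward lateral bump of given amplitude (mm)
    centered at axial position ``z_mm`` (trajectory coordinates) with the
    given axial width.  ``kind='indent'``: inward notch carved into the
    proximal (head) end of the contour around lateral offset ``z_mm``
    from the axis, of given depth (amplitude) and lateral width —
    emulating the probe-cooling heat-sink indent.
    """

    kind: str
    z_mm: float
    amplitude_mm: float
    width_mm: float

    def __post_init__(self) -> None:
        if self.kind not in ("extrusion", "indent"):
            raise ValidationError("artifact kind must be 'extrusion' or 'indent'")
        if self.amplitude_mm < 0 or self.width_mm <= 0:
            raise ValidationError("artifact amplitude must be >= 0 and width > 0")


@dataclass(frozen=True)
class RenderParams:
    """Appearance of the rendered cross-section photograph.

    ``boundary_sd``/``boundary_corr`` control a smooth random in/out
    displacement of the ablation contour (a correlated Gaussian field,
    sd in mm, correlation length in mm) emulating local gel
    inhomogeneity — the source of the irregular contours seen on real
    samples; set ``boundary_sd=0`` for geometrically exact renders.
    """

    scale: float = 0.2  # mm per pixel
    fg_color: tuple[float, float, float] = MAGENTA_HSV
    bg_color: tuple[float, float, float] = OFFWHITE_HSV
    gradient_width: float = 1.5  # mm of linear blend at the boundary
    noise_sd: float = 0.02  # per-channel RGB noise
    boundary_sd: float = 0.4  # mm, local contour roughness
    boundary_corr: float = 8.0  # mm, roughness correlation length
    artifact_spec: tuple[ContourArtifact, ...] = ()

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValidationError("scale must be > 0")
        if self.gradient_width < 0:
            raise ValidationError("gradient_width must be >= 0")
        if self.boundary_sd < 0 or self.boundary_corr <= 0:
            raise ValidationError("boundary_sd must be >= 0 and boundary_corr > 0")
        if tuple(self.fg_color) == tuple(self.bg_color):
            raise ValidationError("fg and bg colors must differ")
        object.__setattr__(self, "artifact_spec", tuple(self.artifact_spec))


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a replicated-sample cohort for one profile.

    ``efficiency_range`` is the per-sample generator output fraction of
    planned power (observed 0.85–0.90); it scales the thermal model's
    net deposition efficiency around the range midpoint.
    """

    profile: AblationProfile
    n: int
    efficiency_range: tuple[float, float] = (0.85, 0.90)
    diffusivity_jitter: float = 0.03  # relative sd of per-sample diffusivity
    render: RenderParams = field(default_factory=RenderParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValidationError("cohort size n must be >= 2")
        lo, hi = self.efficiency_range
        if not (0 < lo <= hi <= 1):
            raise ValidationError("efficiency_range must satisfy 0 < lo <= hi <= 1")
        if self.diffusivity_jitter < 0:
            raise ValidationError("diffusivity_jitter must be >= 0")


@dataclass
class SceneMask:
    """Full 2-D cross-section mask in physical (mm) coordinates.

    ``values`` is (lateral, axial): row ``axis_index`` is the probe axis,
    columns run distal → proximal with the trajectory start (profile
    position 0) at column ``start_index``; isotropic ``cell`` mm spacing.
    ``values`` may be boolean (a hard mask) or float (a signed level-set,
    foreground where ≥ 0); the level-set form carries sub-cell contour
    position through rendering.
    """

    values: np.ndarray
    cell: float
    axis_index: int
    start_index: int
    trajectory_length: float

    @property
    def mask(self) -> np.ndarray:
        v = self.values
        return v if v.dtype == bool else v >= 0.0


@dataclass
class CrossSectionImage:
    """A rendered (or loaded) color cross-section photograph.

    ``pixels`` is (H, W, 3) float RGB in [0, 1].  Rows run proximal
    (entry, top) → distal (bottom): ``start_row`` is the trajectory start
    and smaller rows are *further along* the retraction.  ``axis_column``
    is the probe axis.  ``truth_mask`` carries the ground-truth
    segmentation when the image is synthetic.
    """

    pixels: np.ndarray
    scale: float
    axis_column: int
    start_row: int
    truth_mask: np.ndarray | None = None
    trajectory_length: float | None = None
    sample_id: str | None = None

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValidationError("scale must be > 0")
        if not 0 <= self.axis_column < self.pixels.shape[1]:
            raise ValidationError("axis_column outside image width")


def scene_from_field(
    maxfield: heatsim.MaxTemperatureField, threshold: float | None = None
) -> SceneMask:
    """Mirror a simulated field into a full cross-section level-set.

    The scene stores the maximum temperature minus the coagulation
    threshold, so the zero level is the ablation contour; the final
    thresholding happens at render resolution, which keeps sub-grid-cell
    contour shifts (the per-sample variability of interest) measurable.
    """
    grid = maxfield.grid
    if abs(grid.dr - grid.dz) > 1e-12:
        raise ValidationError("scene construction requires an isotropic grid (dr == dz)")
    if threshold is None:
        threshold = maxfield.params.threshold_temp
    full = heatsim.mirror_mask(maxfield.values - threshold)
    return SceneMask(
        values=full,
        cell=grid.dr,
        axis_index=grid.nr - 1,
        start_index=int(round(maxfield.trajectory_start_z / grid.dz)),
        trajectory_length=maxfield.trajectory_length,
    )


def _hsv_blend(f: np.ndarray, fg: Sequence[float], bg: Sequence[float]) -> np.ndarray:
    """Blend bg→fg in HSV (hue circular, shortest arc); f=1 is foreground."""
    h_fg, s_fg, v_fg = fg
    h_bg, s_bg, v_bg = bg
    dh = (h_fg - h_bg + 180.0) % 360.0 - 180.0
    h = (h_bg + f * dh) % 360.0
    s = s_bg + f * (s_fg - s_bg)
    v = v_bg + f * (v_fg - v_bg)
    hsv = np.stack([h / 360.0, s, v], axis=-1)
    return hsv2rgb(hsv)


def render(
    mask2d: SceneMask | np.ndarray,
    params: RenderParams | None = None,
    seed: int | np.random.SeedSequence = 0,
    *,
    cell_mm: float = 0.5,
    axis_index: int | None = None,
    start_index: int | None = None,
    trajectory_length: float | None = None,
    sample_id: str | None = None,
) -> CrossSectionImage:
    """Render a physical-coordinate mask into a synthetic photograph.

    The signed distance to the mask boundary is mapped to a linear
    magenta↔off-white blend over ``gradient_width`` (centered on the
    boundary, so the color midpoint coincides with the true contour),
    then seeded per-channel Gaussian noise is added.  The resampled
    ground-truth mask is attached as ``truth_mask``.
    """
    params = params or RenderParams()
    if isinstance(mask2d, SceneMask):
        values, cell_mm = mask2d.values, mask2d.cell
        axis_index = mask2d.axis_index
        start_index = mask2d.start_index
        trajectory_length = mask2d.trajectory_length
    else:
        values = np.asarray(mask2d)
        if values.dtype != bool and not np.issubdtype(values.dtype, np.floating):
            values = values.astype(bool)
        if axis_index is None:
            axis_index = values.shape[0] // 2
        if start_index is None:
            start_index = 0
    h_mm = values.shape[1] * cell_mm
    if params.gradient_width > max(h_mm, values.shape[0] * cell_mm):
        raise ValidationError("gradient_width exceeds the image extent")

    f = cell_mm / params.scale
    level = values.dtype == bool  # hard mask vs signed level-set
    fine = ndimage.zoom(values.astype(float), f, order=1, grid_mode=True, mode="nearest")
    # (lateral, axial) at pixel resolution
    truth_lat_ax = fine >= 0.5 if level else fine >= 0.0
    # image orientation: rows = axial, proximal (entry) at the top
    truth = truth_lat_ax.T[::-1, :].copy()
    H, W = truth.shape
    axis_column = int(round(axis_index * f))
    start_row = (H - 1) - int(round(start_index * f))
    axis_column = min(axis_column, W - 1)

    rng = np.random.default_rng(seed)
    if truth.any() and not truth.all():
        inside = ndimage.distance_transform_edt(truth) - 0.5
        outside = ndimage.distance_transform_edt(~truth) - 0.5
        signed_mm = np.where(truth, inside, -outside) * params.scale
        if params.boundary_sd > 0:
            corr_px = params.boundary_corr / params.scale
            rough = ndimage.gaussian_filter(rng.standard_normal(truth.shape), corr_px)
            sd = rough.std()
            if sd > 0:
                signed_mm = signed_mm + params.boundary_sd * rough / sd
            truth = signed_mm >= 0.0
    else:
        signed_mm = np.where(truth, np.inf, -np.inf)
    if params.gradient_width > 0:
        blend = np.clip(0.5 + signed_mm / params.gradient_width, 0.0, 1.0)
    else:
        blend = truth.astype(float)
    rgb = _hsv_blend(blend, params.fg_color, params.bg_color)
    if params.noise_sd > 0:
        rgb = rgb + rng.normal(0.0, params.noise_sd, rgb.shape)
    rgb = np.clip(rgb, 0.0, 1.0)
    return CrossSectionImage(
        pixels=rgb,
        scale=params.scale,
        axis_column=axis_column,
        start_row=start_row,
        truth_mask=truth,
        trajectory_length=trajectory_length,
        sample_id=sample_id,
    )


def perturb_contour(
    mask2d: SceneMask,
    artifact_spec: Sequence[ContourArtifact],
    seed: int | np.random.SeedSequence = 0,
) -> SceneMask:
    """Apply extrusion/indent artifacts to a physical-coordinate mask.

    Returns a new :class:`SceneMask`; an empty spec is the identity.
    Extrusion sides (left/right of the axis) are drawn from ``seed``.
    Level-set scenes are binarized first (artifacts are cell-resolution
    edits of the contour).
    """
    if not artifact_spec:
        return mask2d
    rng = np.random.default_rng(seed)
    m = mask2d.mask.copy()
    cell = mask2d.cell
    n_lat, n_ax = m.shape
    for art in artifact_spec:
        if art.kind == "extrusion":
            j0 = mask2d.start_index + art.z_mm / cell
            side = 1 if rng.random() < 0.5 else -1
            sigma_j = max(art.width_mm / (2.0 * cell), 1.0)
            jj = np.arange(n_ax)
            bump_px = (art.amplitude_mm / cell) * np.exp(
                -((jj - j0) ** 2) / (2.0 * sigma_j**2)
            )
            for j in np.nonzero(bump_px >= 0.5)[0]:
                col = m[:, j]
                fg = np.nonzero(col)[0]
                if fg.size == 0 or not col[mask2d.axis_index]:
                    continue
                # extend the run crossing the axis outward on one side
                k = mask2d.axis_index
                if side > 0:
                    hi = k
                    while hi + 1 < n_lat and col[hi + 1]:
                        hi += 1
                    new_hi = min(n_lat - 1, hi + int(round(bump_px[j])))
                    col[hi : new_hi + 1] = True
                else:
                    lo = k
                    while lo - 1 >= 0 and col[lo - 1]:
                        lo -= 1
                    new_lo = max(0, lo - int(round(bump_px[j])))
                    col[new_lo : lo + 1] = True
        else:  # indent: carve down from the proximal (high-z) contour end
            i0 = mask2d.axis_index + art.z_mm / cell
            half_px = art.width_mm / (2.0 * cell)
            depth_px = art.amplitude_mm / cell
            ii = np.arange(n_lat)
            depth = depth_px * np.exp(-((ii - i0) ** 2) / (2.0 * max(half_px / 1.5, 1.0) ** 2))
            for i in np.nonzero(depth >= 0.5)[0]:
                row = m[i, :]
                fg = np.nonzero(row)[0]
                if fg.size == 0:
                    continue
                top = fg[-1]
                row[max(0, top - int(round(depth[i])) + 1) : top + 1] = False
    return replace_scene(mask2d, m)


def replace_scene(scene: SceneMask, values: np.ndarray) -> SceneMask:
    return SceneMask(
        values=values,
        cell=scene.cell,
        axis_index=scene.axis_index,
        start_index=scene.start_index,
        trajectory_length=scene.trajectory_length,
    )


def generate_cohort(
    spec: CohortSpec,
    thermal: heatsim.ThermalParams | None = None,
    grid: heatsim.SimulationGrid | None = None,
    trajectory_start_z: float = 20.0,
) -> list[CrossSectionImage]:
    """Simulate and render ``spec.n`` replicate samples of one profile.

    Each sample draws its generator output fraction uniformly from
    ``efficiency_range`` (the generators delivered 85–90 % of planned
    power); the sample's net deposition efficiency is the thermal
    default scaled by that draw relative to the range midpoint, so the
    cohort mean matches a single default run.  Thermal diffusivity gets
    a relative Gaussian jitter (gel inhomogeneity).  Rendering noise and
    artifact placement use per-sample seeds derived from ``spec.seed``,
    so cohorts are fully reproducible.
    """
    thermal = thermal or heatsim.ThermalParams()
    grid = grid or heatsim.SimulationGrid()
    schedule = discretize(spec.profile)
    power = profile_power(spec.profile)
    gen_mid = 0.5 * (spec.efficiency_range[0] + spec.efficiency_range[1])
    images: list[CrossSectionImage] = []
    for i in range(spec.n):
        ss = np.random.SeedSequence([int(spec.seed), i])
        rng = np.random.default_rng(ss)
        gen_factor = rng.uniform(*spec.efficiency_range)
        eff = thermal.efficiency * gen_factor / gen_mid
        factor = 1.0 + rng.normal(0.0, spec.diffusivity_jitter) if spec.diffusivity_jitter > 0 else 1.0
        factor = max(factor, 0.2)
        params_i = replace(thermal, efficiency=eff, diffusivity=thermal.diffusivity * factor)
        fieldmax = heatsim.simulate(
            schedule, power, params_i, grid, trajectory_start_z=trajectory_start_z
        )
        scene = scene_from_field(fieldmax)
        kid_artifact, kid_render = ss.spawn(2)
        if spec.render.artifact_spec:
            scene = perturb_contour(scene, spec.render.artifact_spec, seed=kid_artifact)
        img = render(
            scene,
            spec.render,
            seed=kid_render,
            sample_id=f"{spec.profile.name}-{i:02d}",
        )
        images.append(img)
    return images


# ---------------------------------------------------------------------------
# PNG + JSON sidecar I/O


def save_image(img: CrossSectionImage, path: str | Path) -> None:
    """Write an 8-bit RGB PNG plus a JSON sidecar with the geometry.

    The sidecar (``<stem>.json``) holds scale_mm_per_px, axis_column,
    start_row and trajectory_length_mm; the ground-truth mask, when
    present, goes to ``<stem>_truth.png``.
    """
    path = Path(path)
    arr = np.round(np.clip(img.pixels, 0, 1) * 255).astype(np.uint8)
    Image.fromarray(arr).save(path)
    sidecar = {
        "scale_mm_per_px": img.scale,
        "axis_column": int(img.axis_column),
        "start_row": int(img.start_row),
        "trajectory_length_mm": img.trajectory_length,
        "sample_id": img.sample_id,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    if img.truth_mask is not None:
        Image.fromarray((img.truth_mask * 255).astype(np.uint8)).save(
            path.with_name(path.stem + "_truth.png")
        )


def load_image(path: str | Path) -> CrossSectionImage:
    """Load a PNG written by :func:`save_image` (sidecar required)."""
    path = Path(path)
    arr = np.asarray(Image.open(path).convert("RGB"), dtype=float) / 255.0
    meta = json.loads(path.with_suffix(".json").read_text())
    truth_path = path.with_name(path.stem + "_truth.png")
    truth = None
    if truth_path.exists():
        truth = np.asarray(Image.open(truth_path).convert("L")) > 127
    return CrossSectionImage(
        pixels=arr,
        scale=float(meta["scale_mm_per_px"]),
        axis_column=int(meta["axis_column"]),
        start_row=int(meta["start_row"]),
        truth_mask=truth,
        trajectory_length=meta.get("trajectory_length_mm"),
        sample_id=meta.get("sample_id"),
    )
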