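"""End-to-end study orchestration.

profile → schedule → heat simulation → cohort rendering → segmentation →
morphometry → repeatability statistics, fully seeded: a single global
seed fans out deterministically to per-profile, per-sample streams, so a
rerun with the same configuration reproduces every CSV byte for byte.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import heatsim, imaging, morphometry, segmentation, stats
from .profiles import (
    AblationProfile,
    ProbeSchedule,
    ValidationError,
    discretize,
    load_profile,
    profile_power,
    speed_at,
    study_profiles,
)

__all__ = [
    "ExperimentConfig",
    "StudyReport",
    "run_experiment",
    "power_log",
    "load_config",
]

log = logging.getLogger("ablashape")


@dataclass
class ExperimentConfig:
    """Everything needed to run a seeded repeatability study."""

    profiles: Sequence[AblationProfile]
    n_per_profile: int = 6
    thermal: heatsim.ThermalParams = field(default_factory=heatsim.ThermalParams)
    grid: heatsim.SimulationGrid = field(default_factory=heatsim.SimulationGrid)
    render: imaging.RenderParams = field(default_factory=imaging.RenderParams)
    efficiency_range: tuple[float, float] = (0.85, 0.90)
    diffusivity_jitter: float = 0.03
    margin: float = 1.0
    alpha: float = 0.05
    trajectory_start_z: float = 20.0
    output_dir: Path | None = None
    seed: int = 0
    save_images: bool = False

    def __post_init__(self) -> None:
        self.profiles = list(self.profiles)
        if not self.profiles:
            raise ValidationError("config needs at least one profile")
        names = [p.name for p in self.profiles]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate profile names in config")


@dataclass
class StudyReport:
    """Results of one study run."""

    widths: pd.DataFrame  # sample_id, shape_label, profile, z_mm, width_mm
    repeatability: pd.DataFrame  # profile, group, z_mm, speed_mm_s, repeatability_mm
    shape_summaries: dict[str, pd.DataFrame]  # per-profile median/IQR tables
    sample_metrics: pd.DataFrame  # head/tail/volume/sphericity per sample
    noninferiority: stats.NoninferiorityResult | None
    regression: dict | None
    group_medians: dict[str, float]
    config_seed: int

    def to_json_dict(self) -> dict:
        d: dict = {
            "seed": self.config_seed,
            "group_medians_mm": self.group_medians,
            "per_shape_median_repeatability_mm": {
                prof: float(np.median(g["repeatability_mm"]))
                for prof, g in self.repeatability.groupby("profile")
            },
        }
        if self.noninferiority is not None:
            r = self.noninferiority
            d["noninferiority"] = {
                "p_value": r.p_value,
                "delta_mm": r.delta,
                "ci_upper_mm": r.ci_upper,
                "margin_mm": r.margin,
                "alpha": r.alpha,
                "n_conf": r.n_conf,
                "n_std": r.n_std,
                "noninferior": bool(r.noninferior),
            }
        if self.regression is not None:
            d["speed_regression"] = {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.regression.items()
            }
        return d


def _profile_seed(seed: int, idx: int) -> int:
    """Deterministic per-profile cohort seed derived from the global seed."""
    return int(np.random.SeedSequence([int(seed), 7919, idx]).generate_state(1)[0] % (2**31))


def run_experiment(config: ExperimentConfig) -> StudyReport:
    """Execute all stages for all profiles and assemble the study report.

    Writes ``widths.csv``, ``repeatability.csv``, ``sample_metrics.csv``
    and ``report.json`` (plus per-sample PNGs when ``save_images``) into
    ``output_dir`` when set.  Deterministic per seed.
    """
    t0 = time.perf_counter()
    width_rows: list[dict] = []
    rep_rows: list[dict] = []
    metric_rows: list[dict] = []
    shape_summaries: dict[str, pd.DataFrame] = {}
    out = Path(config.output_dir) if config.output_dir else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    for idx, profile in enumerate(config.profiles):
        t_prof = time.perf_counter()
        spec = imaging.CohortSpec(
            profile=profile,
            n=config.n_per_profile,
            efficiency_range=config.efficiency_range,
            diffusivity_jitter=config.diffusivity_jitter,
            render=config.render,
            seed=_profile_seed(config.seed, idx),
        )
        images = imaging.generate_cohort(
            spec, config.thermal, config.grid, config.trajectory_start_z
        )
        wps: list[morphometry.WidthProfile] = []
        for img in images:
            try:
                mask = segmentation.segment(img)
                wp = morphometry.measure_profile(
                    mask, img, profile.total_distance, shape_label=profile.shape_label
                )
            except Exception:
                log.error("stage failed for sample %s of %s", img.sample_id, profile.name)
                raise
            wps.append(wp)
            zfine, wfine = morphometry.width_function(mask, img)
            vol = morphometry.revolve_volume((zfine, wfine))
            surf = morphometry.revolve_surface((zfine, wfine))
            metric_rows.append(
                {
                    "sample_id": img.sample_id,
                    "profile": profile.name,
                    "shape_label": profile.shape_label,
                    "head_mm": wp.head,
                    "tail_mm": wp.tail,
                    "length_total_mm": wp.length_total,
                    "volume_mm3": vol,
                    "sphericity": morphometry.sphericity(vol, surf) if vol > 0 else np.nan,
                }
            )
            for z, w in wp.points:
                width_rows.append(
                    {
                        "sample_id": img.sample_id,
                        "profile": profile.name,
                        "shape_label": profile.shape_label,
                        "z_mm": z,
                        "width_mm": w,
                    }
                )
            if out is not None and config.save_images:
                imaging.save_image(img, out / f"{img.sample_id}.png")
        shape_summaries[profile.name] = morphometry.summarize(wps)
        group = "standard" if profile.is_standard else "configurable"
        for z in [p[0] for p in wps[0].points]:
            vals = [dict(wp.points)[z] for wp in wps]
            rep_rows.append(
                {
                    "profile": profile.name,
                    "shape_label": profile.shape_label,
                    "group": group,
                    "z_mm": z,
                    "speed_mm_s": speed_at(profile, z),
                    "repeatability_mm": stats.repeatability_at_point(vals),
                }
            )
        log.info(
            "profile %s: %d samples in %.1f s",
            profile.name,
            config.n_per_profile,
            time.perf_counter() - t_prof,
        )

    widths = pd.DataFrame(
        width_rows, columns=["sample_id", "profile", "shape_label", "z_mm", "width_mm"]
    )
    repeat = pd.DataFrame(
        rep_rows,
        columns=["profile", "shape_label", "group", "z_mm", "speed_mm_s", "repeatability_mm"],
    )
    metrics = pd.DataFrame(
        metric_rows,
        columns=[
            "sample_id", "profile", "shape_label", "head_mm", "tail_mm",
            "length_total_mm", "volume_mm3", "sphericity",
        ],
    )

    conf_vals = repeat.loc[repeat["group"] == "configurable", "repeatability_mm"].to_numpy()
    std_vals = repeat.loc[repeat["group"] == "standard", "repeatability_mm"].to_numpy()
    noninf = None
    if conf_vals.size and std_vals.size:
        noninf = stats.mann_whitney_noninferiority(
            conf_vals, std_vals, margin=config.margin, alpha=config.alpha
        )
    group_medians = {
        g: float(np.median(v)) for g, v in
        (("configurable", conf_vals), ("standard", std_vals)) if v.size
    }
    regression = None
    if len(repeat) >= 3 and repeat["speed_mm_s"].nunique() > 1:
        regression = stats.speed_regression(
            repeat["repeatability_mm"].to_numpy(), repeat["speed_mm_s"].to_numpy()
        )

    report = StudyReport(
        widths=widths,
        repeatability=repeat,
        shape_summaries=shape_summaries,
        sample_metrics=metrics,
        noninferiority=noninf,
        regression=regression,
        group_medians=group_medians,
        config_seed=config.seed,
    )
    if out is not None:
        widths.to_csv(out / "widths.csv", index=False, float_format="%.6g")
        repeat.to_csv(out / "repeatability.csv", index=False, float_format="%.6g")
        metrics.to_csv(out / "sample_metrics.csv", index=False, float_format="%.6g")
        (out / "report.json").write_text(
            json.dumps(report.to_json_dict(), indent=2, sort_keys=True)
        )
    log.info("study finished in %.1f s", time.perf_counter() - t0)
    return report


def power_log(
    schedule: ProbeSchedule,
    power_of_t: Callable[[float], float],
    efficiency: float = 1.0,
    capture_interval: float = 30.0,
) -> pd.DataFrame:
    """Synthetic generator log: output power sampled every 30 s.

    The planned power is scaled by the efficiency factor (the generator
    delivered 85–90 % of planned values).  A 600 s program yields 21
    samples (t = 0, 30, …, 600); a zero-duration schedule a single one.
    """
    total = schedule.total_duration
    if total <= 0:
        times = np.array([0.0])
    else:
        times = np.arange(0.0, total + capture_interval / 2, capture_interval)
        times[-1] = min(times[-1], total)
    watts = np.array([efficiency * power_of_t(min(t, total)) for t in times])
    return pd.DataFrame({"t_s": times, "power_w": watts})


def load_config(path: str | Path) -> ExperimentConfig:
    """Build an :class:`ExperimentConfig` from a YAML study file.

    Profile entries are either names of the ten shipped study profiles
    or paths to profile YAML files; thermal/grid/render sections map
    directly onto the corresponding dataclass fields.
    """
    d = yaml.safe_load(Path(path).read_text())
    shipped = study_profiles()
    profiles = []
    for entry in d["profiles"]:
        if entry in shipped:
            profiles.append(shipped[entry])
        else:
            profiles.append(load_profile(entry))
    kwargs: dict = {"profiles": profiles}
    if "thermal" in d:
        kwargs["thermal"] = heatsim.ThermalParams(**d["thermal"])
    if "grid" in d:
        kwargs["grid"] = heatsim.SimulationGrid(**d["grid"])
    if "render" in d:
        kwargs["render"] = imaging.RenderParams(**d["render"])
    for key in (
        "n_per_profile", "efficiency_range", "diffusivity_jitter", "margin",
        "alpha", "trajectory_start_z", "output_dir", "seed", "save_images",
    ):
        if key in d:
            kwargs[key] = tuple(d[key]) if key == "efficiency_range" else d[key]
    return ExperimentConfig(**kwargs)
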