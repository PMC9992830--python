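"""YAML pipeline configuration.

Kernel lengthscales are entered in km (space) and years (time) and squared
internally into the theta divisors; the grid is given as a planar bounding
box in km with a spacing in km.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .field_gpr import GridSpec, KernelParams
from .mobility import (
    DEFAULT_N_RUNS,
    DEFAULT_RETROSPECTION_YEARS,
    DEFAULT_STEP_YEARS,
    DEFAULT_WINDOW_YEARS,
)

__all__ = ["PipelineConfig", "load_config"]

# Non-canonical order-of-magnitude defaults for an anisotropic kernel
# reaching over multiple hundred kilometers and years.
DEFAULT_KERNEL = {
    "theta_x_km": 800.0,
    "theta_y_km": 800.0,
    "theta_t_years": 800.0,
    "tau2": 1.0,
    "eta": 0.1,
}


@dataclass
class PipelineConfig:
    kernel: KernelParams = field(
        default_factory=lambda: KernelParams.from_lengthscales(
            DEFAULT_KERNEL["theta_x_km"],
            DEFAULT_KERNEL["theta_y_km"],
            DEFAULT_KERNEL["theta_t_years"],
            DEFAULT_KERNEL["tau2"],
            DEFAULT_KERNEL["eta"],
        )
    )
    grid: GridSpec | None = None
    times: list[float] = field(default_factory=list)
    retrospection_years: float = DEFAULT_RETROSPECTION_YEARS
    n_runs: int = DEFAULT_N_RUNS
    window_years: float = DEFAULT_WINDOW_YEARS
    step_years: float = DEFAULT_STEP_YEARS
    snp_min: int = 25_000
    contam_max: float = 0.1
    relatedness_threshold: float = 0.245
    mds_dimensions: int = 2
    age_window: tuple[float, float] | None = None


def load_config(path: str | Path | None) -> PipelineConfig:
    """Read a YAML config; missing keys fall back to package defaults."""
    cfg = PipelineConfig()
    if path is None:
        return cfg
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}

    kern = {**DEFAULT_KERNEL, **raw.get("kernel", {})}
    cfg.kernel = KernelParams.from_lengthscales(
        kern["theta_x_km"],
        kern["theta_y_km"],
        kern["theta_t_years"],
        kern["tau2"],
        kern["eta"],
    )
    if "grid" in raw:
        g = raw["grid"]
        bbox = g["bbox_km"]  # [x_min, x_max, y_min, y_max]
        cfg.grid = GridSpec(
            bbox[0] * 1000.0,
            bbox[1] * 1000.0,
            bbox[2] * 1000.0,
            bbox[3] * 1000.0,
            g["spacing_km"] * 1000.0,
        )
    cfg.times = [float(t) for t in raw.get("times", [])]
    mob = raw.get("mobility", {})
    cfg.retrospection_years = float(
        mob.get("retrospection_years", cfg.retrospection_years)
    )
    cfg.n_runs = int(mob.get("n_runs", cfg.n_runs))
    cfg.window_years = float(mob.get("window_years", cfg.window_years))
    cfg.step_years = float(mob.get("step_years", cfg.step_years))
    if "age_window" in mob:
        lo, hi = mob["age_window"]
        cfg.age_window = (float(lo), float(hi))
    qc = raw.get("qc", {})
    cfg.snp_min = int(qc.get("snp_min", cfg.snp_min))
    cfg.contam_max = float(qc.get("contam_max", cfg.contam_max))
    cfg.relatedness_threshold = float(
        qc.get("relatedness_threshold", cfg.relatedness_threshold)
    )
    cfg.mds_dimensions = int(raw.get("mds_dimensions", cfg.mds_dimensions))
    return cfg
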