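"""Mobility vectors and regional diachronic summaries.

A mobility vector points from a sample's burial location to the
maximum-probability cell of its similarity surface in a past time slice —
a simplified proxy for mobility within the individual's (or their
ancestors') lifetime.  Age uncertainty is propagated by Monte-Carlo
resampling of the sample's calibrated age (default 25 runs); per-sample
estimates are then pooled into regional moving-mean curves of vector
length with a standard-error band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .field_gpr import GPModel, GridSpec, predict_field_grid
from .genio import SampleRecord
from .similarity import SimilaritySurface, max_similarity_point, similarity_surface

__all__ = [
    "MobilityVector",
    "MobilityEstimate",
    "RegionalSeries",
    "DEFAULT_RETROSPECTION_YEARS",
    "DEFAULT_N_RUNS",
    "DEFAULT_WINDOW_YEARS",
    "DEFAULT_STEP_YEARS",
    "resample_ages",
    "mobility_vector",
    "per_sample_mobility",
    "regional_series",
    "direction_bins",
]

# Analysis defaults: the retrospection distance (years before a sample's
# resampled age at which the field is sliced) is informed by the temporal
# kernel lengthscale; 25 age-resampling runs; 400-year moving window.
DEFAULT_RETROSPECTION_YEARS = 667.0
DEFAULT_N_RUNS = 25
DEFAULT_WINDOW_YEARS = 400.0
DEFAULT_STEP_YEARS = 50.0


@dataclass(frozen=True)
class MobilityVector:
    """Displacement from burial location to maximum-similarity cell."""

    dx: float  # meters
    dy: float  # meters
    origin_x: float  # max-similarity cell center, meters
    origin_y: float
    burial_x: float
    burial_y: float
    slice_time: float
    tie: bool = False

    @property
    def length_km(self) -> float:
        return math.hypot(self.dx, self.dy) / 1000.0

    @property
    def direction_deg(self) -> float | None:
        """Compass bearing: 0 = North, clockwise, in [0, 360); None if zero."""
        if self.dx == 0.0 and self.dy == 0.0:
            return None
        d = math.degrees(math.atan2(self.dx, self.dy)) % 360.0
        return 0.0 if d == 360.0 else d  # tiny negative angles round up to 360


@dataclass
class MobilityEstimate:
    """Per-sample resampled mobility vectors and their summary."""

    sample_id: str
    vectors: list[MobilityVector]
    age_draws: list[float]
    age_lo: float
    age_hi: float
    region_tag: str | None = None
    age_median: float | None = None

    @property
    def n_runs(self) -> int:
        return len(self.vectors)

    @property
    def mean_vector(self) -> MobilityVector:
        """Component-wise mean of dx, dy (directions can cancel)."""
        dx = float(np.mean([v.dx for v in self.vectors]))
        dy = float(np.mean([v.dy for v in self.vectors]))
        v0 = self.vectors[0]
        return MobilityVector(
            dx, dy, v0.burial_x + dx, v0.burial_y + dy,
            v0.burial_x, v0.burial_y,
            float(np.mean([v.slice_time for v in self.vectors])),
            tie=any(v.tie for v in self.vectors),
        )

    @property
    def sd_length_km(self) -> float:
        return float(np.std([v.length_km for v in self.vectors]))


def resample_ages(sample: SampleRecord, n: int = DEFAULT_N_RUNS, seed: int = 0) -> list[float]:
    """Draw n ages reflecting the sample's age uncertainty.

    With a calibrated age probability table, draws come from it directly;
    otherwise from a normal centered on the median with sd equal to a
    quarter of the 2-sigma range, truncated to [age_lo, age_hi].
    Deterministic given the seed.
    """
    if n < 1:
        raise ValueError("need at least one resampling run")
    rng = np.random.default_rng(seed)
    if sample.age_pmf is not None:
        years = np.array([y for y, _ in sample.age_pmf], dtype=float)
        probs = np.array([p for _, p in sample.age_pmf], dtype=float)
        return rng.choice(years, size=n, p=probs / probs.sum()).tolist()
    lo, hi = sample.age_lo, sample.age_hi
    if lo == hi:
        return [float(lo)] * n
    sd = (hi - lo) / 4.0
    draws = np.empty(n)
    filled = 0
    while filled < n:
        cand = rng.normal(sample.age_median, sd, size=2 * (n - filled))
        cand = cand[(cand >= lo) & (cand <= hi)]
        take = min(len(cand), n - filled)
        draws[filled:filled + take] = cand[:take]
        filled += take
    return draws.tolist()


def mobility_vector(
    burial_x: float, burial_y: float, surface: SimilaritySurface
) -> MobilityVector:
    """Vector from the burial location to the max-similarity cell center."""
    origin, _, tie = max_similarity_point(surface)
    return MobilityVector(
        dx=origin.x - burial_x,
        dy=origin.y - burial_y,
        origin_x=origin.x,
        origin_y=origin.y,
        burial_x=burial_x,
        burial_y=burial_y,
        slice_time=surface.slice_time,
        tie=tie,
    )


def per_sample_mobility(
    sample: SampleRecord,
    z: np.ndarray,
    model: GPModel,
    grid: GridSpec,
    retrospection: float = DEFAULT_RETROSPECTION_YEARS,
    n_runs: int = DEFAULT_N_RUNS,
    seed: int = 0,
) -> MobilityEstimate:
    """Resample ages, slice the field, and collect one vector per run.

    For each resampled age a the field is evaluated at slice time
    a - retrospection and the sample's surface and vector computed there.
    Run-level failures are recorded and excluded; at least one successful
    run is required.
    """
    if retrospection <= 0:
        raise ValueError("retrospection distance must be positive")
    if sample.x is None or sample.y is None:
        raise ValueError(
            f"sample {sample.sample_id!r} has no planar coordinates; "
            "run project_coordinates first"
        )
    ages = resample_ages(sample, n=n_runs, seed=seed)
    vectors, kept_ages, failures = [], [], []
    for a in ages:
        t_slice = a - retrospection
        try:
            (field,) = predict_field_grid(model, grid, [t_slice])
            surf = similarity_surface(sample.sample_id, z, field)
            vectors.append(mobility_vector(sample.x, sample.y, surf))
            kept_ages.append(a)
        except ValueError as exc:
            failures.append((a, str(exc)))
    if not vectors:
        raise RuntimeError(
            f"all {n_runs} runs failed for sample {sample.sample_id!r}: "
            f"{failures[:3]}"
        )
    return MobilityEstimate(
        sample_id=sample.sample_id,
        vectors=vectors,
        age_draws=kept_ages,
        age_lo=sample.age_lo,
        age_hi=sample.age_hi,
        region_tag=sample.region_tag,
        age_median=sample.age_median,
    )


@dataclass
class RegionalSeries:
    """Moving-mean mobility length per region with a 2-SE band."""

    region_tag: str | None
    window_centers: np.ndarray  # years
    mean_length_km: np.ndarray
    band_halfwidth_km: np.ndarray  # 2*SE of per-sample means; inf if < 2 samples
    n_samples: np.ndarray
    n_runs: np.ndarray


def regional_series(
    estimates: Sequence[MobilityEstimate],
    window: float = DEFAULT_WINDOW_YEARS,
    step: float = DEFAULT_STEP_YEARS,
    region_tag: str | None = None,
    pool: str = "runs",
) -> RegionalSeries:
    """Moving mean of mobility-vector length over resampled runs.

    Each run is anchored at its resampled sample age; windows of width
    ``window`` slide by ``step`` over the anchor range.  The curve pools
    either all runs (``pool='runs'``, the default) or per-sample mean
    lengths (``pool='samples'``).  The band is two standard errors of the
    per-sample mean lengths in the window, infinite when a window holds
    fewer than two samples.
    """
    if pool not in ("runs", "samples"):
        raise ValueError("pool must be 'runs' or 'samples'")
    if not estimates:
        empty = np.array([])
        return RegionalSeries(region_tag, empty, empty, empty,
                             empty.astype(int), empty.astype(int))
    anchors, lengths, sample_idx = [], [], []
    for s_idx, est in enumerate(estimates):
        for a, v in zip(est.age_draws, est.vectors):
            anchors.append(a)
            lengths.append(v.length_km)
            sample_idx.append(s_idx)
    anchors = np.asarray(anchors)
    lengths = np.asarray(lengths)
    sample_idx = np.asarray(sample_idx)
    sample_means = np.array(
        [np.mean([v.length_km for v in est.vectors]) for est in estimates]
    )

    lo, hi = anchors.min(), anchors.max()
    centers = np.arange(lo, hi + step / 2.0, step)
    mean_len = np.full(len(centers), np.nan)
    band = np.full(len(centers), np.inf)
    n_samp = np.zeros(len(centers), dtype=int)
    n_run = np.zeros(len(centers), dtype=int)
    half = window / 2.0
    for i, c in enumerate(centers):
        in_win = (anchors >= c - half) & (anchors <= c + half)
        n_run[i] = int(in_win.sum())
        samples_here = np.unique(sample_idx[in_win])
        n_samp[i] = len(samples_here)
        if n_run[i] == 0:
            continue
        if pool == "runs":
            mean_len[i] = float(lengths[in_win].mean())
        else:
            mean_len[i] = float(sample_means[samples_here].mean())
        if n_samp[i] >= 2:
            se = float(sample_means[samples_here].std(ddof=1)) / math.sqrt(
                n_samp[i]
            )
            band[i] = 2.0 * se
    return RegionalSeries(region_tag, centers, mean_len, band, n_samp, n_run)


def direction_bins(
    vectors: Sequence[MobilityVector], n_bins: int = 8
) -> np.ndarray:
    """Counts of vector bearings in equal compass bins starting at North.

    Bins are half-open [lo, hi) going clockwise from 0 degrees; zero-length
    vectors (undefined direction) are excluded.
    """
    if n_bins < 2:
        raise ValueError("need at least 2 direction bins")
    width = 360.0 / n_bins
    counts = np.zeros(n_bins, dtype=int)
    for v in vectors:
        d = v.direction_deg
        if d is None:
            continue
        counts[int(d // width) % n_bins] += 1
    return counts
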