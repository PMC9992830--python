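"""Spatial probability surfaces of genetic similarity.

Given the interpolated ancestry field in a past time slice and one sample's
ancestry-component values, each grid cell is scored by the Gaussian
likelihood of the sample's value under the field's predictive distribution
there; Bayes normalization with a uniform spatial prior (the grid lives on
an equal-area projection, so a uniform cell prior is a uniform spatial
prior) and a cellwise product over components yield a normalized similarity
probability surface.

The likelihood variance is the predictive variance plus the kernel nugget
eta, so locally heterogeneous ancestry retains support and the surface
cannot collapse onto training locations.  Because the predictive sd grows
toward sqrt(tau2 + eta) away from data, the surface is only peaked where
the field is actually supported by observations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .field_gpr import FieldSlice, GridSpec, SpaceTimePoint

__all__ = [
    "SimilaritySurface",
    "component_likelihood",
    "similarity_surface",
    "max_similarity_point",
]


@dataclass
class SimilaritySurface:
    """Normalized per-cell probabilities on a FieldSlice's lattice."""

    sample_id: str
    slice_time: float
    grid: GridSpec
    probabilities: np.ndarray  # n_cells, row-major (y slowest, x fastest)

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if (p < 0).any():
            raise ValueError("negative probability in similarity surface")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"similarity surface sums to {p.sum()!r}, expected 1"
            )
        self.probabilities = p


def component_likelihood(
    z: float, mu: float, sigma: float, eta: float = 0.0
) -> float:
    """Gaussian density of component value z under N(mu, sigma^2 + eta)."""
    if sigma < 0 or eta < 0:
        raise ValueError("sigma and eta must be non-negative")
    var = sigma * sigma + eta
    if var == 0.0:
        if z == mu:
            return math.inf  # point-mass sentinel; callers must handle
        raise ValueError(
            "zero total variance with z != mu: likelihood undefined"
        )
    return math.exp(-0.5 * (z - mu) ** 2 / var) / math.sqrt(2.0 * math.pi * var)


def _log_component_likelihoods(
    z: np.ndarray, field: FieldSlice, eta: np.ndarray
) -> np.ndarray:
    var = field.sd ** 2 + eta[None, :]
    if (var <= 0).any():
        raise ValueError("zero total variance in field slice; need eta > 0")
    return -0.5 * ((z[None, :] - field.mean) ** 2 / var + np.log(2 * np.pi * var))


def similarity_surface(
    sample_id: str,
    z: np.ndarray,
    field: FieldSlice,
    eta: np.ndarray | float | None = None,
) -> SimilaritySurface:
    """Bayes-normalized probability surface for one sample in one time slice.

    ``z`` holds the sample's k ancestry-component values; ``eta`` the
    per-component nugget added to the predictive variance (defaults to the
    fitted kernel nuggets carried by the slice).  Per component the cell
    likelihoods are normalized under a uniform prior, multiplied cellwise
    across components, and renormalized — computed in a single log-space
    pass (normalize-then-multiply and multiply-then-renormalize coincide
    under the uniform prior).
    """
    z = np.atleast_1d(np.asarray(z, dtype=float))
    k = field.mean.shape[1]
    if z.shape != (k,):
        raise ValueError(f"expected {k} component values, got shape {z.shape}")
    if eta is None:
        eta_arr = np.array([p.eta for p in field.params], dtype=float)
    else:
        eta_arr = np.broadcast_to(np.asarray(eta, dtype=float), (k,)).copy()
    logp = _log_component_likelihoods(z, field, eta_arr).sum(axis=1)
    norm = logsumexp(logp)
    if not np.isfinite(norm):
        raise ValueError(
            f"similarity surface for sample {sample_id!r} at t={field.time} "
            "underflowed: zero likelihood in every cell"
        )
    return SimilaritySurface(
        sample_id, field.time, field.grid, np.exp(logp - norm)
    )


def max_similarity_point(
    surface: SimilaritySurface,
) -> tuple[SpaceTimePoint, float, bool]:
    """Cell center of maximum probability, its probability, and a tie flag.

    Ties are broken deterministically by row-major order (smallest y, then
    smallest x); any tie at the maximum is reported via the flag.
    """
    p = surface.probabilities
    idx = int(np.argmax(p))
    tie = bool((np.abs(p - p[idx]) <= 1e-12 * max(p[idx], 1e-300)).sum() > 1)
    centers = surface.grid.cell_centers()
    x, y = centers[idx]
    return SpaceTimePoint(x, y, surface.slice_time), float(p[idx]), tie

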