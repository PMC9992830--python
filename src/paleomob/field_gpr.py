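"""Anisotropic Gaussian-process regression over space and time.

Scattered per-sample ancestry components are modeled as draws from a
Gaussian process over three independent coordinates — planar easting x,
northing y (meters) and time t (calendar years) — with the separable
squared-exponential covariance

    Cov(a, b) = tau2 * exp(-[(ax-bx)^2/theta_x + (ay-by)^2/theta_y
                            + (at-bt)^2/theta_t]) + eta * delta(a, b)

where delta is the Kronecker delta on *exact* coordinate equality (so the
nugget eta sits on the diagonal and on exact duplicates, absorbing local
ancestry heterogeneity and measurement noise).  theta_k is the per-dimension
divisor of squared separation, in units of distance squared; the associated
"lengthscale" is sqrt(theta_k).

Each ancestry component is fitted individually with a constant mean equal
to its training mean, so predictions revert to the data mean far from all
observations and the predictive variance saturates at tau2 + eta.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import linalg, optimize, stats

__all__ = [
    "SpaceTimePoint",
    "KernelParams",
    "GPModel",
    "FieldSlice",
    "GridSpec",
    "kernel_value",
    "fit_gp",
    "gp_predict",
    "predict_field_grid",
    "mle_kernel",
    "loocv_score",
    "empirical_variogram",
]

logger = logging.getLogger(__name__)

_JITTER_FRACTION = 1e-8  # of tau2, added only if the factorization fails


@dataclass(frozen=True)
class SpaceTimePoint:
    """A position in the three-dimensional independent-variable space."""

    x: float  # meters, planar equal-area
    y: float  # meters
    t: float  # years calBC/AD

    def __post_init__(self) -> None:
        if not all(map(math.isfinite, (self.x, self.y, self.t))):
            raise ValueError(f"non-finite coordinates: {self}")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.t], dtype=float)


@dataclass(frozen=True)
class KernelParams:
    """Covariance parameters: squared-distance divisors, sill and nugget.

    theta_x, theta_y are in m^2; theta_t in y^2; tau2 and eta in squared
    ancestry-component units.
    """

    theta_x: float
    theta_y: float
    theta_t: float
    tau2: float
    eta: float = 0.0

    def __post_init__(self) -> None:
        if min(self.theta_x, self.theta_y, self.theta_t) <= 0 or self.tau2 <= 0:
            raise ValueError(f"theta_* and tau2 must be positive: {self}")
        if self.eta < 0:
            raise ValueError(f"nugget eta must be non-negative: {self}")

    @classmethod
    def from_lengthscales(
        cls,
        ell_x_km: float,
        ell_y_km: float,
        ell_t_years: float,
        tau2: float,
        eta: float = 0.0,
    ) -> "KernelParams":
        """Build from lengthscales (sqrt of the divisors), spatial ones in km."""
        return cls(
            theta_x=(ell_x_km * 1000.0) ** 2,
            theta_y=(ell_y_km * 1000.0) ** 2,
            theta_t=ell_t_years ** 2,
            tau2=tau2,
            eta=eta,
        )

    @property
    def lengthscales(self) -> tuple[float, float, float]:
        """(x, y) lengthscales in km and t lengthscale in years."""
        return (
            math.sqrt(self.theta_x) / 1000.0,
            math.sqrt(self.theta_y) / 1000.0,
            math.sqrt(self.theta_t),
        )


def _sq_scaled_dists(A: np.ndarray, B: np.ndarray, p: KernelParams) -> np.ndarray:
    theta = np.array([p.theta_x, p.theta_y, p.theta_t])
    diff = A[:, None, :] - B[None, :, :]
    return np.einsum("ijk,k->ij", diff ** 2, 1.0 / theta)


def _exact_equal(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    return (A[:, None, :] == B[None, :, :]).all(axis=2)


def _cov(A: np.ndarray, B: np.ndarray, p: KernelParams) -> np.ndarray:
    k = p.tau2 * np.exp(-_sq_scaled_dists(A, B, p))
    if p.eta > 0:
        k = k + p.eta * _exact_equal(A, B)
    return k


def kernel_value(a: SpaceTimePoint, b: SpaceTimePoint, p: KernelParams) -> float:
    """Covariance between two space-time points under the kernel."""
    aa, bb = a.as_array(), b.as_array()
    s = ((aa - bb) ** 2 / np.array([p.theta_x, p.theta_y, p.theta_t])).sum()
    v = p.tau2 * math.exp(-s)
    if (aa == bb).all():
        v += p.eta
    return v


@dataclass
class GPModel:
    """A fitted constant-mean GP, one kernel per ancestry component."""

    points: np.ndarray  # n x 3
    offsets: np.ndarray  # k component means
    centered: np.ndarray  # n x k
    params: list[KernelParams]  # one per component
    chol: list[np.ndarray] = field(repr=False, default_factory=list)
    alpha: list[np.ndarray] = field(repr=False, default_factory=list)

    @property
    def n_components(self) -> int:
        return self.centered.shape[1]


class SingularCovarianceError(np.linalg.LinAlgError):
    pass


def _points_array(points: Sequence[SpaceTimePoint] | np.ndarray) -> np.ndarray:
    if isinstance(points, np.ndarray):
        return np.asarray(points, dtype=float).reshape(-1, 3)
    return np.array([p.as_array() for p in points])


def _factorize(K: np.ndarray, tau2: float) -> np.ndarray:
    try:
        return linalg.cholesky(K, lower=True)
    except linalg.LinAlgError:
        jitter = _JITTER_FRACTION * tau2
        logger.warning(
            "covariance factorization failed; retrying with jitter %.3g", jitter
        )
        try:
            return linalg.cholesky(K + jitter * np.eye(len(K)), lower=True)
        except linalg.LinAlgError:
            raise SingularCovarianceError(
                "training covariance is singular even after jitter; duplicate "
                "coordinates with differing values require a positive nugget eta"
            ) from None


def fit_gp(
    points: Sequence[SpaceTimePoint] | np.ndarray,
    values: np.ndarray,
    params: KernelParams | Sequence[KernelParams],
    mean_offset: float | Sequence[float] | None = None,
) -> GPModel:
    """Fit the GP: center each component, build and factorize the covariance.

    ``values`` is n x k (k components).  ``params`` may be a single
    KernelParams shared by all components or one per component.  By default
    each component is centered by its arithmetic training mean; a fixed
    ``mean_offset`` can be supplied instead (used e.g. by the closed-form
    leave-one-out identities).
    """
    X = _points_array(points)
    Y = np.atleast_2d(np.asarray(values, dtype=float))
    if Y.shape[0] != X.shape[0]:
        Y = Y.T
    n, k = Y.shape
    if n < 2:
        raise ValueError("at least 2 training points are required")
    plist = [params] * k if isinstance(params, KernelParams) else list(params)
    if len(plist) != k:
        raise ValueError(f"need {k} KernelParams, got {len(plist)}")

    if mean_offset is None:
        offsets = Y.mean(axis=0)
    else:
        offsets = np.broadcast_to(np.asarray(mean_offset, dtype=float), (k,)).copy()
    centered = Y - offsets

    # duplicate coordinates with conflicting values are only resolvable
    # through the nugget
    eq = _exact_equal(X, X)
    np.fill_diagonal(eq, False)
    for c, p in enumerate(plist):
        if p.eta == 0 and eq.any():
            ii, jj = np.nonzero(np.triu(eq))
            if any(centered[i, c] != centered[j, c] for i, j in zip(ii, jj)):
                raise SingularCovarianceError(
                    "duplicate coordinates with differing values and eta = 0; "
                    "use a positive nugget"
                )

    model = GPModel(X, offsets, centered, plist)
    for c, p in enumerate(plist):
        K = _cov(X, X, p)
        L = _factorize(K, p.tau2)
        model.chol.append(L)
        model.alpha.append(linalg.cho_solve((L, True), centered[:, c]))
    return model


def gp_predict(
    model: GPModel,
    queries: Sequence[SpaceTimePoint] | np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Predictive mean and sd at query points, per component.

    Returns (mean, sd), each m x k.  The nugget contributes to the prior
    variance (tau2 + eta) and enters the cross-covariance only where a query
    coincides exactly with a training coordinate.  Variance is floored at 0.
    """
    Q = _points_array(queries)
    m = Q.shape[0]
    k = model.n_components
    mean = np.empty((m, k))
    sd = np.empty((m, k))
    for c, p in enumerate(model.params):
        kstar = _cov(Q, model.points, p)  # includes eta on exact coincidence
        mean[:, c] = model.offsets[c] + kstar @ model.alpha[c]
        v = linalg.solve_triangular(model.chol[c], kstar.T, lower=True)
        var = (p.tau2 + p.eta) - np.einsum("ij,ij->j", v, v)
        sd[:, c] = np.sqrt(np.maximum(var, 0.0))
    return mean, sd


@dataclass(frozen=True)
class GridSpec:
    """Regular planar lattice of cell centers."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float
    spacing: float  # meters

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if self.x_max <= self.x_min or self.y_max <= self.y_min:
            raise ValueError("bounding box is degenerate")

    @property
    def x_centers(self) -> np.ndarray:
        nx = max(1, int((self.x_max - self.x_min) // self.spacing))
        return self.x_min + self.spacing * (0.5 + np.arange(nx))

    @property
    def y_centers(self) -> np.ndarray:
        ny = max(1, int((self.y_max - self.y_min) // self.spacing))
        return self.y_min + self.spacing * (0.5 + np.arange(ny))

    def cell_centers(self) -> np.ndarray:
        """Cells in row-major order: y varies slowest, x fastest."""
        xs, ys = self.x_centers, self.y_centers
        gx, gy = np.meshgrid(xs, ys)
        return np.column_stack([gx.ravel(), gy.ravel()])

    @property
    def n_cells(self) -> int:
        return len(self.x_centers) * len(self.y_centers)


@dataclass
class FieldSlice:
    """GP predictive mean and sd per component over a grid at one time."""

    time: float
    grid: GridSpec
    mean: np.ndarray  # n_cells x k, row-major cell order
    sd: np.ndarray  # n_cells x k
    params: list[KernelParams]


DEFAULT_CELL_BUDGET = 2_000_000


def predict_field_grid(
    model: GPModel,
    grid: GridSpec,
    times: Sequence[float],
    cell_budget: int = DEFAULT_CELL_BUDGET,
) -> list[FieldSlice]:
    """Evaluate the GP on a lattice of cell centers at each requested time."""
    if grid.n_cells * len(times) > cell_budget:
        raise ValueError(
            f"grid of {grid.n_cells} cells x {len(times)} times exceeds the "
            f"cell budget ({cell_budget}); use a coarser spacing"
        )
    centers = grid.cell_centers()
    slices = []
    for t in times:
        pts = np.column_stack([centers, np.full(len(centers), float(t))])
        mean, sd = gp_predict(model, pts)
        slices.append(FieldSlice(float(t), grid, mean, sd, list(model.params)))
    return slices


# ---------------------------------------------------------------------------
# kernel selection

def _nll_profiled(
    log_params: np.ndarray, X: np.ndarray, Yc: np.ndarray, eq: np.ndarray
) -> tuple[float, np.ndarray]:
    """Negative log marginal likelihood with tau2 profiled out, and gradient.

    log_params = log(theta_x, theta_y, theta_t, eta/tau2).  With the
    correlation matrix C (unit sill plus scaled nugget), the profile MLE is
    tau2_hat = y' C^-1 y / n and the objective reduces to
    n/2 log tau2_hat + 1/2 log|C| per component (constants dropped).
    The gradient in log-parameters uses dC/dlog(theta_k) = C0 * (d_k^2 /
    theta_k) elementwise and dC/dlog(g) = g * eq.
    """
    theta = np.exp(log_params[:3])
    g = math.exp(log_params[3])
    diff2 = (X[:, None, :] - X[None, :, :]) ** 2
    scaled = np.einsum("ijk,k->ij", diff2, 1.0 / theta)
    C0 = np.exp(-scaled)
    C = C0 + g * eq
    bad = 1e12, np.zeros(4)
    try:
        L = linalg.cholesky(C, lower=True)
    except linalg.LinAlgError:
        return bad
    n = len(X)
    logdet = 2.0 * np.log(np.diag(L)).sum()
    Cinv = linalg.cho_solve((L, True), np.eye(n))
    dC = [C0 * diff2[:, :, k] / theta[k] for k in range(3)] + [g * eq]
    trace_terms = np.array([np.sum(Cinv * dCk) for dCk in dC])
    total = 0.0
    grad = np.zeros(4)
    for c in range(Yc.shape[1]):
        alpha = Cinv @ Yc[:, c]
        quad = float(Yc[:, c] @ alpha)
        if quad <= 0:
            return bad
        total += 0.5 * n * math.log(quad / n) + 0.5 * logdet
        for p_idx, dCk in enumerate(dC):
            dquad = -float(alpha @ dCk @ alpha)
            grad[p_idx] += 0.5 * n * dquad / quad + 0.5 * trace_terms[p_idx]
    return total, grad


def mle_kernel(
    points: Sequence[SpaceTimePoint] | np.ndarray,
    values: np.ndarray,
    init: KernelParams,
    bounds: dict[str, tuple[float, float]] | None = None,
    n_starts: int = 8,
    seed: int = 0,
) -> tuple[KernelParams, float]:
    """Maximum-likelihood kernel parameters.

    Optimizes the Gaussian log marginal likelihood over log-transformed
    (theta_x, theta_y, theta_t, eta/tau2), with tau2 profiled in closed
    form.  Multi-start from a fixed seed-derived set of initializations.
    Returns the best KernelParams and the log marginal likelihood achieved
    (up to an additive constant).
    """
    X = _points_array(points)
    Y = np.atleast_2d(np.asarray(values, dtype=float))
    if Y.shape[0] != X.shape[0]:
        Y = Y.T
    Yc = Y - Y.mean(axis=0)
    eq = _exact_equal(X, X).astype(float)

    b = {
        "theta_x": (init.theta_x / 1e4, init.theta_x * 1e4),
        "theta_y": (init.theta_y / 1e4, init.theta_y * 1e4),
        "theta_t": (init.theta_t / 1e4, init.theta_t * 1e4),
        "nugget_ratio": (1e-8, 1e2),
    }
    b.update(bounds or {})
    log_bounds = [
        tuple(map(math.log, b[k]))
        for k in ("theta_x", "theta_y", "theta_t", "nugget_ratio")
    ]

    x0 = np.log(
        [init.theta_x, init.theta_y, init.theta_t, max(init.eta / init.tau2, 1e-6)]
    )
    # the profiled likelihood is multimodal (a nugget-dominated basin competes
    # with the smooth-field basin), so starts are spread over the whole
    # bounded log-box, not just perturbed around the init
    rng = np.random.default_rng(seed)
    lo = np.array([b_[0] for b_ in log_bounds])
    hi = np.array([b_[1] for b_ in log_bounds])
    starts = [x0] + [
        lo + (hi - lo) * rng.uniform(0.1, 0.9, size=4)
        for _ in range(n_starts - 1)
    ]

    results = []
    for start in starts:
        res = optimize.minimize(
            _nll_profiled,
            start,
            args=(X, Yc, eq),
            method="L-BFGS-B",
            jac=True,
            bounds=log_bounds,
        )
        if res.fun < 1e12:
            results.append(res)
    if not results:
        raise RuntimeError(
            "kernel likelihood optimization failed to converge from any start"
        )
    # Noise-only data leaves the nugget ratio unidentifiable along a flat
    # ridge (vanishing lengthscales mimic a pure nugget).  Among optima whose
    # likelihoods are statistically indistinguishable (likelihood-ratio
    # criterion at 5% over the 4 free parameters), prefer the largest nugget
    # ratio: the conservative reading that does not claim spatial structure
    # the likelihood cannot support.
    flat_tol = 0.5 * float(stats.chi2.ppf(0.95, df=4))
    best_fun = min(res.fun for res in results)
    best = max(
        (res for res in results if res.fun <= best_fun + flat_tol),
        key=lambda res: res.x[3],
    )

    theta = np.exp(best.x[:3])
    g = math.exp(best.x[3])
    diff = X[:, None, :] - X[None, :, :]
    C = np.exp(-np.einsum("ijk,k->ij", diff ** 2, 1.0 / theta)) + g * eq
    L = linalg.cholesky(C, lower=True)
    n = len(X)
    quads = [
        float(np.square(linalg.solve_triangular(L, Yc[:, c], lower=True)).sum())
        for c in range(Yc.shape[1])
    ]
    tau2_hat = float(np.mean(quads) / n)
    if g >= 1.0:
        logger.warning(
            "fitted nugget/sill ratio %.3g >= 1: likelihood surface is nearly "
            "flat (noise-dominated data)", g,
        )
    fitted = KernelParams(
        theta_x=float(theta[0]),
        theta_y=float(theta[1]),
        theta_t=float(theta[2]),
        tau2=tau2_hat,
        eta=g * tau2_hat,
    )
    return fitted, -float(best.fun)


def log_marginal_likelihood(
    points: Sequence[SpaceTimePoint] | np.ndarray,
    values: np.ndarray,
    params: KernelParams,
) -> float:
    """Profiled-form log marginal likelihood for comparison across params."""
    X = _points_array(points)
    Y = np.atleast_2d(np.asarray(values, dtype=float))
    if Y.shape[0] != X.shape[0]:
        Y = Y.T
    Yc = Y - Y.mean(axis=0)
    eq = _exact_equal(X, X).astype(float)
    lp = np.log(
        [params.theta_x, params.theta_y, params.theta_t,
         max(params.eta / params.tau2, 1e-300)]
    )
    return -_nll_profiled(lp, X, Yc, eq)[0]


def loocv_score(
    points: Sequence[SpaceTimePoint] | np.ndarray,
    values: np.ndarray,
    params: KernelParams | Sequence[KernelParams],
) -> float:
    """Mean squared leave-one-out prediction error, via closed form.

    Uses the standard identity e_i = alpha_i / (K^-1)_ii on the full
    factorization; no refits.  The GP mean is held fixed at the full-data
    component mean, matching a brute-force refit with the same fixed
    offset.  Averaged over points and components.
    """
    X = _points_array(points)
    Y = np.atleast_2d(np.asarray(values, dtype=float))
    if Y.shape[0] != X.shape[0]:
        Y = Y.T
    n, k = Y.shape
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 points")
    plist = [params] * k if isinstance(params, KernelParams) else list(params)
    Yc = Y - Y.mean(axis=0)
    errs = []
    for c, p in enumerate(plist):
        K = _cov(X, X, p)
        L = _factorize(K, p.tau2)
        Kinv = linalg.cho_solve((L, True), np.eye(n))
        alpha = Kinv @ Yc[:, c]
        e = alpha / np.diag(Kinv)
        errs.append(e ** 2)
    return float(np.mean(errs))


def empirical_variogram(
    points: Sequence[SpaceTimePoint] | np.ndarray,
    values: np.ndarray,
    space_bins: Sequence[float],
    time_bins: Sequence[float],
) -> "pd.DataFrame":
    """Empirical semivariance gamma over (space-lag, time-lag) bins.

    For each bin, gamma = 1/2 * mean squared value difference over the
    sample pairs whose planar separation and absolute time lag fall in it.
    Empty bins are reported with count 0 and gamma NaN.  Returns a tidy
    DataFrame with bin edges, pair counts and gamma per component.
    """
    import pandas as pd

    X = _points_array(points)
    Y = np.atleast_2d(np.asarray(values, dtype=float))
    if Y.shape[0] != X.shape[0]:
        Y = Y.T
    n, k = Y.shape
    if n < 2:
        raise ValueError("variogram needs at least 2 points")
    iu, ju = np.triu_indices(n, k=1)
    sdist = np.hypot(X[iu, 0] - X[ju, 0], X[iu, 1] - X[ju, 1])
    tdist = np.abs(X[iu, 2] - X[ju, 2])
    sq = (Y[iu] - Y[ju]) ** 2  # pairs x k

    space_bins = np.asarray(space_bins, dtype=float)
    time_bins = np.asarray(time_bins, dtype=float)
    si = np.digitize(sdist, space_bins) - 1
    ti = np.digitize(tdist, time_bins) - 1
    rows = []
    for a in range(len(space_bins) - 1):
        for bb in range(len(time_bins) - 1):
            in_bin = (si == a) & (ti == bb)
            count = int(in_bin.sum())
            row = {
                "space_lo": space_bins[a],
                "space_hi": space_bins[a + 1],
                "time_lo": time_bins[bb],
                "time_hi": time_bins[bb + 1],
                "n_pairs": count,
            }
            for c in range(k):
                row[f"gamma_C{c + 1}"] = (
                    0.5 * float(sq[in_bin, c].mean()) if count else np.nan
                )
            rows.append(row)
    return pd.DataFrame(rows)
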