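"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest

from paleomob.field_gpr import GPModel, KernelParams, kernel_value, SpaceTimePoint


def brute_force_gp_predict(
    X: np.ndarray,
    y: np.ndarray,
    params: KernelParams,
    queries: np.ndarray,
    offset: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Dense-inverse GP conditioning, built only from kernel_value calls.

    Independent of the package's factorization path: covariance entries come
    from pairwise kernel_value evaluations and the solve uses an explicit
    matrix inverse.
    """
    n = len(X)
    pts = [SpaceTimePoint(*row) for row in X]
    K = np.array([[kernel_value(a, b, params) for b in pts] for a in pts])
    Kinv = np.linalg.inv(K)
    mu0 = float(np.mean(y)) if offset is None else offset
    yc = np.asarray(y, dtype=float) - mu0
    means, sds = [], []
    for q in queries:
        qp = SpaceTimePoint(*q)
        kstar = np.array([kernel_value(qp, p, params) for p in pts])
        prior_var = kernel_value(qp, qp, params)  # tau2 + eta
        mean = mu0 + kstar @ Kinv @ yc
        var = prior_var - kstar @ Kinv @ kstar
        means.append(mean)
        sds.append(math.sqrt(max(var, 0.0)))
    return np.array(means), np.array(sds)


def haversine_km(lon1, lat1, lon2, lat2, radius_km=6371.0088):
    """Great-circle distance oracle on the mean-radius sphere."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlam / 2) ** 2
    return 2 * radius_km * math.asin(math.sqrt(a))


def vincenty_km(lon1, lat1, lon2, lat2, a=6378.137, f=1 / 298.257222101):
    """Geodesic distance on the GRS80 ellipsoid (Vincenty inverse)."""
    L = math.radians(lon2 - lon1)
    u1 = math.atan((1 - f) * math.tan(math.radians(lat1)))
    u2 = math.atan((1 - f) * math.tan(math.radians(lat2)))
    su1, cu1, su2, cu2 = math.sin(u1), math.cos(u1), math.sin(u2), math.cos(u2)
    lam = L
    for _ in range(200):
        sl, cl = math.sin(lam), math.cos(lam)
        sin_sigma = math.hypot(cu2 * sl, cu1 * su2 - su1 * cu2 * cl)
        if sin_sigma == 0:
            return 0.0
        cos_sigma = su1 * su2 + cu1 * cu2 * cl
        sigma = math.atan2(sin_sigma, cos_sigma)
        sin_alpha = cu1 * cu2 * sl / sin_sigma
        cos2_alpha = 1 - sin_alpha ** 2
        cos_2sm = cos_sigma - 2 * su1 * su2 / cos2_alpha if cos2_alpha else 0.0
        C = f / 16 * cos2_alpha * (4 + f * (4 - 3 * cos2_alpha))
        lam_new = L + (1 - C) * f * sin_alpha * (
            sigma + C * sin_sigma * (cos_2sm + C * cos_sigma * (-1 + 2 * cos_2sm ** 2))
        )
        if abs(lam_new - lam) < 1e-12:
            lam = lam_new
            break
        lam = lam_new
    b = a * (1 - f)
    u_sq = cos2_alpha * (a ** 2 - b ** 2) / b ** 2
    A = 1 + u_sq / 16384 * (4096 + u_sq * (-768 + u_sq * (320 - 175 * u_sq)))
    B = u_sq / 1024 * (256 + u_sq * (-128 + u_sq * (74 - 47 * u_sq)))
    d_sigma = B * sin_sigma * (
        cos_2sm
        + B / 4 * (
            cos_sigma * (-1 + 2 * cos_2sm ** 2)
            - B / 6 * cos_2sm * (-3 + 4 * sin_sigma ** 2) * (-3 + 4 * cos_2sm ** 2)
        )
    )
    return b * A * (sigma - d_sigma)


def random_kernel(rng: np.random.Generator) -> KernelParams:
    """A random valid anisotropic kernel at study-realistic magnitudes."""
    return KernelParams(
        theta_x=float(rng.uniform(1e10, 1e12)),   # 100-1000 km lengthscale
        theta_y=float(rng.uniform(1e10, 1e12)),
        theta_t=float(rng.uniform(1e4, 1e6)),     # 100-1000 y lengthscale
        tau2=float(rng.uniform(0.1, 2.0)),
        eta=float(rng.uniform(0.0, 0.3)),
    )


def random_training_set(
    rng: np.random.Generator, n: int, n_components: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    X = np.column_stack(
        [
            rng.uniform(0, 3e6, n),
            rng.uniform(0, 3e6, n),
            rng.uniform(-8000, 2000, n),
        ]
    )
    Y = rng.normal(size=(n, n_components))
    return X, Y


@pytest.fixture
def rng():
    return np.random.default_rng(20230223)
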