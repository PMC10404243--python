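"""Structural temporal priors: RW2 trend, seasonal AR, AR(2) cycle, AR(1)×space.

The log-intensity decomposes into a long-term trend μ_t (second-order random
walk), a seasonal component s_t (lag-m autoregression, random-walk form at
coefficient 1), a cycle c_t (stationary AR(2), parameterised by its first two
partial autocorrelations so that stationarity is the open box |p_k| < 1), and a
spatial field with AR(1) dependence across periods.  Each builder returns the
sparse precision matrix of the corresponding Gaussian prior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .errors import DomainError, SizeError

__all__ = [
    "TrendSpec",
    "SeasonalSpec",
    "CycleSpec",
    "GroupARSpec",
    "rw2_precision",
    "seasonal_precision",
    "ar2_from_pacf",
    "pacf_from_ar2",
    "ar2_autocovariance",
    "ar2_precision",
    "ar1_precision",
    "spacetime_precision",
]


@dataclass(frozen=True)
class TrendSpec:
    """Second-order random-walk trend: Δ²μ_t ~ N(0, 1/innovation_precision)."""

    T: int
    innovation_precision: float = 1.0

    def __post_init__(self):
        if self.T < 3:
            raise SizeError("RW2 trend needs T >= 3")
        if self.innovation_precision <= 0:
            raise DomainError("innovation precision must be positive")


@dataclass(frozen=True)
class SeasonalSpec:
    """Seasonal lag-m autoregression s_t = φ_s s_{t−m} + η_s.

    φ_s = 1 gives the seasonal random walk (intrinsic, null space of dimension
    m spanned by all period-m sequences); |φ_s| < 1 gives a proper prior.
    """

    T: int
    period: int = 4
    lag_coefficient: float = 1.0
    innovation_precision: float = 1.0

    def __post_init__(self):
        if self.period < 2:
            raise SizeError("seasonal period must be at least 2")
        if self.T <= self.period:
            raise SizeError("seasonal component needs T > period")
        if abs(self.lag_coefficient) > 1:
            raise DomainError("|seasonal lag coefficient| must be <= 1")
        if self.innovation_precision <= 0:
            raise DomainError("innovation precision must be positive")


@dataclass(frozen=True)
class CycleSpec:
    """Stationary AR(2) cycle via partial autocorrelations (p1, p2)."""

    T: int
    pacf1: float
    pacf2: float
    innovation_precision: float = 1.0

    def __post_init__(self):
        if not (abs(self.pacf1) < 1 and abs(self.pacf2) < 1):
            raise DomainError("PACF parameters must lie strictly inside (-1, 1)")
        if self.innovation_precision <= 0:
            raise DomainError("innovation precision must be positive")


@dataclass(frozen=True)
class GroupARSpec:
    """Temporal AR(1) dependence Φ of the spatial field across periods."""

    phi: float

    def __post_init__(self):
        if not abs(self.phi) < 1:
            raise DomainError("|Phi| must be < 1")


def _second_difference_operator(T: int) -> sp.csr_matrix:
    data = np.tile([1.0, -2.0, 1.0], T - 2)
    rows = np.repeat(np.arange(T - 2), 3)
    cols = (np.arange(T - 2)[:, None] + np.arange(3)[None, :]).ravel()
    return sp.csr_matrix((data, (rows, cols)), shape=(T - 2, T))


def rw2_precision(spec: TrendSpec) -> sp.csr_matrix:
    """Precision of the second-order random walk: prec · DᵀD.

    Rank T−2; the null space holds constant and linear sequences, which is why
    the trend absorbs level and slope while its prior only penalises curvature.
    """
    D = _second_difference_operator(spec.T)
    return (spec.innovation_precision * (D.T @ D)).tocsr()


def seasonal_precision(spec: SeasonalSpec) -> sp.csr_matrix:
    """Precision prec · LᵀL with L the (T−m)×T lag-m rows (s_t − φ_s s_{t−m})."""
    T, m, phi = spec.T, spec.period, spec.lag_coefficient
    rows = np.repeat(np.arange(T - m), 2)
    cols = np.column_stack([np.arange(T - m), np.arange(m, T)]).ravel()
    data = np.tile([-phi, 1.0], T - m)
    L = sp.csr_matrix((data, (rows, cols)), shape=(T - m, T))
    return (spec.innovation_precision * (L.T @ L)).tocsr()


def ar2_from_pacf(p1: float, p2: float) -> tuple[float, float]:
    """Durbin–Levinson map from partial autocorrelations to AR(2) coefficients.

    θ₂ = p₂ and θ₁ = p₁(1 − p₂); any (p1, p2) in the open unit box maps to a
    stationary AR(2).  Complex characteristic roots (a genuine cycle) occur
    iff θ₁² + 4θ₂ < 0.
    """
    if not (abs(p1) < 1 and abs(p2) < 1):
        raise DomainError("PACF values must lie strictly inside (-1, 1)")
    return p1 * (1.0 - p2), p2


def pacf_from_ar2(theta1: float, theta2: float) -> tuple[float, float]:
    """Inverse of :func:`ar2_from_pacf`."""
    p2 = theta2
    if not abs(p2) < 1:
        raise DomainError("non-stationary AR(2): |theta2| >= 1")
    p1 = theta1 / (1.0 - p2)
    if not abs(p1) < 1:
        raise DomainError("non-stationary AR(2) coefficients")
    return p1, p2


def _check_stationary_ar2(theta1: float, theta2: float):
    if not (abs(theta2) < 1 and theta2 + theta1 < 1 and theta2 - theta1 < 1):
        raise DomainError(f"AR(2) coefficients ({theta1}, {theta2}) are not stationary")


def ar2_autocovariance(theta1: float, theta2: float, sigma2: float, nlags: int) -> np.ndarray:
    """Autocovariances γ(0..nlags) of a stationary AR(2) with innovation var σ².

    Solves the Yule–Walker equations for (γ0, γ1, γ2) and extends by the AR
    recursion γ(k) = θ₁γ(k−1) + θ₂γ(k−2).
    """
    _check_stationary_ar2(theta1, theta2)
    A = np.array(
        [
            [1.0, -theta1, -theta2],
            [-theta1, 1.0 - theta2, 0.0],
            [-theta2, -theta1, 1.0],
        ]
    )
    g = np.linalg.solve(A, np.array([sigma2, 0.0, 0.0]))
    gam = np.empty(nlags + 1)
    gam[: min(3, nlags + 1)] = g[: min(3, nlags + 1)]
    for k in range(3, nlags + 1):
        gam[k] = theta1 * gam[k - 1] + theta2 * gam[k - 2]
    return gam


def ar2_precision(spec: CycleSpec) -> sp.csr_matrix:
    """Exact precision of the stationary AR(2), banded with bandwidth 2.

    Built as prec·BᵀB from the conditional rows for t ≥ 2 plus the inverse of
    the stationary 2×2 covariance of the initial pair, so Q⁻¹ equals the full
    Yule–Walker autocovariance matrix.
    """
    theta1, theta2 = ar2_from_pacf(spec.pacf1, spec.pacf2)
    _check_stationary_ar2(theta1, theta2)
    T = spec.T
    prec = spec.innovation_precision
    sigma2 = 1.0 / prec

    if T == 1:
        g0 = ar2_autocovariance(theta1, theta2, sigma2, 0)[0]
        return sp.csr_matrix(np.array([[1.0 / g0]]))

    gam = ar2_autocovariance(theta1, theta2, sigma2, 1)
    Gamma2 = np.array([[gam[0], gam[1]], [gam[1], gam[0]]])
    Q = sp.lil_matrix((T, T))
    Q[:2, :2] = np.linalg.inv(Gamma2)
    if T > 2:
        rows = np.repeat(np.arange(T - 2), 3)
        cols = (np.arange(T - 2)[:, None] + np.arange(3)[None, :]).ravel()
        data = np.tile([-theta2, -theta1, 1.0], T - 2)
        B = sp.csr_matrix((data, (rows, cols)), shape=(T - 2, T))
        Q = sp.csr_matrix(Q) + prec * (B.T @ B)
    return sp.csr_matrix(Q)


def ar1_precision(T: int, phi: float) -> sp.csr_matrix:
    """Precision of a stationary AR(1) with unit marginal variance.

    Tridiagonal: diag (1, 1+Φ², …, 1+Φ², 1)/(1−Φ²), off-diagonal −Φ/(1−Φ²).
    """
    if not abs(phi) < 1:
        raise DomainError("|Phi| must be < 1")
    if T < 1:
        raise SizeError("T must be >= 1")
    if T == 1:
        return sp.csr_matrix(np.array([[1.0]]))
    s = 1.0 / (1.0 - phi**2)
    diag = np.full(T, (1.0 + phi**2) * s)
    diag[0] = diag[-1] = s
    off = np.full(T - 1, -phi * s)
    return sp.diags([off, diag, off], offsets=[-1, 0, 1]).tocsr()


def spacetime_precision(Q_space: sp.spmatrix, group: GroupARSpec, T: int) -> sp.csc_matrix:
    """Separable space–time precision Q_time(Φ) ⊗ Q_space (period-major order).

    The AR(1) factor has unit stationary marginal variance, so every period's
    marginal covariance is exactly Q_space⁻¹ regardless of Φ.
    """
    Qt = ar1_precision(T, group.phi)
    return sp.kron(Qt, sp.csc_matrix(Q_space), format="csc")
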