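"""Matérn covariance bookkeeping and the sparse SPDE precision.

A stationary Gaussian field with Matérn covariance is the solution of the SPDE
(κ² − Δ)^{α/2} (τ x) = W on R², and its finite-element discretisation on a mesh
is a Gaussian Markov random field with the sparse precision

    Q = τ² (κ² C̃ + G)ᵀ C̃⁻¹ (κ² C̃ + G)          (α = 2, ν = 1, d = 2)

where C̃ is the lumped mass matrix and G the stiffness matrix.  This module
handles the (σ, ρ) ↔ (log τ, log κ) reparameterisation, builds Q, and samples
from GMRFs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.special import gamma as gamma_fn, kv

from ._linalg import sample_gmrf  # re-exported: simulator and tests use it from here
from .errors import DomainError
from .mesh import FEMMatrices

__all__ = [
    "MaternParams",
    "matern_correlation",
    "range_to_kappa",
    "kappa_to_range",
    "sigma_from_tau_kappa",
    "tau_from_sigma_kappa",
    "spde_precision",
    "sample_gmrf",
]


def matern_correlation(h, kappa: float, nu: float = 1.0):
    """Matérn correlation C(h) = 2^{1−ν}/Γ(ν) (κh)^ν K_ν(κh), with C(0)=1."""
    if kappa <= 0 or nu <= 0:
        raise DomainError("kappa and nu must be positive")
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise DomainError("distances must be non-negative")
    x = kappa * h
    with np.errstate(invalid="ignore", over="ignore"):
        c = 2.0 ** (1.0 - nu) / gamma_fn(nu) * x**nu * kv(nu, x)
    c = np.where(x == 0, 1.0, c)
    c = np.where(np.isnan(c), 0.0, c)  # kv underflow at large κh
    return c if c.ndim else float(c)


def range_to_kappa(rho: float, nu: float = 1.0) -> float:
    """κ = √(8ν)/ρ — the range ρ is the distance at which correlation ≈ 0.1."""
    if rho <= 0:
        raise DomainError("range rho must be positive")
    return float(np.sqrt(8.0 * nu) / rho)


def kappa_to_range(kappa: float, nu: float = 1.0) -> float:
    if kappa <= 0:
        raise DomainError("kappa must be positive")
    return float(np.sqrt(8.0 * nu) / kappa)


def sigma_from_tau_kappa(tau: float, kappa: float, nu: float = 1.0, d: int = 2) -> float:
    """Marginal standard deviation σ with σ² = Γ(ν) / (4π)^{d/2} κ^{2ν} τ² Γ(ν+d/2))."""
    if tau <= 0 or kappa <= 0:
        raise DomainError("tau and kappa must be positive")
    var = gamma_fn(nu) / (
        (4.0 * np.pi) ** (d / 2.0) * kappa ** (2.0 * nu) * tau**2 * gamma_fn(nu + d / 2.0)
    )
    return float(np.sqrt(var))


def tau_from_sigma_kappa(sigma: float, kappa: float, nu: float = 1.0, d: int = 2) -> float:
    """Invert the marginal-variance identity for τ at given σ and κ."""
    if sigma <= 0 or kappa <= 0:
        raise DomainError("sigma and kappa must be positive")
    num = gamma_fn(nu)
    den = (4.0 * np.pi) ** (d / 2.0) * kappa ** (2.0 * nu) * sigma**2 * gamma_fn(nu + d / 2.0)
    return float(np.sqrt(num / den))


@dataclass(frozen=True)
class MaternParams:
    """Matérn field parameters in both natural and internal scales.

    ``sigma`` (marginal sd) and ``rho`` (range, km) are the interpretable pair;
    ``log_tau``/``log_kappa`` are the internal SPDE scale parameters the
    inference engine works with.  The two pairs are kept mutually consistent.
    ν is fixed at 1 (α = 2 in two dimensions).
    """

    sigma: float
    rho: float
    log_tau: float
    log_kappa: float
    nu: float = 1.0

    @classmethod
    def from_sigma_rho(cls, sigma: float, rho: float, nu: float = 1.0) -> "MaternParams":
        if sigma <= 0 or rho <= 0:
            raise DomainError("sigma and rho must be positive")
        kappa = range_to_kappa(rho, nu)
        tau = tau_from_sigma_kappa(sigma, kappa, nu)
        return cls(sigma=sigma, rho=rho, log_tau=float(np.log(tau)),
                   log_kappa=float(np.log(kappa)), nu=nu)

    @classmethod
    def from_log_tau_kappa(cls, log_tau: float, log_kappa: float, nu: float = 1.0) -> "MaternParams":
        tau, kappa = float(np.exp(log_tau)), float(np.exp(log_kappa))
        return cls(sigma=sigma_from_tau_kappa(tau, kappa, nu),
                   rho=kappa_to_range(kappa, nu),
                   log_tau=float(log_tau), log_kappa=float(log_kappa), nu=nu)


def spde_precision(fem: FEMMatrices, params: MaternParams) -> sp.csc_matrix:
    """Sparse precision of the discretised Matérn field (α = 2).

    Q = τ² (κ²C̃ + G)ᵀ C̃⁻¹ (κ²C̃ + G) with C̃ = diag(C_lumped).  Lumping is
    used in both factors so Q keeps the sparsity of the squared mesh adjacency.
    """
    c = np.asarray(fem.C_lumped, dtype=float)
    if np.any(c <= 0):
        raise DomainError("lumped mass has non-positive entries; mesh is degenerate")
    tau = np.exp(params.log_tau)
    kappa = np.exp(params.log_kappa)
    Ct = sp.diags(c)
    K = (kappa**2) * Ct + fem.G
    Q = tau**2 * (K.T @ sp.diags(1.0 / c) @ K)
    Q = ((Q + Q.T) * 0.5).tocsc()  # symmetrise away round-off
    return Q
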