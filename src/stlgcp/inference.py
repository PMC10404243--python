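"""Laplace-approximation inference for the latent Gaussian LGCP.

Fitting proceeds in two nested stages, in the spirit of integrated nested
Laplace approximation (INLA):

1. *Inner*: for fixed hyperparameters θ, the latent log-posterior
   (Poisson pseudo-likelihood + GMRF prior) is maximised by Newton iteration;
   the Gaussian approximation at the mode gives latent means, variances and
   the Laplace estimate of the evidence
   log π(θ | Y) ≈ log π(θ) + ℓ(x*) − ½x*ᵀQ_p x* + ½log|Q_p| − ½log|Q_post|.

2. *Outer*: the evidence is maximised over θ (empirical Bayes, default) or
   explored on a small axial design around the mode ('grid'); hyperparameter
   uncertainty comes from the curvature of the evidence at the mode, on the
   transformed (unconstrained) scale.

Sum-to-zero constraints on intrinsic components are imposed by conditioning by
kriging: the unconstrained Gaussian approximation is corrected exactly to the
constraint subspace.  Latent marginals are Gaussian (no skewness correction),
a documented simplification relative to full INLA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import minimize
from scipy.stats import norm

from ._linalg import SPDFactor
from .errors import ConvergenceError, FitError, NotPositiveDefiniteError, SpecError
from .mesh import FEMMatrices, Mesh
from .model import (
    AugmentedData,
    CovariateDesign,
    LatentLayout,
    ModelSpec,
    PointPattern,
    build_design,
    build_layout,
)
from .spde import MaternParams, spde_precision

__all__ = [
    "PoissonAugLikelihood",
    "GaussianPseudoLikelihood",
    "gaussian_approx",
    "PriorConfig",
    "LGCPModel",
    "FitResult",
    "fit",
    "extract_components",
]

_Z975 = norm.ppf(0.975)


# ---------------------------------------------------------------------------
# likelihood objects (diagonal Hessian in the linear predictor)
# ---------------------------------------------------------------------------


@dataclass
class PoissonAugLikelihood:
    """Augmented-Poisson pseudo-likelihood Σ yη − Σ a·exp(η)."""

    y: np.ndarray
    a: np.ndarray

    def loglik(self, eta):
        return float(self.y @ eta - self.a @ np.exp(eta))

    def grad(self, eta):
        return self.y - self.a * np.exp(eta)

    def curv(self, eta):
        """Negative second derivative wrt η (non-negative)."""
        return self.a * np.exp(eta)


@dataclass
class GaussianPseudoLikelihood:
    """Gaussian observation model η ~ N(y_obs, 1/w); makes Newton exact."""

    y_obs: np.ndarray
    w: np.ndarray

    def loglik(self, eta):
        r = eta - self.y_obs
        return float(-0.5 * self.w @ r**2 + 0.5 * np.sum(np.log(self.w / (2 * np.pi))))

    def grad(self, eta):
        return -self.w * (eta - self.y_obs)

    def curv(self, eta):
        return np.broadcast_to(self.w, eta.shape)


# ---------------------------------------------------------------------------
# inner Laplace step
# ---------------------------------------------------------------------------


@dataclass
class GaussianApprox:
    """Mode, posterior precision and log-determinants of the inner step."""

    mode: np.ndarray
    Q_post: sp.csc_matrix
    factor: SPDFactor
    logdet_post: float
    loglik_at_mode: float
    prior_quad: float  # x*ᵀ Q_p x*
    n_iter: int


def gaussian_approx(
    B: sp.spmatrix,
    likelihood,
    Q_prior: sp.spmatrix,
    x0: np.ndarray | None = None,
    gtol: float = 1e-6,
    xtol: float = 1e-8,
    max_iter: int = 50,
) -> GaussianApprox:
    """Newton maximisation of the latent log-posterior with step halving.

    Converges when max |gradient| < ``gtol`` or the relative change of the
    mode falls below ``xtol``.  Raises :class:`ConvergenceError` (carrying the
    last iterate) after ``max_iter`` iterations.
    """
    B = sp.csr_matrix(B)
    Qp = sp.csc_matrix(Q_prior)
    n = Qp.shape[0]
    x = np.zeros(n) if x0 is None else np.array(x0, dtype=float)

    def objective(x):
        return likelihood.loglik(B @ x) - 0.5 * float(x @ (Qp @ x))

    f = objective(x)
    for it in range(1, max_iter + 1):
        eta = B @ x
        g = B.T @ likelihood.grad(eta) - Qp @ x
        if np.max(np.abs(g)) < gtol:
            break
        W = likelihood.curv(eta)
        H = (Qp + B.T @ sp.diags(W) @ B).tocsc()
        try:
            fac = SPDFactor(H)
        except NotPositiveDefiniteError as exc:
            raise ConvergenceError(f"Hessian not SPD at iteration {it}: {exc}", x) from exc
        step = fac.solve(g)
        alpha, accepted = 1.0, False
        for _ in range(30):
            x_new = x + alpha * step
            f_new = objective(x_new)
            if np.isfinite(f_new) and f_new >= f - 1e-9 * max(1.0, abs(f)):
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            # concave objective: a stalled line search means the improvement is
            # below floating-point resolution, i.e. we are at the mode
            break
        rel = np.linalg.norm(x_new - x) / max(1.0, np.linalg.norm(x_new))
        x, f = x_new, f_new
        if rel < xtol:
            break
    else:
        raise ConvergenceError(f"Newton did not converge in {max_iter} iterations", x)

    eta = B @ x
    H = (Qp + B.T @ sp.diags(likelihood.curv(eta)) @ B).tocsc()
    fac = SPDFactor(H)
    return GaussianApprox(
        mode=x,
        Q_post=H,
        factor=fac,
        logdet_post=fac.logdet,
        loglik_at_mode=likelihood.loglik(eta),
        prior_quad=float(x @ (Qp @ x)),
        n_iter=it,
    )


# ---------------------------------------------------------------------------
# hyperparameters: transforms and priors
# ---------------------------------------------------------------------------

_HYPER_TABLE = {
    # internal name: (natural-dict key, transform, label)
    "log_prec_trend": ("prec_trend", "exp", "precision_trend"),
    "log_prec_seasonal": ("prec_seasonal", "exp", "precision_seasonal"),
    "z_phi_s": ("phi_s", "tanh", "seasonal_pacf"),
    "log_prec_cycle": ("prec_cycle", "exp", "precision_cycle"),
    "z_pacf1": ("pacf1", "tanh", "cycle_pacf1"),
    "z_pacf2": ("pacf2", "tanh", "cycle_pacf2"),
    "log_tau": ("log_tau", "id", "log_tau"),
    "log_kappa": ("log_kappa", "id", "log_kappa"),
    "z_phi": ("phi", "tanh", "group_phi"),
}


@dataclass
class PriorConfig:
    """Weakly-informative hyperpriors on the transformed scale.

    Log-precisions get a log-gamma(shape, rate) prior; Fisher-z transformed
    autoregressive coefficients get N(0, z_sd²); (log τ, log κ) get independent
    normals centred at values implying σ = ``sigma0`` and range
    ``range_fraction`` × window diameter.
    """

    prec_shape: float = 1.0
    prec_rate: float = 5e-5
    z_sd: float = 1.0
    sigma0: float = 1.0
    range_fraction: float = 0.2
    log_tau_sd: float = 1.0
    log_kappa_sd: float = 1.0
    log_tau_center: float | None = None
    log_kappa_center: float | None = None

    def resolve_centers(self, diameter: float) -> "PriorConfig":
        if self.log_tau_center is None or self.log_kappa_center is None:
            p = MaternParams.from_sigma_rho(self.sigma0, self.range_fraction * diameter)
            if self.log_tau_center is None:
                self.log_tau_center = p.log_tau
            if self.log_kappa_center is None:
                self.log_kappa_center = p.log_kappa
        return self


class HyperMap:
    """Ordered mapping between the transformed vector and natural parameters."""

    def __init__(self, spec: ModelSpec):
        names = []
        if spec.use_trend:
            names.append("log_prec_trend")
        if spec.use_seasonal:
            names.append("log_prec_seasonal")
            if spec.seasonal_phi_fixed is None:
                names.append("z_phi_s")
        if spec.use_cycle:
            names += ["log_prec_cycle", "z_pacf1", "z_pacf2"]
        if spec.use_field:
            names += ["log_tau", "log_kappa", "z_phi"]
        self.names = names
        self.labels = [_HYPER_TABLE[n][2] for n in names]

    @property
    def k(self) -> int:
        return len(self.names)

    def natural(self, vec: np.ndarray) -> dict:
        out = {}
        for name, v in zip(self.names, vec):
            key, tf, _ = _HYPER_TABLE[name]
            out[key] = float(np.exp(v)) if tf == "exp" else (
                float(np.tanh(v)) if tf == "tanh" else float(v)
            )
        return out

    def transform_natural(self, vec: np.ndarray) -> np.ndarray:
        """Element-wise transform to the natural/reporting scale."""
        out = np.empty_like(np.asarray(vec, dtype=float))
        for i, name in enumerate(self.names):
            tf = _HYPER_TABLE[name][1]
            out[i] = np.exp(vec[i]) if tf == "exp" else (
                np.tanh(vec[i]) if tf == "tanh" else vec[i]
            )
        return out

    def log_prior(self, vec: np.ndarray, priors: PriorConfig) -> float:
        lp = 0.0
        for name, v in zip(self.names, vec):
            tf = _HYPER_TABLE[name][1]
            if tf == "exp":
                lp += priors.prec_shape * v - priors.prec_rate * np.exp(v)
            elif tf == "tanh":
                lp += -0.5 * (v / priors.z_sd) ** 2
            elif name == "log_tau":
                lp += -0.5 * ((v - priors.log_tau_center) / priors.log_tau_sd) ** 2
            elif name == "log_kappa":
                lp += -0.5 * ((v - priors.log_kappa_center) / priors.log_kappa_sd) ** 2
        return float(lp)

    def initial(self, priors: PriorConfig) -> np.ndarray:
        vec = []
        for name in self.names:
            if name.startswith("log_prec"):
                vec.append(np.log(10.0))
            elif name == "log_tau":
                vec.append(priors.log_tau_center)
            elif name == "log_kappa":
                vec.append(priors.log_kappa_center)
            else:
                vec.append(0.0)
        return np.array(vec, dtype=float)


# ---------------------------------------------------------------------------
# assembled model + evidence
# ---------------------------------------------------------------------------


@dataclass
class LGCPModel:
    """Everything needed to evaluate the Laplace evidence at a given θ."""

    pattern: PointPattern
    mesh: Mesh
    fem: FEMMatrices
    weights: np.ndarray
    data: AugmentedData
    layout: LatentLayout
    B: sp.csr_matrix
    spec: ModelSpec
    covariates: CovariateDesign | None
    priors: PriorConfig
    hyper: HyperMap

    @classmethod
    def build(
        cls,
        pattern: PointPattern,
        mesh: Mesh,
        fem: FEMMatrices,
        weights: np.ndarray,
        data: AugmentedData,
        spec: ModelSpec,
        covariates: CovariateDesign | None = None,
        priors: PriorConfig | None = None,
    ) -> "LGCPModel":
        layout = build_layout(spec, mesh.n_vertices, pattern.T, data.Z.shape[1] - 1)
        B = build_design(layout, data)
        priors = priors or PriorConfig()
        priors.resolve_centers(mesh.diameter())
        return cls(pattern=pattern, mesh=mesh, fem=fem, weights=weights, data=data,
                   layout=layout, B=B, spec=spec, covariates=covariates,
                   priors=priors, hyper=HyperMap(spec))

    # -- prior assembly ---------------------------------------------------

    def _space_precision(self, nat: dict):
        if not self.spec.use_field:
            return None
        params = MaternParams.from_log_tau_kappa(nat["log_tau"], nat["log_kappa"])
        return spde_precision(self.fem, params)

    def _prior_parts(self, nat: dict):
        """Joint prior precision and its log-determinant (block-wise)."""
        Q_space = self._space_precision(nat)
        Qp = self.layout.prior_precision(nat, Q_space)
        logdet = self.layout.n_fixed * np.log(self.spec.fixed_effect_precision)
        T = self.layout.T
        jitter = 1e-6
        # intrinsic blocks: prec·S + jitter·I shares eigenvectors with S, so the
        # log-determinant Σ log(prec·λ_i + jitter) stays stable at extreme prec
        from .temporal import (
            CycleSpec as _Cyc,
            SeasonalSpec as _Seas,
            TrendSpec as _Tr,
            ar2_precision as _ar2,
            rw2_precision as _rw2,
            seasonal_precision as _seas,
        )

        if self.spec.use_trend:
            lam = np.linalg.eigvalsh(_rw2(_Tr(T, 1.0)).toarray())
            logdet += float(np.sum(np.log(nat["prec_trend"] * np.clip(lam, 0, None) + jitter)))
        if self.spec.use_seasonal:
            phi_s = (self.spec.seasonal_phi_fixed
                     if self.spec.seasonal_phi_fixed is not None else nat["phi_s"])
            S = _seas(_Seas(T, self.spec.seasonal_period, phi_s, 1.0)).toarray()
            lam = np.linalg.eigvalsh(S)
            logdet += float(np.sum(np.log(nat["prec_seasonal"] * np.clip(lam, 0, None) + jitter)))
        if self.spec.use_cycle:
            # proper stationary block scales linearly with the precision
            S = _ar2(_Cyc(T, nat["pacf1"], nat["pacf2"], 1.0)).toarray()
            sign, ld = np.linalg.slogdet(S)
            if sign <= 0:
                raise NotPositiveDefiniteError("cycle prior block not SPD")
            logdet += T * np.log(nat["prec_cycle"]) + ld
        if self.spec.use_field:
            from .temporal import ar1_precision

            Qt = ar1_precision(T, nat["phi"]).toarray()
            _, ld_t = np.linalg.slogdet(Qt)
            ld_s = SPDFactor(Q_space).logdet
            logdet += self.mesh.n_vertices * ld_t + T * ld_s
        return Qp, float(logdet)

    # -- evidence ---------------------------------------------------------

    def log_marginal(
        self, theta_vec: np.ndarray, x0: np.ndarray | None = None, gtol: float = 1e-6
    ) -> tuple[float, GaussianApprox]:
        """Laplace approximation of log π(θ | Y), up to an additive constant."""
        nat = self.hyper.natural(theta_vec)
        Qp, logdet_prior = self._prior_parts(nat)
        lik = PoissonAugLikelihood(self.data.y, self.data.a)
        ga = gaussian_approx(self.B, lik, Qp, x0=x0, gtol=gtol)
        lp = (
            self.hyper.log_prior(theta_vec, self.priors)
            + ga.loglik_at_mode
            - 0.5 * ga.prior_quad
            + 0.5 * logdet_prior
            - 0.5 * ga.logdet_post
        )
        return float(lp), ga


# ---------------------------------------------------------------------------
# fit result and the outer optimisation
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Posterior summaries of hyperparameters, fixed effects and components.

    All summary tables use the columns mean, sd, q025, q50, q975, mode.
    ``intensity`` holds the fitted posterior-mean log-intensity per
    node-period; ``totals`` the per-period predicted event totals with 95%
    intervals next to the observed counts.
    """

    hyperparameters: pd.DataFrame
    fixed_effects: pd.DataFrame
    components: pd.DataFrame
    field: pd.DataFrame
    intensity: pd.DataFrame
    totals: pd.DataFrame
    latent_mean: np.ndarray
    latent_sd: np.ndarray
    layout: LatentLayout
    theta_mode: np.ndarray
    theta_cov: np.ndarray
    converged: bool
    n_outer_iter: int
    log_evidence: float
    seed: int
    strategy: str


def _summary_frame(index, mean, sd, mode=None) -> pd.DataFrame:
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    return pd.DataFrame(
        {
            "mean": mean,
            "sd": sd,
            "q025": mean - _Z975 * sd,
            "q50": mean,
            "q975": mean + _Z975 * sd,
            "mode": mean if mode is None else np.asarray(mode, dtype=float),
        },
        index=index,
    )


def _constrain(mean, Sigma, A):
    """Conditioning by kriging: project N(mean, Σ) onto {Ax = 0}.

    Returns corrected mean, corrected marginal variances, and the correction
    operator (W, S⁻¹) needed to project posterior draws.
    """
    if A.shape[0] == 0:
        return mean, np.diag(Sigma).copy(), None
    W = Sigma @ A.T
    S = A @ W
    Sinv = np.linalg.inv(S)
    mean_c = mean - W @ (Sinv @ (A @ mean))
    var_c = np.diag(Sigma) - np.einsum("ij,ij->i", W @ Sinv, W)
    return mean_c, np.clip(var_c, 0.0, None), (W, Sinv, A)


def fit(
    model: LGCPModel,
    strategy: str = "eb",
    seed: int = 0,
    maxiter: int = 100,
    n_draws: int = 500,
    fd_step: float = 0.05,
    dense_cutoff: int = 8000,
) -> FitResult:
    """Fit the model: empirical-Bayes (default) or axial-grid hyperposterior.

    All randomness (posterior draws for predicted totals) is governed by
    ``seed``; rerunning with the same seed reproduces every summary exactly.
    """
    if strategy not in ("eb", "grid"):
        raise SpecError("strategy must be 'eb' or 'grid'")
    rng = np.random.default_rng(seed)
    hyper = model.hyper

    warm = {"x": None}

    def neg_lp(v):
        try:
            lp, ga = model.log_marginal(v, x0=warm["x"])
        except (ConvergenceError, NotPositiveDefiniteError):
            # numerically infeasible θ: steer the optimiser away
            return 1e10
        warm["x"] = ga.mode
        return -lp

    theta0 = hyper.initial(model.priors)
    if hyper.k:
        res = minimize(
            neg_lp,
            theta0,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "eps": 1e-4, "ftol": 1e-10, "gtol": 1e-4},
        )
        if not np.all(np.isfinite(res.x)):
            raise FitError("hyperparameter optimisation diverged", res)
        theta_hat = res.x
        n_outer = int(res.nit)
        converged = bool(res.success or res.status == 1)
    else:
        theta_hat, n_outer, converged = theta0, 0, True

    # curvature of the evidence at the mode (transformed scale)
    k = hyper.k
    if k:
        lp0, _ = model.log_marginal(theta_hat, x0=warm["x"])
        H = np.zeros((k, k))
        h = fd_step
        lp_cache = {}

        def lp_at(v):
            key = tuple(np.round(v, 12))
            if key not in lp_cache:
                lp_cache[key], _ = model.log_marginal(v, x0=warm["x"])
            return lp_cache[key]

        for i in range(k):
            ei = np.zeros(k)
            ei[i] = h
            H[i, i] = (lp_at(theta_hat + ei) - 2 * lp0 + lp_at(theta_hat - ei)) / h**2
            for j in range(i + 1, k):
                ej = np.zeros(k)
                ej[j] = h
                H[i, j] = H[j, i] = (
                    lp_at(theta_hat + ei + ej)
                    - lp_at(theta_hat + ei - ej)
                    - lp_at(theta_hat - ei + ej)
                    + lp_at(theta_hat - ei - ej)
                ) / (4 * h**2)
        neg_H = -H
        eigvals = np.linalg.eigvalsh(neg_H)
        if np.any(eigvals <= 0):
            warnings.warn(
                "evidence Hessian not positive definite; falling back to "
                "diagonal curvature", RuntimeWarning,
            )
            d = np.clip(-np.diag(H), 1e-6, None)
            theta_cov = np.diag(1.0 / d)
        else:
            theta_cov = np.linalg.inv(neg_H)
        theta_sd = np.sqrt(np.diag(theta_cov))
    else:
        lp0 = model.log_marginal(theta_hat)[0]
        theta_cov = np.zeros((0, 0))
        theta_sd = np.zeros(0)

    # optional axial 'grid' exploration: reweighted moments on the z-scale
    if strategy == "grid" and k:
        pts = [theta_hat]
        lps = [lp0]
        for i in range(k):
            for s in (-1.0, 1.0):
                v = theta_hat.copy()
                v[i] += s * 1.2 * theta_sd[i]
                lp_i, _ = model.log_marginal(v, x0=warm["x"])
                pts.append(v)
                lps.append(lp_i)
        pts = np.array(pts)
        w = np.exp(np.array(lps) - max(lps))
        w /= w.sum()
        theta_mean_z = w @ pts
        theta_var_z = w @ (pts - theta_mean_z) ** 2 + np.diag(theta_cov)
        theta_sd = np.sqrt(theta_var_z)
        theta_center = theta_mean_z
    else:
        theta_center = theta_hat

    # hyperparameter summaries on the natural/reporting scale
    if k:
        gh_x, gh_w = np.polynomial.hermite_e.hermegauss(31)
        nat_mean = np.empty(k)
        nat_sd = np.empty(k)
        q_lo = np.empty(k)
        q_hi = np.empty(k)
        q_md = np.empty(k)
        nat_mode = hyper.transform_natural(theta_hat)
        for i, name in enumerate(hyper.names):
            zs = theta_center[i] + theta_sd[i] * gh_x
            tf = _HYPER_TABLE[name][1]
            vals = np.exp(zs) if tf == "exp" else (np.tanh(zs) if tf == "tanh" else zs)
            m1 = float(np.sum(gh_w * vals) / np.sum(gh_w))
            m2 = float(np.sum(gh_w * vals**2) / np.sum(gh_w))
            nat_mean[i] = m1
            nat_sd[i] = np.sqrt(max(m2 - m1**2, 0.0))
            qz = theta_center[i] + theta_sd[i] * np.array([-_Z975, 0.0, _Z975])
            qn = np.exp(qz) if tf == "exp" else (np.tanh(qz) if tf == "tanh" else qz)
            q_lo[i], q_md[i], q_hi[i] = qn
        hyper_df = pd.DataFrame(
            {"mean": nat_mean, "sd": nat_sd, "q025": q_lo, "q50": q_md,
             "q975": q_hi, "mode": nat_mode},
            index=hyper.labels,
        )
    else:
        hyper_df = pd.DataFrame(columns=["mean", "sd", "q025", "q50", "q975", "mode"])

    # latent Gaussian approximation at the hyper mode
    lp_final, ga = model.log_marginal(theta_hat, x0=warm["x"], gtol=1e-8)
    layout = model.layout
    dim = layout.dim
    if dim > dense_cutoff:
        raise FitError(
            f"latent dimension {dim} exceeds dense summary cutoff {dense_cutoff}"
        )
    Sigma = np.linalg.inv(ga.Q_post.toarray())

    # empirical-Bayes correction (Kass–Steffey): propagate hyperparameter
    # uncertainty into the latent covariance through the sensitivity of the
    # conditional mode, Σ → Σ + J Σ_θ Jᵀ with J = ∂x*(θ)/∂θ
    if k:
        J = np.zeros((dim, k))
        for i in range(k):
            ei = np.zeros(k)
            ei[i] = fd_step
            _, ga_p = model.log_marginal(theta_hat + ei, x0=ga.mode)
            _, ga_m = model.log_marginal(theta_hat - ei, x0=ga.mode)
            J[:, i] = (ga_p.mode - ga_m.mode) / (2 * fd_step)
        Sigma = Sigma + J @ theta_cov @ J.T

    mean_c, var_c, corr = _constrain(ga.mode, Sigma, layout.constraints)
    sd_c = np.sqrt(var_c)

    # posterior draws (kriging-corrected) for nonlinear functionals
    L = np.linalg.cholesky(Sigma + 1e-12 * np.eye(dim))
    draws = mean_c + (rng.standard_normal((n_draws, dim)) @ L.T)
    if corr is not None:
        W, Sinv, A = corr
        # A @ mean_c = 0 already, so correcting each draw preserves the mean
        draws = draws - (draws @ A.T) @ Sinv @ W.T

    # fixed effects
    sl = layout.slices["fixed"]
    fixed_df = _summary_frame(model.data.names, mean_c[sl], sd_c[sl])

    # temporal components
    comp_rows = []
    for name in ("trend", "seasonal", "cycle"):
        if name in layout.slices:
            s = layout.slices[name]
            for t in range(layout.T):
                comp_rows.append(
                    dict(component=name, period=t + 1, mean=mean_c[s][t], sd=sd_c[s][t])
                )
    comp_df = pd.DataFrame(comp_rows)
    if len(comp_df):
        comp_df["q025"] = comp_df["mean"] - _Z975 * comp_df["sd"]
        comp_df["q50"] = comp_df["mean"]
        comp_df["q975"] = comp_df["mean"] + _Z975 * comp_df["sd"]

    # spatial field: time-averaged per-node summaries
    N, T = layout.N, layout.T
    if "field" in layout.slices:
        s = layout.slices["field"]
        xi_mean = mean_c[s].reshape(T, N)
        xi_draws = draws[:, s].reshape(n_draws, T, N)
        xi_avg_draws = xi_draws.mean(axis=1)
        field_df = pd.DataFrame(
            {
                "node": np.arange(N),
                "x": model.mesh.vertices[:, 0],
                "y": model.mesh.vertices[:, 1],
                "mean": xi_mean.mean(axis=0),
                "sd": xi_avg_draws.std(axis=0, ddof=1),
            }
        )
    else:
        xi_mean = np.zeros((T, N))
        field_df = pd.DataFrame(columns=["node", "x", "y", "mean", "sd"])

    # fitted log-intensity per node-period (posterior mean = sum of means)
    p = model.data.Z.shape[1] - 1
    beta = mean_c[layout.slices["fixed"]]
    node_Z = np.ones((T, N, 1 + p))
    if p and model.covariates is not None:
        node_Z[:, :, 1:] = model.covariates.node_values
    log_int = node_Z @ beta
    for name in ("trend", "seasonal", "cycle"):
        if name in layout.slices:
            log_int += mean_c[layout.slices[name]][:, None]
    log_int += xi_mean
    intensity_df = pd.DataFrame(
        {
            "node": np.tile(np.arange(N), T),
            "period": np.repeat(np.arange(1, T + 1), N),
            "log_intensity": log_int.ravel(),
        }
    )

    # per-period predicted totals with intervals, from the posterior draws
    w_quad = np.asarray(model.weights, dtype=float)
    lam_draws = np.einsum("tnp,dp->dtn", node_Z, draws[:, layout.slices["fixed"]])
    for name in ("trend", "seasonal", "cycle"):
        if name in layout.slices:
            lam_draws += draws[:, layout.slices[name]][:, :, None]
    if "field" in layout.slices:
        lam_draws += draws[:, layout.slices["field"]].reshape(n_draws, T, N)
    tot_draws = np.einsum("dtn,n->dt", np.exp(np.clip(lam_draws, -700, 700)), w_quad)
    observed = model.pattern.counts_per_period()
    totals_df = pd.DataFrame(
        {
            "period": np.arange(1, T + 1),
            "observed": observed,
            "mean": tot_draws.mean(axis=0),
            "q025": np.quantile(tot_draws, 0.025, axis=0),
            "q50": np.quantile(tot_draws, 0.5, axis=0),
            "q975": np.quantile(tot_draws, 0.975, axis=0),
        }
    )

    return FitResult(
        hyperparameters=hyper_df,
        fixed_effects=fixed_df,
        components=comp_df,
        field=field_df,
        intensity=intensity_df,
        totals=totals_df,
        latent_mean=mean_c,
        latent_sd=sd_c,
        layout=layout,
        theta_mode=theta_hat,
        theta_cov=theta_cov,
        converged=converged,
        n_outer_iter=n_outer,
        log_evidence=float(lp_final),
        seed=seed,
        strategy=strategy,
    )


def extract_components(result: FitResult) -> dict[str, pd.DataFrame]:
    """Per-component posterior tables of a fit.

    Returns the temporal component paths (mean and 95% interval per period),
    the per-period predicted-vs-observed totals, and the time-averaged spatial
    field surface.  Components absent from the model are simply absent here.
    """
    out = {}
    if len(result.components):
        out["components"] = result.components.copy()
    out["totals"] = result.totals.copy()
    if len(result.field):
        out["field"] = result.field.copy()
    return out
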