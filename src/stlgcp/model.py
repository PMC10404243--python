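"""Point patterns, covariate designs, and the augmented-Poisson representation.

The Cox-process likelihood over a window Ω involves the intractable integral
∫_Ω exp(λ(s,t)) ds per period.  Approximating it with the dual-cell quadrature
rule of the mesh turns the likelihood into that of (N + n_t) independent
Poisson-type pseudo-observations per period: one row per mesh node with
response 0 and exposure α_k·e(s_k,t), and one row per event with response 1 and
exposure 0 (its contribution is the linear predictor itself).  This module
builds that augmented data set and the joint latent-Gaussian layout
[intercept+β | μ | s | c | ξ].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import shapely
from shapely.geometry import Polygon

from .errors import EmptyPatternError, RangeError, SpecError
from .mesh import Mesh, projection_matrix
from .temporal import (
    CycleSpec,
    GroupARSpec,
    SeasonalSpec,
    TrendSpec,
    ar2_precision,
    rw2_precision,
    seasonal_precision,
    spacetime_precision,
)

__all__ = [
    "PointPattern",
    "CovariateDesign",
    "AugmentedData",
    "ModelSpec",
    "LatentLayout",
    "aggregate_periods",
    "augment_likelihood",
    "build_layout",
    "build_design",
]


@dataclass
class PointPattern:
    """Events with planar coordinates and 1-based period indices.

    ``x``/``y`` in the planar (km) coordinate system of the window, ``t`` in
    {1..T}.  ``period_labels`` carries the calendar labels (e.g. '2002Q3').
    """

    x: np.ndarray
    y: np.ndarray
    t: np.ndarray
    window: Polygon
    T: int
    period_labels: list[str] = field(default_factory=list)
    n_dropped_outside: int = 0

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.t = np.asarray(self.t, dtype=int)
        if not (len(self.x) == len(self.y) == len(self.t)):
            raise SpecError("x, y, t must have equal length")
        if len(self.t) and (self.t.min() < 1 or self.t.max() > self.T):
            raise RangeError("period indices must lie in 1..T")

    @property
    def n_events(self) -> int:
        return len(self.x)

    def counts_per_period(self) -> np.ndarray:
        """n_t for t = 1..T."""
        return np.bincount(self.t, minlength=self.T + 1)[1:]


@dataclass
class CovariateDesign:
    """Per-node-per-period covariate values with one shared column ordering.

    ``node_values`` has shape (T, N, p).  Continuous columns are expected to be
    standardised; categorical covariates enter one-hot with a dropped reference
    level.  Event rows take the value at the nearest mesh node, so categorical
    and continuous covariates are treated identically.
    """

    node_values: np.ndarray
    names: list[str]

    def __post_init__(self):
        self.node_values = np.asarray(self.node_values, dtype=float)
        if self.node_values.ndim != 3:
            raise SpecError("node_values must have shape (T, N, p)")
        if self.node_values.shape[2] != len(self.names):
            raise SpecError("number of names must match number of columns")
        flat = self.node_values.reshape(-1, max(1, self.node_values.shape[2]))
        if self.node_values.shape[2] and np.any(np.all(flat == 0, axis=0)):
            raise SpecError("covariate design contains an all-zero column")

    @property
    def p(self) -> int:
        return self.node_values.shape[2]


@dataclass
class AugmentedData:
    """Pseudo-observations of the augmented Poisson representation.

    Rows are ordered period-major: for each t, first the N node rows
    (y=0, a=α_k·e_{kt}), then the n_t event rows (y=1, a=0).  ``A_space`` maps
    the per-period spatial field values at the N nodes to each row (identity
    rows for nodes, barycentric rows for events); ``Z`` holds intercept and
    covariates.
    """

    y: np.ndarray
    a: np.ndarray
    t: np.ndarray
    A_space: sp.csr_matrix
    Z: np.ndarray
    names: list[str]
    N: int
    T: int

    @property
    def n_rows(self) -> int:
        return len(self.y)


@dataclass
class ModelSpec:
    """Which intensity components are active, and their structural settings."""

    use_trend: bool = True
    use_seasonal: bool = True
    seasonal_period: int = 4
    seasonal_phi_fixed: float | None = None  # None: estimate φ_s; 1.0: random-walk form
    use_cycle: bool = True
    use_field: bool = True
    fixed_effect_precision: float = 1e-3  # diffuse Gaussian prior on intercept and β

    def active_components(self) -> list[str]:
        out = []
        if self.use_trend:
            out.append("trend")
        if self.use_seasonal:
            out.append("seasonal")
        if self.use_cycle:
            out.append("cycle")
        if self.use_field:
            out.append("field")
        return out


def aggregate_periods(
    events: pd.DataFrame,
    frequency: str,
    window: Polygon,
    start: str | None = None,
    end: str | None = None,
) -> PointPattern:
    """Aggregate dated events into quarterly or monthly period indices.

    Parameters
    ----------
    events : DataFrame with columns x, y, date (datetime-like)
    frequency : 'quarterly' or 'monthly'
    window : observation-window polygon; events outside are dropped (counted)
    start, end : optional period bounds (anything pandas parses); by default
        the range of the data.  Dates outside an explicit range raise.
    """
    if frequency not in ("quarterly", "monthly"):
        raise SpecError(f"frequency must be 'quarterly' or 'monthly', got {frequency!r}")
    if len(events) == 0:
        raise EmptyPatternError("no events supplied")
    freq = "Q" if frequency == "quarterly" else "M"
    dates = pd.to_datetime(events["date"])
    periods = dates.dt.to_period(freq)

    p0 = pd.Period(pd.to_datetime(start), freq=freq) if start else periods.min()
    p1 = pd.Period(pd.to_datetime(end), freq=freq) if end else periods.max()
    if (periods < p0).any() or (periods > p1).any():
        raise RangeError("event dates fall outside the declared study range")

    inside = shapely.contains_xy(window, events["x"].to_numpy(), events["y"].to_numpy())
    n_dropped = int((~inside).sum())
    ev = events[inside]
    t = (periods[inside] - p0).map(lambda d: d.n).to_numpy() + 1
    T = (p1 - p0).n + 1
    labels = [str(p0 + k) for k in range(T)]
    return PointPattern(
        x=ev["x"].to_numpy(), y=ev["y"].to_numpy(), t=t, window=window, T=T,
        period_labels=labels, n_dropped_outside=n_dropped,
    )


def augment_likelihood(
    pattern: PointPattern,
    mesh: Mesh,
    weights: np.ndarray,
    covariates: CovariateDesign | None = None,
    offset: np.ndarray | float = 1.0,
) -> AugmentedData:
    """Build the augmented pseudo-Poisson data set.

    ``offset`` is the exposure multiplier e(s,t): scalar, or array (T, N).
    Only the product α_k · e_{kt} enters the likelihood.
    """
    N, T = mesh.n_vertices, pattern.T
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (N,):
        raise SpecError("weights length must equal the number of mesh vertices")
    off = np.broadcast_to(np.asarray(offset, dtype=float), (T, N))
    if np.any(off[:, weights > 0] <= 0):
        raise SpecError("offset must be positive wherever quadrature weight is positive")

    p = covariates.p if covariates is not None else 0
    names = ["intercept"] + (list(covariates.names) if covariates is not None else [])

    # event geometry: barycentric rows and nearest nodes (for covariate lookup)
    if pattern.n_events:
        pts = np.column_stack([pattern.x, pattern.y])
        A_events = projection_matrix(mesh, pts)
        mesh._ensure_location_index()
        _, nearest = mesh._vertex_tree.query(pts)
        nearest = np.atleast_1d(nearest)
    else:
        A_events = sp.csr_matrix((0, N))
        nearest = np.array([], dtype=int)

    eye = sp.identity(N, format="csr")
    y_parts, a_parts, t_parts, A_parts, Z_parts = [], [], [], [], []
    for t in range(1, T + 1):
        sel = np.where(pattern.t == t)[0]
        n_t = len(sel)
        y_parts.append(np.zeros(N))
        a_parts.append(weights * off[t - 1])
        t_parts.append(np.full(N, t))
        A_parts.append(eye)
        Zn = np.ones((N, 1 + p))
        if p:
            Zn[:, 1:] = covariates.node_values[t - 1]
        Z_parts.append(Zn)
        if n_t:
            y_parts.append(np.ones(n_t))
            a_parts.append(np.zeros(n_t))
            t_parts.append(np.full(n_t, t))
            A_parts.append(A_events[sel])
            Ze = np.ones((n_t, 1 + p))
            if p:
                Ze[:, 1:] = covariates.node_values[t - 1][nearest[sel]]
            Z_parts.append(Ze)

    return AugmentedData(
        y=np.concatenate(y_parts),
        a=np.concatenate(a_parts),
        t=np.concatenate(t_parts).astype(int),
        A_space=sp.vstack(A_parts).tocsr(),
        Z=np.vstack(Z_parts),
        names=names,
        N=N,
        T=T,
    )


@dataclass
class LatentLayout:
    """Index bookkeeping for the joint latent vector and its prior.

    Order: [intercept+β | μ_{1..T} | s_{1..T} | c_{1..T} | ξ_{1..NT}] with only
    the active blocks present.  ``constraints`` holds sum-to-zero rows (the
    trend always; the seasonal phases when φ_s is fixed at 1).
    """

    spec: ModelSpec
    N: int
    T: int
    n_fixed: int
    slices: dict
    dim: int
    constraints: np.ndarray  # (n_con, dim)

    def prior_precision(self, theta: dict, Q_space: sp.spmatrix | None = None) -> sp.csc_matrix:
        """Assemble the block-diagonal joint prior precision.

        ``theta`` maps natural-scale hyperparameter names ('prec_trend',
        'prec_seasonal', 'phi_s', 'prec_cycle', 'pacf1', 'pacf2', 'phi') to
        values; ``Q_space`` is the SPDE precision when the field is active.
        Intrinsic blocks receive a small diagonal jitter so the joint prior is
        proper; interpretability constraints are applied downstream.
        """
        blocks = [sp.identity(self.n_fixed) * self.spec.fixed_effect_precision]
        jitter = 1e-6
        if self.spec.use_trend:
            Q = rw2_precision(TrendSpec(self.T, theta["prec_trend"]))
            blocks.append(Q + jitter * sp.identity(self.T))
        if self.spec.use_seasonal:
            phi_s = (
                self.spec.seasonal_phi_fixed
                if self.spec.seasonal_phi_fixed is not None
                else theta["phi_s"]
            )
            Q = seasonal_precision(
                SeasonalSpec(self.T, self.spec.seasonal_period, phi_s, theta["prec_seasonal"])
            )
            blocks.append(Q + jitter * sp.identity(self.T))
        if self.spec.use_cycle:
            Q = ar2_precision(
                CycleSpec(self.T, theta["pacf1"], theta["pacf2"], theta["prec_cycle"])
            )
            blocks.append(Q)
        if self.spec.use_field:
            if Q_space is None:
                raise SpecError("field active but no spatial precision supplied")
            blocks.append(spacetime_precision(Q_space, GroupARSpec(theta["phi"]), self.T))
        return sp.block_diag(blocks, format="csc")


def build_layout(spec: ModelSpec, N: int, T: int, p: int) -> LatentLayout:
    """Lay out the latent vector and constraint matrix for the active blocks."""
    if spec.use_trend and T < 3:
        raise SpecError("RW2 trend requires T >= 3")
    if spec.use_seasonal and T <= spec.seasonal_period:
        raise SpecError("seasonal component requires T > period")
    n_fixed = 1 + p
    slices = {"fixed": slice(0, n_fixed)}
    pos = n_fixed
    for name in spec.active_components():
        size = N * T if name == "field" else T
        slices[name] = slice(pos, pos + size)
        pos += size
    dim = pos

    rows = []
    if spec.use_trend:
        r = np.zeros(dim)
        r[slices["trend"]] = 1.0
        rows.append(r)
    if spec.use_seasonal and spec.seasonal_phi_fixed == 1.0:
        # one overall sum-to-zero row: separates the seasonal level from the
        # intercept while leaving the phase pattern (the component's signal)
        # to be identified by the data
        r = np.zeros(dim)
        r[slices["seasonal"]] = 1.0
        rows.append(r)
    constraints = np.array(rows) if rows else np.zeros((0, dim))
    return LatentLayout(spec=spec, N=N, T=T, n_fixed=n_fixed, slices=slices,
                        dim=dim, constraints=constraints)


def build_design(layout: LatentLayout, data: AugmentedData) -> sp.csr_matrix:
    """Sparse design matrix B with η = B x for the augmented rows."""
    R = data.n_rows
    parts = [sp.csr_matrix(data.Z)]
    if layout.spec.use_trend or layout.spec.use_seasonal or layout.spec.use_cycle:
        t_inc = sp.csr_matrix(
            (np.ones(R), (np.arange(R), data.t - 1)), shape=(R, data.T)
        )
        for name in ("trend", "seasonal", "cycle"):
            if name in layout.slices:
                parts.append(t_inc)
    if layout.spec.use_field:
        # period-major ξ: column block t holds the N node values of period t
        blocks = []
        for t in range(1, data.T + 1):
            mask = data.t == t
            rows_t = data.A_space[mask]
            before = sp.csr_matrix((rows_t.shape[0], data.N * (t - 1)))
            after = sp.csr_matrix((rows_t.shape[0], data.N * (data.T - t)))
            blocks.append(sp.hstack([before, rows_t, after]))
        parts.append(sp.vstack(blocks))
    B = sp.hstack(parts, format="csr")
    if B.shape[1] != layout.dim:
        raise SpecError("design width does not match latent layout")
    return B


def augmented_loglik(eta: np.ndarray, data: AugmentedData) -> float:
    """Augmented log-likelihood Σ yη − Σ a·exp(η) (up to an additive constant)."""
    return float(data.y @ eta - data.a @ np.exp(eta))
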