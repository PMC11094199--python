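"""Degree-block (heterogeneous mean-field) version of the U-B-A model.

Nodes are grouped by degree k with per-degree class fractions (u_k, b_k,
a_k).  Transmission couples to the degree-weighted neighbour densities
psi_x = sum_k (k p_k / <k>) x_k, while the media field couples to the plain
bootlegger fraction b = sum_k p_k b_k, identical for all nodes.  Per-contact
rates default to alpha_n = alpha / <k> and rho_n = rho / <k>, which makes the
delta-distributed (regular) network reduce exactly to the homogeneous model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.stats import poisson as _poisson

from .homogeneous import ModelParams, Trajectory

__all__ = [
    "DegreeDistribution",
    "DegreeBlockState",
    "DegreeBlockTrajectory",
    "rhs_degree_block",
    "integrate_degree_block",
    "epidemic_threshold",
    "early_growth_condition",
    "steady_state_self_consistency",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DegreeDistribution:
    """A finite-support degree distribution with cached moments."""

    support: np.ndarray  # degrees k >= 1
    pk: np.ndarray       # probabilities, sum to 1

    def __post_init__(self) -> None:
        support = np.asarray(self.support, dtype=float)
        pk = np.asarray(self.pk, dtype=float)
        if support.ndim != 1 or pk.shape != support.shape:
            raise ValueError("support and pk must be 1-d arrays of equal length")
        if support.size == 0:
            raise ValueError("empty degree support")
        if np.any(support < 1) or np.any(support != np.round(support)):
            raise ValueError("degrees must be integers >= 1")
        if np.any(pk < 0):
            raise ValueError("pk must be non-negative")
        if abs(pk.sum() - 1.0) > 1e-12:
            raise ValueError(f"pk must sum to 1 within 1e-12, got {pk.sum()!r}")
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "pk", pk)

    @property
    def first_moment(self) -> float:
        return float(self.support @ self.pk)

    @property
    def second_moment(self) -> float:
        return float((self.support**2) @ self.pk)

    @property
    def n_classes(self) -> int:
        return int(self.support.size)

    def neighbor_weights(self) -> np.ndarray:
        """Degree-weighted probabilities k p_k / <k> used in the psi sums."""
        return self.support * self.pk / self.first_moment

    # ---- constructors -------------------------------------------------

    @classmethod
    def _normalized(cls, support: np.ndarray, weights: np.ndarray) -> "DegreeDistribution":
        keep = weights > 0
        w = weights[keep]
        return cls(support=support[keep], pk=w / w.sum())

    @classmethod
    def delta(cls, k0: int) -> "DegreeDistribution":
        """Regular network: every node has degree k0."""
        return cls(support=np.array([k0], dtype=float), pk=np.array([1.0]))

    regular = delta

    @classmethod
    def poisson(cls, mean: float) -> "DegreeDistribution":
        """Poisson degree distribution truncated to [1, mean + 10 sqrt(mean)]."""
        if mean <= 0:
            raise ValueError("mean must be positive")
        kmax = int(math.ceil(mean + 10 * math.sqrt(mean)))
        ks = np.arange(1, kmax + 1, dtype=float)
        return cls._normalized(ks, _poisson.pmf(ks, mean))

    @classmethod
    def powerlaw(cls, exponent: float, kmin: int = 1, kmax: int | None = None,
                 n: int | None = None) -> "DegreeDistribution":
        """Truncated power law p_k ~ k^-exponent on [kmin, kmax].

        When kmax is omitted it follows the structural-cutoff convention
        kmax = sqrt(n) for a network of n nodes.
        """
        if kmax is None:
            if n is None:
                raise ValueError("provide either kmax or n")
            kmax = max(kmin + 1, int(math.sqrt(n)))
        ks = np.arange(kmin, kmax + 1, dtype=float)
        return cls._normalized(ks, ks ** (-float(exponent)))

    @classmethod
    def from_degrees(cls, degrees: Sequence[int]) -> "DegreeDistribution":
        """Empirical distribution from a degree sequence; k = 0 nodes dropped."""
        deg = np.asarray(degrees, dtype=int)
        n_isolated = int((deg == 0).sum())
        if n_isolated:
            logger.warning("dropping %d isolated nodes from the degree distribution", n_isolated)
        deg = deg[deg > 0]
        if deg.size == 0:
            raise ValueError("degree sequence has no nodes with degree >= 1")
        ks, counts = np.unique(deg, return_counts=True)
        return cls(support=ks.astype(float), pk=counts / counts.sum())

    @classmethod
    def from_csv(cls, path) -> "DegreeDistribution":
        """Read columns (k, p_k) from a CSV file; probabilities renormalized."""
        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise ValueError("expected two columns: degree, probability")
        return cls._normalized(
            df.iloc[:, 0].to_numpy(dtype=float), df.iloc[:, 1].to_numpy(dtype=float)
        )


@dataclass
class DegreeBlockState:
    """Per-degree fractions on a degree distribution plus the shared media level."""

    dd: DegreeDistribution
    u: np.ndarray
    b: np.ndarray
    a: np.ndarray
    m: float
    t: float | None = None

    def __post_init__(self) -> None:
        k = self.dd.n_classes
        for name in ("u", "b", "a"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (k,):
                raise ValueError(f"{name} must have shape ({k},), got {arr.shape}")
            setattr(self, name, arr)

    @property
    def psi_u(self) -> float:
        return float(self.dd.neighbor_weights() @ self.u)

    @property
    def psi_b(self) -> float:
        return float(self.dd.neighbor_weights() @ self.b)

    @property
    def psi_a(self) -> float:
        return float(self.dd.neighbor_weights() @ self.a)

    @property
    def b_fraction(self) -> float:
        """Plain (unweighted) bootlegger fraction over the whole population."""
        return float(self.dd.pk @ self.b)

    def aggregate(self) -> tuple[float, float, float]:
        return (
            float(self.dd.pk @ self.u),
            float(self.dd.pk @ self.b),
            float(self.dd.pk @ self.a),
        )


def _network_rates(params: ModelParams, dd: DegreeDistribution,
                   alpha_n: float | None, rho_n: float | None) -> tuple[float, float]:
    mean_k = dd.first_moment
    return (
        params.alpha / mean_k if alpha_n is None else alpha_n,
        params.rho / mean_k if rho_n is None else rho_n,
    )


def _rhs_arrays(
    u: np.ndarray,
    b: np.ndarray,
    a: np.ndarray,
    m: float,
    params: ModelParams,
    dd: DegreeDistribution,
    alpha_n: float,
    rho_n: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    p = params
    k = dd.support
    w = dd.neighbor_weights()
    psi_b = float(w @ b)
    psi_a = float(w @ a)
    b_frac = float(dd.pk @ b)
    theta = m / (p.c + m)
    f_ub = alpha_n * k * (1.0 - theta) * u * psi_b
    f_ba_peer = rho_n * k * b * psi_a
    f_ba_media = p.gamma * m * b
    f_ab = p.beta * a
    du = p.mu * (b + a) - f_ub
    db = f_ub - f_ba_peer + f_ab - f_ba_media - p.mu * b
    da = f_ba_peer - f_ab + f_ba_media - p.mu * a
    dm = p.phi * b_frac - p.phi0 * (m - p.m0)
    return du, db, da, dm


def rhs_degree_block(
    state: DegreeBlockState,
    params: ModelParams,
    dd: DegreeDistribution | None = None,
    alpha_n: float | None = None,
    rho_n: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Per-degree derivatives (du_k, db_k, da_k) and dm.

    Per-degree conservation holds exactly: du_k + db_k + da_k = 0 for every k.
    """
    if dd is None:
        dd = state.dd
    elif not np.array_equal(dd.support, state.dd.support):
        raise ValueError("state support does not match the supplied degree distribution")
    a_n, r_n = _network_rates(params, dd, alpha_n, rho_n)
    return _rhs_arrays(state.u, state.b, state.a, state.m, params, dd, a_n, r_n)


@dataclass
class DegreeBlockTrajectory:
    """Time-resolved per-degree fractions plus the shared media level."""

    dd: DegreeDistribution
    t: np.ndarray
    u: np.ndarray  # shape (T, K)
    b: np.ndarray
    a: np.ndarray
    m: np.ndarray  # shape (T,)

    @property
    def final_state(self) -> DegreeBlockState:
        return DegreeBlockState(
            dd=self.dd, u=self.u[-1], b=self.b[-1], a=self.a[-1],
            m=float(self.m[-1]), t=float(self.t[-1]),
        )

    def aggregate(self) -> Trajectory:
        """Population-level fractions sum_k p_k x_k as a homogeneous-style trajectory."""
        pk = self.dd.pk
        return Trajectory(
            t=self.t, u=self.u @ pk, b=self.b @ pk, a=self.a @ pk, m=self.m
        )


def default_init(dd: DegreeDistribution, params: ModelParams, b0: float = 1e-3) -> DegreeBlockState:
    k = dd.n_classes
    return DegreeBlockState(
        dd=dd,
        u=np.full(k, 1.0 - b0),
        b=np.full(k, b0),
        a=np.zeros(k),
        m=params.m0,
    )


def integrate_degree_block(
    params: ModelParams,
    dd: DegreeDistribution,
    init: DegreeBlockState | None = None,
    t_end: float = 1000.0,
    dt_out: float = 1.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    alpha_n: float | None = None,
    rho_n: float | None = None,
) -> DegreeBlockTrajectory:
    """Integrate the degree-block ODE system."""
    if init is None:
        init = default_init(dd, params)
    elif not np.array_equal(init.dd.support, dd.support):
        raise ValueError("init support does not match the degree distribution")
    a_n, r_n = _network_rates(params, dd, alpha_n, rho_n)
    K = dd.n_classes

    def f(t: float, y: np.ndarray) -> np.ndarray:
        u, b, a, m = y[:K], y[K : 2 * K], y[2 * K : 3 * K], y[3 * K]
        du, db, da, dm = _rhs_arrays(u, b, a, m, params, dd, a_n, r_n)
        return np.concatenate([du, db, da, [dm]])

    y0 = np.concatenate([init.u, init.b, init.a, [init.m]])
    t_eval = np.arange(0.0, t_end + 0.5 * dt_out, dt_out)
    if t_eval[-1] > t_end:
        t_eval = t_eval[:-1]
    sol = solve_ivp(f, (0.0, float(t_end)), y0, method="LSODA", t_eval=t_eval,
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"degree-block integration failed: {sol.message}")
    y = sol.y
    return DegreeBlockTrajectory(
        dd=dd,
        t=sol.t,
        u=y[:K].T,
        b=y[K : 2 * K].T,
        a=y[2 * K : 3 * K].T,
        m=y[3 * K],
    )


def epidemic_threshold(dd: DegreeDistribution) -> float:
    """Network epidemic threshold <k>^2 / <k^2> (in (0, 1]).

    The contagion can invade iff the reproduction number exceeds this value;
    it equals 1 on regular graphs and shrinks with degree heterogeneity.
    """
    return dd.first_moment**2 / dd.second_moment


def early_growth_condition(
    params: ModelParams,
    dd: DegreeDistribution,
    m: float | None = None,
    alpha_n: float | None = None,
) -> bool:
    """Necessary condition for initial growth of the bootlegger class.

    Linearizing around the all-unaware state at media level ``m`` (default
    m0) gives a 2x2 linear system psi_b' = C1 psi_b + C2 psi_a,
    psi_a' = C3 psi_a + C4 psi_b; growth requires C1*C3 < C2*C4.
    """
    p = params
    if m is None:
        m = p.m0
    if m < p.m0:
        raise ValueError(f"media level m={m} below the intrinsic level m0={p.m0}")
    a_n, _ = _network_rates(params, dd, alpha_n, None)
    c1 = a_n * (dd.second_moment / dd.first_moment) * (p.c / (p.c + m)) - (p.gamma * m + p.mu)
    c2 = p.beta
    c3 = -(p.beta + p.mu)
    c4 = p.gamma * m
    return bool(c1 * c3 < c2 * c4)


def steady_state_self_consistency(
    params: ModelParams,
    dd: DegreeDistribution,
    alpha_n: float | None = None,
    rho_n: float | None = None,
    damping: float = 0.5,
    tol: float = 1e-10,
    max_iter: int = 100_000,
) -> DegreeBlockState:
    """Solve the steady-state self-consistency system by damped iteration.

    The per-degree closed forms express (u_k, a_k, b_k) in terms of the
    neighbour densities (psi_b, psi_a) and the plain bootlegger fraction b;
    closing the loop gives a monotone bounded fixed-point map on [0, 1]^3.
    A non-trivial fixed point exists iff R_m > <k>^2 / <k^2>; below that
    threshold the exact zero solution is returned.
    """
    from .homogeneous import reproduction_number

    p = params
    a_n, r_n = _network_rates(params, dd, alpha_n, rho_n)
    k = dd.support
    w = dd.neighbor_weights()
    z = p.z
    K = dd.n_classes

    if reproduction_number(params) <= epidemic_threshold(dd):
        return DegreeBlockState(dd=dd, u=np.ones(K), b=np.zeros(K), a=np.zeros(K), m=p.m0)

    psi_b, psi_a, b = 1e-3, 1e-3, 1e-3
    for _ in range(max_iter):
        m_eff = p.m0 + z * b
        denom_u = p.mu * (p.c + m_eff)
        b_k = ((p.beta + p.mu) / (p.beta + p.mu + r_n * k * psi_a + p.gamma * m_eff)) * (
            a_n * k * p.c * psi_b / (a_n * k * p.c * psi_b + denom_u)
        )
        a_k = (r_n * k * psi_a + p.gamma * m_eff) / (p.beta + p.mu) * b_k
        psi_b_new = float(w @ b_k)
        psi_a_new = float(w @ a_k)
        b_new = float(dd.pk @ b_k)
        change = max(abs(psi_b_new - psi_b), abs(psi_a_new - psi_a), abs(b_new - b))
        psi_b = (1 - damping) * psi_b + damping * psi_b_new
        psi_a = (1 - damping) * psi_a + damping * psi_a_new
        b = (1 - damping) * b + damping * b_new
        if change < tol:
            break
    else:
        raise RuntimeError(
            f"self-consistency iteration did not converge: residual {change:.3g} "
            f"after {max_iter} iterations"
        )

    m_eff = p.m0 + z * b
    u_k = p.mu * (p.c + m_eff) / (p.mu * (p.c + m_eff) + a_n * k * p.c * psi_b)
    b_k = ((p.beta + p.mu) / (p.beta + p.mu + r_n * k * psi_a + p.gamma * m_eff)) * (
        a_n * k * p.c * psi_b / (a_n * k * p.c * psi_b + p.mu * (p.c + m_eff))
    )
    a_k = (r_n * k * psi_a + p.gamma * m_eff) / (p.beta + p.mu) * b_k
    return DegreeBlockState(dd=dd, u=u_k, b=b_k, a=a_k, m=m_eff)
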