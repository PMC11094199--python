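"""Homogeneous (well-mixed) U-B-A contagion model with a media-awareness field.

The population is split into Unaware (u), Bootlegger (b) and Aware (a)
fractions on the simplex u + b + a = 1, coupled to a global media level m.
Transmission U->B is damped by a Holling type-II media response
Theta = m / (c + m); the media level grows with the bootlegger fraction
and relaxes back to an intrinsic level m0.

This module provides the vector field, trajectory integration, equilibrium
computation (piracy-free and endemic), the reproduction number and its
normalized sensitivities, media-parameter thresholds and a bifurcation scan.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace as _dc_replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "ModelParams",
    "HomogeneousState",
    "CubicCoefficients",
    "Equilibrium",
    "SensitivityIndices",
    "Trajectory",
    "rhs",
    "integrate",
    "reproduction_number",
    "cubic_coefficients",
    "steady_states",
    "a_star_coefficients",
    "sensitivity_indices",
    "sensitivity_indices_numeric",
    "c_threshold",
    "m0_threshold",
    "bifurcation_scan",
    "jacobian",
]

logger = logging.getLogger(__name__)

PARAM_FIELDS = ("mu", "alpha", "beta", "rho", "gamma", "phi", "phi0", "c", "m0")

#: default feasibility tolerance for |u* + b* + a* - 1|
FEASIBILITY_TOL = 1e-9
#: eigenvalue real-part tolerance used for stability classification
STABILITY_TOL = 1e-8


@dataclass(frozen=True)
class ModelParams:
    """The nine strictly positive rate/media constants of the model.

    Parameters
    ----------
    mu : demographic turnover rate (1/time).
    alpha : U->B peer transmission rate.
    beta : A->B relapse rate.
    rho : B->A positive-peer influence rate.
    gamma : media success rate (B->A at rate ``gamma * m``).
    phi : media growth rate per unit bootlegger fraction.
    phi0 : media depletion rate.
    c : half-saturation constant of the media response.
    m0 : intrinsic awareness level of the society.
    """

    mu: float
    alpha: float
    beta: float
    rho: float
    gamma: float
    phi: float
    phi0: float
    c: float
    m0: float

    def __post_init__(self) -> None:
        for name in PARAM_FIELDS:
            v = getattr(self, name)
            if not isinstance(v, (int, float)) or isinstance(v, bool):
                raise ValueError(f"parameter {name!r} must be a number, got {v!r}")
            if not math.isfinite(v) or v <= 0:
                raise ValueError(
                    f"parameter {name!r} must be strictly positive and finite, got {v!r}"
                )
            object.__setattr__(self, name, float(v))

    @property
    def z(self) -> float:
        """Steady-state media gain phi / phi0."""
        return self.phi / self.phi0

    def replace(self, **changes: float) -> "ModelParams":
        return _dc_replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAM_FIELDS}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        unknown = set(d) - set(PARAM_FIELDS)
        if unknown:
            raise ValueError(f"unknown parameter names: {sorted(unknown)}")
        missing = set(PARAM_FIELDS) - set(d)
        if missing:
            raise ValueError(f"missing parameter names: {sorted(missing)}")
        return cls(**{k: d[k] for k in PARAM_FIELDS})


@dataclass(frozen=True)
class HomogeneousState:
    """Population fractions (u, b, a), media level m and optional time t."""

    u: float
    b: float
    a: float
    m: float
    t: float | None = None

    def theta(self, params: ModelParams) -> float:
        """Holling type-II media response m / (c + m)."""
        return self.m / (params.c + self.m)

    def as_array(self) -> np.ndarray:
        return np.array([self.u, self.b, self.a, self.m], dtype=float)


def as_state(
    init: "HomogeneousState | Sequence[float]", params: ModelParams
) -> HomogeneousState:
    """Coerce a state-like input into a valid on-simplex state.

    Accepts a :class:`HomogeneousState` or a sequence ``(u, b, a[, m])``.
    Initial conditions with u + b + a < 1 are accepted: the deficit is
    assigned to the aware class (with a logged warning), which preserves the
    given (u, b) pair.  Media defaults to the intrinsic level m0.
    """
    if isinstance(init, HomogeneousState):
        u, b, a, m = init.u, init.b, init.a, init.m
    else:
        vals = list(init)
        if len(vals) == 3:
            u, b, a = vals
            m = params.m0
        elif len(vals) == 4:
            u, b, a, m = vals
        else:
            raise ValueError("state must be (u, b, a) or (u, b, a, m)")
    for name, v in (("u", u), ("b", b), ("a", a), ("m", m)):
        if not math.isfinite(v):
            raise ValueError(f"non-finite state component {name}={v!r}")
    if min(u, b, a) < -FEASIBILITY_TOL or max(u, b, a) > 1 + FEASIBILITY_TOL:
        raise ValueError(f"fractions must lie in [0, 1], got (u, b, a)=({u}, {b}, {a})")
    deficit = 1.0 - (u + b + a)
    if deficit < -1e-9:
        raise ValueError(f"u + b + a = {u + b + a} exceeds 1")
    if deficit > 1e-9:
        logger.warning(
            "initial fractions sum to %.6g < 1; assigning deficit %.6g to the aware class",
            u + b + a,
            deficit,
        )
        a = a + deficit
    else:
        # absorb tiny rounding so the simplex constraint holds exactly
        a = 1.0 - u - b
    return HomogeneousState(u=float(u), b=float(b), a=float(a), m=float(m))


def _rhs_array(y: np.ndarray, p: ModelParams) -> np.ndarray:
    u, b, a, m = y
    theta = m / (p.c + m)
    f_ub = p.alpha * (1.0 - theta) * u * b     # U -> B peer transmission
    f_ba_peer = p.rho * b * a                  # B -> A positive peer influence
    f_ba_media = p.gamma * m * b               # B -> A media-driven conversion
    f_ab = p.beta * a                          # A -> B relapse
    # turnover written as mu*(b+a) inflow into U so that du+db+da cancels
    # algebraically for any state (equivalent to mu - mu*u on the simplex)
    du = p.mu * (b + a) - f_ub
    db = f_ub - f_ba_peer + f_ab - f_ba_media - p.mu * b
    da = f_ba_peer - f_ab + f_ba_media - p.mu * a
    dm = p.phi * b - p.phi0 * (m - p.m0)
    return np.array([du, db, da, dm])


def rhs(state: HomogeneousState, params: ModelParams) -> tuple[float, float, float, float]:
    """Time derivatives (du, db, da, dm) of the homogeneous model.

    The three class derivatives cancel algebraically (du + db + da = 0),
    so the simplex constraint is conserved exactly by the flow.
    """
    y = state.as_array()
    if not np.all(np.isfinite(y)):
        raise ValueError(f"non-finite state: {state}")
    if y[:3].min() < -FEASIBILITY_TOL or y[:3].max() > 1 + FEASIBILITY_TOL:
        raise ValueError(f"state fractions outside [0, 1]: {state}")
    du, db, da, dm = _rhs_array(y, params)
    return float(du), float(db), float(da), float(dm)


@dataclass
class Trajectory:
    """Dense output of :func:`integrate` as aligned numpy arrays."""

    t: np.ndarray
    u: np.ndarray
    b: np.ndarray
    a: np.ndarray
    m: np.ndarray

    def __len__(self) -> int:
        return len(self.t)

    def states(self) -> Iterator[HomogeneousState]:
        for i in range(len(self.t)):
            yield HomogeneousState(
                u=self.u[i], b=self.b[i], a=self.a[i], m=self.m[i], t=self.t[i]
            )

    @property
    def final_state(self) -> HomogeneousState:
        return HomogeneousState(
            u=self.u[-1], b=self.b[-1], a=self.a[-1], m=self.m[-1], t=self.t[-1]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.t, "u": self.u, "b": self.b, "a": self.a, "m": self.m}
        )


def integrate(
    params: ModelParams,
    init: HomogeneousState | Sequence[float],
    t_end: float,
    dt_out: float = 1.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the model from ``init`` to ``t_end``, sampled every ``dt_out``."""
    state = as_state(init, params)
    t_eval = np.arange(0.0, t_end + 0.5 * dt_out, dt_out)
    if t_eval[-1] > t_end:
        t_eval = t_eval[:-1]
    sol = solve_ivp(
        lambda t, y: _rhs_array(y, params),
        (0.0, float(t_end)),
        state.as_array(),
        method=method,
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    u, b, a, m = sol.y
    drift = np.abs(u + b + a - 1.0)
    if drift.max() > 1e-6:
        raise RuntimeError(f"simplex constraint violated: max drift {drift.max():.3g}")
    return Trajectory(t=sol.t, u=u, b=b, a=a, m=m)


def reproduction_number(params: ModelParams) -> float:
    """Reproduction number of the piracy contagion under media awareness.

    R_m = alpha * c * (beta + mu) / (mu * (c + m0) * (beta + mu + m0 * gamma)).
    The endemic state exists (and the piracy-free state is unstable) iff
    R_m > 1.
    """
    p = params
    return (p.alpha * p.c * (p.beta + p.mu)) / (
        p.mu * (p.c + p.m0) * (p.beta + p.mu + p.m0 * p.gamma)
    )


@dataclass(frozen=True)
class CubicCoefficients:
    """Coefficients of p*b*^2 + q*b* + r = 0 after factoring out b* = 0."""

    p: float
    q: float
    r: float


def cubic_coefficients(params: ModelParams) -> CubicCoefficients:
    """Coefficients of the steady-state polynomial in the bootlegger fraction.

    Substituting the steady-state expressions for u* and a* into the simplex
    constraint yields p b*^3 + q b*^2 + r b* = 0; the returned (p, q, r) are
    the coefficients of the quadratic left after removing the root b* = 0.
    sign(r) is opposite to sign(R_m - 1).
    """
    p_ = params
    z = p_.z
    p = (p_.mu * z + p_.alpha * p_.c) * (p_.gamma * z - p_.rho)
    q = (
        (p_.mu * z + p_.alpha * p_.c) * (p_.beta + p_.mu + p_.m0 * p_.gamma)
        + p_.mu * (p_.c + p_.m0) * (p_.gamma * z - p_.rho)
        + p_.alpha * p_.c * p_.rho
    )
    r = p_.mu * (p_.c + p_.m0) * (p_.beta + p_.mu + p_.m0 * p_.gamma) - p_.alpha * p_.c * (
        p_.beta + p_.mu
    )
    return CubicCoefficients(p=p, q=q, r=r)


def a_star_coefficients(params: ModelParams, u_star: float) -> tuple[float, float, float]:
    """Coefficients (p_a, q_a, r_a) of the steady-state quadratic in a*.

    Used as a consistency cross-check on endemic feasibility: the feasible
    endemic a* must be a root of p_a a*^2 + q_a a* + r_a = 0 at the endemic
    u*.
    """
    if not 0 <= u_star <= 1:
        raise ValueError(f"u_star must lie in [0, 1], got {u_star}")
    p_ = params
    z = p_.z
    p_a = p_.gamma * z - p_.rho
    q_a = (p_.rho - 2 * z * p_.gamma) * (1 - u_star) - p_.gamma * p_.m0 - (p_.mu + p_.beta)
    r_a = (
        p_.gamma * p_.m0 * (1 - u_star)
        + p_.gamma * z
        - p_.gamma * z * u_star * (2 - u_star)
    )
    return p_a, q_a, r_a


@dataclass
class Equilibrium:
    """A steady state with class label, feasibility and stability flags."""

    state: HomogeneousState
    kind: str  # "piracy_free" | "endemic"
    feasible: bool
    stable: bool
    eigenvalues: np.ndarray


def jacobian(params: ModelParams, state: HomogeneousState, step: float = 1e-7) -> np.ndarray:
    """Central-difference Jacobian of the vector field at ``state``."""
    y0 = state.as_array()
    J = np.empty((4, 4))
    for j in range(4):
        h = step * max(1.0, abs(y0[j]))
        yp = y0.copy()
        ym = y0.copy()
        yp[j] += h
        ym[j] -= h
        J[:, j] = (_rhs_array(yp, params) - _rhs_array(ym, params)) / (2 * h)
    return J


def _classify(params: ModelParams, state: HomogeneousState) -> tuple[bool, np.ndarray]:
    eig = np.linalg.eigvals(jacobian(params, state))
    # one eigenvalue is structurally 0 (simplex conservation direction);
    # stability is decided by the remaining spectrum
    return bool(np.max(eig.real) < STABILITY_TOL), eig


def _endemic_b_roots(coeffs: CubicCoefficients) -> list[float]:
    p, q, r = coeffs.p, coeffs.q, coeffs.r
    if abs(p) < 1e-14:  # degenerate quadratic -> linear equation
        if abs(q) < 1e-14:
            return []
        return [-r / q]
    disc = q * q - 4 * p * r
    if disc < 0:
        return []
    s = math.sqrt(disc)
    return [(-q + s) / (2 * p), (-q - s) / (2 * p)]


def _back_substitute(params: ModelParams, b_star: float) -> HomogeneousState | None:
    """Assemble (u*, b*, a*, m*) from a bootlegger root via the steady-state maps."""
    p = params
    z = p.z
    m_star = p.m0 + z * b_star
    u_star = ((p.c + p.m0 + z * b_star) * p.mu) / (
        (p.c + p.m0 + z * b_star) * p.mu + p.alpha * p.c * b_star
    )
    denom = p.beta + p.mu - p.rho * b_star
    if abs(denom) < 1e-14:
        return None
    a_star = (p.m0 + z * b_star) * p.gamma * b_star / denom
    return HomogeneousState(u=u_star, b=b_star, a=a_star, m=m_star)


def steady_states(params: ModelParams) -> list[Equilibrium]:
    """All steady states of the model with feasibility and stability labels.

    The piracy-free state E0 = (1, 0, 0, m0) is always present.  A unique
    feasible endemic state exists iff the reproduction number exceeds 1; it
    is recovered from the quadratic root in b* by back-substitution.
    """
    out: list[Equilibrium] = []
    e0_state = HomogeneousState(u=1.0, b=0.0, a=0.0, m=params.m0)
    stable, eig = _classify(params, e0_state)
    out.append(
        Equilibrium(state=e0_state, kind="piracy_free", feasible=True, stable=stable, eigenvalues=eig)
    )
    for b_star in _endemic_b_roots(cubic_coefficients(params)):
        if not 0 < b_star <= 1:
            continue
        st = _back_substitute(params, b_star)
        if st is None:
            continue
        feasible = (
            0 <= st.u <= 1
            and 0 <= st.a <= 1
            and abs(st.u + st.b + st.a - 1.0) < FEASIBILITY_TOL
        )
        if not feasible:
            continue
        stable, eig = _classify(params, st)
        out.append(
            Equilibrium(state=st, kind="endemic", feasible=True, stable=stable, eigenvalues=eig)
        )
    return out


@dataclass(frozen=True)
class SensitivityIndices:
    """Normalized sensitivities of the reproduction number, one per parameter."""

    alpha: float
    c: float
    beta: float
    m0: float
    mu: float
    gamma: float

    def to_dict(self) -> dict[str, float]:
        return {
            "alpha": self.alpha,
            "c": self.c,
            "beta": self.beta,
            "m0": self.m0,
            "mu": self.mu,
            "gamma": self.gamma,
        }


def sensitivity_indices(params: ModelParams) -> SensitivityIndices:
    """Closed-form normalized sensitivity indices (x / R_m) dR_m/dx."""
    p = params
    bm = p.beta + p.mu
    bmg = p.beta + p.mu + p.m0 * p.gamma
    cm = p.c + p.m0
    return SensitivityIndices(
        alpha=1.0,
        c=p.m0 / cm,
        beta=(p.beta / bm) * (p.m0 * p.gamma / bmg),
        m0=-((p.m0 * p.gamma / bmg) + (p.m0 / cm)),
        mu=-((p.beta / bm) + (p.mu / bmg)),
        gamma=-(p.m0 * p.gamma / bmg),
    )


def sensitivity_indices_numeric(params: ModelParams, rel_step: float = 1e-6) -> SensitivityIndices:
    """Central-difference counterpart of :func:`sensitivity_indices`."""
    r0 = reproduction_number(params)

    def one(name: str) -> float:
        x = getattr(params, name)
        rp = reproduction_number(params.replace(**{name: x * (1 + rel_step)}))
        rm = reproduction_number(params.replace(**{name: x * (1 - rel_step)}))
        return (rp - rm) / (2 * rel_step * r0)

    return SensitivityIndices(
        alpha=one("alpha"),
        c=one("c"),
        beta=one("beta"),
        m0=one("m0"),
        mu=one("mu"),
        gamma=one("gamma"),
    )


def c_threshold(params: ModelParams) -> float:
    """Threshold half-saturation constant below which piracy dies out.

    Returns ``math.inf`` when no finite threshold exists (the piracy-free
    state then prevails for every c, e.g. whenever alpha <= mu).
    """
    p = params
    denom = (p.alpha - p.mu) - (p.alpha * p.m0 * p.gamma) / (p.beta + p.mu + p.m0 * p.gamma)
    if p.alpha <= p.mu or denom <= 0:
        return math.inf
    return p.m0 * p.mu / denom


def m0_threshold(params: ModelParams) -> float:
    """Intrinsic-awareness threshold above which piracy is eliminated.

    Positive root of mu*gamma*m0^2 + mu*(beta+mu+c*gamma)*m0
    + c*(beta+mu)*(mu-alpha) = 0.  When alpha <= mu both roots are
    non-positive and piracy-free holds for every m0 > 0, so 0 is returned.
    """
    p = params
    if p.alpha <= p.mu:
        return 0.0
    A = p.mu * p.gamma
    B = p.mu * (p.beta + p.mu + p.c * p.gamma)
    C = p.c * (p.beta + p.mu) * (p.mu - p.alpha)
    disc = B * B - 4 * A * C
    return (-B + math.sqrt(disc)) / (2 * A)


def bifurcation_scan(
    base: ModelParams,
    values: Sequence[float] | np.ndarray,
    param: str = "alpha",
) -> pd.DataFrame:
    """Sweep one parameter and tabulate equilibria against R_m.

    Returns a frame with one row per (grid point, equilibrium branch),
    columns ``swept_value, R_m, branch, b_star, stable``, sorted by R_m.
    A forward transcritical bifurcation shows up as the endemic branch
    appearing exactly where R_m crosses 1.
    """
    if param not in PARAM_FIELDS:
        raise ValueError(f"unknown parameter {param!r}; expected one of {PARAM_FIELDS}")
    rows = []
    for v in values:
        p = base.replace(**{param: float(v)})
        rm = reproduction_number(p)
        for eq in steady_states(p):
            rows.append(
                {
                    "swept_value": float(v),
                    "R_m": rm,
                    "branch": eq.kind,
                    "b_star": eq.state.b,
                    "stable": eq.stable,
                }
            )
    return pd.DataFrame(rows).sort_values(["R_m", "branch"], kind="stable").reset_index(drop=True)
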