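"""Stochastic agent-based U-B-A dynamics on explicit graphs.

Discrete-time scheme: per step of length dt each node fires its transitions
with exponential probabilities 1 - exp(-rate * dt) computed from the state
at the start of the step, matching the degree-block rates to first order in
dt.  Demographic turnover replaces a node in place by a fresh Unaware node,
keeping the topology fixed.  The media level is shared by all nodes and is
advanced by the exact solution of its linear ODE over each step.

Two contact models are available.  With ``contact="annealed"`` (default) a
node of degree k sees k * psi effective neighbours of each class, where psi
is the degree-weighted population fraction; this is the stochastic
counterpart of the degree-block mean field and reproduces its steady state.
With ``contact="quenched"`` transition rates use the node's actual
neighbour counts on the fixed graph; dynamic pair correlations then
depress transmission and the steady state departs visibly from the mean
field (several percent in the class fractions for typical parameters).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .degree_block import DegreeDistribution
from .homogeneous import ModelParams

__all__ = [
    "U", "B", "A",
    "Graph",
    "AgentTrajectory",
    "EnsembleSummary",
    "PeakAnalysis",
    "generate_er",
    "generate_ba",
    "read_edge_list",
    "write_edge_list",
    "simulate_agents",
    "simulate_ensemble",
    "degree_stratified_summary",
    "ensemble_summary",
    "media_peak_analysis",
]

logger = logging.getLogger(__name__)

U, B, A = 0, 1, 2  # node labels
MAX_STEP_PROBABILITY = 0.1


@dataclass
class Graph:
    """Undirected simple graph with CSR adjacency for fast neighbour counts."""

    n: int
    edges: np.ndarray          # (E, 2) with u < v, deduplicated
    adjacency: sp.csr_matrix   # symmetric 0/1
    degrees: np.ndarray

    @classmethod
    def from_edges(cls, n: int, edges: np.ndarray | Sequence[tuple[int, int]]) -> "Graph":
        edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
        n_loops = int((edges[:, 0] == edges[:, 1]).sum()) if edges.size else 0
        if n_loops:
            logger.warning("dropped %d self-loops", n_loops)
            edges = edges[edges[:, 0] != edges[:, 1]]
        if edges.size:
            edges = np.sort(edges, axis=1)
            edges = np.unique(edges, axis=0)
        if edges.size and (edges.min() < 0 or edges.max() >= n):
            raise ValueError("edge endpoints outside 0..n-1")
        if edges.size:
            rows = np.concatenate([edges[:, 0], edges[:, 1]])
            cols = np.concatenate([edges[:, 1], edges[:, 0]])
            adj = sp.csr_matrix(
                (np.ones(rows.size, dtype=np.int8), (rows, cols)), shape=(n, n)
            )
        else:
            adj = sp.csr_matrix((n, n), dtype=np.int8)
        degrees = np.asarray(adj.sum(axis=1)).ravel().astype(np.int64)
        return cls(n=n, edges=edges, adjacency=adj, degrees=degrees)

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "Graph":
        mapping = {node: i for i, node in enumerate(sorted(g.nodes()))}
        edges = np.array([(mapping[u], mapping[v]) for u, v in g.edges()], dtype=np.int64)
        return cls.from_edges(len(mapping), edges.reshape(-1, 2))

    @property
    def n_edges(self) -> int:
        return int(self.edges.shape[0])

    @property
    def mean_degree(self) -> float:
        return float(self.degrees.mean())

    def degree_distribution(self) -> DegreeDistribution:
        return DegreeDistribution.from_degrees(self.degrees)


def generate_er(n: int, mean_degree: float, seed: int | None = None) -> Graph:
    """Erdos-Renyi G(n, M) graph with M = round(n * mean_degree / 2) edges."""
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if mean_degree <= 0 or mean_degree >= n:
        raise ValueError(f"mean degree {mean_degree} infeasible for n={n}")
    m = int(round(n * mean_degree / 2))
    if m > n * (n - 1) // 2:
        raise ValueError("requested density exceeds the complete graph")
    return Graph.from_networkx(nx.gnm_random_graph(n, m, seed=seed))


def generate_ba(n: int, links_per_node: int, seed: int | None = None) -> Graph:
    """Barabasi-Albert preferential-attachment graph."""
    if n < 2 or links_per_node < 1 or links_per_node >= n:
        raise ValueError(f"infeasible BA parameters n={n}, m={links_per_node}")
    return Graph.from_networkx(nx.barabasi_albert_graph(n, links_per_node, seed=seed))


def read_edge_list(path: str | Path) -> Graph:
    """Read a KONECT-dialect edge list: lines of "u v", `%`/`#` comments.

    Node ids are compacted to 0..n-1 (1-based files are detected by their
    minimum id); duplicate, reversed and self-loop edges are collapsed.
    """
    path = Path(path)
    pairs: list[tuple[int, int]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("%") or line.startswith("#"):
                continue
            tokens = line.split()
            try:
                u, v = int(tokens[0]), int(tokens[1])
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: cannot parse edge from {line!r}") from exc
            pairs.append((u, v))
    if not pairs:
        raise ValueError(f"{path}: no edges found")
    arr = np.asarray(pairs, dtype=np.int64)
    ids = np.unique(arr)
    remap = {int(old): new for new, old in enumerate(ids)}
    arr = np.vectorize(remap.__getitem__)(arr)
    return Graph.from_edges(len(ids), arr)


def write_edge_list(graph: Graph, path: str | Path) -> None:
    """Write the graph as a 1-based KONECT-style edge list."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("% sym unweighted\n")
        for u, v in graph.edges:
            fh.write(f"{u + 1} {v + 1}\n")


@dataclass
class AgentTrajectory:
    """Recorded snapshots of an agent simulation.

    ``labels`` holds the per-node label (0=U, 1=B, 2=A) at each recorded
    time; ``u``, ``b``, ``a`` are the corresponding population fractions.
    """

    t: np.ndarray
    u: np.ndarray
    b: np.ndarray
    a: np.ndarray
    m: np.ndarray
    labels: np.ndarray  # (n_records, n) int8
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "u": self.u, "b": self.b, "a": self.a, "m": self.m})


def _check_dt(params: ModelParams, dt: float) -> None:
    # characteristic homogeneous-equivalent rates; the exponential form keeps
    # probabilities valid regardless, but large dt degrades accuracy
    r_max = max(
        params.mu,
        params.beta,
        params.alpha,
        params.rho,
        params.gamma * (params.m0 + params.z),
    )
    p = 1.0 - math.exp(-r_max * dt)
    if p >= MAX_STEP_PROBABILITY:
        raise ValueError(
            f"dt={dt} gives a per-step probability {p:.3f} >= {MAX_STEP_PROBABILITY} "
            f"for the fastest rate {r_max:.3g}; reduce dt below "
            f"{-math.log(1 - MAX_STEP_PROBABILITY) / r_max:.3g}"
        )


def simulate_agents(
    graph: Graph,
    params: ModelParams,
    init_fractions: Sequence[float] = (0.9, 0.1, 0.0),
    t_end: float = 1000.0,
    dt: float = 0.05,
    seed: int | None = None,
    record_dt: float = 0.5,
    alpha_n: float | None = None,
    rho_n: float | None = None,
    contact: str = "annealed",
) -> AgentTrajectory:
    """Run one stochastic realisation of the agent model on ``graph``.

    ``init_fractions`` is (u0, b0[, a0]) with sum <= 1; any deficit goes to
    the aware class.  Labels are assigned i.i.d. per node.  Per-contact rates
    default to alpha / <k> and rho / <k> on the realised graph.  See the
    module docstring for the ``contact`` models.
    """
    p = params
    if contact not in ("annealed", "quenched"):
        raise ValueError(f"unknown contact model {contact!r}")
    _check_dt(p, dt)
    vals = list(init_fractions)
    if len(vals) == 2:
        vals.append(0.0)
    u0, b0, a0 = vals
    total = u0 + b0 + a0
    if total > 1 + 1e-9 or min(u0, b0, a0) < 0:
        raise ValueError(f"invalid initial fractions {init_fractions}")
    a0 += max(0.0, 1.0 - total)

    if alpha_n is None:
        alpha_n = p.alpha / graph.mean_degree
    if rho_n is None:
        rho_n = p.rho / graph.mean_degree

    rng = np.random.default_rng(seed)
    n = graph.n
    labels = rng.choice(3, size=n, p=[u0, b0, a0]).astype(np.int8)
    adj = graph.adjacency
    m = p.m0
    z = p.z

    n_steps = int(round(t_end / dt))
    record_every = max(1, int(round(record_dt / dt)))
    n_records = n_steps // record_every + 1
    rec_t = np.empty(n_records)
    rec_labels = np.empty((n_records, n), dtype=np.int8)
    rec_m = np.empty(n_records)

    p_relapse = 1.0 - math.exp(-p.beta * dt)
    p_turnover = 1.0 - math.exp(-p.mu * dt)
    exp_phi0 = math.exp(-p.phi0 * dt)

    rec = 0
    rec_t[rec] = 0.0
    rec_labels[rec] = labels
    rec_m[rec] = m
    rec += 1

    deg = graph.degrees.astype(np.float64)
    deg_total = deg.sum()

    for step in range(1, n_steps + 1):
        is_b = (labels == B).astype(np.int8)
        is_a = (labels == A).astype(np.int8)
        theta = m / (p.c + m)

        if contact == "quenched":
            nb_b = adj @ is_b  # bootlegger neighbours per node
            nb_a = adj @ is_a
        else:
            # annealed: expected neighbour counts k_i * psi_x
            nb_b = deg * (deg @ is_b / deg_total)
            nb_a = deg * (deg @ is_a / deg_total)

        rand = rng.random(n)
        p_infect = -np.expm1(-alpha_n * (1.0 - theta) * nb_b * dt)
        p_quit = -np.expm1(-(rho_n * nb_a + p.gamma * m) * dt)

        new_labels = labels.copy()
        new_labels[(labels == U) & (rand < p_infect)] = B
        new_labels[(labels == B) & (rand < p_quit)] = A
        new_labels[(labels == A) & (rand < p_relapse)] = B
        # demographic turnover: replaced in place by a fresh Unaware node
        new_labels[rng.random(n) < p_turnover] = U
        labels = new_labels

        # exact update of dm/dt = phi*b - phi0*(m - m0) with b held constant
        b_frac = float((labels == B).mean())
        m_inf = p.m0 + z * b_frac
        m = m_inf + (m - m_inf) * exp_phi0

        if step % record_every == 0:
            rec_t[rec] = step * dt
            rec_labels[rec] = labels
            rec_m[rec] = m
            rec += 1

    rec_t = rec_t[:rec]
    rec_labels = rec_labels[:rec]
    rec_m = rec_m[:rec]
    return AgentTrajectory(
        t=rec_t,
        u=(rec_labels == U).mean(axis=1),
        b=(rec_labels == B).mean(axis=1),
        a=(rec_labels == A).mean(axis=1),
        m=rec_m,
        labels=rec_labels,
        seed=seed,
    )


def simulate_ensemble(
    graph: Graph,
    params: ModelParams,
    replicates: int = 10,
    seed: int | None = None,
    **kwargs,
) -> list[AgentTrajectory]:
    """Run seeded replicate simulations (seeds split from a single seed)."""
    seeds = np.random.SeedSequence(seed).generate_state(replicates)
    return [simulate_agents(graph, params, seed=int(s), **kwargs) for s in seeds]


def degree_stratified_summary(
    trajectory: AgentTrajectory,
    graph: Graph,
    burn_in: float,
) -> pd.DataFrame:
    """Time-averaged per-degree class fractions and neighbour composition.

    Averages all recorded snapshots with t >= burn_in.  Returns one row per
    populated degree with columns k, n_nodes, u, b, a and the mean fractions
    of each class among neighbours (nb_u, nb_b, nb_a).  Degrees with zero
    nodes are omitted; isolated nodes have no neighbour composition and are
    excluded from the nb_* averages.
    """
    keep = trajectory.t >= burn_in
    if not keep.any():
        raise ValueError(f"no snapshots at or after burn_in={burn_in}")
    labels = trajectory.labels[keep]
    n_snap = labels.shape[0]
    deg = graph.degrees
    adj = graph.adjacency
    n = graph.n

    occ = np.zeros((3, n))
    nb = np.zeros((3, n))
    for snap in labels:
        for cls in (U, B, A):
            ind = (snap == cls).astype(np.float64)
            occ[cls] += ind
            nb[cls] += adj @ ind
    occ /= n_snap
    with np.errstate(invalid="ignore", divide="ignore"):
        nb = nb / n_snap / np.where(deg > 0, deg, np.nan)

    rows = []
    for k in np.unique(deg):
        mask = deg == k
        row = {
            "k": int(k),
            "n_nodes": int(mask.sum()),
            "u": occ[U, mask].mean(),
            "b": occ[B, mask].mean(),
            "a": occ[A, mask].mean(),
        }
        if k > 0:
            row["nb_u"] = np.nanmean(nb[U, mask])
            row["nb_b"] = np.nanmean(nb[B, mask])
            row["nb_a"] = np.nanmean(nb[A, mask])
        else:
            row["nb_u"] = row["nb_b"] = row["nb_a"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class EnsembleSummary:
    """Per-time replicate statistics and (optional) per-degree averages."""

    time: pd.DataFrame
    by_degree: pd.DataFrame | None = None


def ensemble_summary(
    trajectories: Sequence[AgentTrajectory],
    graph: Graph | None = None,
    burn_in: float | None = None,
) -> EnsembleSummary:
    """Mean and sd of fractions/media over replicates at each recorded time."""
    if not trajectories:
        raise ValueError("need at least one trajectory")
    t = trajectories[0].t
    for traj in trajectories[1:]:
        if not np.array_equal(traj.t, t):
            raise ValueError("trajectories have mismatched time grids")
    data = {"t": t}
    for name in ("u", "b", "a", "m"):
        stack = np.stack([getattr(traj, name) for traj in trajectories])
        data[f"{name}_mean"] = stack.mean(axis=0)
        data[f"{name}_sd"] = stack.std(axis=0, ddof=0)
    by_degree = None
    if graph is not None and burn_in is not None:
        frames = [degree_stratified_summary(traj, graph, burn_in) for traj in trajectories]
        by_degree = (
            pd.concat(frames).groupby(["k", "n_nodes"], as_index=False).mean()
        )
    return EnsembleSummary(time=pd.DataFrame(data), by_degree=by_degree)


@dataclass
class PeakAnalysis:
    """Timing of the media and bootlegger maxima along one trajectory."""

    t_peak_m: float | None
    t_peak_b: float | None
    has_media_peak: bool
    has_b_peak: bool

    @property
    def b_peak_before_media_peak(self) -> bool | None:
        if self.t_peak_m is None or self.t_peak_b is None:
            return None
        return self.t_peak_b <= self.t_peak_m


def _interior_peak(t: np.ndarray, y: np.ndarray, rel_tol: float = 1e-9) -> float | None:
    span = y.max() - y.min()
    if span <= 1e-6 * max(1.0, np.abs(y).max()):
        return None  # flat series: no meaningful peak
    idx = int(np.argmax(y))
    if idx == 0 or idx == len(y) - 1:
        return None
    if (y[idx] - y[0]) / span < rel_tol or (y[idx] - y[-1]) / span < rel_tol:
        return None
    return float(t[idx])


def media_peak_analysis(trajectory) -> PeakAnalysis:
    """Locate the media and bootlegger maxima; monotone series get a no-peak flag.

    Accepts any trajectory object exposing arrays ``t``, ``b`` and ``m``
    (agent, homogeneous or aggregated degree-block).
    """
    t = np.asarray(trajectory.t, dtype=float)
    b = np.asarray(trajectory.b, dtype=float)
    m = np.asarray(trajectory.m, dtype=float)
    t_m = _interior_peak(t, m)
    t_b = _interior_peak(t, b)
    return PeakAnalysis(
        t_peak_m=t_m,
        t_peak_b=t_b,
        has_media_peak=t_m is not None,
        has_b_peak=t_b is not None,
    )
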