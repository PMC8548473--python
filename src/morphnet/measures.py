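"""Node- and network-level measures over bipartite network series.

Three measures drive the analysis:

* **degree** of node *j*: the row/column sum of the adjacency,
  ``C_D(j) = sum_i A_ij`` - in binary mode the number of distinct
  partners a construct combines with;
* **eigenvector centrality** ``x``: the nonnegative leading eigenvector
  of the full symmetrized adjacency, ``A x = lambda x``, normalized to
  unit Euclidean norm;
* **density** ``d = m / (n (n - 1) / 2)``: realized links over possible
  links.  The unipartite denominator is the default for fidelity to the
  printed formula even though the graph is bipartite; the bipartite
  maximum ``|roots| * |patterns|`` is available as an option.

Undefined measures (empty or singleton networks) propagate as missing
values, never as silent zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .networks import BipartiteNetwork, NetworkSeries


class UndefinedMeasureError(ValueError):
    """Raised when a measure is requested on a network where it is undefined."""


class CentralityConvergenceError(RuntimeError):
    """Power iteration failed to converge; carries iterations and residual."""

    def __init__(self, iterations: int, residual: float):
        self.iterations = iterations
        self.residual = residual
        super().__init__(
            f"power iteration did not converge in {iterations} iterations "
            f"(residual {residual:.3e})"
        )


@dataclass
class CentralityResult:
    """Per-node eigenvector centralities plus the leading eigenvalue."""

    centrality: dict[str, float]
    eigenvalue: float
    iterations: int
    converged: bool
    residual: float


def node_degree(network: BipartiteNetwork) -> dict[str, float]:
    """Degree of every active node (distinct partners in binary mode)."""
    if network.is_empty:
        raise UndefinedMeasureError(
            f"degree undefined on empty network "
            f"({network.dyad_id}, {network.speaker}, session {network.session_index})"
        )
    deg: dict[str, float] = {node: 0.0 for node in network.nodes}
    for (r, p), w in network.edges.items():
        weight = float(w) if network.mode == "weighted" else 1.0
        deg[r] += weight
        deg[p] += weight
    return deg


def eigenvector_centrality(
    network: BipartiteNetwork,
    tol: float = 1e-10,
    max_iter: int = 10000,
    per_component: bool = False,
) -> CentralityResult:
    """Leading-eigenvector centrality by shifted power iteration.

    Iterates ``x <- (A + I) x`` from a uniform positive start; the shift
    leaves the leading eigenvector unchanged while suppressing the -lambda
    branch of the (bipartite, hence symmetric) spectrum that would make
    plain power iteration oscillate.  On disconnected networks mass
    concentrates on the component with the largest eigenvalue (other
    components go to ~0) unless ``per_component`` renormalizes each
    connected component separately.
    """
    if network.m < 1:
        raise UndefinedMeasureError("centrality undefined on a network with no links")
    A, nodes = network.full_adjacency()
    if per_component:
        comp_vals = _per_component_centrality(network, A, nodes, tol, max_iter)
        return comp_vals
    x, lam, its, res = _power_iterate(A, tol, max_iter)
    return CentralityResult(
        centrality=dict(zip(nodes, x.tolist())),
        eigenvalue=float(lam),
        iterations=its,
        converged=True,
        residual=float(res),
    )


def _power_iterate(A: np.ndarray, tol: float, max_iter: int):
    n = A.shape[0]
    x = np.full(n, 1.0 / math.sqrt(n))
    shifted = A + np.eye(n)
    for it in range(1, max_iter + 1):
        y = shifted @ x
        nrm = np.linalg.norm(y)
        if nrm == 0:  # pragma: no cover - impossible with >=1 link
            raise CentralityConvergenceError(it, math.inf)
        y /= nrm
        delta = float(np.max(np.abs(y - x)))
        x = y
        if delta < tol:
            lam = float(x @ (A @ x))
            res = float(np.max(np.abs(A @ x - lam * x)))
            return x, lam, it, res
    lam = float(x @ (A @ x))
    res = float(np.max(np.abs(A @ x - lam * x)))
    raise CentralityConvergenceError(max_iter, res)


def _per_component_centrality(network, A, nodes, tol, max_iter) -> CentralityResult:
    import networkx as nx

    G = network.to_networkx()
    cent: dict[str, float] = {}
    idx = {node: i for i, node in enumerate(nodes)}
    lam_max, its_tot, res_max = 0.0, 0, 0.0
    for comp in nx.connected_components(G):
        comp = sorted(comp)
        sub = A[np.ix_([idx[c] for c in comp], [idx[c] for c in comp])]
        x, lam, its, res = _power_iterate(sub, tol, max_iter)
        cent.update(dict(zip(comp, x.tolist())))
        lam_max = max(lam_max, lam)
        its_tot += its
        res_max = max(res_max, res)
    return CentralityResult(cent, lam_max, its_tot, True, res_max)


def network_density(network: BipartiteNetwork, denominator_mode: str = "unipartite") -> float:
    """Network density; NaN (undefined) when the network has fewer than 2 nodes.

    ``denominator_mode="unipartite"`` uses the unipartite maximum
    ``n (n - 1) / 2``; ``"bipartite"`` uses ``|roots| * |patterns|``.
    """
    if denominator_mode not in ("unipartite", "bipartite"):
        raise ValueError(f"unknown denominator_mode {denominator_mode!r}")
    n = network.n
    if n < 2:
        return math.nan
    if denominator_mode == "unipartite":
        return network.m / (n * (n - 1) / 2)
    return network.m / (len(network.root_nodes) * len(network.pattern_nodes))


@dataclass
class ActivationTable:
    """Boolean node-by-session activity matrix plus per-node run statistics.

    A *run* is a maximal stretch of consecutive sessions in which a node
    is active; gaps are counted between a node's first and last active
    session.  Many short runs per node quantify punctuated usage.
    """

    dyad_id: str
    speaker: str
    activity: pd.DataFrame  # index: node label, columns: session_index (bool)
    stats: pd.DataFrame  # index: node label; n_runs, n_gaps, mean_gap_length, ...

    @property
    def mean_runs_per_node(self) -> float:
        return float(self.stats["n_runs"].mean())


def _run_stats(active: np.ndarray) -> tuple[int, int, float]:
    """(n_runs, n_gaps, mean gap length) for one boolean activity row."""
    on = np.flatnonzero(active)
    if on.size == 0:
        return 0, 0, math.nan
    span = active[on[0] : on[-1] + 1]
    switches = np.diff(span.astype(int))
    n_runs = 1 + int(np.sum(switches == 1))
    gaps_total = int(np.sum(~span))
    n_gaps = n_runs - 1
    mean_gap = gaps_total / n_gaps if n_gaps else 0.0
    return n_runs, n_gaps, mean_gap


def activation_timeline(series: NetworkSeries, speaker: str) -> ActivationTable:
    """Activity matrix and run/gap statistics for one participant."""
    sessions = series.sessions
    nodes = sorted(
        {
            node
            for sess in sessions
            for node in series.get(sess, speaker).nodes
        }
    )
    if not nodes:
        raise UndefinedMeasureError(f"no active nodes for speaker {speaker!r}")
    act = np.zeros((len(nodes), len(sessions)), dtype=bool)
    idx = {node: i for i, node in enumerate(nodes)}
    for j, sess in enumerate(sessions):
        for node in series.get(sess, speaker).nodes:
            act[idx[node], j] = True
    activity = pd.DataFrame(act, index=nodes, columns=sessions)
    stats = pd.DataFrame(
        [_run_stats(row) for row in act],
        index=nodes,
        columns=["n_runs", "n_gaps", "mean_gap_length"],
    )
    stats["n_active_sessions"] = act.sum(axis=1)
    stats["onset"] = [sessions[np.flatnonzero(r)[0]] for r in act]
    stats["offset"] = [sessions[np.flatnonzero(r)[-1]] for r in act]
    return ActivationTable(series.dyad_id, speaker, activity, stats)


def measure_table(
    series: NetworkSeries,
    include_centrality: bool = True,
    density_mode: str = "unipartite",
    tol: float = 1e-10,
    max_iter: int = 10000,
) -> pd.DataFrame:
    """Long table of per-node degree/centrality and per-session density.

    One node-level row per active (node, session, speaker) plus one
    network-level density row per (session, speaker).  Empty strata
    contribute a flagged network-level row with missing density and no
    node rows.  ``include_centrality=False`` skips the eigensolver and
    leaves the centrality column missing (useful for density-only
    pipelines).
    """
    rows: list[dict] = []
    for sess in series.sessions:
        for speaker in series.speakers:
            net = series.get(sess, speaker)
            dens = math.nan if net.is_empty else network_density(net, density_mode)
            rows.append(
                {
                    "dyad_id": series.dyad_id,
                    "session_index": sess,
                    "age_days": net.age_days if net.age_days else series.ages[sess],
                    "speaker": speaker,
                    "level": "network",
                    "node": "",
                    "degree": math.nan,
                    "centrality": math.nan,
                    "density": dens,
                    "m": net.m,
                    "n": net.n,
                }
            )
            if net.is_empty:
                continue
            deg = node_degree(net)
            if include_centrality and net.m >= 1:
                cent = eigenvector_centrality(net, tol=tol, max_iter=max_iter).centrality
            else:
                cent = {}
            for node in net.nodes:
                rows.append(
                    {
                        "dyad_id": series.dyad_id,
                        "session_index": sess,
                        "age_days": net.age_days,
                        "speaker": speaker,
                        "level": "node",
                        "node": node,
                        "degree": deg[node],
                        "centrality": cent.get(node, math.nan),
                        "density": math.nan,
                        "m": net.m,
                        "n": net.n,
                    }
                )
    return pd.DataFrame(rows)
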