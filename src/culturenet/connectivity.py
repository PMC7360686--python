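"""Delayed-synchrony functional connectivity and hub analysis.

For every ordered electrode pair (i presynaptic, j postsynaptic) the
connection strength is the proportion of transmitted spikes

    C_ij = n_synchr,ij / n_j

where ``n_synchr,ij`` counts the spikes of j that follow a spike of i at
an axonal delay tau within a coincidence window [tau - delta/2,
tau + delta/2], and ``n_j`` is the number of spikes received by the
postsynaptic electrode.  The window is half-open, [tau - delta/2,
tau + delta/2), so a lag sitting exactly on a window edge belongs to
exactly one candidate delay.  Each postsynaptic spike is matched at
most once per delay, so C_ij is a proportion in [0, 1].  The delay is not
known a priori: a grid of candidate delays is scanned and the maximum
over the grid is kept, together with the best delay.

Edges are then selected as the largest 5% of the C_ij coefficients over
ordered off-diagonal pairs, node degree counts appearances of an
electrode in the selected edge set (in + out), and hubs are nodes with
at least 10 significant connections.  The functional graph carries the
selected edges with weight C_ij and best delay, retaining isolated
nodes; vertex size in the rendered figure is proportional to degree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .io import SpikeRaster

__all__ = [
    "DelayParams",
    "count_delayed_synchronous",
    "cross_correlation_matrix",
    "select_edges",
    "hub_analysis",
    "build_graph",
    "DelayedSynchronyModel",
    "ConnectivityResults",
]

DEFAULT_TAU_GRID_S = tuple(np.arange(1, 21) * 1e-3)  # 1..20 ms step 1 ms
DEFAULT_DELTA_S = 2e-3
DEFAULT_EDGE_FRACTION = 0.05
DEFAULT_HUB_MIN_CONNECTIONS = 10


@dataclass
class DelayParams:
    """Candidate axonal delays and the coincidence window width.

    ``tau_grid_s`` is the grid of candidate delays tau (default 1-20 ms
    in 1-ms steps, appropriate for a 200-um electrode pitch);
    ``delta_s`` is the full window width delta, so each candidate
    window is [tau - delta/2, tau + delta/2].
    """

    tau_grid_s: Sequence[float] = DEFAULT_TAU_GRID_S
    delta_s: float = DEFAULT_DELTA_S

    def __post_init__(self) -> None:
        taus = np.asarray(self.tau_grid_s, dtype=float)
        if taus.size == 0 or np.any(taus <= 0):
            raise ValueError("tau grid must be non-empty with all tau > 0")
        if self.delta_s <= 0:
            raise ValueError("delta_s must be positive")
        self.tau_grid_s = np.sort(taus)


def count_delayed_synchronous(
    pre_times: np.ndarray,
    post_times: np.ndarray,
    tau_s: float,
    delta_s: float,
) -> int:
    """Number of post spikes with >= 1 pre spike in their delay window.

    A post spike at t_j is matched iff some pre spike t_i satisfies
    ``tau - delta/2 <= t_j - t_i < tau + delta/2``; each post spike is
    counted at most once.
    """
    pre = np.asarray(pre_times, dtype=float)
    post = np.asarray(post_times, dtype=float)
    if pre.size == 0 or post.size == 0:
        return 0
    lo = post - tau_s - delta_s / 2.0
    hi = post - tau_s + delta_s / 2.0
    # lag in [tau - d/2, tau + d/2)  <=>  pre in (post-tau-d/2, post-tau+d/2]
    left = np.searchsorted(pre, lo, side="right")
    right = np.searchsorted(pre, hi, side="right")
    return int(np.count_nonzero(right > left))


def _matched_counts_per_tau(pre: np.ndarray, post: np.ndarray,
                            taus: np.ndarray, delta_s: float) -> np.ndarray:
    """Matched post-spike counts for every tau on the grid (vectorized)."""
    half = delta_s / 2.0
    lo = post[:, None] - taus[None, :] - half
    hi = lo + delta_s
    left = np.searchsorted(pre, lo.ravel(), side="right").reshape(lo.shape)
    right = np.searchsorted(pre, hi.ravel(), side="right").reshape(hi.shape)
    return np.count_nonzero(right > left, axis=0)


def _burst_scope_times(raster: SpikeRaster) -> Dict[str, np.ndarray]:
    """Restrict every electrode's spikes to detected network-burst extents."""
    from .bursts import compute_tsr, detect_network_bursts

    bursts = detect_network_bursts(compute_tsr(raster))
    if not bursts:
        return {eid: np.empty(0) for eid in raster.electrode_ids}
    starts = np.array([b.start_s for b in bursts])
    ends = np.array([b.end_s for b in bursts])
    out = {}
    for eid in raster.electrode_ids:
        t = raster.spike_times[eid]
        if t.size == 0:
            out[eid] = t
            continue
        # inside iff some burst interval [start, end) contains t
        idx = np.searchsorted(starts, t, side="right") - 1
        inside = (idx >= 0) & (t < ends[np.clip(idx, 0, len(ends) - 1)])
        out[eid] = t[inside]
    return out


def cross_correlation_matrix(
    raster: SpikeRaster,
    params: Optional[DelayParams] = None,
    spike_scope: str = "all",
) -> "ConnectivityResults":
    """Compute C_ij over all ordered electrode pairs.

    Returns a :class:`ConnectivityResults` holding the C matrix, the
    best delay per pair, the matched counts ``n_synchr`` at that delay
    and the per-electrode received-spike counts ``n_post``.  Pairs with
    a silent postsynaptic electrode (``n_j = 0``) get C_ij = 0.  Ties
    on the delay grid resolve to the smallest tau.
    """
    if raster.n_electrodes < 2:
        raise ValueError("need at least 2 electrodes")
    if spike_scope not in ("all", "burst"):
        raise ValueError("spike_scope must be 'all' or 'burst'")
    params = params or DelayParams()
    taus = np.asarray(params.tau_grid_s)
    ids = list(raster.electrode_ids)
    times = (raster.spike_times if spike_scope == "all"
             else _burst_scope_times(raster))
    n = len(ids)
    c = np.zeros((n, n))
    best_tau = np.zeros((n, n))
    n_synchr = np.zeros((n, n), dtype=int)
    n_post = np.array([len(times[eid]) for eid in ids], dtype=int)

    for j, post_id in enumerate(ids):
        post = times[post_id]
        if post.size == 0:
            continue
        for i, pre_id in enumerate(ids):
            if i == j:
                continue
            pre = times[pre_id]
            if pre.size == 0:
                continue
            counts = _matched_counts_per_tau(pre, post, taus, params.delta_s)
            b = int(np.argmax(counts))  # first max -> smallest tau
            if counts[b] > 0:
                c[i, j] = counts[b] / n_post[j]
                best_tau[i, j] = taus[b]
                n_synchr[i, j] = counts[b]
    return ConnectivityResults(
        electrode_ids=ids, c_matrix=c, best_tau=best_tau,
        n_synchr=n_synchr, n_post=n_post, params=params,
        spike_scope=spike_scope)


def select_edges(result: "ConnectivityResults",
                 fraction: float = DEFAULT_EDGE_FRACTION) -> pd.DataFrame:
    """Select the largest-C edges: ``k = max(1, floor(fraction * M))``
    over the ``M`` ordered off-diagonal pairs.

    Ties at the cutoff break deterministically by higher ``n_synchr``,
    then lexicographic (pre, post) label.  Edges with C_ij = 0 are never
    selected (k shrinks if fewer nonzero coefficients exist).  Returns a
    table with columns pre, post, c, tau, n_synchr, ordered by rank.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    ids = result.electrode_ids
    n = len(ids)
    m = n * (n - 1)
    k = max(1, math.floor(fraction * m))
    rows = []
    for i in range(n):
        for j in range(n):
            if i == j or result.c_matrix[i, j] <= 0:
                continue
            rows.append((ids[i], ids[j], result.c_matrix[i, j],
                         result.best_tau[i, j], int(result.n_synchr[i, j])))
    df = pd.DataFrame(rows, columns=["pre", "post", "c", "tau", "n_synchr"])
    df = df.sort_values(
        by=["c", "n_synchr", "pre", "post"],
        ascending=[False, False, True, True],
        kind="mergesort").reset_index(drop=True)
    return df.head(min(k, len(df)))


def hub_analysis(
    edges: pd.DataFrame,
    all_nodes: Sequence[str],
    hub_min_connections: int = DEFAULT_HUB_MIN_CONNECTIONS,
    fallback_top_n: int = 5,
) -> pd.DataFrame:
    """Per-node significant-connection counts and hub flags.

    A node's connection count is the number of selected edges it appears
    in (in-degree + out-degree); hubs have at least
    ``hub_min_connections`` connections.  The returned table (columns
    electrode_id, n_connections, is_hub) carries
    ``.attrs["mean_hub_connections"]``: the mean connection count over
    hubs, falling back to the ``fallback_top_n`` highest-degree
    connected nodes when no node meets the hub rule, and 0.0 when there
    are no connected nodes at all.
    """
    counts = {str(n): 0 for n in all_nodes}
    for _, row in edges.iterrows():
        counts[str(row["pre"])] = counts.get(str(row["pre"]), 0) + 1
        counts[str(row["post"])] = counts.get(str(row["post"]), 0) + 1
    df = pd.DataFrame(
        {"electrode_id": list(counts.keys()),
         "n_connections": list(counts.values())})
    df["is_hub"] = df["n_connections"] >= hub_min_connections
    hubs = df[df["is_hub"]]
    if len(hubs):
        mean_conn = float(hubs["n_connections"].mean())
    else:
        connected = df[df["n_connections"] > 0]
        if len(connected):
            top = connected.sort_values(
                ["n_connections", "electrode_id"],
                ascending=[False, True]).head(fallback_top_n)
            mean_conn = float(top["n_connections"].mean())
        else:
            mean_conn = 0.0
    df.attrs["mean_hub_connections"] = mean_conn
    df.attrs["hub_min_connections"] = hub_min_connections
    return df


def build_graph(result: "ConnectivityResults",
                edges: Optional[pd.DataFrame] = None) -> nx.DiGraph:
    """Build the functional graph from the selected edge set.

    Every electrode becomes a node (isolated ones retained) with a
    ``degree`` attribute equal to its significant-connection count;
    edges carry ``weight`` (C_ij) and ``tau`` (best delay, seconds).
    """
    if edges is None:
        edges = select_edges(result)
    g = nx.DiGraph()
    for eid in result.electrode_ids:
        g.add_node(str(eid), degree=0)
    for _, row in edges.iterrows():
        g.add_edge(str(row["pre"]), str(row["post"]),
                   weight=float(row["c"]), tau=float(row["tau"]))
    for n in g.nodes:
        g.nodes[n]["degree"] = g.in_degree(n) + g.out_degree(n)
    return g


class DelayedSynchronyModel:
    """Functional-connectivity inference for one spike raster.

    Parameters
    ----------
    raster : SpikeRaster
    params : DelayParams, optional
        Delay grid and coincidence window (default 1-20 ms step 1 ms,
        delta = 2 ms).
    spike_scope : {"all", "burst"}
        Use all spikes (default) or only spikes inside detected
        network bursts.
    edge_fraction : float
        Proportion of ordered pairs selected as significant edges.
    hub_min_connections : int
        Minimum significant connections for a node to count as a hub.
    """

    def __init__(self, raster: SpikeRaster,
                 params: Optional[DelayParams] = None,
                 spike_scope: str = "all",
                 edge_fraction: float = DEFAULT_EDGE_FRACTION,
                 hub_min_connections: int = DEFAULT_HUB_MIN_CONNECTIONS):
        self.raster = raster
        self.params = params or DelayParams()
        self.spike_scope = spike_scope
        self.edge_fraction = edge_fraction
        self.hub_min_connections = hub_min_connections

    def fit(self) -> "ConnectivityResults":
        res = cross_correlation_matrix(self.raster, self.params,
                                       self.spike_scope)
        res._edge_fraction = self.edge_fraction
        res._hub_min = self.hub_min_connections
        return res


@dataclass
class ConnectivityResults:
    """C matrix, best delays, matched counts and derived edge/hub views."""

    electrode_ids: List[str]
    c_matrix: np.ndarray
    best_tau: np.ndarray
    n_synchr: np.ndarray
    n_post: np.ndarray
    params: DelayParams
    spike_scope: str = "all"
    _edge_fraction: float = DEFAULT_EDGE_FRACTION
    _hub_min: int = DEFAULT_HUB_MIN_CONNECTIONS

    def c_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.c_matrix, index=self.electrode_ids,
                            columns=self.electrode_ids)

    def select_edges(self, fraction: Optional[float] = None) -> pd.DataFrame:
        return select_edges(self, fraction if fraction is not None
                            else self._edge_fraction)

    def hub_table(self, edges: Optional[pd.DataFrame] = None,
                  hub_min_connections: Optional[int] = None) -> pd.DataFrame:
        if edges is None:
            edges = self.select_edges()
        return hub_analysis(
            edges, self.electrode_ids,
            hub_min_connections if hub_min_connections is not None
            else self._hub_min)

    def graph(self, edges: Optional[pd.DataFrame] = None) -> nx.DiGraph:
        if edges is None:
            edges = self.select_edges()
        return build_graph(self, edges)

    def summary(self) -> str:
        edges = self.select_edges()
        hubs = self.hub_table(edges)
        n = len(self.electrode_ids)
        lines = [
            "Delayed-synchrony connectivity",
            "=" * 46,
            f"electrodes                   {n:10d}",
            f"ordered pairs                {n * (n - 1):10d}",
            f"selected edges (top {self._edge_fraction:.0%})     "
            f"{len(edges):10d}",
            f"max C_ij                     {self.c_matrix.max():10.3f}",
            f"hubs (>= {self._hub_min} connections)      "
            f"{int(hubs['is_hub'].sum()):10d}",
            f"mean connections per hub     "
            f"{hubs.attrs['mean_hub_connections']:10.2f}",
            f"delay grid                   "
            f"{self.params.tau_grid_s[0] * 1e3:.0f}-"
            f"{self.params.tau_grid_s[-1] * 1e3:.0f} ms, "
            f"delta {self.params.delta_s * 1e3:.1f} ms",
        ]
        return "\n".join(lines)

    def plot_graph(self, ax=None, seed: int = 0):
        """Functional-graph figure: vertex size proportional to degree,
        node labels ``Cell X [n]``."""
        from .plotting import plot_functional_graph
        return plot_functional_graph(self.graph(), ax=ax, seed=seed)
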